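"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator emulates one instrument output of a drug-cyclodextrin-
liposome formulation study, with defaults anchored to the emulated study's
stated conditions: anisotropy titrations over a 0-12 mM host range at five
temperatures (278-318 K in 10 K steps), A_L phase-solubility series up to
14 mM cyclodextrin, 1024-channel/100 ns TCSPC histograms with 10,000 peak
counts, Stern-Volmer series with optional static upward curvature,
first-order release plateaus and triplicate MTT plates.

All randomness flows through ``numpy.random.default_rng(seed)``: a fixed
seed reproduces byte-identical files.  :func:`generate` writes the CSV
schemas of the consuming modules plus a ground-truth JSON sidecar recording
every true parameter, so downstream recovery tests never re-enter truth by
hand.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from . import io as dio
from .binding import Titration, complex_fraction_1to2
from .cytotoxicity import DoseResponse
from .errors import DomainError
from .formulation import ReleaseTrace
from .photophysics import DecayTrace, QuenchSeries
from .solubility import SolubilityDiagram
from .thermodynamics import ThermoResult, predict_K

__all__ = [
    "MEDIUM_PRESETS", "SCENARIOS",
    "make_titration", "make_titration_series", "make_solubility",
    "make_decay", "make_quench", "make_release", "make_dose_response",
    "make_emission_spectrum", "generate",
]

#: Per-medium binding/thermodynamic presets on the scale of the emulated
#: study: citrate (lactone drug, neutral host) binds entropically; PBS
#: (carboxylate, screened charges) enthalpically; water (unscreened
#: repulsion) shows the endothermic/entropy-driven compensation.
MEDIUM_PRESETS = {
    "citrate_pH3.5": {"K_298": 200.0, "dH": 0.0, "dS": 38.6,
                      "r_free": 0.005, "r_inf": 0.047, "tau_ns": 3.7},
    "PBS_pH7.4": {"K_298": 50.0, "dH": -26.2, "dS": -56.1,
                  "r_free": 0.005, "r_inf": 0.057, "tau_ns": 4.2},
    "water_pH7.4": {"K_298": 55.0, "dH": 16.2, "dS": 87.9,
                    "r_free": 0.005, "r_inf": 0.030, "tau_ns": 4.2},
}

_TEMPERATURES = (278.15, 288.15, 298.15, 308.15, 318.15)  # 5-45 C, 10 C steps


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_titration(K=200.0, r_free=0.005, r_inf=0.047, stoichiometry="1:1",
                   host_max=12e-3, n_points=12, sigma_r=0.001,
                   temperature=298.15, medium="citrate_pH3.5",
                   guest_total=1e-6, seed=0):
    """One anisotropy titration with additive Gaussian noise on r.

    ``K`` is dm^3 mol^-1 for 1:1 and the overall dm^6 mol^-2 constant for
    1:2.  Host grid: ``n_points`` evenly spaced concentrations from 0 to
    ``host_max``.  Returns (Titration, truth dict).
    """
    rng = _rng(seed)
    host = np.linspace(0.0, host_max, n_points)
    if stoichiometry == "1:1":
        f = K * host / (1.0 + K * host)
    elif stoichiometry == "1:2":
        f = complex_fraction_1to2(K, host)
    else:
        raise DomainError("stoichiometry must be '1:1' or '1:2'")
    r = r_free + (r_inf - r_free) * f
    if sigma_r > 0:
        r = r + rng.normal(0.0, sigma_r, size=r.shape)
    r = np.clip(r, -0.199, 0.4)
    t = Titration(host_conc=host, r_obs=r, temperature=temperature,
                  medium=medium, guest_total=guest_total)
    truth = {"K": K, "r_free": r_free, "r_inf": r_inf,
             "stoichiometry": stoichiometry, "sigma_r": sigma_r,
             "temperature_K": temperature, "medium": medium}
    return t, truth


def make_titration_series(medium="PBS_pH7.4", temperatures=_TEMPERATURES,
                          sigma_r=0.001, host_max=12e-3, n_points=12,
                          guest_total=1e-6, seed=0):
    """Titrations at several temperatures with K(T) from van't Hoff.

    K at each temperature derives from the medium preset's (dH, dS), so the
    downstream isotherm -> van't Hoff chain is exercised end to end.
    Returns (list of Titration, truth dict).
    """
    rng = _rng(seed)
    preset = MEDIUM_PRESETS[medium]
    thermo = ThermoResult(dH=preset["dH"], dS=preset["dS"], n_temperatures=2)
    titrations = []
    K_true = {}
    for T in temperatures:
        K_T = predict_K(thermo, T)
        K_true[T] = K_T
        t, _ = make_titration(K=K_T, r_free=preset["r_free"],
                              r_inf=preset["r_inf"], host_max=host_max,
                              n_points=n_points, sigma_r=sigma_r,
                              temperature=T, medium=medium,
                              guest_total=guest_total, seed=rng)
        titrations.append(t)
    truth = {"dH": preset["dH"], "dS": preset["dS"],
             "r_free": preset["r_free"], "r_inf": preset["r_inf"],
             "K_by_T": {str(T): K for T, K in K_true.items()},
             "sigma_r": sigma_r, "medium": medium}
    return titrations, truth


def make_solubility(K=54.0, S0=7.7e-6, cd_max=14e-3, n_points=8,
                    sigma_frac=0.02, curvature=0.0, temperature=298.15,
                    pH=7.4, seed=0):
    """A-type phase-solubility diagram generated from (K, S0).

    The A_L slope follows from the 1:1 model, slope = K S0 / (1 + K S0);
    ``curvature`` adds a quadratic term (mol dm^-3 per M^2) for A_P/A_N
    scenarios.  Multiplicative Gaussian noise of relative size
    ``sigma_frac`` emulates the ~2% concentration uncertainty of volumetric
    sample preparation.  Returns (SolubilityDiagram, truth dict).
    """
    rng = _rng(seed)
    cd = np.linspace(0.0, cd_max, n_points)
    slope = K * S0 / (1.0 + K * S0)
    drug = S0 + slope * cd + curvature * cd * cd
    if sigma_frac > 0:
        drug = drug * (1.0 + rng.normal(0.0, sigma_frac, size=drug.shape))
        drug = np.maximum(drug, 1e-12)
        drug[0] = S0  # intercept is a separately equilibrated saturation point
    d = SolubilityDiagram(cd_conc=cd, drug_total=drug,
                          temperature=temperature, pH=pH)
    truth = {"K": K, "S0": S0, "slope": slope, "curvature": curvature,
             "sigma_frac": sigma_frac, "pH": pH}
    return d, truth


def make_decay(lifetimes=(4.2,), amplitudes=(1.0,), peak_counts=10000,
               n_channels=1024, window_ns=100.0, background=5.0,
               poisson=True, seed=0):
    """TCSPC histogram: Poisson counts around a multi-exponential mean.

    The mean is scaled so the peak channel expects ``peak_counts`` counts
    (the usual stop criterion of a photon-counting acquisition).  With
    ``poisson=False`` the rounded noiseless mean is returned.
    Returns (DecayTrace, truth dict).
    """
    rng = _rng(seed)
    taus = np.asarray(lifetimes, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    t = np.linspace(0.0, window_ns, n_channels, endpoint=False)
    mean = np.zeros_like(t)
    for a, tau in zip(amps, taus):
        mean += a * np.exp(-t / tau)
    mean = mean / mean.max() * (peak_counts - background) + background
    counts = rng.poisson(mean) if poisson else np.round(mean)
    trace = DecayTrace(channel_time=t, counts=counts.astype(float))
    truth = {"lifetimes_ns": taus.tolist(), "amplitudes": amps.tolist(),
             "peak_counts": peak_counts, "background": background,
             "poisson": poisson}
    return trace, truth


def make_quench(K_SV=120.0, tau0=4.2, static_beta=0.0, q_max=0.05,
                n_points=12, sigma_frac=0.005, lifetime_ratios=True, seed=0):
    """Stern-Volmer series with an optional static upward curvature.

    Intensity ratios follow ``1 + K_SV q + beta q^2``: the quadratic term
    (dm^6 mol^-2) emulates the static/ground-state-association contribution
    that bends intensity plots upward at high [Q] while leaving the initial
    slope — the dynamic constant — untouched.  Lifetime ratios stay purely
    dynamic, ``1 + K_SV q``.  The quencher grid is a zero point plus
    geometrically spaced concentrations (dense at low [Q], where the
    linear-region analysis lives).  Returns (QuenchSeries, truth dict).
    """
    rng = _rng(seed)
    q = np.concatenate([[0.0], np.geomspace(q_max / 50.0, q_max,
                                            n_points - 1)])
    dyn = 1.0 + K_SV * q
    inten = dyn + static_beta * q * q
    life = dyn.copy()
    if sigma_frac > 0:
        noise_i = rng.normal(0.0, sigma_frac, size=q.shape)
        noise_t = rng.normal(0.0, sigma_frac, size=q.shape)
        noise_i[0] = noise_t[0] = 0.0  # the [Q]=0 point defines the ratios
        inten = inten * (1.0 + noise_i)
        life = life * (1.0 + noise_t)
    s = QuenchSeries(quencher_conc=q, intensity_ratio=inten,
                     lifetime_ratio=life if lifetime_ratios else None,
                     tau0=tau0)
    truth = {"K_SV": K_SV, "tau0_ns": tau0, "static_beta": static_beta,
             "k_q": K_SV / (tau0 * 1e-9), "sigma_frac": sigma_frac}
    return s, truth


def make_release(k=0.0103, plateau_percent=5.5, I0=100.0, times=None,
                 sigma_frac=0.002, pH=3.5, seed=0):
    """First-order release time course reaching a fractional plateau.

    ``plateau_percent`` is the total intensity rise at t -> inf relative to
    I0; ``k`` in min^-1.  With k=0 the trace is flat (a stable formulation
    at physiological pH).  The default 30-point schedule reads every 5 min
    over the first 20 min, every 10 min through the rise to 200 min — where
    an hour-scale release carries most of its kinetic information — and
    every 30 min from 420 to 600 min to pin the plateau; pass ``times``
    (min) for a custom schedule.  Gaussian noise is ``sigma_frac`` of I0.
    Returns (ReleaseTrace, truth dict).
    """
    rng = _rng(seed)
    if times is None:
        t = np.concatenate([np.arange(0.0, 21.0, 5.0),
                            np.arange(30.0, 201.0, 10.0),
                            np.arange(420.0, 601.0, 30.0)])
    else:
        t = np.asarray(times, dtype=float)
    I_inf = I0 * (1.0 + plateau_percent / 100.0)
    y = I_inf - (I_inf - I0) * np.exp(-k * t) if k > 0 else np.full_like(t, I0)
    if sigma_frac > 0:
        y = y + rng.normal(0.0, sigma_frac * I0, size=y.shape)
    trace = ReleaseTrace(time=t, intensity=np.maximum(y, 1e-9), pH=pH)
    truth = {"k_per_min": k, "tau_half_min": math.log(2) / k if k > 0 else None,
             "plateau_percent": plateau_percent, "I0": I0,
             "sigma_frac": sigma_frac, "pH": pH}
    return trace, truth


def make_dose_response(ic50=17e-9, hill=1.5, bottom=5.0, dose_max=150e-9,
                       n_doses=8, n_replicates=3, sigma=5.0,
                       cell_line="BT-474", treatment="free_drug",
                       exposure_h=48.0, seed=0):
    """Triplicate MTT plate: 4PL mean survival plus Gaussian replicate noise.

    Doses: a zero-dose control plus ``n_doses`` log-spaced concentrations up
    to ``dose_max`` (mol dm^-3).  ``sigma`` is the replicate standard
    deviation in survival percentage points.  Returns (DoseResponse, truth).
    """
    rng = _rng(seed)
    doses = np.concatenate([[0.0], np.geomspace(dose_max / 150.0, dose_max,
                                                n_doses)])
    mean = np.where(doses > 0,
                    bottom + (100.0 - bottom)
                    / (1.0 + (np.where(doses > 0, doses, 1.0) / ic50) ** hill),
                    100.0)
    surv = mean[:, None] + rng.normal(0.0, sigma, size=(doses.size, n_replicates))
    surv = np.maximum(surv, 0.0)
    if sigma == 0:
        surv = np.repeat(mean[:, None], n_replicates, axis=1)
    dr = DoseResponse(dose=doses, survival=surv, cell_line=cell_line,
                      treatment=treatment, exposure_h=exposure_h)
    truth = {"ic50_M": ic50, "hill": hill, "bottom": bottom, "sigma": sigma,
             "cell_line": cell_line, "treatment": treatment}
    return dr, truth


def make_emission_spectrum(form="lactone", wavelengths=None, fwhm=65.0,
                           sigma_frac=0.0, seed=0):
    """Synthetic emission band of the drug at the pH-dependent position.

    The acid-stable lactone emits around 431 nm; ring opening to the
    carboxylate red-shifts the band to ~445 nm.  A single Gaussian band on a
    380-625 nm grid stands in for the broad structureless spectrum.
    Returns (wavelength array, intensity array, truth dict).
    """
    rng = _rng(seed)
    centers = {"lactone": 431.0, "carboxylate": 445.0}
    if form not in centers:
        raise DomainError("form must be 'lactone' or 'carboxylate'")
    wl = (np.arange(380.0, 625.0 + 0.5, 0.5) if wavelengths is None
          else np.asarray(wavelengths, dtype=float))
    c = centers[form]
    s = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    I = np.exp(-0.5 * ((wl - c) / s) ** 2)
    if sigma_frac > 0:
        I = np.maximum(I + rng.normal(0.0, sigma_frac, size=I.shape), 0.0)
    truth = {"form": form, "center_nm": c, "fwhm_nm": fwhm}
    return wl, I, truth


# -- file-level scenario driver ---------------------------------------------

def _gen_cmbcd_1to1(params, outdir, seed):
    medium = params.get("medium", "citrate_pH3.5")
    tits, truth = make_titration_series(
        medium=medium,
        sigma_r=params.get("sigma_r", 0.001),
        host_max=params.get("host_max", 12e-3),
        n_points=params.get("n_points", 12),
        guest_total=params.get("guest_total", 1e-6),
        seed=seed)
    paths = []
    for t in tits:
        name = f"titration_{medium}_{t.temperature:.2f}K.csv"
        paths.append(dio.save_titration(Path(outdir) / name, t))
    return paths, truth


def _gen_ambcd_1to2(params, outdir, seed):
    t, truth = make_titration(
        K=params.get("K_overall", 1e8),
        r_free=params.get("r_free", 0.005),
        r_inf=params.get("r_inf", 0.047),
        stoichiometry="1:2",
        host_max=params.get("host_max", 1e-3),
        n_points=params.get("n_points", 12),
        sigma_r=params.get("sigma_r", 0.001),
        medium=params.get("medium", "PBS_pH7.4"),
        guest_total=params.get("guest_total", 1e-6),
        seed=seed)
    return [dio.save_titration(Path(outdir) / "titration_ambcd_1to2.csv", t)], truth


def _gen_solubility(params, outdir, seed):
    d, truth = make_solubility(
        K=params.get("K", 54.0), S0=params.get("S0", 7.7e-6),
        cd_max=params.get("cd_max", 14e-3),
        n_points=params.get("n_points", 8),
        sigma_frac=params.get("sigma_frac", 0.02),
        curvature=params.get("curvature", 0.0),
        pH=params.get("pH", 7.4), seed=seed)
    return [dio.save_solubility(Path(outdir) / "solubility.csv", d)], truth


def _gen_decay(params, outdir, seed):
    trace, truth = make_decay(
        lifetimes=tuple(params.get("lifetimes", (4.2,))),
        amplitudes=tuple(params.get("amplitudes", (1.0,))),
        peak_counts=params.get("peak_counts", 10000),
        n_channels=params.get("n_channels", 1024),
        window_ns=params.get("window_ns", 100.0),
        background=params.get("background", 5.0),
        poisson=params.get("poisson", True), seed=seed)
    return [dio.save_decay(Path(outdir) / "decay.csv", trace)], truth


def _gen_quench(params, outdir, seed):
    s, truth = make_quench(
        K_SV=params.get("K_SV", 120.0), tau0=params.get("tau0", 4.2),
        static_beta=params.get("static_beta", 0.0),
        q_max=params.get("q_max", 0.05),
        n_points=params.get("n_points", 12),
        sigma_frac=params.get("sigma_frac", 0.005), seed=seed)
    return [dio.save_quench(Path(outdir) / "quench.csv", s)], truth


def _gen_release(params, outdir, seed):
    trace, truth = make_release(
        k=params.get("k", 0.0103),
        plateau_percent=params.get("plateau_percent", 5.5),
        I0=params.get("I0", 100.0), times=params.get("times"),
        sigma_frac=params.get("sigma_frac", 0.002),
        pH=params.get("pH", 3.5), seed=seed)
    return [dio.save_release(Path(outdir) / "release.csv", trace)], truth


def _gen_mtt(params, outdir, seed):
    dr, truth = make_dose_response(
        ic50=params.get("ic50", 17e-9), hill=params.get("hill", 1.5),
        bottom=params.get("bottom", 5.0),
        dose_max=params.get("dose_max", 150e-9),
        n_doses=params.get("n_doses", 8),
        n_replicates=params.get("n_replicates", 3),
        sigma=params.get("sigma", 5.0),
        cell_line=params.get("cell_line", "BT-474"),
        treatment=params.get("treatment", "free_drug"), seed=seed)
    return [dio.save_dose_response(Path(outdir) / "mtt.csv", dr)], truth


SCENARIOS = {
    "cmbcd_1to1": _gen_cmbcd_1to1,
    "ambcd_1to2": _gen_ambcd_1to2,
    "solubility": _gen_solubility,
    "decay": _gen_decay,
    "quench": _gen_quench,
    "release": _gen_release,
    "mtt": _gen_mtt,
}


def generate(config: dict, outdir) -> list:
    """Generate one scenario's dataset files plus a ground-truth sidecar.

    ``config`` needs ``scenario`` (one of :data:`SCENARIOS`) and ``seed``;
    scenario-specific overrides live under ``parameters``.  Returns the list
    of written paths (sidecar last).
    """
    scenario = config.get("scenario")
    if scenario not in SCENARIOS:
        raise DomainError(f"unknown scenario {scenario!r}; "
                          f"expected one of {sorted(SCENARIOS)}")
    seed = int(config.get("seed", 0))
    params = dict(config.get("parameters", {}))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths, truth = SCENARIOS[scenario](params, outdir, seed)
    sidecar = outdir / f"{scenario}_truth.json"
    payload = {"scenario": scenario, "seed": seed, "truth": truth,
               "files": [Path(p).name for p in paths]}
    with open(sidecar, "w", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [*paths, sidecar]
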