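"""CSV reading/writing for all dclkit measurement schemas.

Every file is a plain CSV with optional leading metadata lines of the form
``# key = value``.  Concentrations are always mol dm^-3 on disk; any
display scaling (nM, mM) happens only in reports.  Loaders return the
validated domain containers of the consuming modules.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import Titration
from .cytotoxicity import DoseResponse
from .errors import ValidationError
from .formulation import ReleaseTrace
from .photophysics import DecayTrace, QuenchSeries
from .solubility import SolubilityDiagram

__all__ = [
    "read_csv_with_meta", "write_csv_with_meta",
    "load_titration", "save_titration",
    "load_solubility", "save_solubility",
    "load_decay", "save_decay",
    "load_quench", "save_quench",
    "load_release", "save_release",
    "load_dose_response", "save_dose_response",
    "load_k_table",
]


def read_csv_with_meta(path):
    """Read a CSV with ``# key = value`` metadata lines. Returns (df, meta)."""
    meta = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    meta[key.strip()] = val.strip()
            else:
                body.append(line)
    if not body:
        raise ValidationError(f"{path}: no data rows")
    df = pd.read_csv(_stdio.StringIO("".join(body)))
    return df, meta


def write_csv_with_meta(path, df: pd.DataFrame, meta: dict | None = None,
                        float_format: str = "%.10g"):
    """Write a CSV with metadata header lines; deterministic formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, index=False, float_format=float_format,
                  lineterminator="\n")
    return path


def _meta_float(meta, key, path):
    try:
        return float(meta[key])
    except KeyError:
        raise ValidationError(f"{path}: missing metadata '{key}'") from None


# -- titration ---------------------------------------------------------------

def load_titration(path) -> Titration:
    df, meta = read_csv_with_meta(path)
    for col in ("host_conc_M", "r_obs"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    return Titration(
        host_conc=df["host_conc_M"].to_numpy(),
        r_obs=df["r_obs"].to_numpy(),
        temperature=_meta_float(meta, "temperature_K", path),
        medium=meta.get("medium", ""),
        guest_total=_meta_float(meta, "guest_total_M", path),
        sigma_r=df["sigma_r"].to_numpy() if "sigma_r" in df.columns else None,
    )


def save_titration(path, t: Titration):
    df = pd.DataFrame({"host_conc_M": t.host_conc, "r_obs": t.r_obs})
    if t.sigma_r is not None:
        df["sigma_r"] = t.sigma_r
    meta = {"temperature_K": t.temperature, "medium": t.medium,
            "guest_total_M": t.guest_total}
    return write_csv_with_meta(path, df, meta)


# -- phase solubility --------------------------------------------------------

def load_solubility(path) -> SolubilityDiagram:
    df, meta = read_csv_with_meta(path)
    for col in ("cd_conc_M", "drug_total_M"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    return SolubilityDiagram(
        cd_conc=df["cd_conc_M"].to_numpy(),
        drug_total=df["drug_total_M"].to_numpy(),
        temperature=float(meta.get("temperature_K", 298.15)),
        pH=float(meta.get("pH", 7.4)),
    )


def save_solubility(path, d: SolubilityDiagram, cosolvent_fraction=0.0):
    df = pd.DataFrame({"cd_conc_M": d.cd_conc, "drug_total_M": d.drug_total})
    meta = {"temperature_K": d.temperature, "pH": d.pH,
            "cosolvent_fraction": cosolvent_fraction}
    return write_csv_with_meta(path, df, meta)


# -- TCSPC decay -------------------------------------------------------------

def load_decay(path) -> DecayTrace:
    df, _ = read_csv_with_meta(path)
    for col in ("time_ns", "counts"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    counts = df["counts"].to_numpy()
    if not np.allclose(counts, np.round(counts)):
        bad = int(np.argmax(~np.isclose(counts, np.round(counts))))
        raise ValidationError(f"{path}: non-integer counts at row {bad}")
    return DecayTrace(
        channel_time=df["time_ns"].to_numpy(),
        counts=counts,
        irf=df["irf_counts"].to_numpy() if "irf_counts" in df.columns else None,
    )


def save_decay(path, trace: DecayTrace):
    df = pd.DataFrame({"time_ns": trace.channel_time,
                       "counts": trace.counts.astype(int)})
    if trace.irf is not None:
        df["irf_counts"] = trace.irf.astype(int)
    return write_csv_with_meta(path, df)


# -- quenching ---------------------------------------------------------------

def load_quench(path) -> QuenchSeries:
    df, meta = read_csv_with_meta(path)
    if "q_conc_M" not in df.columns:
        raise ValidationError(f"{path}: missing column 'q_conc_M'")
    return QuenchSeries(
        quencher_conc=df["q_conc_M"].to_numpy(),
        intensity_ratio=(df["i0_over_i"].to_numpy()
                         if "i0_over_i" in df.columns else None),
        lifetime_ratio=(df["tau0_over_tau"].to_numpy()
                        if "tau0_over_tau" in df.columns else None),
        tau0=_meta_float(meta, "tau0_ns", path),
    )


def save_quench(path, s: QuenchSeries):
    df = pd.DataFrame({"q_conc_M": s.quencher_conc})
    if s.intensity_ratio is not None:
        df["i0_over_i"] = s.intensity_ratio
    if s.lifetime_ratio is not None:
        df["tau0_over_tau"] = s.lifetime_ratio
    return write_csv_with_meta(path, df, {"tau0_ns": s.tau0})


# -- release -----------------------------------------------------------------

def load_release(path) -> ReleaseTrace:
    df, meta = read_csv_with_meta(path)
    for col in ("time_min", "intensity"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    return ReleaseTrace(time=df["time_min"].to_numpy(),
                        intensity=df["intensity"].to_numpy(),
                        pH=float(meta.get("pH", 3.5)))


def save_release(path, t: ReleaseTrace):
    df = pd.DataFrame({"time_min": t.time, "intensity": t.intensity})
    return write_csv_with_meta(path, df, {"pH": t.pH})


# -- MTT dose response -------------------------------------------------------

def load_dose_response(path) -> DoseResponse:
    df, meta = read_csv_with_meta(path)
    if "dose_M" not in df.columns:
        raise ValidationError(f"{path}: missing column 'dose_M'")
    rep_cols = [c for c in df.columns if c.startswith("rep")
                and c.endswith("_survival_pct")]
    if not rep_cols:
        raise ValidationError(f"{path}: no replicate survival columns")
    return DoseResponse(
        dose=df["dose_M"].to_numpy(),
        survival=df[rep_cols].to_numpy(),
        cell_line=meta.get("cell_line", ""),
        treatment=meta.get("treatment", ""),
        exposure_h=float(meta.get("exposure_h", 48.0)),
    )


def save_dose_response(path, dr: DoseResponse):
    df = pd.DataFrame({"dose_M": dr.dose})
    for j in range(dr.n_replicates):
        df[f"rep{j + 1}_survival_pct"] = dr.survival[:, j]
    meta = {"cell_line": dr.cell_line, "treatment": dr.treatment,
            "exposure_h": dr.exposure_h}
    return write_csv_with_meta(path, df, meta)


# -- K(T) table for van't Hoff ----------------------------------------------

def load_k_table(path):
    """Read a temperature_K, K_assoc [, K_se] table as a dict T -> K."""
    df, _ = read_csv_with_meta(path)
    for col in ("temperature_K", "K_assoc"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    return dict(zip(df["temperature_K"].astype(float),
                    df["K_assoc"].astype(float)))
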