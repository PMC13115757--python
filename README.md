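# dclkit

Analysis toolkit for **drug-in-cyclodextrin-in-liposome (DCL) formulation
studies** — the experimental workflow in which a poorly soluble drug (the
motivating case is camptothecin, CPT) is solubilized as a host–guest
inclusion complex with a charged β-cyclodextrin derivative and then loaded
into liposomal carriers.

`dclkit` implements the complete quantitative chain such a study produces,
for formulation scientists and photophysicists who want the fitting done
reproducibly rather than in a spreadsheet:

* **Binding equilibria** from fluorescence anisotropy titrations.
  Complexation slows the guest's rotational diffusion, so the anisotropy
  rises from `r_free` to `r_inf` with host concentration. The observed
  anisotropy is population-weighted,

  `r([H]) = r_free + (r_inf − r_free) · f_bound([H])`,

  with `f_bound = K[H]/(1+K[H])` for a 1:1 complex (exact host-depletion
  solver available) or `K[H]²/(1+K[H]²)` for an overall 1:2 complex.
  Nonlinear and double-reciprocal fits, plus AICc stoichiometry selection.
* **Van't Hoff thermodynamics**: `ln K = −ΔH/(RT) + ΔS/R` regressed over
  temperature, with ΔH in kJ mol⁻¹ and ΔS in J K⁻¹ mol⁻¹.
* **Higuchi–Connors phase solubility**: diagram classification
  (A_L/A_P/A_N/B) and the 1:1 stability constant
  `K = slope / (S₀(1 − slope))`.
* **Photophysics**: L-format anisotropy
  `r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)`, multi-exponential TCSPC decay
  fitting with Poisson weights, amplitude-weighted mean lifetimes
  `⟨τ⟩ = ΣAᵢτᵢ²/ΣAᵢτᵢ`, and Stern–Volmer quenching
  `I₀/I = τ₀/τ = 1 + K_SV[Q]` with automatic linear-region analysis and
  `k_q = K_SV/τ₀`.
* **Formulation metrics**: encapsulation efficiency, loading fold-changes,
  and apparent first-order release kinetics
  `I(t) = I_∞ − (I_∞ − I₀)e^(−kt)` with `τ½ = ln 2 / k`.
* **Cytotoxicity**: MTT survival normalization, four-parameter-logistic
  IC50 fitting (top fixed at the 100% control), and two-tailed Student's
  t-tests on log IC50 across replicates.
* **Synthetic data**: seeded generators that emulate every instrument
  output above, each with a ground-truth JSON sidecar, so the whole chain
  is testable end to end.

## Worked example

Titrations at five temperatures (5–45 °C) in PBS at pH 7.4, generated
noise-free from an enthalpy-driven binding model, fitted per temperature
and passed to the van't Hoff analysis:

```python
from dclkit import fit_binding_isotherm, vant_hoff_fit
from dclkit.synth import make_titration_series

titrations, truth = make_titration_series(medium="PBS_pH7.4", sigma_r=0.0)
K_by_T = {}
for t in titrations:
    fit = fit_binding_isotherm(t, stoichiometry="1:1")
    K_by_T[t.temperature] = fit.K
    print(f"T = {t.temperature:.2f} K   K = {fit.K:6.1f} dm3 mol-1   "
          f"r_inf = {fit.r_inf:.4f}")

thermo = vant_hoff_fit(K_by_T)
print(f"dH = {thermo.dH:.1f} kJ mol-1   dS = {thermo.dS:.1f} J K-1 mol-1   "
      f"dG(298 K) = {thermo.dG_at(298.15):.2f} kJ mol-1")
```

```
T = 278.15 K   K =   97.7 dm3 mol-1   r_inf = 0.0570
T = 288.15 K   K =   65.9 dm3 mol-1   r_inf = 0.0570
T = 298.15 K   K =   45.7 dm3 mol-1   r_inf = 0.0570
T = 308.15 K   K =   32.4 dm3 mol-1   r_inf = 0.0570
T = 318.15 K   K =   23.5 dm3 mol-1   r_inf = 0.0570
dH = -26.2 kJ mol-1   dS = -56.1 J K-1 mol-1   dG(298 K) = -9.47 kJ mol-1
```

The association constant falls with temperature exactly as the generating
enthalpy (−26.2 kJ mol⁻¹) dictates, and the regression returns the
generating ΔH and ΔS; the negative ΔS is the entropic penalty of confining
the charged guest in the cavity. With the generator's realistic anisotropy
noise (σ_r ≈ 0.001) the per-temperature constants scatter by 10–20%, which
is why low-affinity anisotropy titrations are reported with wide
uncertainty bands.

The same analyses are scriptable from the shell:

```sh
$ dclkit synth --scenario solubility --seed 11 --out demo
$ dclkit solubility demo/solubility.csv
{
  "K_stability": 52.78678726877004,
  "intercept_M": 7.802332006083334e-06,
  "r_squared": 0.9952362153080628,
  "slope": 0.0004062931207738094,
  "type": "A_L"
}
```

— a linear (A_L-type) diagram whose slope and intercept give a stability
constant of ≈53 dm³ mol⁻¹, recovering the generator's K = 54 within the 2%
concentration noise. `dclkit run --config cfg.yaml --seed N --out DIR`
executes a multi-stage pipeline (isotherms → van't Hoff, solubility,
decay, quenching, release, MTT) and writes `results.json` plus a text
report; outputs are byte-identical for a fixed config and seed.

## Layout

```
src/dclkit/
  binding.py        anisotropy isotherms, species fractions, stoichiometry
  thermodynamics.py van't Hoff fits and K(T) prediction
  solubility.py     Higuchi–Connors diagrams and stability constants
  photophysics.py   anisotropy, TCSPC decays, Stern–Volmer, band positions
  formulation.py    encapsulation efficiency and release kinetics
  cytotoxicity.py   MTT normalization, 4PL IC50, replicate t-tests
  synth.py          seeded generators + ground-truth sidecars
  io.py             CSV schemas ('#'-metadata headers)
  pipeline.py, cli.py   multi-stage runner and `dclkit` command
```

See `docs/methods.md` for the models, assumptions, numerical choices and
known limitations.
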