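# Methods

This note records the models behind each `dclkit` module, the assumptions
they make, the defaults of the synthetic-data generators, and the numerical
choices that matter when reproducing or extending an analysis.

## Binding equilibria from anisotropy titrations

**Model.** A fluorescent guest G (drug) binds a host H (cyclodextrin).
Complexation raises the steady-state anisotropy because the complex
tumbles more slowly; the guest's fluorescence lifetime and intensity are
taken as complexation-invariant, which makes the observed anisotropy the
*population*-weighted mean

    r([H]) = r_free + (r_inf − r_free) · f_bound([H]).

If lifetime or quantum yield changed on binding, intensity weighting would
be required instead; the assumption is explicit in `predict_anisotropy`
and holds for the emulated chromophore (lifetimes ~4 ns in free and bound
states).

**Species fractions.** For 1:1 binding, mass action gives the quadratic
`K·c² − (K·G + K·H + 1)·c + K·G·H = 0` in the complex concentration c.
The physical (smaller) root is evaluated in the cancellation-safe product
form `c = 2KGH / (b + √(b² − 4K²GH))`, which agrees with a bisection
oracle to < 1e-15 in the bound fraction across six decades of K. Because
the emulated experiments hold the guest at ~1 µM against mM host, fitting
uses the depletion-free limit `f = K[H]/(1+K[H])` (the exact solver is
exercised in tests). The 1:2 complex is described by a single overall
constant, `f = K[H]²/(1+K[H]²)` — no explicit 1:1 intermediate — which is
the right description when the second host adds cooperatively and only an
overall constant is identifiable from a one-channel titration.

**Fitting.** `fit_binding_isotherm` minimizes (optionally σ-weighted)
squared residuals over (K, r_free, r_inf) with Levenberg–Marquardt
(lmfit), ftol = xtol = 1e-10, max_nfev = 2000. Starting values are
deterministic and data-driven: r_free from the zero-host point, r_inf at
120% of the observed maximum (capped below the bound), K from the
double-reciprocal fit (1:1) or the inverse-squared half-rise concentration
(1:2). r_inf is bounded at 0.4, the one-photon anisotropy limit; without
that bound, low-saturation titrations (K·H_max ≪ 1) drift along the
`K·(r_inf − r_free) ≈ const` ridge toward unphysical optima. Standard
errors come from the covariance at the optimum. A flat series yields a
`K_unidentifiable` warning rather than a spurious constant.

**Stoichiometry selection** fits both models and compares small-sample
corrected AIC; since both carry three parameters the comparison reduces to
residual sums of squares, and ties go to 1:1 on parsimony. On noiseless
data the evidence gap exceeds 10 AICc units; at the default noise the
selection accuracy over the simulation grid is ≥ 95%.

**What recovery looks like at study conditions.** With 12 points over
0–12 mM, anisotropy amplitude 0.042 and σ_r = 0.001, the Fisher bound puts
the relative standard error of K̂ (K = 200 dm³ mol⁻¹) near 16%. The
estimator is essentially unbiased (median signed bias ~1% over 200
replicates; 95% CI coverage ≈ 95%), but single-titration constants are
intrinsically uncertain at this design — a property of the measurement,
not of the software — which is why multi-temperature trends, not single
K values, carry the thermodynamic conclusions.

## Van't Hoff thermodynamics

Ordinary least squares of ln K on 1/T: ΔH = −slope·R, ΔS = intercept·R
(R = 8.314 J K⁻¹ mol⁻¹), reported in kJ mol⁻¹ and J K⁻¹ mol⁻¹
respectively, with ΔG(T) = ΔH − T·ΔS/1000. The regression is unweighted
by default; per-K standard errors can be supplied (`K_se`) to weight by
1/σ²_lnK, but note that weighting by *fit-estimated* uncertainties biases
ΔH toward zero when the errors correlate with the estimates themselves —
in seeded simulations of the noisy titration chain the weighted median ΔH
landed ~35% short of truth while the unweighted one was centred — so the
unweighted default is also the recommendation unless the uncertainties
come from an independent source. Duplicate temperatures are averaged in
ln K with a warning. ΔCp is assumed zero (linear plot); curvature from
heat-capacity changes is out of scope. `predict_K` inverts the relation
exactly, so fit → predict round trips are machine-precise on noiseless
grids.

## Higuchi–Connors phase solubility

Total dissolved drug vs CD concentration. Classification order matters:
a post-peak decline (B-type, limited-solubility complex) is checked first,
then quadratic curvature by a t-test on the x² coefficient (α = 0.05,
A_P/A_N) — curvature must be excluded *before* the linear call because a
straight line fits a gentle parabola with R² above any practical cutoff —
and finally A_L requires R² ≥ 0.98 with positive slope. For A_L diagrams
`K = slope/(S₀(1 − slope))`, valid for slope < 1. S₀ is the diagram
intercept, not an independently measured saturation: with a co-solvent in
the diagram (the emulated protocol dissolves the drug in ~6% methanol)
the two differ, which is why printed fold-enhancements and stability
constants from such studies are generally not mutually derivable. The
package reports both quantities separately and does not attempt to
reconcile them.

## Photophysics

**Anisotropy** uses the L-format expression
`r = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)`. Printed sources occasionally
carry a minus sign in the denominator; that is a typesetting corruption of
the standard form (the denominator is the total intensity
`I_∥ + 2I_⊥`), and `dclkit` uses the `+` form.

**Decay fitting.** `I(t) = Σ Aᵢ·exp(−t/τᵢ) + background`, 1–3 components.
Tail fitting from the peak channel is the default: the emulated lifetimes
(~4 ns) are long against an LED excitation pulse, and the study decays are
mono-exponential; iterative reconvolution with a measured IRF is available
(`use_irf=True`). Weights are Poissonian with *model-based* variance
(Pearson, σᵢ = √max(modelᵢ, 1)): observed-count weighting is biased at the
few-count background level and inflates reduced χ² by ~30% at a 5-count
background, whereas Pearson weighting keeps χ²_red centred on 1 for a
correct model. Lifetimes collapsing within 1% of each other trigger a
reduce-the-model warning. The amplitude-weighted mean lifetime is
`ΣAᵢτᵢ²/ΣAᵢτᵢ`.

**Stern–Volmer analysis.** Dynamic quenching is linear,
`I₀/I = τ₀/τ = 1 + K_SV[Q]`; at high quencher, static (ground-state or
sphere-of-action) contributions bend the intensity ratio upward while
lifetime ratios stay linear. The linear region is found by a quadratic
curvature screen: fit `a + b·q + c·q²`, t-test on c at α = 0.05. With no
significant curvature, K_SV is the plain linear slope over all points.
With curvature, K_SV is the limiting slope b — the dynamic constant — and
the reported mask keeps points whose curvature share c·q² is within 2% of
the linear part. A fixed R² threshold was rejected as the region rule:
high-leverage tail points dominate the variance, so even strongly curved
series keep R² > 0.99 and the threshold never excludes the tail.
`k_q = K_SV/τ₀` with τ₀ converted ns → s, reported in dm³ mol⁻¹ s⁻¹.

**Band positions.** `emission_peak_nm` locates an emission maximum by
parabolic interpolation through the three samples around the grid maximum
— sufficient for the broad (~65 nm FWHM) bands involved, where the
physically meaningful number is the ~14 nm lactone → carboxylate red
shift, not sub-nanometre peak metrology.

## Formulation: loading and release

Encapsulation efficiency is 100 × (encapsulated / total initial drug
concentration); values above 100% are clipped with a warning since small
calibration overshoots occur. Release at lysosomal pH follows an apparent
first-order law `I(t) = I_∞ − (I_∞ − I₀)e^(−kt)` on the fluorescence
intensity, an explicitly semi-quantitative proxy (quantum-yield and
microenvironment changes contribute); results are therefore reported as
percentage intensity changes, never absolute drug mass.

Two estimation modes:

* **plateau** — the classical ln(I_∞ − I_t) vs t regression. The plateau
  window (last 20% of points) must be flat in two senses: spread within 1%
  of its mean *and* residual linear trend below 10% of the total rise —
  the spread test alone cannot notice a slow drift when the whole release
  amplitude is ~5%. Because a finite-time window mean always sits slightly
  below the true asymptote (biasing k upward by several percent even on
  perfect data), I_∞ is refined from the window mean by maximizing the
  linearity of the ln-plot, with the regression subset frozen so the
  objective stays unimodal; points whose gap to I_∞ is within 3 tail
  standard deviations are excluded as noise-dominated.
* **free** — direct nonlinear fit of (I_∞, I₀, k). This is the
  statistically efficient choice on noisy traces (at 0.2% intensity noise
  the ln-linear estimator discards most of the information in the small
  late-time gaps) and is used for noisy-recovery validation.

`τ½ = ln 2/k` holds exactly by construction. A trace whose total excursion
is below 1% of I₀ is reported as *stable* (k undefined), the expected
verdict for a leak-tight formulation at physiological pH.

## Cytotoxicity

Survival is 100 × (treated / control absorbance) at 550 nm,
blank-subtracted upstream. Dose–response is a four-parameter logistic on
log dose with the top fixed at 100% — the zero-dose control defines 100%
by construction — and the bottom floored at 0; IC50 is the midpoint dose,
fitted via log₁₀ IC50 for scale and positivity (which also makes the fit
exactly scale-equivariant). A fit is refused when mean survival never
crosses 50% (IC50 would be extrapolation). Per-replicate fits feed the
group comparison: a two-tailed equal-variance Student's t-test on
log-transformed IC50s (replicate IC50s are approximately log-normal),
significant at p < 0.05. The test holds its nominal size at n = 3 per
group (measured type-I error ≈ 0.045–0.047 over 2000 null simulations).
Whether IC50s should be fitted per replicate or on pooled means is
genuinely open in practice; both are provided, with per-replicate the
default for testing because it propagates replicate scatter.

## Synthetic data: what is emulated, and what is not

Generator defaults are the emulated study's conditions; they are inputs to
the analysis, not tuning knobs.

| scenario | defaults |
|---|---|
| `cmbcd_1to1` | 12-point titrations, 0–12 mM host, guest 1 µM, σ_r = 0.001, five temperatures 278–318 K; K(T) derived from the medium preset's (ΔH, ΔS) so the isotherm → van't Hoff chain is exercised end to end |
| `ambcd_1to2` | overall K = 1e8 dm⁶ mol⁻² (half-saturation 0.1 mM), host 0–1 mM |
| `solubility` | K = 54 dm³ mol⁻¹, S₀ = 7.7 µM, CD 0–14 mM, 8 points, 2% relative noise (volumetric concentration uncertainty) |
| `decay` | 1024 channels / 100 ns, 10,000 expected peak counts, Poisson statistics, τ = 4.2 ns, 5-count background |
| `quench` | K_SV = 120 dm³ mol⁻¹, τ₀ = 4.2 ns, zero + geometric quencher grid 1–50 mM (dense at low [Q], where the linear-region analysis lives), 0.5% ratio noise; optional quadratic static term β·q² (β = 1500 dm⁶ mol⁻² for the curved scenario) that leaves the initial slope — the dynamic constant — untouched |
| `release` | k = 0.0103 min⁻¹, 5.5% plateau rise, 0.2% of I₀ noise; 30-point schedule (every 5 min to 20 min, every 10 min to 200 min, every 30 min from 420–600 min) chosen by Fisher-information analysis — it lowers the k standard error versus uniform sampling while remaining an ordinary kinetics protocol |
| `mtt` | IC50 = 17 nM, Hill 1.5, 5% survival floor, zero-dose control + 8 log-spaced doses to 150 nM, triplicates with 5-point survival noise |

Medium presets (`citrate_pH3.5`, `PBS_pH7.4`, `water_pH7.4`) carry the
binding, thermodynamic and photophysical scales of the three studied
media: entropy-driven lactone inclusion in citrate (ΔH ≈ 0,
ΔS = +38.6 J K⁻¹ mol⁻¹), enthalpy-driven screened-carboxylate binding in
PBS (ΔH = −26.2 kJ mol⁻¹, ΔS = −56.1 J K⁻¹ mol⁻¹), and
repulsion-dominated entropy-driven binding in water (ΔH = +16.2,
ΔS = +87.9).

All randomness flows through `numpy.random.default_rng(seed)`; a fixed
seed reproduces files byte for byte, and every dataset ships a
ground-truth sidecar so recovery tests never restate truth by hand.

*Not emulated*: inner-filter effects, photobleaching, scatter/IRF
artifacts in decays, plate-edge effects and systematic (non-Gaussian)
replicate structure in MTT data, drug–membrane partitioning dynamics in
release traces. Passing round-trip tests therefore demonstrates estimator
correctness and calibration under the stated noise model, not robustness
to every instrumental pathology of real data.

## Known limitations

* The 1:2 model omits the 1:1 intermediate; titrations with comparable
  stepwise constants would need a two-constant model and richer data.
* Host-deficient (2:1) stoichiometries, global multi-wavelength analysis
  and time-resolved anisotropy decays are out of scope.
* Phase-solubility analysis covers A/B-type 1:1 diagrams only.
* Release fluorescence is a proxy; no mass-transfer or lactone/carboxylate
  speciation modelling is attempted.
* Single-titration K estimates at low saturation are dominated by the
  `K·(r_inf − r_free)` identifiability ridge; the r_inf ≤ 0.4 bound keeps
  fits physical but cannot create information the design lacks.
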