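# Methods

## Model

PA–CWM binding is treated as single-layer Langmuir adsorption at
equilibrium: `q(C) = K·C·S/(1 + K·C)` with `q` in mg PA (catechin units)
per mg CWM and `C` in mg C.U./L. The two parameters are generated by
rational surfaces in absolute temperature `T` (K) and ethanol `E` (% v/v),

```
param(T, E) = (n0 + nT·T + nE·E) / (d0 + dT·T + dE·E + dTE·T·E),
```

calibrated over 15–35 °C and 0–15 % v/v. Outside that envelope evaluation
is permitted but flagged with an `ExtrapolationWarning`. All interfaces
(files, CLI, schedules) speak °C; Kelvin is internal (`T_K = T_C + 273.15`).

### Default surface constants

The default coefficient sets are

```
K_eq  : num (1.21e-3, -2.69e-1·T, 0·E)    den (0, -9.01·T, -1.25e2·E, T·E)
S_CWM : num (4.57e1, 0·T, 2.04e1·E)       den (0, 4.57e-1·T, -6.69·E, T·E)
```

Two of these constants are exponent corrections of a widely circulated but
internally inconsistent transcription (K_eq numerator T-coefficient
−2.69×10⁻³; S_CWM numerator constant 4.57×10⁻¹). That variant makes the
capacity surface collapse to `S = 1/T ≈ 0.0035 mg/mg` at 0 % ethanol —
two orders of magnitude below the adsorption actually observed at 15 °C —
and cannot reproduce the winemaking-scale masses the model is known for.
The corrected constants restore a physically coherent capacity
(S ≈ 0.35 mg/mg at 15 °C/0 %, decreasing in both T and E over the
calibrated grid) and reproduce the cold-soak benchmark masses to better
than 0.1 % (758.4 vs 758 mg bound; 741.6 vs 742 mg/L) and the
reversible-pathway masses within 8 % (565.5 vs ≈525 mg; 934.5 vs
≈975 mg/L). At 35 °C/15 % the corrected `K_eq` is large (≈2.8 L/mg), so
the one-litre system is essentially capacity-limited there: the residual
8 % gap against the ≈525 mg benchmark traces to the capacity constant and
no transcription variant consistent with the printed mantissas closes it
without breaking the cold-soak numbers. Both surfaces remain fully
user-overridable through the `model.coefficients.{keq,scwm}` config block
(seven named constants each), and the alternative transcription is
exercised in the test suite as an explicit coefficient set.

### Batch equilibrium

A closed system (volume `V` L, CWM `m` mg, total PA `total` mg) satisfies
`C·V + q(C)·m = total`. Substituting the isotherm yields
`K·V·C² + (V + K·(S·m − total))·C − total = 0`. Because the leading
coefficient is positive and the constant term non-positive, exactly one
root is non-negative; it is computed with the cancellation-free quadratic
form and asserted to lie in `[0, total/V]`. Degenerate inputs: `m = 0`
gives `C = total/V, q = 0`; `total = 0` gives the empty state; `V = 0`
with PA present raises. Every solved state is checked against the mass
balance to a relative residual of 1e-9; a bisection solver on the
mass-balance residual serves as an independent oracle in the tests.

### Langmuir fitting

`fit_langmuir` is nonlinear least squares (`scipy.optimize.curve_fit`,
bounds K, S > 0) with starting values `S₀ = 1.1·max(q)`,
`K₀ = 1/median(c)` — standard isotherm-fitting practice. Fewer than three
points, fewer than two distinct concentrations, negative values, or an
all-zero isotherm (capacity degenerates to the zero boundary) raise
`FitFailureError` rather than returning a boundary estimate.

## Ramp simulation

The bench protocol equilibrates at 15 °C (720 min) and re-equilibrates at
22.5, 30 and 35 °C (120 min holds). Holds are treated as attained
equilibria — the analysis of such experiments reads each sampling point as
an equilibrium state — so hold durations are metadata and within-hold
kinetics are out of scope. Three reversibility assumptions:

* `equilibrium`: each step is an independent batch solve at (T, E). With
  the default surfaces S decreases with temperature at every calibrated
  ethanol level, so percent desorption is non-decreasing along the ramp
  (asserted on the grid, not assumed).
* `empirical`: steps after the first release user-supplied fractions of
  the step-1 bound mass (e.g. the bundled reference fractions), bypassing
  the isotherm. Fractions round-trip exactly through
  `percent_desorption_series`.
* `partial`: a fraction φ of the step-1 bound mass is irreversible. The
  frozen pool `φ·A₁` is removed from the total **and** the adsorbent mass
  is scaled by `(1 − φ)` before the per-step solves. This is the unique
  simple construction that is self-consistent (re-solving at the step-1
  condition returns the step-1 state exactly, because `A₁ = q₁·m`) and
  satisfies both limits: φ = 0 coincides with `equilibrium` mode and
  φ = 1 freezes the system (no desorption and no re-adsorption).

Supernatant withdrawal (125 µL per sampled step at the bench) is ignored
by default — ≈2.8 % of the working volume per step, within assay noise —
but `withdrawal_uL` depletes volume and total PA per step to make that
approximation testable.

Percent desorption is `100·(A₁ − A_k)/A₁` relative to the mass bound at
the first step; negative values (net further adsorption) are reported, not
clipped; a zero baseline raises `UndefinedBaselineError`.

## Assay quantification

Concentrations are read against a (+)-catechin calibration line (OLS via
`scipy.stats.linregress`, R² reported). The assay reads each cuvette twice
at 510 nm: a background read before the reagent (875 µL total volume) and
a final read after (1000 µL). Because the reads occur at different
volumes, the background is rescaled by 875/1000 before subtraction —
volume-consistent subtraction is the defensible default and both the
dilution factor (default 1000/75 for a 75 µL sample) and background scale
are configurable. Negative concentrations (noise near blank) floor at
zero with a warning rather than erroring. Adsorbed amount per mg CWM is
`q = (C_control_mean − C_trial)·V/m`; negative q (trial above control) is
reported with a warning since it is informative, not invalid.

## Statistics

Cell summaries are arithmetic means with sample SDs (n−1). Significance
letters come from one-way ANOVA (α = 0.05) followed, when the omnibus test
rejects, by Tukey HSD all-pairs comparisons feeding an insert-and-absorb
compact letter display ('a' = smallest mean; groups sharing a letter are
not significantly different). Tukey HSD is a deliberate choice of post-hoc
generator: plain spreadsheet ANOVA does not define a letter-assignment
procedure, and Tukey is the standard generator of letter displays. When
every group has zero internal variance the F statistic is undefined and
groups are clustered by exact equality instead. The letter display's
type-I behaviour is verified by simulation (two null groups, 1,000 runs:
distinct-letter rate ≈ 5 %).

Model-versus-data error reports use the observed q as the percent-error
denominator (matching "error between the data and the model"), exclude
zero observations from the MPE with an explicit count, and report signed
mean bias separately so over/underestimation language is reproducible.

## Composition

mDP = total subunit moles / terminal moles (phloroglucinolysis releases
terminal units free and extension units as phloroglucinol adducts);
% galloylation counts gallate-ester subunits (epicatechin gallate),
% gallo counts trihydroxylated-B-ring subunits (epigallocatechin); aMW =
mDP × mole-weighted subunit mass. aMW uses free flavan-3-ol masses with no
interflavan-bond or adduct-mass correction — no standard correction is
agreed for this assay and the MW table is configurable per profile.

GPC traces map elution volume to log₁₀ MW through a monotone-decreasing
calibration. Cumulative mass is accumulated **from low to high molar
mass**, so the 90 % quantile sits in the high-MW tail — the direction that
makes the quantile sensitive to loss of large polymers, which is what the
metric is used to detect. The quantile is linearly interpolated between
samples; a single-sample (monodisperse) trace returns its MW at any
quantile; an all-zero trace raises.

## Winemaking scenario

Defaults describe one litre of standard red wine: 750 berries × 10 mg CWM
= 7,500 mg adsorbent, 1,500 mg/L PA. The model pathway solves the batch
equilibrium at the finished-wine condition (35 °C, 15 % v/v). The
cold-soak pathway solves it at 15 °C/0 % — where the surfaces are reported
to fit observed adsorption well — and multiplies the bound mass by
(1 − 0.4796), the measured final desorption fraction at 35 °C/15 % from
the bundled reference table. This is the most literal reading of the
comparison; whether the original extrapolation used modelled or measured
15 °C adsorption is not documented, so the desorption fraction and both
conditions are spec fields.

## Synthetic data

Generators emulate the bench experiment's statistical structure: triplicate
control (no CWM) and trial series over the ramp, with absorbances obtained
by inverting the calibration so the quantification chain is an exact
round-trip at zero noise. Noise is multiplicative Gaussian on
concentration by default (the reference table's SDs grow with their means,
indicating multiplicative error); placement on absorbance is configurable.
Defaults follow the bench conditions: 3 replicates, cv = 3 % (mid-range of
the 1–10 % CVs implied by the reference SDs). All generators are pure
functions of (truth, parameters, seed).

What the generator does **not** emulate: instrument drift, carryover,
between-day calibration shifts, matrix interference (anthocyanins, iron
chemistry), or within-hold kinetics. Passing recovery tests therefore show
the estimator chain is unbiased under clean multiplicative noise, not that
real assays are.

Known estimator limitation: per-trial percent desorption divides by that
trial's noisy 15 °C baseline, so its expectation is biased upward by
roughly `cv(q₁)²` of the retained fraction. The end-to-end recovery check
(500 seeds, cv = 3 %, bias < 0.5 percentage points) is run at the 0 %
ethanol condition, where the adsorbed baseline is largest relative to
assay noise (cv(q₁) ≈ 5 %); at 15 % ethanol the bench geometry leaves a
small baseline (q₁ ≈ 0.08 mg/mg) and the same chain shows percentage-point
biases of several units — a real feature of ratio estimators at low
binding, documented rather than hidden.

## Problem sizes and numerics

Solver–oracle agreement is checked on 1,000 random systems (relative
1e-9); fit recovery on 100 seeds of 24-point designs at cv = 2 % (max
observed error ≈6.5 % for K, well inside the 10 % band); end-to-end
recovery on 500 seeds; letter-display type-I on 1,000 simulations. The
full suite runs in well under a minute. Quadratic roots use the
cancellation-free form; surface singularity is guarded with a scale-aware
tolerance (|den| ≤ 1e-12 × term magnitude); temperatures convert once at
the interface boundary.
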