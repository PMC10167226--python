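# Methods

## Hydropathy scoring

Two per-residue scales are packaged. The Kyte–Doolittle index is used as
published (dimensionless, larger = more hydrophobic). The "biological"
hydrophobicity scale is the apparent free energy of Sec61-translocon
membrane insertion, ΔG_app, in kcal/mol; because favourable insertion
(hydrophobic) is *negative* on that scale, it is exposed negated so both
scales share the orientation larger = more hydrophobic. The published raw
values remain available on the scale object. Lookup of any character
outside the 20 standard one-letter codes is an error, and an incomplete
scale table is rejected at load time.

The combined hydropathy of a variant is the **sum** of per-residue values
over loop motifs 1–3 plus the single anchor residue at position 206. Sum
rather than mean: the motifs share length, so the two are affine-
equivalent for tripeptide panels, and the sum handles the anchor residue
and whole-loop deletions (three empty motifs, score 0) without
reweighting. The downstream regression is invariant to any affine
recoding of the score (verified by a dedicated test), so this choice
cannot change R², p-values or predictions.

The wild-type and mutant motif sequences of the original experimental
panel are available only in figure form; the packaged panel is therefore
generated synthetically (see *Synthetic data*) with the same mutational
architecture — EGR triple swaps, SS/SAS polar substitutions, a T→W anchor
swap and a loop deletion — rather than transcribed sequences.

## Aggregation mass (amorphous-aggregation activity)

Turbidity traces (A360 vs time, 90 s plate cadence, 45 °C assays) are
baseline-corrected by subtracting the mean of the first `n_initial`
points (default 3; negative values are retained, since clipping would
bias AUC ratios). Each replicate's area under the curve is computed by
trapezoidal integration *on the actual timestamps* over the common time
window of samples and controls (window endpoints interpolated), avoiding
resampling artifacts from missed plate cycles. The aggregation mass is
`100 × mean(AUC) / mean(control AUC)`; the per-replicate masses' standard
deviation is reported, and replicates are reduced AUC-first (AUC per
replicate, then mean ± sd), matching the usual means-of-replicates
presentation. The control against itself is exactly 100% for any positive
trace, and the statistic is invariant to rescaling both sample and
control signals — both are regression-tested.

## Activity regression and prediction

Ordinary least squares of aggregation mass (%) on combined hydropathy,
fitted to per-variant means at a single molar ratio (one point per
variant, as the correlation panels are drawn). The model object stores
slope, intercept, R², the two-sided slope-t p-value, the residual
standard deviation and the sufficient statistics (n, x̄, Sxx) needed for
confidence bands at arbitrary x. Predictions report the confidence
interval of the **mean response**,
`ŷ ± t(1−α/2, n−2) · s · √(1/n + (x−x̄)²/Sxx)`,
not a prediction interval for a single future assay: the published
interval widths for held-out chaperones (a few percentage points) are
mean-response bands. An optional clamp truncates points and bounds to
[0, 100] since the response is a percentage of the control. The
implementation is scipy's `linregress` plus explicit t-quantile algebra;
the test suite cross-checks slope, R², p and the CI against statsmodels
OLS `get_prediction` as an independent oracle. `correlate` exposes the
same statistics (Pearson R², slope-t p) for arbitrary paired columns, and
a 1000-simulation test confirms the nominal 5% type-I error rate.

## Amyloid kinetics

### Empirical sigmoid

`F = F0 + A / (1 + exp[r_max(τ½ − t)])`. Fitted per trace by bounded
least squares (A, r_max > 0) from data-derived initial guesses (baseline
median, amplitude, half-crossing time) refined over a fixed grid of
growth-rate multipliers — fully deterministic, no RNG. A fit is rejected
(non-convergence error) when no start yields A > 0, r_max > 0 and R²
above 0.5, e.g. for monotone-decreasing traces; a fitted τ½ outside the
observed time range is flagged, not rejected. Noiseless self-consistency
is recovered to better than 0.1% and the median τ½ error at 2% Gaussian
noise is ≈0.07% (100 simulations).

### Integrated rate law

Fibril mass follows the closed-form first-order perturbative solution of
the moment equations

    dP/dt = k_n m^n_c + k_2 m^n_2 M,   dM/dt = 2 k_+ m P,   m = m0 − M,

expressed through the identifiable combinations λ = √(2 k₊ k_n m0^n_c)
and κ = √(2 k₊ k₂ m0^(n₂+1)) and the derived coefficients
C± = ±λ²/(2κ²), k∞ = √(2κ²/(n₂(n₂+1)) + 2λ²/n_c),
k̃∞ = √(k∞² − 4C₊C₋κ²) and B± = (k∞ ± k̃∞)/(2κ).

Numerical safety is contractual: all exp(κt) factors are combined in log
space (`logaddexp`/`log1p`), k̃∞ is computed stably as √(k∞² + λ⁴/κ²),
and the outer exponent k∞²/(κk̃∞) is applied to the *log* of the bracket,
so the evaluation cannot overflow for any κt (tested at κt ≈ 10⁶). The
identity B₋ + C₊ ≥ 0 (equivalent to |B₋|/C₊ = λ²/(2κ²B₊) ≤ 1) keeps the
`log1p` argument in (−1, 0]; rounding across −1 is clipped, where −inf
correctly propagates to M = 1.

Degenerate branches: k₂ = 0 uses the κ→0 limit
`M = 1 − (1 + λ²t/k∞⁰)^(k∞⁰²/λ²) e^(−k∞⁰t)` with k∞⁰ = λ√(2/n_c)
(verified to match the closed form continuously as κ→0); k_n = 0 without
seeds returns the identically-zero unseeded limit, since the algebraic
formula's λ=0 value (1 − e^(−k∞t)) is an artifact of the perturbative
derivation, not physics.

**Validity domain.** The closed form is a first-order perturbative
solution: against numerical integration of the moment ODEs its half-time
error grows smoothly with λ/κ — ≈1% at λ/κ = 0.1, ≈6% at 0.25, ≈21% at
λ = κ (confirmed independent of ODE detail and of floating-point
evaluation, via 50-digit arithmetic). The package therefore validates the
closed form over κ spanning two decades (10⁻⁴·⁵–10⁻²·⁵ s⁻¹) with
λ/κ ∈ [0.01, 0.2] — the secondary-nucleation-dominated regime the
solution was derived for and the regime of unseeded Aβ42 — where the
half-time discrepancy stays below 5%. Fits to systems approaching λ ≈ κ
should be treated as qualitative.

Defaults: n_c = n₂ = 2 (the standard Aβ42 reaction orders; configurable,
since M(t) data at one concentration cannot determine them) and
m0 = 3 µmol/L monomer.

### Constrained global fit

A chaperone dilution series (ratios 0/10/50/100% of the 3 µM Aβ42
monomer) is fitted jointly: the control's (λ², κ²) plus one multiplicative
factor per non-control condition on the *identifiable product*
corresponding to the chosen free constant — k_n scales λ² only, k₂ scales
κ² only, k₊ scales both. Individual rate constants are not identifiable
from M(t) alone, so results are reported as the products k₊k_n and k₊k₂
plus per-condition factors. Optimization is Levenberg–Marquardt in
log-parameter space from a moment-based initial guess (κ from the control
sigmoid's r_max; λ by bisecting the model half time onto the fitted τ½;
factors from half-time shifts), refined by a seeded Latin-hypercube
multi-start over ±3 decades (default 16 starts; the synthetic-recovery
studies use 4, since the moment-based guess makes additional starts
redundant there). Non-finite residuals from extreme starts are penalized,
not propagated. A panel whose curves are all flat is rejected as
degenerate (free and shared parameters indistinguishable). Repeating the
fit for each candidate free constant and ranking by residual sum of
squares selects the inhibited microscopic step; on the generator's
k₂-suppression truth at 2% noise the correct model wins 100/100 seeded
runs, with suppression factors recovered to a few percent.

ThT replicates are normalized to the [0, 1] mass-fraction scale through
their own sigmoid fits ((F − F0)/A), then averaged; replicates whose fit
fails fall back to min/max normalization with a flag. Min/max is also
available as the primary mode since either convention is defensible. Note
the sigmoid is not the rate law, so fluorescence normalization carries a
small (few-percent) systematic amplitude distortion into κ; the recovered
*factors* are insensitive to it because it is shared across conditions.

## Biophysical QC

SEC subunit counts: the chromatogram peak inside a user window is the
signal maximum; half-height crossings are linearly interpolated; volumes
map to molecular weight through a user-calibrated log10(MW)-vs-volume
line (≥3 standards, slope necessarily negative) and to subunit counts by
rounding MW/monomer-MW (floored at 1, unrounded MW retained). The
low-volume FWHM edge maps to the larger count. CD conversion:
MRE = θ_mdeg/(10·l·c·n_bonds) with n_bonds = n_residues − 1 by default
(configurable, conventions differ). Emission maxima: centered moving
average (default 5 points) then argmax, reported to 1 nm, with partial-
kernel edge bins excluded; flat spectra are rejected.

## Synthetic data

All generators are deterministic under a fixed seed (independent
substreams per generator) and emit the exact CSV/TSV dialects the readers
consume; file round-trips are tested.

*Variant panels*: fixed archetypes (wild-type-like hydrophobic motifs,
EGR swaps of one to three motifs, SS/SAS substitutions, T→W anchor, loop
deletion) plus random tripeptides. True activity is
`clamp(intercept + slope·H + noise, 0, 100)` with defaults slope = −3.1
%/unit and intercept = 42 % on the biological scale, chosen so the most
polar archetype sits at ≈100% (inactive) and the wild-type-like variants
near 30% — the dynamic range of the equimolar turbidity assay. Random
variants are rejection-sampled onto the hydropathy interval where the
linear map stays inside [0, 100], so at zero noise the truth is exactly
linear and the end-to-end round trip recovers it exactly; with noise
(default sd 3%, typical replicate scatter) the clamp only acts on the
noise term.

*Turbidity plates*: the control is a logistic in A360 (amplitude 0.5 AU,
half time 1800 s) on the 90 s cadence — the assay only uses the AUC, so
any saturating shape with controllable area suffices; variant traces are
the control scaled by activity/100 (AUC ratio = activity by linearity of
the integral), 3 replicates, additive Gaussian instrument noise
(default 0.005 AU).

*ThT panels*: baseline kinetics k_n = 4.6×10⁻⁵ s⁻¹M⁻¹, k₊ = 3×10⁶
M⁻¹s⁻¹, k₂ = 6.2×10³ M⁻²s⁻¹ at m0 = 3 µM, giving λ/κ ≈ 0.05 and a
control half time of ≈1.9 h — Aβ42-like, secondary-nucleation dominated.
The configured constant (default k₂) is suppressed to 100/50/20/10% at
ratios 0/10/50/100%; curves are scaled to fluorescence (F0 = 100,
A = 1000) with multiplicative Gaussian noise (default 2%), 4 replicates,
600 s cadence over 33 h.

*SEC*: a piecewise-Gaussian peak whose center maps to exactly the
configured subunit count (default 25) and whose half-height crossings map
to the configured range (default 18–30), on a fixed four-standard
calibration.

What the generators do **not** emulate: substrate-dependent trace shapes,
evaporation drifts and edge effects of real plates, polydisperse SEC
baselines, or chaperones that affect aggregate size rather than amount
(which decouples turbidity from true aggregation mass). Passing tests
therefore demonstrate correctness of the computations and identifiability
under the stated noise models, not robustness to every plate artifact.

## Problem sizes and determinism

Monte-Carlo studies use 100 simulations (sigmoid recovery, global-fit
model selection), 100 parameter draws for the closed-form-vs-ODE box and
1000 for boundary identities; the acceptance script scales the ODE box to
60 draws and model selection to 30 simulations, sizes at which the
Monte-Carlo error is well below the margins being tested. All randomness
flows from explicit seeds; hypothesis property tests run derandomized.
The pipeline manifests record a SHA-256 hash per output file, and reruns
with the same inputs and seed reproduce the hashes exactly.

## Known limitations

- Reproduction of the original study's printed regression numbers
  requires its per-variant supplementary panel, which has no public
  accession; those two validations fail honestly when the panel file is
  absent (they are not skipped).
- Only unseeded kinetics are modelled: no seeded-aggregation or
  fragmentation branches, and no fitting of reaction orders.
- Single-peak SEC estimation only; overlapping oligomer distributions are
  out of scope.
- The activity regression treats per-variant means as exchangeable
  points; replicate-level mixed-effects modelling is not implemented.
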