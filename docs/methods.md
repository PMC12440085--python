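# Methods

## Connectivity model

Functional connectivity between parcels *i* and *j* is the Pearson
correlation of their full preprocessed BOLD series, Fisher-transformed,
*z* = atanh(*r*). The transform is variance-stabilizing (for Gaussian
series, var(*z*) ≈ 1/(T−3)), which justifies averaging and pooled
t-testing of edge values across subjects. Correlations are clamped at
|r| = 1 − 10⁻⁶ before atanh so degenerate inputs (duplicated columns)
yield large finite z (≈ ±7.254) instead of infinities, preserving the
ranking of extreme edges while keeping downstream means and tests
finite. The diagonal is stored as NaN (written "NA" in TSV) and excluded
from every computation; edges are canonical unordered pairs (i < j) in
row-major upper-triangle order. No detrending, windowing or filtering is
done here — inputs are assumed already preprocessed.

## Edge-wise inference

The cross-sectional contrast is Δz = mean_A − mean_B per edge, tested
with a two-sided unpaired pooled-variance Student t on the per-subject z
values (Welch available via `test="welch"`). Raw z values are always
tested; the noise band never enters inference. The multiple-testing
family is all R(R−1)/2 edges jointly, corrected by the Benjamini–
Hochberg step-up (q_(i) = min_{k≥i} p_(k)·m/k, capped at 1); a
per-lobe-pair family is available via `fdr_family="per_lobe_pair"` for
analyses that correct within anatomical blocks. Degenerate zero-variance
edges are kept total: p = 1 when the means agree, the smallest positive
normal double when they differ, with a logged warning — this keeps the
vectorized pipeline from emitting NaNs on pathological fixtures.

The longitudinal (trial) effect is a difference-in-differences:
per-subject change matrices post − pre within each arm, then the same
edge-wise contrast of treated changes vs control changes. This is
algebraically identical to the group×time interaction of the balanced
2×2 repeated-measures ANOVA when time has two levels (interaction
F = t²); the test suite asserts that equivalence against an independent
mixed-ANOVA implementation to 10⁻¹⁰ rather than shipping a second ANOVA
engine. Consequences tested as identities: invariance to global baseline
shifts, negation under arm swap, and exact equality with the contrast of
precomputed change matrices.

The significance weight exported for ribbon/bubble scaling is
w = |Δz|·(1−q). The functional form of such weights is a presentation
choice, not an inferential one; this one is bounded, zero at q = 1 and
monotone in both effect magnitude and evidence. An alternative
|Δz|·(−log₁₀ q) scaling is available behind `weight_scheme="neglog10q"`.

## Noise band and directional classification

A band of ±0.05 on z separates meaningful positive (P), effectively zero
(Z) and meaningful negative (N) connectivity; the boundary |z| = 0.05
counts as meaningful, reading the band as an open interval. The band is
applied only to significant edges and only for interpretation.

Cross-sectional rule (d = mean_A − mean_B): the edge is attributed to the
group whose mean lies outside the band on the side consistent with
sign(d); when one group is clearly positive and the other clearly
negative, both qualify, and the group with the larger |mean| wins, with
the positive category preferred on an exact tie (the tie-break is a
deterministic convention for a case the banded semantics leave open).
Both means in the band → indeterminate.

Longitudinal rule (Δ = post − pre, banded signs s_pre, s_post):
more/less positive and more/less negative require the relevant endpoint
outside the band and the other endpoint not of opposite meaningful sign;
a full P↔N crossing is its own `sign_transition` category rather than
being forced into the four bars; both endpoints in the band (or Δ = 0)
→ indeterminate. Both rule tables are verified cell-by-cell against
independently hand-enumerated decision tables over a 7×7 grid spanning
±0.3.

Aggregation increments the symmetric label-pair cell (hemisphere, lobe
or network) of each classified edge with its count and weight;
within-label edges land on the diagonal. Conservation — Σ tally = number
of significant edges, upper-triangle+diagonal count = edges in, Σ degree
= 2·edges — is asserted on randomized fixtures.

## Synthetic cohorts

The generator draws per-subject series x_t ∈ ℝ^R from
x_t = φ·x_{t−1} + √(1−φ²)·L·ε_t, with L the Cholesky factor of the
target correlation matrix and a stationary start. The AR(1) innovation
sharing emulates the temporal smoothness of band-limited resting-state
signal while leaving the contemporaneous correlation exactly equal to
the target for any φ ∈ [0, 0.95) — sufficient because every downstream
statistic uses only contemporaneous correlation. The default φ = 0.4
adds realistic autocorrelation (which shrinks the effective number of
independent volumes and thus widens sampling noise); validation runs
that need exact calibration use φ = 0.

Group differences are injected on the Fisher-z scale — the scale on which
effects are tested — as z shifts at chosen edges, mapped back through
tanh. Base matrices are compound-symmetric at a background level
base_z = 0.1 (a modest positive background typical of parcel-level
resting data) unless a full matrix is supplied. After any injection the
matrix is repaired to positive definite by eigenvalue clipping at 10⁻⁶
with diagonal renormalization, and the realized z gap at every injected
edge is re-verified to within 10⁻³ of target (an error advises smaller or
sparser injections otherwise).

Defaults mirror the motivating study conditions: 116 volumes at TR 3 s;
cross-sectional groups of 56 (condition A) vs 18 (condition B); trials
of 20 subjects per arm with paired pre/post scans, where all pre scans
and control post scans draw from the base matrix and treated post scans
carry the injections. The default parcellation is 32 synthetic regions
(4 per lobe, round-robin over the 9 networks and 2 hemispheres,
shuffled by seed) — enough to exercise all label machinery at desk-scale
edge counts; it does not reproduce any real atlas. Injection magnitudes
used in validation (Δz = 0.5) are chosen for statistical power at these
sample sizes, not claimed to match any empirical effect distribution.
Every scan's random stream derives from (master seed, subject index,
scan index), so cohorts regenerate byte-identically and can be produced
in parallel.

What the simulator does not emulate: hemodynamic response shape,
physiological noise, motion artifacts, spatial autocorrelation of real
parcellations, non-Gaussian tails, or site/scanner effects. Passing
validation therefore demonstrates the statistical machinery is correct
under the stated generative model, not that any specific biological
finding reproduces.

## Regional layer

SUVr = regional uptake / pons uptake and volume ratio = volume / eTIV are
dimensionless, scale-invariant normalizations; comparisons run on the
normalized values. Per-region group tests use the same pooled t; marker
associations use per-region simple OLS (slope, Pearson r, two-sided
slope p), pooled across groups. FDR is applied within each anatomical
lobe, mirroring the convention of grouping regions by anatomical
position before correction. Slope p-values below machine resolution are
floored at the smallest positive normal rather than reported as zero. No
covariate adjustment (age, sex, lipids) is implemented: the modelled
analyses are unadjusted.

## Validation problem sizes

The packaged validation (tests and `scripts/acceptance.py`) uses 30
regions (435 edges), 20 subjects per group/arm and 116 volumes: 200
replicates for null FDR (realized FDR compared against
α + 3·Monte-Carlo SE), 50 replicates for recovery of ten injected
Δz = 0.5 effects (observed: sensitivity ≈ 1.0, realized FDR ≈ 0.04), and
200 subjects per condition for generative fidelity (|realized − target|
well under 0.05). These sizes give Monte-Carlo standard errors small
enough for the stated bounds while completing in seconds.

## Known limitations

* The edge test assumes independent subjects and roughly equal group
  variances (Welch is available but off by default).
* BH-FDR across correlated edges relies on the usual positive-dependence
  robustness of the step-up procedure; no permutation or network-based
  statistic is provided.
* The cross-sectional tie-break and the weight function are deterministic
  conventions for under-determined presentation choices; both are
  config-switchable and recorded in outputs.
* No covariates, no NIfTI/voxel handling, no preprocessing: inputs are
  parcellated series in delimited text.
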