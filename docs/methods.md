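# Methods

## Problem and approach

`metabodisc` reconstructs, as tested code, a classic ¹H-NMR metabonomic
discrimination workflow for two groups of cell extracts (a drug-sensitive
and a drug-resistant phenotype): spectral bucketing and total-area
normalization, OPLS-DA with Pareto scaling and sevenfold cross-validation,
CV-ANOVA model validation, and biomarker calling from back-scaled loadings
colour-coded by correlation coefficient with an analytic significance
cutoff. Because no real spectra ship with the package, a synthetic cohort
generator with known ground truth drives every stage.

## Synthetic spectra

Each metabolite is a list of Lorentzian lines `(centre ppm, relative area,
FWHM in Hz)` plus a baseline concentration. A spectrum is the sum over
peaks of area-parameterized Lorentzians (area ∝ level × relative area),
each metabolite's multiplet displaced by one per-sample shift offset drawn
from a Gaussian truncated at ±3 s.d. (mimicking pH-driven whole-multiplet
movement), plus white Gaussian noise. There is no FID-domain simulation:
no apodization, phasing, baseline distortion, J-coupling evolution, water
hump, or satellites. Multiplets must be written out as explicit peak lists.
Axes are stored in ascending ppm; plots flip to the NMR display convention.

Defaults of the bundled cohort (`default_cohort_scenario`):

| parameter | default | rationale |
|---|---|---|
| n_per_group | 10 | typical biological-replicate design for cellular metabonomics |
| spectrometer frequency | 600 MHz | standard high-field cell-extract work |
| axis | 0.5–9.5 ppm, 16384 points | ≥3 points per 0.002 ppm bucket |
| linewidth | 1.2 Hz FWHM | cryoprobe-quality lines |
| within_group_cv | 0.03 | low biological variation: a tightly controlled cell-culture cohort |
| noise_sd | 1.0 (≈0.1% of a major peak height) | high-SNR 1D NOESY-presat acquisition |
| shift_jitter_sd | 0.0002 ppm | buffered (pH 7.4), tightly referenced extracts; a tenth of the bucket width, the regime in which 0.002 ppm bucketing is meaningful at all. At jitter comparable to the bucket width, bucket contents scramble across samples and no binning scheme this narrow can work; positional drift of that size is what wider buckets or peak alignment are for, both out of scope. |

The library holds 36 metabolites with textbook-like chemical shifts for
cellular aqueous extracts. Positions and intensities are simulator
configuration, not measured assignments; peaks of perturbed metabolites are
deliberately kept ≥0.04 ppm away from other metabolites' peaks so that
window-level calls are attributable. Fourteen metabolites receive fold
changes in the resistant-analogue group (factors from {0.5, 0.6, 0.67,
1.5, 2.0}; GSH = 0.6, a decrease). Base levels were chosen so that the
*expected total spectral area is near-balanced between groups* (imbalance
≈0.1%): total-area normalization presumes roughly conserved total signal,
and a grossly unbalanced perturbation set would induce spurious apparent
changes in every unperturbed metabolite — a property of the normalization,
not of the biology being emulated.

What passing tests on this generator do *not* show: robustness to baseline
error, peak overlap in crowded regions, larger pH-driven shifts,
non-Gaussian replicate variation, or peak-shape changes — real-data
features the simulator does not model.

## Preprocessing

Buckets are left-closed half-open intervals `[left, left+0.002)` anchored
at 0.5 ppm; a trailing partial bucket would be discarded (none arises under
the defaults: (9.5−0.5)/0.002 = 4500 exactly). Bucket values are
trapezoidal integrals of intensity over the bucket's ppm interval, computed
from the cumulative trapezoid of the raw points evaluated at the bucket
edges — exact for edges between axis points and linear in the spectrum.
The water-suppression window 4.7–5.2 ppm is removed *conservatively*: any
bucket overlapping the window by positive length is dropped (250 buckets,
leaving 4250). Edge classification uses a 1e-9 ppm tolerance so buckets
that merely touch the window boundary are kept despite floating-point edge
arithmetic. Normalization to unit total area happens after exclusion and
uses only retained buckets. The anchor choice (low end) is recorded in the
matrix metadata; anchoring at 9.5 ppm instead would shift boundaries by
less than one bucket.

## OPLS-DA

Pareto scaling divides each mean-centred column by the square root of its
sample standard deviation (ddof=1); zero-variance columns are centred only,
their scale recorded as 1 and flagged, and they acquire zero weight
automatically (a centred constant column is identically zero).

The O-PLS NIPALS loop, per orthogonal round on the current X with centred
±1-coded y:

```
w      = X'y / (y'y),  normalised          t      = X w
p      = X't / (t't)                       w_orth = p − (w'p) w, normalised
t_orth = X w_orth                          p_orth = X't_orth / (t_orth't_orth)
X     ← X − t_orth p_orth'
```

After the requested rounds the predictive component (w, t_pred, p_pred, c)
is fitted on the deflated X. For a two-class y one predictive component is
the full predictive subspace; the default adds **one** orthogonal component
(the standard two-class OPLS-DA layout for score plots). The count is
configurable; nothing in the workflow depends on it beyond the variance
split, and R²X_pred/R²X_orth are reported separately against the total sum
of squares of the scaled X.

Class coding: the group listed *second* in the metadata codes +1, so a
positive back-scaled loading reads as "increased in the resistant-analogue
group".

Cross-validation uses stratified folds: within each class, indices are
shuffled with the run seed and dealt round-robin into 7 folds, so every
fold retains both classes whenever the class sizes allow. Per fold the
scaler **and** the model are refit on the training rows only (leakage-free
Q²); a `global_scaling` compatibility flag reproduces the
scale-once-globally behaviour of common chemometrics packages, which is
slightly optimistic. PRESS accumulates out-of-fold squared errors and
Q² = 1 − PRESS/SSY with SSY from the full centred y. Venetian-blind
(order-based) fold assignment was considered and rejected as the default
because it couples fold membership to sample order.

CV-ANOVA: F = ((SSY − PRESS)/df1)/(PRESS/df2) with df1 = number of model
components (predictive + orthogonal) and df2 = n − 1 − df1; p is the upper
tail of F(df1, df2). Degrees-of-freedom conventions differ between
implementations, so both dfs are recorded in the result. PRESS ≥ SSY clamps
F to 0 (p = 1).

## Biomarker calling

Back-scaled loadings multiply the predictive loading by each column's
scaling factor, restoring covariance-like magnitudes so intense buckets
dominate the plot the way peaks dominate a spectrum. Each bucket's colour
is |r|, its Pearson correlation with the predictive score t_pred
(STOCSY-style convention); correlating against the class vector y instead
is available via `corr_basis="y"` — on strongly separated cohorts the two
are nearly identical, and the t_pred basis is the default because the
colour code is meant to display contribution to the *modelled*
discrimination.

The analytic cutoff is r_crit = t_crit/√(t_crit² + df) with t_crit the
two-tailed (1 − α/2) Student-t quantile. The default df = n − 1 with n the
per-group replicate count gives the conventional 0.602 at n = 10, α = 0.05;
the textbook two-sample df = n_total − 2 (cutoff ≈0.444 at 10+10) is
available through the `df` argument. Ties at |r| = r_crit are
non-significant (strict inequality).

Bucket-to-metabolite aggregation is this package's construction (there is
no single community standard): a metabolite is called changed when the
median |r| over its assigned buckets exceeds r_crit *and* all its
significant buckets agree in loading sign; the shared sign maps through the
class coding to "increase"/"decrease" in the +1 group. The median makes the
call robust to low-|r| window-edge buckets; the sign-consistency rule
suppresses windows straddling two oppositely-changing signals. Assignment
windows default to peak centre ± 0.015 ppm, wide enough to absorb the
modelled shift jitter.

## Numerical choices and degenerate inputs

- Bin-count arithmetic uses floor((high−low)/width + 1e-9) to survive
  binary floating-point (9.0/0.002 is not exactly 4500 in float64).
- Degenerate NIPALS components (zero weight or zero score norm) raise with
  the component named rather than silently producing NaNs; a single-class y
  and an all-constant X are rejected up front.
- A fold whose training split would lose a whole class raises; round-robin
  stratification makes this impossible when each class has ≥ n_folds
  members.
- Normalization of an all-zero (or negative-total) bucket vector raises.
- Correlations of constant buckets are defined as 0 and flagged, never NaN.

## Problem sizes used in the test suite

The default cohort (20 spectra × 16384 points → 20 × 4250 buckets) runs the
full pipeline in well under a second, so the acceptance-level checks use it
directly, including the 200-permutation Q² null. Property sweeps that need
many replicate cohorts (recovery power vs fold change, null false-call
rate) use a reduced 3-metabolite configuration on a 0.5–3.5 ppm axis
(1500 buckets, 5/group) with 20–40 replicates per condition.

## Known limitations

- Only two-class OPLS-DA with a single predictive component; no OPLS
  regression on continuous y, multi-class models, VIP scores or SUS plots.
- No peak alignment, baseline correction, or variable-width bucketing; the
  simulator's jitter is accordingly kept below the bucket width.
- The bucket-to-metabolite aggregation rule and the df convention of the
  |r| cutoff are documented choices among defensible alternatives; both are
  overridable.
- Headline statistics of any specific real dataset (e.g. CV-ANOVA p-values
  of a published cohort) are not bit-reproducible here: they depend on
  unreleased data and on vendor software's exact CV deflation scheme.
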