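# Methods

## Connectivity model

Static functional connectivity is the sample Pearson correlation r_ij
between the time series of ROI i and ROI j, computed on the full retained
series (no windowing).  Correlations are mapped to positive similarities

    η_ij = exp(−ξ (1 − r_ij)/(1 + r_ij)),  ξ > 0 (default 2),

a strictly increasing function of r with η(1) = 1, η(0) = e^−ξ and
η → 0 as r → −1.  The transform exists to stop negative correlations from
cancelling positive ones in sums and means.  At r = −1 the underlying
hyperbolic distance diverges; the default clamps r to −1 + 1e−12 and warns
(at ξ = 2 the result underflows double precision and flushes to exactly 0,
which preserves monotonicity), and a hard-error mode is available.  The
matrix diagonal is defined as η = 1 but excluded from every downstream
sum and mean: nodal integration Γ_i sums the N−1 off-diagonal entries of
row i, and the network composites average each unordered ROI pair once
(upper triangle).  Under this convention Γ ∈ (0, N−1] and composites
∈ (0, 1], and for a constant off-diagonal η = c, Γ_i = (N−1)c and every
composite equals c — a conservation identity the tests pin.

## Atlas

The default atlas is 36 spherical ROIs (6 mm radius, MNI mm centres)
partitioned into six resting-state networks (DMN 6, DAN 6, FPCN 9, AN 4,
SMN 5, VN 6), shipped as a TSV and loadable from any file with the same
columns.  Atlas row order defines matrix indices.  Voxel membership for
time-series extraction is centre-within-radius (Euclidean, in mm), the
rule common sphere-ROI toolboxes use.  This yields 36 Γ measures,
6 intra- and 15 inter-network composites (57 summary measures) and 630
edges.

## Quality control

Frame-wise displacement follows the Power formulation: the sum of absolute
backward differences of the six realignment parameters, rotations
converted to arc length on a 50 mm sphere (configurable).  A subject is
excluded when mean FD exceeds the sample mean + 2 SD (sample SD, single
pass, no iteration).  The threshold is computed over the pooled sample by
default because the exclusion is a data-quality screen, not a group
contrast; a per-group variant is available via a flag.

## Group inference

Each measure is tested with the t statistic of the group coefficient in
measure ~ intercept + group + age + sex (group coded patient = 1, so
positive t means patients > controls).  Significance comes from label
permutation with the Freedman–Lane scheme when covariates are present:
reduced-model (nuisance-only) residuals are row-permuted, re-attached to
the nuisance fit, and the full model refit.  The permuted statistic is
evaluated in closed form — the nuisance fit lies in the design's column
space, so the group coefficient is w·PR (w the group row of the design
pseudoinverse) and the residual sum of squares is ‖R‖² − ‖UᵀPR‖² (U an
orthonormal design basis) — which avoids materialising the permuted
outcome tensor and makes thousand-permutation runs over hundreds of
measures essentially a few matrix products.  Equality with the explicit
refit is verified to 1e−15 in the tests.

Sampled permutation p-values use the add-one convention (1+b)/(1+B) so a
p of 0 is impossible; the raw proportion is available.  Without
covariates, when the number of distinct label assignments C(n, n_patients)
does not exceed the permutation budget, the null is enumerated
exhaustively and the p-value is the exact tail proportion (deterministic,
seed-independent).  Exhaustive enumeration is covariate-free only: under
Freedman–Lane a statistic value depends on the full permutation, not just
the label split, so assignments do not index that null.

Multiplicity: Benjamini–Hochberg FDR at α = 0.05, applied separately to
the 36 nodal measures and to the 21 network composites (two families with
different scientific granularity), alongside an explicitly lenient
uncorrected p < 0.05 tier.  Demographics tables use the two-sample t
(age), two-sided Fisher exact (sex and other binary factors; implemented
by hypergeometric enumeration with the point-probability rule and a 1e−7
relative tie tolerance), Mann–Whitney U (education, mean FD; exact when
combined n ≤ 12 without ties, otherwise normal approximation with tie
correction), and Welch's t (MMSE, MoCA, whose variances differ strongly
between impaired and intact groups).

## Network-based statistic

Per edge, the same covariate-adjusted model yields t and F = t².  Edges
with F strictly above the primary threshold (default 5.3) are split by the
sign of t into the two effect directions; connected components of each
directional graph are the candidate effects, sized by edge count.
Group labels are permuted (Freedman–Lane) and the maximal component size
recorded per permutation and direction.

A component of size M gets corrected p = (1 + #{null max ≥ M})/(B + 1),
where the null max is pooled over both directions.  The pooled null is a
deliberate design choice: both directions are reported together, and
testing each against its own null at α gives a family-wise error near 2α
in simulation (~0.07 at α = 0.05 under the generator's global null),
whereas the max statistic over everything reported keeps it below α
(~0.03 measured).  Per-direction nulls remain available
(`combined_null=False`), as does the strict proportion #{null > M}/B
(`paper_strict`), which is anti-conservative and can return 0.

Component extraction uses a union-find over the suprathreshold edge list —
the permutation loop visits ~2B tiny graphs per run — and is verified
against an independent breadth-first-search oracle on 1,000 random graphs.

### Power at a lenient primary threshold

F = 5.3 at df (1, 26) admits about 3% of the 630 edges per permutation
(~9 per direction).  On a 36-node graph that many random edges already
form components with median max size 3–4 and 95th percentile ~8 — before
accounting for the positive dependence between edges that share a network,
which enlarges the null further.  Consequently only components of roughly
15+ edges can reach family-wise significance at this threshold, and a
planted 6-edge effect (observed size ~10–12 with spillover) is usually
detected descriptively but not confirmed: measured recovery of such a
plant at δ = −0.25 is ~0.15–0.3, not a power the threshold permits.  This
is a property of the component-size statistic at a lenient threshold, not
of the implementation; the same deficit is flagged reliably by the
network-composite tier, which aggregates the 20 AN–SMN edges into one
test.

## Brain–behavior association

Altered measures (uncorrected tier, patients only) are Spearman-correlated
with MMSE and MoCA.  Pairs with missing scores are dropped pairwise.
Outliers are removed in a single pass with the Tukey rule per variable:
points outside the closed fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (quartiles
by linear interpolation between order statistics) are excluded and always
reported; a bivariate variant (fence on robust Theil–Sen residuals) is
selectable.  Spearman p is exact by enumeration for n ≤ 7 without ties,
otherwise the t approximation.  No multiplicity correction is applied at
this tier — it is declared exploratory, with p < 0.05 flags only.  Fewer
than five surviving points suppresses the correlation with an error.

## Synthetic-study generator

The generator emulates the target study design: 15 patients and 15
controls, T = 220 timepoints, the 36-ROI six-network atlas.  Group-level
population correlation matrices are block-structured — within-network
r = 0.3, between-network r = 0.0 by default, emulating ROI series after
nuisance regression (including global-signal removal), after which
between-network correlations center near zero and within-network levels
run ~0.2–0.4.  Planted effects add δ to chosen edges (or whole network
pairs) in one group; the default planted component is a 6-edge AN–SMN
path with maximum node degree 2, so δ = −0.25 keeps the target positive
definite without repair.  Non-positive-definite targets are repaired by
eigenvalue clipping with re-normalisation to unit diagonal; a repair
moving any entry by more than 0.05 rejects the configuration.

Series are multivariate normal innovations (Cholesky factor of the
target) passed through a common AR(1) filter (coefficient 0.3, mimicking
band-passed fMRI smoothness).  Because all channels share the filter, the
cross-channel correlation matrix is exactly the target at any AR level;
the AR term only widens the sampling variability of per-subject
correlation estimates, as it does in real data.  Demographics (age
distributions, sex splits, mean-FD levels, MMSE/MoCA means and SDs per
group) are sampled from the cohort characteristics the pipeline is
designed around.  Cognitive scores are intercept + slope·η(target edge) +
noise, rounded and clipped to [0, 30], with slope 0 (no coupling) by
default.  All randomness flows from one study seed through spawned
per-subject child seeds.

What the generator does not model: hemodynamics, physiological noise,
scanner drift, motion artefacts in the series themselves, heterogeneous
within-network correlations, and negative between-network coupling.
Passing calibration tests therefore demonstrates the statistical machinery
is correct under the stated covariance model, not that real-data effect
sizes will match.

## Numerical choices and limitations

- Permutation tie handling compares |t*| ≥ |t| − 1e−12 to avoid
  floating-point misclassification of exactly-equal statistics.
- Correlation matrices are clipped into [−1, 1] and symmetrised against
  rounding before transformation; η at the r = −1 clamp flushes to 0.
- Edge ties exactly at the F threshold are excluded (strict >).
- Measured operating characteristics at the defaults (B = 1000 per
  study): NBS family-wise error under the global null ~0.03; behavior
  association null flag rate ~0.05; a strongly coupled (edge, score) pair
  ranks first in ~100% of replicates.  These are recomputed by
  `scripts/acceptance.py` and asserted (with the planted-recovery bound
  discussed above) in `tests/test_acceptance.py`.
- Monte-Carlo scales (200 null studies, 50 recovery replicates, 500
  association replicates, B = 1000) were chosen to give binomial standard
  errors of ~0.01–0.02 on the measured rates while keeping a full
  calibration run near one minute on a single CPU.
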