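# Methods

This note documents the statistical models implemented in `ventbeta`, the
choices made where conventions diverge, and what the synthetic-data tests
do and do not demonstrate about real survey data.

## Data model

All analyses consume an `IncidenceMatrix`: an ordered sites × species
boolean grid. Abundance information enters only through the estimators
module (Chao1, rarefaction). Species columns that are empty (occupancy
frequency 0) are retained for label bookkeeping but excluded from γ and
from coverage targets; the minimum-set solver warns when it drops them.

**Field merging.** Vent "fields" closer than a threshold (default 3 km)
are combined into one site, reflecting the working assumption that such
fields tap a shared heat source. Distance is great-circle (haversine) on a
spherical Earth, R = 6371 km — at a 3 km scale the spherical approximation
errs by far less than the uncertainty of the station coordinates. The
merge takes the transitive closure of the "closer than threshold"
relation, so chains collapse into one site, and the merged label
concatenates members in input order. Because geological judgment can keep
nearby-but-distinct sites separate (several southern back-arc sites are
2–3 km apart yet treated as independent), merging is an explicit operation
the user applies, never an implicit default.

## Pairwise partition

With `a, b, c` the shared/unique species counts of a pair and
`n = a + b + c`:

- `O = a/n`, `R = 2·min(b,c)/n`, `D = |b−c|/n`; these sum to 1 and place
  the pair on the simplex.
- `β = 1 − O = R + D` (Jaccard dissimilarity), `N = O + D` when the pair
  shares at least one species.
- When `a = 0` the pair is given `N = 0` and `I = 0`, `RC = β = 1`:
  a disjoint pair carries no nestedness signal, and all of its
  dissimilarity is assigned to the complement component.
- `β_ratio = I/β` is undefined for identical sites (β = 0); such pairs are
  reported as missing and excluded from β_ratio summaries rather than
  imputed.

Summaries report mean, median, min, max per component; medians accompany
means because pairwise dissimilarity distributions from small systems are
routinely skewed.

Whittaker's multiplicative β is computed as γ divided by mean α. With the
bundled per-site richness of the three vent systems this gives 1.96
(back-arc), 3.495 (arc; published as 3.49 after pre-rounding the mean to
12.9) and 2.15 (ridge — computed from the listed α values whose mean is
33.0, consistent with the printed ratio).

## Raup–Crick null model

The null hypothesis is random assembly from the regional pool under two
constraints: each site keeps its observed richness, and species are drawn
without replacement with probability proportional to their observed
occupancy frequency (species found nowhere are never drawn). Sampling
uses exponential sort keys (`Exp(1)/w_j`, keep the α smallest), which is
distributionally identical to sequential weighted draws with
renormalization and vectorizes across replicates; tests validate it
against an exhaustive enumeration of the sequential scheme on small cases
and against an independent reference implementation of the same null
model.

Null replicates are whole matrices — every site redrawn per replicate, all
pairs scored against the same replicate stream. For each pair,

    rc_dissim = [ #(SS_null > SS_obs) + 0.5·#(SS_null = SS_obs) ] / n_sim

where SS is the shared-species count, and `β_RC = 2·rc_dissim − 1`. Ties
are split (half-weight) following the probabilistic reading of the index;
the alternative full-weight convention (used by some reference software,
which also adds a +1 continuity term) shifts borderline pairs — the raw
`P(SS_null ≥ SS_obs)` is therefore stored alongside (`p_ge`) so either
convention can be recovered. Significance at confidence level `ci` means
`|β_RC| ≥ ci`, equating each tail to `(1 − ci)/2` of probability mass;
`similar` flags β_RC at or below the negative bound, `dissimilar` at or
above the positive one. Defaults: 9,999 replicates, 95% band, mandatory
seed.

**Calibration.** "Data generated by the null model itself" requires a
concrete frequency profile, so the calibration harness is two-stage: a
random-regime template matrix fixes occupancy frequencies, each
calibration dataset is a whole-matrix null replicate of that template, and
the test is then run on the dataset exactly as a user would (weights
re-estimated from the dataset). At the default 8 × 40 scale this yields a
type-I rate of 4–5% at the 95% band and under 1% at the 99% band. The
rate sits slightly below nominal because shared-species counts are
discrete: the atom of probability at the cutoff is half-counted, never
over-counted, so the test is mildly conservative and not anticonservative.
Generating calibration data directly from a continuous abundance law
instead (e.g. the geometric frequency law) is *not* a null-model draw —
the frequency-weighted null cannot represent an arbitrary law, and that
mismatch masquerades as assembly signal.

## LCBD

Total β-diversity is the total variance of the community matrix: with
`d_ij = sqrt(β_J(i,j))`, form `A = [−d_ij²/2]`, double-centre (Gower) to
`G`; then `SS_total = trace(G)` and `LCBD_i = G_ii / SS_total`. The square
root is what makes the Jaccard coefficient Euclidean-embeddable, hence `G`
positive semidefinite and every contribution non-negative (asserted
numerically at 1e−10). LCBD values sum to 1 by construction; the analysis
refuses matrices with no β-diversity at all.

Significance: each species column is permuted independently across sites —
the null preserves every species' occupancy frequency while destroying
site identity — and `p_i = (1 + #{LCBD_null_i ≥ LCBD_obs_i}) / (1 +
n_perm)`, the add-one form avoiding zero p-values at finite replicates.
Default 9,999 permutations, seeded.

## Estimators

Chao1: classic `S_obs + F1²/(2F2)`; when no doubletons exist the classic
form is undefined and the bias-corrected form
`S_obs + F1(F1−1)/(2(F2+1))` is substituted automatically (the variant can
be forced). Rarefaction uses the hypergeometric expectation
`E[S_n] = Σ (1 − C(N−N_i, n)/C(N, n))` computed through log-gamma, exact
against subsample enumeration on small vectors and stable to N ≈ 1e5.

## Inference

Permutation ANOVA uses the one-way F statistic with nulls from random
reassignment of the pooled values to groups of the original sizes;
the permutation t-test uses the pooled-variance two-sample t, two-sided.
Both report `(1 + #exceedances)/(1 + n_perm)` and sort the pooled values
before drawing permutations so p-values are invariant to input order.
Kendall's τ-b handles ties; its p-value is exact (Mahonian enumeration)
for n ≤ 9 without ties, otherwise a normal approximation with
tie-corrected variance and continuity correction.

A caveat carried through the documentation: pairwise dissimilarities
within a system share sites, so cross-system tests on them treat
non-independent values as exchangeable. Results are descriptive of the
pooled distributions, not strict tests on independent replicates.

## Minimum set and group splits

The minimum set is solved exactly by ascending-size exhaustive search over
site subsets (bitmask unions), refusing matrices beyond 25 sites where a
greedy heuristic (flagged non-exact, lowest index on ties) takes over. All
minimal solutions are enumerated because alternative covers are exactly
what a planner weighs. `group_overlap` and `subset_pairs` handle
two-system regions: per-group γ, shared species, and within/between pair
partitions.

## Clustering

UPGMA (size-weighted average linkage) is implemented directly so that the
tie-break — lowest-index pair first on equal minimum distances — is
deterministic and documented; on tie-free inputs it agrees exactly with
standard average-linkage implementations (tested via cophenetic
distances). Merge heights are average inter-cluster dissimilarities at
merge time, giving an ultrametric; Newick export places each node at half
its merge height so root-to-leaf depths are equal.

## Synthetic communities

The generator emulates the structure, not the biology, of multi-site
incidence surveys at the scale of the study systems: defaults of 8 sites ×
40 species, per-site richness targets spanning roughly 30–70% of the pool
(a 2–3× α range), and a geometric occupancy-frequency law (ratio 0.8) that
reproduces the skew of real vent checklists, where singletons are 20–50%
of the pool and a handful of species are ubiquitous. Regimes: `random` is
the Raup–Crick null itself; `nested` ranks species and gives site i the
top α_i, making every pair strictly nested (R = 0, β_ratio = 1 where
defined); `turnover` slides equal-richness windows along the ranked pool
(D = 0, β_ratio = 0); `mixed` blends a shared core with per-site windows,
interpolating mean replacement between the extremes. Generation is
bit-reproducible from the spec's seed.

What passing these tests shows: the analytical chain recovers known
structure exactly and the null-model inference is calibrated under its own
assumptions. What it does not show: robustness to detection failure
(false absences), uneven sampling effort between sites, taxonomic
lumping/splitting, or spatial autocorrelation — none of which the
generator emulates, and all of which affect real survey matrices.

## Numerical and interface choices

- Every stochastic routine requires an explicit seed; the pipeline derives
  per-stage streams from one master seed via CRC-salted `SeedSequence`, so
  a bundle is a pure function of (inputs, config, seed) and reruns are
  byte-identical.
- Pipeline problem sizes in tests and the acceptance script are scaled to
  run in seconds (hundreds of replicates per test, 999–9,999 where the
  quantity is a headline number); all statistics are estimators whose
  precision grows with the replicate counts the user sets.
- Wide-CSV round trips are lossless; long CSV cannot represent empty
  species columns or arbitrary column order (orders are first-appearance)
  and is exact only on matrices where those coincide.
- Degenerate inputs fail loudly: empty pairs, single-site matrices,
  identical-composition matrices (for LCBD), constant vectors (for τ),
  richness exceeding the positive-frequency pool (for the null model).

## Known limitations

- The Raup–Crick test conditions on observed occupancy frequencies; with
  very few sites the weight estimates are coarse and the test mildly
  conservative.
- LCBD p-values use the standard independent-column permutation null; any
  real interspecific association structure is destroyed under that null.
- The minimum set optimizes presence coverage only — no costs, areas or
  complementarity weights.
- Bundled published data are system-level summaries (α, γ, environment,
  checklist), not the full site-by-species matrices, so full-matrix
  analyses of the real systems require the user to supply those matrices.
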