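# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `erpconsensus`, in the order the pipeline uses them.

## Data model

The unit of analysis is a per-subject, per-condition ERP epoch matrix
(time-points × channels, µV, average-referenced). Conditions are
temporally concatenated in a fixed, recorded order, so a subject with two
300-sample conditions at 65 electrodes contributes one 600 × 65 matrix.
Rows are *topographies* — the scalp field at one time-point — and all
clustering operates on their spatial similarity. Correlation-based methods
(hierarchical, modified k-means, AAHC) see average-referenced rows, the
microstate convention; Euclidean methods (k-means, FCM, SOM, spectral) see
the raw rows, where overall field strength is informative.

## Base clusterers

Seven methods share one interface (`run_base`), each returning a hard
partition with canonical 1..k labels (first-occurrence order):

- **k-means** — Euclidean, scikit-learn, best of `restarts` inits.
- **hierarchical_corr** — average-linkage agglomeration of the distance
  1 − spatial correlation, cut at k. Deterministic.
- **fcm** — fuzzy c-means with fuzziness 2.0, defuzzified by maximal
  membership; implemented in-package (standard alternating updates).
- **som** — a batch self-organizing map on a 1 × k grid, units initialized
  along the first principal axis, Gaussian neighbourhood shrinking from
  k/2 to 0.25 over 30 epochs; each unit is one cluster. In-package.
- **diffusion_spectral** — Gaussian affinity with median-distance
  bandwidth, symmetric-normalized diffusion operator, top-k eigenvector
  embedding scaled by eigenvalues, Euclidean k-means in the embedding.
- **modified_kmeans** — microstate k-means: assignment by maximal spatial
  correlation with each template; templates refit as cluster mean maps, or
  as the dominant eigenvector of the members' channelwise scatter in the
  polarity-invariant variant (selectable; the default is polarity-aware
  because polarity is informative in ERPs). Empty clusters are re-seeded
  from the worst-fit time-point. Best of `restarts` by global explained
  variance (GEV).
- **aahc** — atomize-and-agglomerate: start from singletons, repeatedly
  dissolve the cluster contributing least GEV and reassign its members to
  the remaining cluster whose template they correlate with best, stop at
  k. Deterministic.

Ties in assignments break toward the lowest cluster id.

## Consensus function (CSPA) and its robustness measures

The consensus of a set of partitions is the average-linkage cut, at k, of
1 − co-association (fraction of partitions placing two points together).
Two numerical safeguards matter in practice:

- Co-association distances over m partitions take only m + 1 distinct
  values; scipy's NN-chain linkage can emit an invalid tree on such
  heavily tied inputs. When that happens the linkage is rebuilt with a
  deterministic symmetric perturbation of order 1e−9 — far below the 1/m
  tie quantum, so no non-tied comparison can flip.
- Average linkage peels extreme outliers off as micro-clusters. A handful
  of erratic time-points (transition samples between anticorrelated
  states, where the net field is near zero and subjects' partitions
  scatter) can then consume cluster ids and force genuine states to merge.
  If the plain cut yields fewer than k clusters with at least
  `min_cluster_size` members (2 below n = 400, else 3), the dendrogram is
  cut deeper until k substantive clusters exist and the debris points are
  absorbed into the cluster they co-associate with most. Unanimous
  ensembles whose clusters all reach the floor pass through unchanged.

## Stabilization and method selection

Stochastic methods are stabilized on the grand average: run Mr = 20 times,
form the consensus of the first r runs for r = 2..20, and accept the
smallest r (starting at 3, since the criterion references r − 1 and r + 1)
whose consecutive mutual similarities all reach τ = 0.90 with changes at
most ε = 0.03; otherwise r = Mr with a logged non-convergence. The
calibrated repeat count is then reused for every subject (a per-subject
recalibration flag exists but is off by default).

Selection clusters every subject with every candidate (stabilized where
stochastic) and with the modified-k-means benchmark, and keeps candidates
whose Rand index with the benchmark reaches `sim_threshold` (default 0.8)
on at least half the subjects. The benchmark is always retained.

## Time-window determination

Partitions are first smoothed temporally: label runs shorter than
`min_segment` = 3 samples are reassigned to the neighbouring run whose
mean topography they correlate with best, independently inside each
condition slice. This is the standard microstate segment-rejection step;
it removes single-sample label flips that would otherwise split a
contiguous map run, and at 3 samples (~7 ms) it is far below any window
duration of interest.

Within a component's experimental interval, each cluster contributes its
longest interval-intersecting run. The run's inner-similarity is the
Fisher-z average of all pairwise spatial correlations of its time-points
(correlations clipped to ±(1 − 1e−7); a literal variance-stabilization of
the *distances* 1 − r is not computable, since arctanh requires arguments
inside (−1, 1), so the transform is applied to the correlations
themselves, which reproduces `InnSim = 1 − D_avg` for `D = 1 − r`).
Qualification requires inner-similarity ≥ 0.90, duration ≥ 60 ms (counted
as time-points × sample period — note that a printed 59 ms window spans 26
samples ≈ 61 ms of signal), and interval coverage ≥ 1/3. The coverage
floor exists because without it a neighbouring component's cluster, whose
run merely brushes the interval, wins whenever the target cluster narrowly
fails another filter — turning a near-miss into a gross misdetection
instead of an honest no-window outcome, which the statistics layer
excludes pairwise. Among qualifiers the product
inner-similarity × overlap decides (a lexicographic rule is selectable);
the chosen run, in ms on the epoch grid, is the measurement window.

`choose_k` scans a range of cluster counts, runs the whole pipeline per k,
and scores each k by the mean inner-similarity × overlap of the detected
windows — a pragmatic stand-in for a full cluster-number criterion.

## Synthetic studies and what they do (not) show

The generator emulates a dipole-simulator-style validation study: six ERP
components (P1, N1, P2, N2, P3, N4), two conditions, 20 subjects, 65
quasi-uniform electrodes on a unit disc, epochs −100..600 ms at 429 Hz
(300 samples per condition), white Gaussian noise at SNR 20 dB measured on
each subject's whole dataset, and a per-subject latency shift of up to ±5
samples applied to the signal as a whole (inter-subject response-latency
variability; an independent per-component jitter mode exists). Components
are raised-cosine envelopes times fixed scalp maps (sums of weighted
spatial Gaussians, average-referenced, unit peak); N2 spans 175–292 ms
peaking at 233 ms (negative, right-posterior), P3 spans 240–385 ms peaking
at 310 ms (positive, centro-parietal). Ground-truth measurement windows
come from the signed-area rule — the shortest run of samples holding a
fixed fraction of the polarity-signed area — with per-component fractions
solved in closed form so the clean N2 and P3 templates yield 201–265 ms
and 265.97–356.88 ms on the sample grid. Ground truth is computed on each
component's own clean envelope (components overlap in time, so a mixed
waveform would contaminate it), both jitter-free at study level and
jitter-shifted per subject for individual-level accuracy.

Three generator features deserve comment because they were design choices,
not givens:

- **An ongoing background rhythm** (one fixed dipolar scalp field, present
  before stimulus onset and again after the evoked sequence, suppressed in
  between) gives the pre-stimulus period a coherent topographic state.
  Without it the baseline is channel-iid noise, which cannot form a
  cluster, scatters across all clusters, and starves the k = 7 budget.
  Real baselines have spatial structure; pure white noise does not.
- **Component timing/amplitude defaults** were calibrated once, at design
  time, so the topographic handover points between adjacent components sit
  near the signed-area window edges — the regime in which clustering-based
  windows can agree with signed-area windows at all, and the regime the
  original validation design evidently occupied. All seven state maps
  correlate below ~0.25 pairwise.
- **Between-subject gains** (whole-response gain SD 0.10; condition-2 task
  gain SD 0.12) make the task effect a random effect across subjects, so
  ANOVA p values land in a realistic range (~1e−5) instead of degenerating
  to ~1e−22. Being whole-matrix scalings they leave every within-condition
  amplitude ratio — hence every crossover and true window — untouched.

Passing on these data shows the machinery recovers windows under
calibrated noise, latency variability and subject heterogeneity. It does
not show robustness to artifacts, non-Gaussian or temporally correlated
noise, drifting topographies within a component, or misspecified k — real
recordings have all of these.

## Statistics

- **TOST**: two one-sample t tests on per-subject differences,
  t₁ = (mean + δ)/(s/√n) against the upper tail and t₂ = (mean − δ)/(s/√n)
  against the lower tail, df = n − 1, margin δ = 5 ms, α = 0.05; the
  companion 90 % CI of the mean difference is reported. Zero-variance
  samples inside the margin give p = 0 by convention (logged), outside
  p = 1. Missing per-subject windows are excluded pairwise, never imputed.
- **ANOVA**: the two designs the evaluation needs — within-only two-level
  task (F equals the squared paired t) and balanced mixed 2 × 2 with a
  between-subject group factor, by standard partitioned sums of squares.
  Two levels need no sphericity correction. Unbalanced designs are
  rejected.
- **Robustness**: the pipeline is re-run n times (default 50; scaled runs
  use 20) with derived seeds on fixed data; deterministic methods are
  computed once and cached since they cannot vary. The report holds
  per-effect mean and SD of the p values and every seed used.

## Numerical conventions

Sample i maps to epoch_start + i/f_s × 1000 ms; windows are closed
intervals [first-sample ms, last-sample ms]; all user-facing times are ms,
internal indices 0-based. A master seed is fanned out with
`numpy.random.SeedSequence` into per-method, per-subject, per-repeat
sub-seeds (all below 2³¹), making every stage independently reproducible.

## Scale of the shipped experiments

The test suite runs the full 20-subject, 65-channel study once (shared
session fixture) for the isolation and equivalence checks, a 20-rerun
robustness comparison, and reduced studies (4–10 subjects, 16–32 channels)
elsewhere; these sizes keep a complete run to a few minutes while the
full-scale checks still exercise the study design at its published size.
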