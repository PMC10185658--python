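# Methods notes

## Network construction

The package works with Pearson-correlation networks throughout. The
population network pools all `N` individuals; the leave-one-out (LOO)
network for individual `q` is re-estimated on the other `N − 1` rows; and
the individual-specific network (ISN-L) interpolates linearly,
`w^q = N w^a − (N − 1) w^(a−q)`, so that as `N` grows the population
network is approximately the average of the ISNs. The SSN differential
`w^a − w^(a−q)` carries the same information up to the affine map
`ssn = (isn − w^a)/(N − 1)`; both representations are exposed and the
algebraic identities are enforced by tests to machine precision.

LOO correlations for all `N` individuals are computed by downdating the
pooled cross-product sums (cost `O(N p²)` total rather than `N` full
passes); the input is centred first so the downdate is numerically stable.
The association measure is pluggable (`population_network(data,
association=...)`) but Pearson is the default and the only measure used in
the benchmarks; mutual-information edges are out of scope.

Edge order is fixed everywhere as the upper triangle in row-major order
over the module's node sequence. Constant columns are rejected at ingest
rather than silently propagating NaN correlations.

## Detectors

**Empirical-null LOO tests.** For a module with edge set `Me`, the observed
statistic per individual is `T_q = Σ_{(i,j)∈Me} |w^a − w^(a−q)|` (LOO-ISN)
or the corresponding maximum (MultiLOO-ISN). Absolute differences are used
in both statistics so that deviations in either direction count; a
`signed` switch restores the raw-difference variant. The null distribution
comes from `Rep` datasets of `N` rows drawn from a multivariate normal with
zero mean and covariance equal to the estimated module adjacency (repaired
to the nearest PSD matrix by eigenvalue clipping at 1e−10 when round-off
makes it indefinite); from each null dataset one uniformly chosen
individual is removed and the same statistic computed. Both statistics are
extracted from one shared simulation, so the two tests agree run-for-run on
single-edge modules. Empirical p-values use `(1 + #{T̂ ≥ T_q})/(Rep + 1)`,
never exactly zero; the outlier score is `1 − p`. `Rep` defaults to 1000;
the benchmark suites use 300 (p-value resolution 1/301 is ample when only
the ranking feeds an AUC). Type-I error at nominal 0.05 is verified to lie
in [0.02, 0.10] over 200 null datasets at `Rep = 1000`.

**Modular Cook's distance.** For each target edge `c` of the `C` module
edges, a linear model predicts edge `c`'s per-individual ISN weight from
the other `C − 1` edge weights plus an intercept. Cook's distance for
individual `q` uses the classical residual-leverage form with denominator
`(C + 1)σ̂²`, `σ̂² = SSE/(N − C)`. The denominator is a per-target
constant, so the aggregated ranking is insensitive to the exact parameter
count convention. All `C` regressions are solved at once via the
partitioned inverse of the augmented Gram matrix `[1, F]ᵀ[1, F]`: the
residuals of model `c` are `Z G e_c / G_cc` and the reduced-design
leverages are `h_Z − e²G_cc`, giving an `O(NC²)` total instead of `C`
separate fits. A brute-force delete-one refit oracle confirms equality to
relative error below 1e−8. The per-individual distances over the `C`
targets are aggregated by max, median or mean. The method needs `k > 2`
(with one edge there are no predictors) and `N > C + 1` (else the model is
saturated); other inputs yield a not-applicable result.

**kNN.** The outlier score is the mean Euclidean distance to the
`k_min`-th through `k_max`-th nearest neighbours (self excluded), computed
on the raw module feature matrix without standardization — the edge
weights share a scale by construction. Two named variants fix the range:
`kNN log(N),P` uses min/max of `ln N` (natural log, rounded) and the module
size; `kNN 5,sqrt(N)` uses min/max of 5 and `√N` rounded.

**OPTICS outlier factor.** Core distance = distance to the MinPts-th
neighbour; reachability from `p` to neighbour `o` is
`max(core(o), d(p, o))`; local reachability density is the inverse mean
reachability over the MinPts neighbourhood; the score is the mean ratio of
neighbour densities to own density (≈1 in homogeneous regions). Neighbour
ties are broken by ascending index. The implementation is cross-checked
against an independent LOF implementation on small instances (the formulas
coincide for point data).

**Spoutlier / OTS / mOTS.** One reference set of `s + 1 = 21` individuals
is sampled per call; a target inside the reference uses the other `s`
points, any other target drops one uniformly at random, and zero distances
to exact replicates are kept — this is the replicate-aware scheme. The
literature variant (`Spoutlier-l`) samples `s` points and replaces zero
distances by the smallest non-zero one. Distances are Euclidean or cosine
dissimilarity (`1 − cos`); cosine needs `C ≥ 2` feature dimensions and is
not applicable to single-edge modules. `mOTS` repeats the draw 10 times
and takes the per-individual median score. The combination rule for
`mOTS glob` is not pinned down by its description, so the package
rank-normalizes each metric's ensemble scores to [0, 1] and averages —
scale-free and monotone-invariant. When `N ≤ s + 1` every target simply
uses all other points (the exhaustive limit).

**SSN Z-test.** `Z = ΔPCC/((1 − PCC²)/(n − 1))` in the leave-one-out
framing: `PCC` is the LOO edge on `n = N − 1` individuals and `ΔPCC` the
change when the individual is added back. The null hypothesis is an
equality of expected edge weights, so the p-value is two-tailed normal;
the score is `|Z|`. Single-edge only.

All stochastic detectors take an explicit seed. Scores are
orientation-consistent (higher = more outlying) so downstream AUC never
needs per-method sign flips.

## Synthetic benchmarks

**Normal scheme** (co-expression): controls are i.i.d.
`N(0, Σ_ctrl)`; the `M` outliers draw from `N(0, Σ_out)`, one shared
`Σ_out` in "common" mode or an independent one per outlier in "specific"
mode. Both covariances are random correlation matrices from a C-vine
construction with Beta(a, a) partial correlations; `a = 1` (uniform
partials) gives mean |off-diagonal| ≈ 0.40–0.45 across module sizes 5–17,
a moderate concentration typical of a co-expression module. Both matrices
are overridable for users with a specific covariance scheme in mind. Rows
are shuffled after concatenation (seeded) so outliers carry no positional
signal. The grid crosses N ∈ {100, 500, 1000, 2000}, M ∈ {1, 5, 10},
k ∈ {2, 3, 5, 7, 9, 11, 17} and the two outlier modes: 168 settings.

Because each outlier's covariance is drawn independently of `Σ_ctrl`, the
covariance shift is strong; on the modular strata (k ≥ 5) the best
detectors approach AUC 1 — see the calibration caveat below.

**Compositional scheme** (microbiome): concentration masses `D` over
`p = 10k` taxa come from Pareto(1, 0.7) (high heterogeneity), Pareto(1, 4)
(mild) or all ones (none). Cases inflate `perc_increase · p` randomly
chosen taxa (rounded, minimum one) by `mult` and renormalize to `Σ D`, so
cases differ compositionally but not in total mass; both vectors are then
scaled by intensity 3 and used as Dirichlet concentrations, with each
individual's probabilities feeding a multinomial of 5000 reads. Counts are
CLR-transformed after adding a pseudocount of 1 (zeros are certain under
multinomial sampling; the value is configurable). The network is sampled
ten times larger than the module to avoid bias toward perfect negative
correlations, and the module — guaranteed by rejection sampling to contain
at least one inflated taxon — is extracted only at the end. The grid
crosses N ∈ {100, 500, 1000}, M ∈ {1, 5, 10}, k ∈ {2, 5, 11, 17}, the
three heterogeneity levels, mult ∈ {1.1, 1.5, 2} and perc ∈ {10%, 25%,
40%}: 972 settings.

What the generators do *not* emulate: phylogenetic correlation between
taxa, library-size variation (reads are fixed at 5000), batch structure,
and heavy-tailed expression noise. Passing benchmarks therefore show that
the detectors recover association-structure outliers under the stated
sampling models, not that they are robust to every artefact of real data.

## Evaluation

Outlier scores are compared to ground truth with the Mann-Whitney AUC
(ties 0.5; verified exactly against a pair-counting oracle). Aggregation is
two-stage: per (method, setting) the median AUC over runs, then the median
and mean of those per-setting medians across settings. Where a reported
table's "mean" could average per-setting means instead, the package
defaults to the mean of per-setting medians (the per-setting summary is
defined as the median throughout); a pooled flat aggregation is available
for diagnostics. Methods inapplicable to a setting are excluded from that
setting's aggregates, not imputed. Seeding is hierarchical (master →
setting → run → consumer, via `SeedSequence` with stable registry
positions), so results are independent of execution order and of which
other methods run.

## Desk-scale benchmark sizes

The full study (168 × 200 + 972 × 150 runs) is cluster-scale. The bundled
suites (`isnsig.benchmarks`) run stratified subsets chosen to preserve
each scheme's structure at minutes of compute: normal-scheme
N ∈ {100, 500} × k ∈ {5, 11, 17} × M ∈ {1, 5} × both modes at 30 runs per
setting; compositional N ∈ {100, 500} × k ∈ {2, 5, 11} × M ∈ {1, 5} at 25%
inflation across all heterogeneity levels, 30 runs (multiplier 2) and 20
runs (multiplier 1.1). Null tests use `Rep = 300` here.

A calibration caveat follows from the stratification: the subsets drop the
hardest strata of the full grids (k = 3 for Cook's distance, M = 10,
10% inflation, the largest sample sizes), so subset aggregates sit above
the corresponding full-grid table values — markedly for the normal scheme,
where Cook's median AUC saturates near 1.0 on k ≥ 5 strata, mildly for the
compositional scheme (LOO-ISN lands on the full-grid value almost exactly;
kNN runs a few hundredths high). The compositional generator is fully
specified by its stated parameters; the normal-scheme covariances are
this package's documented stand-ins.

## Network follow-up tools

Filtration curves sweep an increasing threshold, zero out edges with
weight below it, and record the Fiedler value (second-smallest eigenvalue
of `L = Deg − W`, diagonal ignored) of each thresholded graph. Negative
ISN edges are kept as-is by default — thresholding "weight < t" removes
the most negative edges first — with an absolute-value option; how
negative edges should enter a Laplacian is genuinely open, and for
nonnegative graphs the curve is provably non-increasing. The default
threshold grid is 100 evenly spaced values spanning the pooled edge-weight
range of all networks under comparison, so curves share an axis. Group
summaries report mean ± sd per threshold for named individual groups
(e.g. flagged outliers vs the rest).

The rank ensemble ranks individuals per method (descending score, rank 1 =
most outlying, ties averaged), takes the geometric mean across methods and
orders ascending with ties broken by individual id. Enrichment of a
top-ranked set against a categorical phenotype uses the one-sided
hypergeometric tail per level with Benjamini-Hochberg correction across
levels. Community detection is deliberately an input (a node → module
mapping), not a feature: the assessment methods are agnostic to how
modules were found.

## Known limitations

- The LOO-ISN/MultiLOO-ISN null assumes multivariate normality of the
  module features; on CLR-transformed counts this is an approximation
  (empirically well-calibrated in the type-I check, but not guaranteed).
- Rankers' scores are not calibrated probabilities; turning a ranking into
  a decision threshold is out of scope.
- Cook's distance is undefined for `N ≤ C + 1`; modules beyond ~16 nodes
  need cohorts in the hundreds.
- Dense `p × p` storage throughout; intended for modules and networks up
  to a few hundred nodes, not genome-scale graphs.
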