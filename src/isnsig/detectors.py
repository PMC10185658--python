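"""Outlier detectors for module-restricted individual-specific networks.

Every detector scores each of the N individuals for deviation from the
population association structure (higher score = more outlying).  The methods
fall into four families:

* leave-one-out tests with an empirical null (``loo_isn_test``,
  ``multiloo_isn_test``) and the single-edge SSN Z-test (``ssn_m``) — these
  also return p-values;
* modular Cook's distance (``cooks_scores``): each module edge weight is
  regressed on all other module edges, per-individual Cook's distances are
  aggregated across target edges;
* distance-based rankers on the N x C edge-weight feature matrix
  (``knn_scores``, ``spoutlier_scores``, ``mots_scores``);
* the density-based OPTICS outlier factor (``optics_of_scores``).

Not every method applies to every setting: the SSN Z-test is single-edge
(k = 2) only, cosine distances need C >= 2 feature dimensions, and Cook's
distance needs k > 2 and N > C + 1.  Inapplicable calls return an
``OutlierResult`` with ``applicable=False`` and a reason instead of raising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .networks import DataMatrix, ModuleSpec, loo_correlations, population_network

__all__ = [
    "DetectorConfig",
    "OutlierResult",
    "NullDistribution",
    "ssn_m",
    "loo_isn_test",
    "multiloo_isn_test",
    "cooks_scores",
    "knn_scores",
    "optics_of_scores",
    "spoutlier_scores",
    "mots_scores",
    "nearest_psd",
    "METHOD_NAMES",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Shared tuning knobs.

    s: Spoutlier reference-set size (20 as suggested in the original work).
    ensemble_reps: repetitions for the median-ensemble (mOTS) variants.
    k_min, k_max: kNN neighbour range (resolved by the registry if None).
    min_pts: OPTICS neighbourhood size.
    rep: number of null datasets for the empirical-null tests.
    aggregation: how Cook's distances are pooled across target edges.
    metric: 'euclidean' or 'cosine' for the Spoutlier family.
    absolute: use |w^a - w^{a-q}| inside the sum/max statistics (two-sided
        outlier detection); set False for the signed variant.
    """

    s: int = 20
    ensemble_reps: int = 10
    k_min: int | None = None
    k_max: int | None = None
    min_pts: int = 5
    rep: int = 1000
    aggregation: str = "max"
    metric: str = "euclidean"
    absolute: bool = True

    def __post_init__(self) -> None:
        if self.s < 2:
            raise ValueError("reference size s must be >= 2")
        if self.ensemble_reps < 1:
            raise ValueError("ensemble_reps must be >= 1")
        if (self.k_min is not None and self.k_max is not None
                and self.k_min > self.k_max):
            raise ValueError("k_min > k_max")


@dataclass(frozen=True)
class OutlierResult:
    method: str
    scores: np.ndarray | None
    pvalues: np.ndarray | None = None
    applicable: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.applicable:
            if self.scores is None or not np.all(np.isfinite(self.scores)):
                raise ValueError(f"{self.method}: non-finite outlier scores")
            if self.pvalues is not None:
                p = np.asarray(self.pvalues)
                if np.any(p <= 0) or np.any(p > 1):
                    raise ValueError(f"{self.method}: p-values outside (0, 1]")

    @classmethod
    def not_applicable(cls, method: str, reason: str) -> "OutlierResult":
        return cls(method, None, None, applicable=False, reason=reason)


@dataclass(frozen=True)
class NullDistribution:
    """Draws of the leave-one-out statistic under H0."""

    statistics: np.ndarray
    rep: int
    statistic_kind: str  # 'sum' or 'max'

    def __post_init__(self) -> None:
        if self.rep < 100:
            raise ValueError("rep must be >= 100 for a usable empirical null")
        if not np.all(np.isfinite(self.statistics)):
            raise ValueError("non-finite null statistics")


def nearest_psd(a: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Nearest positive semidefinite repair by eigenvalue clipping."""
    sym = (a + a.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    if vals.min() < -1e-8:  # meaningfully indefinite, not just round-off
        warnings.warn("module adjacency not positive semidefinite; "
                      "clipping eigenvalues", stacklevel=2)
    vals = np.clip(vals, eps, None)
    return (vecs * vals) @ vecs.T


# ---------------------------------------------------------------------------
# leave-one-out family


def ssn_m(data: DataMatrix, edge: tuple[str, str]) -> OutlierResult:
    """Single-edge SSN Z-test.

    With PCC_n the correlation on n = N-1 individuals (the LOO edge) and
    dPCC = w^a - w^{a-q} the change when the left-out individual is added
    back, Z = dPCC / ((1 - PCC_n^2) / (n - 1)); the two-tailed normal
    p-value follows, and OS = |Z|.
    """
    if len(edge) != 2:
        return OutlierResult.not_applicable(
            "SSN-m", "SSN-m assesses a single edge (k = 2) only")
    sub = data.restrict(list(edge))
    if sub.n_individuals < 4:
        raise ValueError("SSN-m needs at least 4 individuals")
    pop = population_network(sub).weights[0, 1]
    loo = loo_correlations(sub)[:, 0, 1]
    n = sub.n_individuals - 1
    z = (pop - loo) / ((1.0 - loo ** 2) / (n - 1))
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return OutlierResult("SSN-m", np.abs(z), p)


def _observed_loo_diffs(data: DataMatrix, module: ModuleSpec) -> np.ndarray:
    """w^a - w^{a-q} on the module's edges, shape (N, C).

    Correlations between module nodes involve only the module columns, so the
    computation is restricted up front.
    """
    sub = data.restrict(module.nodes)
    pop = population_network(sub).weights
    loo = loo_correlations(sub)
    iu, ju = np.triu_indices(module.k, 1)
    return pop[iu, ju][None, :] - loo[:, iu, ju]


def simulate_null_statistics(adjacency: np.ndarray, n: int, rep: int,
                             rng: np.random.Generator,
                             absolute: bool = True) -> dict[str, NullDistribution]:
    """Empirical null for the leave-one-out statistics.

    ``rep`` datasets of ``n`` rows are drawn from a multivariate normal with
    zero mean and covariance equal to the (PSD-repaired) module adjacency.
    From each dataset the full correlation matrix and the correlation matrix
    with one uniformly chosen row removed are compared; both the sum and the
    max statistic are returned so the two tests can share one simulation.
    """
    if rep < 1:
        raise ValueError("rep must be positive")
    k = adjacency.shape[0]
    cov = nearest_psd(adjacency)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    x = rng.standard_normal((rep, n, k)) @ chol.T
    x -= x.mean(axis=1, keepdims=True)
    q_full = np.einsum("bni,bnj->bij", x, x)
    d = np.einsum("bii->bi", q_full)
    r_full = q_full / np.sqrt(d[:, :, None] * d[:, None, :])
    drop = rng.integers(0, n, size=rep)
    xd = x[np.arange(rep), drop]  # removed rows, (rep, k)
    c = q_full - xd[:, :, None] * xd[:, None, :]
    s = -xd  # column sums after removal (columns were centred)
    c -= (s[:, :, None] * s[:, None, :]) / (n - 1)
    dl = np.einsum("bii->bi", c)
    r_loo = c / np.sqrt(dl[:, :, None] * dl[:, None, :])
    iu, ju = np.triu_indices(k, 1)
    diffs = r_full[:, iu, ju] - r_loo[:, iu, ju]
    if absolute:
        diffs = np.abs(diffs)
    return {
        "sum": NullDistribution(diffs.sum(axis=1), rep, "sum"),
        "max": NullDistribution(diffs.max(axis=1), rep, "max"),
    }


def _empirical_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    # p = (1 + #{null >= obs}) / (rep + 1): never zero, valid under H0
    counts = (null[None, :] >= observed[:, None]).sum(axis=1)
    return (1.0 + counts) / (null.size + 1.0)


def _loo_family_test(data: DataMatrix, module: ModuleSpec, config: DetectorConfig,
                     seed, kinds: tuple[str, ...]) -> dict[str, OutlierResult]:
    if config.rep < 1:
        raise ValueError("rep must be positive")
    if data.n_individuals < 10:
        raise ValueError("leave-one-out tests need N >= 10")
    rng = np.random.default_rng(seed)
    sub = data.restrict(module.nodes)
    adjacency = population_network(sub).weights
    nulls = simulate_null_statistics(adjacency, data.n_individuals, config.rep,
                                     rng, absolute=config.absolute)
    diffs = _observed_loo_diffs(data, module)
    if config.absolute:
        diffs = np.abs(diffs)
    names = {"sum": "LOO-ISN", "max": "MultiLOO-ISN"}
    out = {}
    for kind in kinds:
        t_obs = diffs.sum(axis=1) if kind == "sum" else diffs.max(axis=1)
        p = _empirical_pvalues(t_obs, nulls[kind].statistics)
        out[kind] = OutlierResult(names[kind], 1.0 - p, p)
    return out


def loo_isn_test(data: DataMatrix, module: ModuleSpec,
                 config: DetectorConfig = DetectorConfig(),
                 seed=None) -> OutlierResult:
    """LOO-ISN: empirical-null test on the summed edge discrepancy.

    The statistic for individual q is T_q = sum over module edges of
    |w^a - w^{a-q}|; its null distribution comes from multivariate-normal
    datasets simulated with covariance equal to the estimated module
    adjacency (one random individual removed per null dataset).
    """
    return _loo_family_test(data, module, config, seed, ("sum",))["sum"]


def multiloo_isn_test(data: DataMatrix, module: ModuleSpec,
                      config: DetectorConfig = DetectorConfig(),
                      seed=None) -> OutlierResult:
    """MultiLOO-ISN: as LOO-ISN but with the maximum edge discrepancy."""
    return _loo_family_test(data, module, config, seed, ("max",))["max"]


# ---------------------------------------------------------------------------
# Cook's distance family


def _cooks_distance_matrix(features: np.ndarray) -> np.ndarray:
    """Cook's distances, shape (N, C): column c treats edge c as the target.

    For target edge c the linear model regresses feature c on the other C-1
    features plus an intercept.  All C regressions are solved at once through
    the inverse Gram matrix of the augmented design Z = [1, F]: the residual
    of regressing column j of Z on the remaining columns is Z G[:, j] / G_jj
    (G = (Z'Z)^-1), its sum of squares is 1 / G_jj, and the leverage of the
    reduced design is h_Z - e^2 * G_jj.  D follows the classical
    residual-leverage form with denominator (C + 1) * sigma^2.
    """
    n, c = features.shape
    z = np.column_stack([np.ones(n), features])
    gram = z.T @ z
    try:
        g = np.linalg.inv(gram)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient module design; using pseudo-inverse",
                      stacklevel=3)
        g = np.linalg.pinv(gram)
    # guard: near-singular Gram gives huge diagonal; fall back to pinv result
    e_all = z @ g  # (n, c+1); column j / g_jj = residuals of model j
    hz = np.einsum("ij,ij->i", e_all, z)  # full-design leverage diag(Z G Z')
    d = np.empty((n, c))
    for t in range(c):
        j = t + 1
        gjj = g[j, j]
        if gjj <= 0:
            warnings.warn("non-positive Gram inverse diagonal; "
                          "degenerate target edge", stacklevel=3)
            d[:, t] = 0.0
            continue
        e = e_all[:, j] / gjj  # residuals, SSE = 1/gjj
        h = hz - (e ** 2) * gjj  # leverage of the design without column j
        h = np.clip(h, 0.0, 1.0 - 1e-12)
        dof = n - c  # C parameters: intercept + (C-1) slopes
        sigma2 = (1.0 / gjj) / dof
        d[:, t] = (e ** 2) * h / ((c + 1) * sigma2 * (1.0 - h) ** 2)
    return d


_AGGREGATORS = {"max": np.max, "median": np.median, "med": np.median,
                "mean": np.mean}


def cooks_scores(features, aggregation: str = "max") -> OutlierResult:
    """Modular Cook's distance scores.

    ``features`` is the N x C module edge-weight matrix (array or DataFrame).
    Each edge is used in turn as the regression target; the C per-individual
    Cook's distances are aggregated by ``aggregation`` (max/median/mean).
    """
    f = np.asarray(getattr(features, "values", features), dtype=float)
    n, c = f.shape
    name = f"Cook's {aggregation}"
    if aggregation not in _AGGREGATORS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if c < 2:
        return OutlierResult.not_applicable(
            name, "Cook's distance needs a modular setting (k > 2)")
    if n <= c + 1:
        return OutlierResult.not_applicable(
            name, f"linear model not fittable: N={n} <= C+1={c + 1}")
    d = _cooks_distance_matrix(f)
    return OutlierResult(name, _AGGREGATORS[aggregation](d, axis=1))


# ---------------------------------------------------------------------------
# distance / density rankers


def knn_scores(features, k_min: int, k_max: int) -> OutlierResult:
    """Average distance to the k_min-th ... k_max-th nearest neighbours."""
    f = np.asarray(getattr(features, "values", features), dtype=float)
    n = f.shape[0]
    if k_min > k_max:
        raise ValueError("k_min > k_max")
    if k_min < 1 or k_max >= n:
        raise ValueError("need 1 <= k_min <= k_max < N")
    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(f)
    dist, _ = nn.kneighbors(f)
    scores = dist[:, k_min:k_max + 1].mean(axis=1)  # column 0 is self
    return OutlierResult(f"kNN {k_min},{k_max}", scores)


def optics_of_scores(features, min_pts: int) -> OutlierResult:
    """OPTICS outlier factor (density-contrast score, higher = more outlying).

    Follows the original construction: the core distance of a point is the
    distance to its MinPts-th neighbour; the reachability distance from p to
    a neighbour o is max(core(o), d(p, o)); the local reachability density is
    the inverse mean reachability over p's MinPts neighbourhood; and the
    outlier factor is the mean ratio of neighbour densities to the point's
    own density.  Points in homogeneous regions score ~1.
    """
    f = np.asarray(getattr(features, "values", features), dtype=float)
    n = f.shape[0]
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    if min_pts >= n:
        raise ValueError("min_pts must be < N")
    nn = NearestNeighbors(n_neighbors=min_pts + 1).fit(f)
    dist, idx = nn.kneighbors(f)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self; ties: ascending index
    core = dist[:, -1]  # distance to the MinPts-th neighbour
    reach = np.maximum(dist, core[idx])
    mean_reach = reach.mean(axis=1)
    with np.errstate(divide="ignore"):
        lrd = np.where(mean_reach > 0, 1.0 / mean_reach, np.inf)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = lrd[idx] / lrd[:, None]
    # duplicate-heavy neighbourhoods: inf/inf means identical density -> 1
    ratio[np.isnan(ratio)] = 1.0
    ratio[np.isinf(ratio)] = np.finfo(float).max / (10.0 * min_pts)
    of = ratio.mean(axis=1)
    return OutlierResult(f"OPTICS-OF {min_pts}", np.minimum(of, np.finfo(float).max))


def _pairwise_to_reference(f: np.ndarray, ref: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        d2 = ((f[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
        return np.sqrt(np.maximum(d2, 0.0))
    if metric == "cosine":
        fn = np.linalg.norm(f, axis=1)
        rn = np.linalg.norm(ref, axis=1)
        denom = np.outer(fn, rn)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (f @ ref.T) / denom
        cos = np.where(denom > 0, cos, 0.0)  # zero vector: undefined angle
        return 1.0 - np.clip(cos, -1.0, 1.0)
    raise ValueError(f"unknown metric {metric!r}")


def spoutlier_scores(features, s: int = 20, metric: str = "euclidean",
                     seed=None, replicate_aware: bool = True) -> OutlierResult:
    """Spoutlier: minimum distance to a small random reference set.

    ``replicate_aware=True`` is the modified scheme: s+1 individuals are
    sampled; a target inside the reference uses the other s, any other target
    drops one uniformly at random, and zero distances (exact replicates) are
    kept.  ``replicate_aware=False`` is the literature variant: s reference
    points, and a zero distance is replaced by the smallest non-zero one.
    If N <= s + 1 every target simply uses all other points as reference.
    """
    f = np.asarray(getattr(features, "values", features), dtype=float)
    n, c = f.shape
    name = f"OTS {metric}" if replicate_aware else "Spoutlier-l"
    if metric == "cosine" and c < 2:
        return OutlierResult.not_applicable(
            name, "cosine dissimilarity needs a multi-dimensional feature "
                  "space (C >= 2)")
    rng = np.random.default_rng(seed)
    if n <= s + 1:
        d = _pairwise_to_reference(f, f, metric)
        np.fill_diagonal(d, np.inf)
        return OutlierResult(name, d.min(axis=1))
    if replicate_aware:
        ref_idx = rng.choice(n, size=s + 1, replace=False)
        d = _pairwise_to_reference(f, f[ref_idx], metric)
        in_ref = np.full(n, -1, dtype=int)
        in_ref[ref_idx] = np.arange(s + 1)
        drop = rng.integers(0, s + 1, size=n)  # column ignored per target
        drop[ref_idx] = in_ref[ref_idx]  # targets in the reference drop self
        d[np.arange(n), drop] = np.inf
        scores = d.min(axis=1)
    else:
        ref_idx = rng.choice(n, size=s, replace=False)
        d = _pairwise_to_reference(f, f[ref_idx], metric)
        d[d == 0] = np.inf  # discard replicates / self
        scores = d.min(axis=1)
        scores[~np.isfinite(scores)] = 0.0  # all-zero row: true replicate set
    return OutlierResult(name, scores)


def mots_scores(features, config: DetectorConfig = DetectorConfig(),
                seed=None) -> OutlierResult:
    """Median ensemble of Spoutlier runs (mOTS).

    ``config.metric`` 'euclidean' or 'cosine' gives the single-metric
    ensembles; 'glob' rank-normalizes both metrics' ensemble scores to [0, 1]
    and averages them.
    """
    f = np.asarray(getattr(features, "values", features), dtype=float)
    n, c = f.shape
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    if config.metric == "glob":
        if c < 2:
            return OutlierResult.not_applicable(
                "mOTS glob", "cosine base predictor needs C >= 2")
        child_e, child_c = ss.spawn(2)
        eu = mots_scores(f, replace(config, metric="euclidean"), child_e)
        co = mots_scores(f, replace(config, metric="cosine"), child_c)
        ranks_e = stats.rankdata(eu.scores)
        ranks_c = stats.rankdata(co.scores)
        norm = (np.vstack([ranks_e, ranks_c]) - 1.0) / max(n - 1, 1)
        return OutlierResult("mOTS glob", norm.mean(axis=0))
    name = f"mOTS {config.metric}"
    if config.metric == "cosine" and c < 2:
        return OutlierResult.not_applicable(
            name, "cosine dissimilarity needs C >= 2")
    children = ss.spawn(config.ensemble_reps) if config.ensemble_reps > 1 \
        else [ss]  # single-rep ensemble == one seeded Spoutlier call
    runs = []
    for child in children:
        r = spoutlier_scores(f, config.s, config.metric, child)
        runs.append(r.scores)
    return OutlierResult(name, np.median(np.vstack(runs), axis=0))


# ---------------------------------------------------------------------------
# method registry (resolved by the evaluation harness)

METHOD_NAMES = (
    "LOO-ISN",
    "MultiLOO-ISN",
    "SSN-m",
    "kNN log(N),P",
    "kNN 5,sqrt(N)",
    "Optics 5",
    "Optics sqrt(N)",
    "OTS euclidean",
    "OTS cosine",
    "mOTS euc",
    "mOTS cosine",
    "mOTS glob",
    "Spoutlier-l",
    "Cook's max",
    "Cook's med",
    "Cook's mean",
)


def resolve_knn_range(name: str, n: int, k: int) -> tuple[int, int]:
    """Neighbour ranges for the two named kNN variants.

    'kNN log(N),P' uses min/max of ln(N) and the module size; 'kNN 5,sqrt(N)'
    uses min/max of 5 and sqrt(N).  Values are rounded and kept in [1, N-1].
    """
    if name == "kNN log(N),P":
        a, b = round(math.log(n)), k
    elif name == "kNN 5,sqrt(N)":
        a, b = 5, round(math.sqrt(n))
    else:
        raise KeyError(name)
    lo, hi = sorted((int(a), int(b)))
    return max(1, min(lo, n - 1)), max(1, min(hi, n - 1))


def resolve_min_pts(name: str, n: int) -> int:
    if name == "Optics 5":
        return min(5, n - 1)
    if name == "Optics sqrt(N)":
        return max(2, min(round(math.sqrt(n)), n - 1))
    raise KeyError(name)
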