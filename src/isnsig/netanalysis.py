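"""Follow-up analysis of real ISN collections.

Graph filtration curves summarize one ISN by sweeping an increasing edge
threshold, zeroing out edges below it, and recording the algebraic
connectivity (Fiedler value, the second-smallest Laplacian eigenvalue) of
each thresholded graph.  Outlying individuals separate visibly from the
population band of curves.  The module also provides a geometric-mean rank
ensemble combining several detectors' outlier scores, pairwise score
agreement, and one-sided hypergeometric enrichment (BH-corrected) of a
top-ranked outlier set against categorical phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .networks import Network

__all__ = [
    "FiltrationCurve",
    "EnsembleRanking",
    "fiedler_value",
    "filtration_curve",
    "shared_threshold_grid",
    "curve_group_summary",
    "rank_ensemble",
    "enrichment_test",
    "score_agreement",
]


@dataclass(frozen=True)
class FiltrationCurve:
    thresholds: np.ndarray
    values: np.ndarray
    network_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("thresholds and values differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class EnsembleRanking:
    """Per-individual geometric-mean rank and the resulting ordering."""

    individuals: tuple[str, ...]
    geometric_mean_rank: np.ndarray
    ordering: tuple[str, ...]


def fiedler_value(weights: np.ndarray) -> float:
    """Second-smallest eigenvalue of the graph Laplacian L = Deg - W.

    The diagonal of ``weights`` is ignored (no self-loops).  For graphs with
    nonnegative weights the value is >= 0 and equals 0 iff the graph is
    disconnected.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("weights must be symmetric")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    lap = np.diag(w.sum(axis=1)) - w
    vals = np.linalg.eigvalsh(lap)
    return float(vals[1])


def filtration_curve(network: Network | np.ndarray, thresholds,
                     absolute: bool = False) -> FiltrationCurve:
    """Fiedler value of the graph after zeroing edges with weight < t.

    ``absolute=True`` thresholds |weight| instead, an option for networks
    where negative edges should count by magnitude.
    """
    if isinstance(network, Network):
        w, net_id = network.weights, network.role
    else:
        w, net_id = np.asarray(network, dtype=float), ""
    base = np.abs(w) if absolute else w
    t = np.asarray(thresholds, dtype=float)
    values = np.empty(t.size)
    for i, thr in enumerate(t):
        wt = np.where(base < thr, 0.0, w)
        values[i] = fiedler_value(wt)
    return FiltrationCurve(t, values, net_id)


def shared_threshold_grid(networks: Sequence[Network], n_points: int = 100,
                          absolute: bool = False) -> np.ndarray:
    """Evenly spaced thresholds spanning the pooled edge-weight range of all
    networks, so per-individual curves are directly comparable."""
    lo, hi = np.inf, -np.inf
    for net in networks:
        w = net.weights.copy()
        np.fill_diagonal(w, np.nan)
        vals = np.abs(w) if absolute else w
        lo = min(lo, np.nanmin(vals))
        hi = max(hi, np.nanmax(vals))
    return np.linspace(lo, hi, n_points)


def curve_group_summary(curves: Sequence[FiltrationCurve],
                        groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Mean and standard deviation per threshold across named groups of
    individuals (e.g. outliers vs rest)."""
    by_id = {c.network_id: c for c in curves}
    rows = []
    for gname, members in groups.items():
        stack = np.vstack([by_id[m].values for m in members])
        t = by_id[list(members)[0]].thresholds
        for j, thr in enumerate(t):
            rows.append({"group": gname, "threshold": thr,
                         "mean": stack[:, j].mean(),
                         "sd": stack[:, j].std(ddof=1) if len(members) > 1
                         else 0.0})
    return pd.DataFrame(rows)


def rank_ensemble(score_table: pd.DataFrame) -> EnsembleRanking:
    """Geometric-mean rank ensemble of several methods' outlier scores.

    ``score_table`` is individuals x methods (higher score = more outlying).
    Per method, individuals are ranked descending (rank 1 = most outlying,
    ties averaged); the per-individual geometric mean across methods is then
    sorted ascending, ties broken by individual id.
    """
    if score_table.shape[1] < 1:
        raise ValueError("need at least one method column")
    ranks = score_table.apply(lambda col: stats.rankdata(-col.to_numpy()),
                              axis=0)
    gmean = np.exp(np.log(ranks.to_numpy()).mean(axis=1))
    ids = tuple(str(i) for i in score_table.index)
    order = sorted(range(len(ids)), key=lambda i: (gmean[i], ids[i]))
    return EnsembleRanking(ids, gmean, tuple(ids[i] for i in order))


def enrichment_test(top_set: Sequence[str],
                    category_labels: Mapping[str, str] | pd.Series,
                    ) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a top-outlier set per category
    level, Benjamini-Hochberg corrected across levels.

    ``category_labels`` maps every individual in the population to a level.
    For a level with K carriers in a population of size P, drawing n = |top|
    and observing x carriers, p = P(X >= x) under Hypergeometric(P, K, n).
    """
    labels = pd.Series(category_labels, dtype=str)
    if labels.empty:
        raise ValueError("empty category labels")
    top = [str(t) for t in top_set]
    missing = set(top) - set(labels.index.astype(str))
    if missing:
        raise KeyError(f"top-set individuals without a label: {sorted(missing)}")
    pop_n = len(labels)
    n_draw = len(top)
    top_labels = labels.loc[top]
    rows = []
    for level, k_success in labels.value_counts().items():
        x = int((top_labels == level).sum())
        p = float(stats.hypergeom.sf(x - 1, pop_n, int(k_success), n_draw))
        rows.append({"level": level, "population": int(k_success),
                     "in_top": x, "pvalue": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["pvalue_bh"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df.sort_values("pvalue").reset_index(drop=True)


def score_agreement(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of methods' outlier-score vectors."""
    if score_table.shape[1] < 2:
        raise ValueError("need at least two methods to compare")
    return score_table.corr(method="pearson")
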