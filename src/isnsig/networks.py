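"""Population, leave-one-out, and individual-specific correlation networks.

An individual-specific network (ISN) assigns each individual ``q`` in a cohort
of size ``N`` its own weighted network over the same ``p`` features.  The
construction used here is linear interpolation between the population network
(Pearson correlation pooled over all individuals, elements ``w_ij^a``) and the
leave-one-out (LOO) network re-estimated without individual ``q`` (elements
``w_ij^{a-q}``)::

    w_ij^q = N * w_ij^a - (N - 1) * w_ij^{a-q}

so that the population network is (asymptotically) the average of the ISNs.
The sample-specific network (SSN) variant is the plain difference
``w_ij^a - w_ij^{a-q}``; the two are linked edgewise by
``ssn = (isn - w^a) / (N - 1)``.

Modules are node subsets; the induced ``C = k(k-1)/2`` edge weights of an
individual's ISN form that individual's feature vector for outlier detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "Network",
    "ModuleSpec",
    "population_network",
    "loo_network",
    "loo_correlations",
    "lioness_isns",
    "ssn_networks",
    "module_features",
    "read_data_matrix",
    "write_edge_list",
    "write_isn_table",
]


def _as_labels(labels: Sequence[str]) -> tuple[str, ...]:
    return tuple(str(x) for x in labels)


@dataclass(frozen=True)
class DataMatrix:
    """N individuals x p features numeric matrix with identifiers.

    Invariants enforced at construction: N >= 3, p >= 2, finite values,
    unique ids, and no constant column (a constant column has no defined
    correlation with anything and is rejected up front rather than producing
    NaN edges downstream).
    """

    values: np.ndarray
    individual_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "individual_ids", _as_labels(self.individual_ids))
        object.__setattr__(self, "feature_ids", _as_labels(self.feature_ids))
        n, p = values.shape
        if n < 3:
            raise ValueError(f"need at least 3 individuals, got {n}")
        if p < 2:
            raise ValueError(f"need at least 2 features, got {p}")
        if len(self.individual_ids) != n or len(self.feature_ids) != p:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature ids are not unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("data matrix contains non-finite values")
        sd = values.std(axis=0)
        if np.any(sd == 0):
            bad = [self.feature_ids[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant (zero-variance) column(s): {bad}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def index_of(self, individual_id: str) -> int:
        try:
            return self.individual_ids.index(str(individual_id))
        except ValueError:
            raise KeyError(f"unknown individual id: {individual_id!r}") from None

    def restrict(self, feature_subset: Sequence[str]) -> "DataMatrix":
        """Column-restrict to the given features, preserving their order."""
        cols = [self._feature_index(f) for f in feature_subset]
        return DataMatrix(self.values[:, cols], self.individual_ids,
                          [self.feature_ids[j] for j in cols])

    def drop_individual(self, individual_id: str) -> "DataMatrix":
        i = self.index_of(individual_id)
        keep = np.ones(self.n_individuals, dtype=bool)
        keep[i] = False
        return DataMatrix(self.values[keep],
                          [x for j, x in enumerate(self.individual_ids) if j != i],
                          self.feature_ids)

    def _feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(str(feature_id))
        except ValueError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.individual_ids),
                            columns=list(self.feature_ids))


@dataclass(frozen=True)
class Network:
    """Symmetric weighted network over named features.

    ``role`` records how the network was built: ``"population"``,
    ``"loo:<q>"``, ``"isn:<q>"`` or ``"ssn:<q>"``.  Population and LOO
    networks are correlation matrices (unit diagonal, entries in [-1, 1]);
    ISN/SSN entries are unbounded linear combinations of correlations.
    """

    weights: np.ndarray
    feature_ids: tuple[str, ...]
    role: str
    n_samples: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "feature_ids", _as_labels(self.feature_ids))
        p = len(self.feature_ids)
        if w.shape != (p, p):
            raise ValueError("weight matrix shape does not match feature ids")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix is not symmetric")

    @property
    def kind(self) -> str:
        return self.role.split(":", 1)[0]

    @property
    def individual(self) -> str | None:
        return self.role.split(":", 1)[1] if ":" in self.role else None

    def edge_weight(self, a: str, b: str) -> float:
        ids = list(self.feature_ids)
        return float(self.weights[ids.index(str(a)), ids.index(str(b))])


@dataclass(frozen=True)
class ModuleSpec:
    """Ordered node subset of size k with its C = k(k-1)/2 induced edges.

    The edge order is fixed everywhere in the package: upper triangle,
    row-major over the module's node order.
    """

    nodes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", _as_labels(self.nodes))
        if len(self.nodes) < 2:
            raise ValueError("a module needs at least 2 nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("module nodes are not unique")

    @property
    def k(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.k * (self.k - 1) // 2

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        n = self.nodes
        return tuple((n[i], n[j]) for i in range(len(n)) for j in range(i + 1, len(n)))

    def node_indices(self, feature_ids: Sequence[str]) -> np.ndarray:
        ids = [str(x) for x in feature_ids]
        try:
            return np.array([ids.index(v) for v in self.nodes], dtype=int)
        except ValueError:
            missing = [v for v in self.nodes if v not in ids]
            raise KeyError(f"module node(s) not among features: {missing}") from None

    def edge_labels(self) -> list[str]:
        return [f"{a}|{b}" for a, b in self.edges]


def _pearson(values: np.ndarray, feature_ids: Sequence[str]) -> np.ndarray:
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [str(feature_ids[j]) for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance column(s) in correlation input: {bad}")
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def population_network(data: DataMatrix,
                       association: Callable[[np.ndarray], np.ndarray] | None = None,
                       ) -> Network:
    """Pearson-correlation population network pooled over all individuals.

    ``association`` may replace Pearson with another symmetric pairwise
    association measure mapping an (n, p) matrix to a (p, p) matrix.
    """
    if association is None:
        w = _pearson(data.values, data.feature_ids)
    else:
        w = np.asarray(association(data.values), dtype=float)
    return Network(w, data.feature_ids, "population", data.n_individuals)


def loo_network(data: DataMatrix, q: str) -> Network:
    """Correlation network on the N-1 individuals excluding ``q``."""
    if data.n_individuals < 4:
        raise ValueError("leave-one-out needs at least 4 individuals")
    reduced = data.drop_individual(q)
    w = _pearson(reduced.values, data.feature_ids)
    return Network(w, data.feature_ids, f"loo:{q}", data.n_individuals - 1)


def loo_correlations(data: DataMatrix) -> np.ndarray:
    """All N leave-one-out correlation matrices, shape (N, p, p).

    Computed by downdating the pooled cross-product sums, so the cost is
    O(N p^2) rather than N full correlation passes.  Row q of the result
    equals ``np.corrcoef`` on the data without individual q (to floating
    point round-off; the input is centred first to keep the downdate stable).
    """
    if data.n_individuals < 4:
        raise ValueError("leave-one-out needs at least 4 individuals")
    x = data.values - data.values.mean(axis=0)
    n = x.shape[0]
    q_full = x.T @ x
    s = -x  # column sums after removing row q: (sum x) - x_q = -x_q
    # cross products after removing row q, then subtract the mean term
    c = q_full[None, :, :] - x[:, :, None] * x[:, None, :]
    c -= (s[:, :, None] * s[:, None, :]) / (n - 1)
    d = np.einsum("qii->qi", c)
    if np.any(d <= 0):
        bad_q, bad_j = np.nonzero(d <= 0)
        raise ValueError(
            "zero variance after removing individual "
            f"{data.individual_ids[bad_q[0]]!r} for column "
            f"{data.feature_ids[bad_j[0]]!r}")
    r = c / np.sqrt(d[:, :, None] * d[:, None, :])
    ii = np.arange(x.shape[1])
    r[:, ii, ii] = 1.0
    return np.clip(r, -1.0, 1.0)


def lioness_isns(data: DataMatrix) -> list[Network]:
    """Per-individual ISNs by linear interpolation: N*w^a - (N-1)*w^{a-q}."""
    pop = population_network(data)
    loo = loo_correlations(data)
    n = data.n_individuals
    return [Network(n * pop.weights - (n - 1) * loo[i], data.feature_ids,
                    f"isn:{qid}", n)
            for i, qid in enumerate(data.individual_ids)]


def ssn_networks(data: DataMatrix) -> list[Network]:
    """Per-individual SSN differentials w^a - w^{a-q} (whole-cohort reference)."""
    pop = population_network(data)
    loo = loo_correlations(data)
    return [Network(pop.weights - loo[i], data.feature_ids,
                    f"ssn:{qid}", data.n_individuals)
            for i, qid in enumerate(data.individual_ids)]


def module_features(networks: Sequence[Network], module: ModuleSpec) -> pd.DataFrame:
    """Stack module edge weights of per-individual networks into an N x C frame.

    Row order follows ``networks``; column order is the module's deterministic
    upper-triangle row-major edge order.
    """
    if not networks:
        raise ValueError("no networks given")
    idx = module.node_indices(networks[0].feature_ids)
    k = len(idx)
    iu, ju = np.triu_indices(k, 1)
    rows = np.array([net.weights[np.ix_(idx, idx)][iu, ju] for net in networks])
    names = [net.individual if net.individual is not None else net.role
             for net in networks]
    return pd.DataFrame(rows, index=names, columns=module.edge_labels())


# ---------------------------------------------------------------------------
# file interfaces


def read_data_matrix(path, sep: str | None = None) -> DataMatrix:
    """Read a TSV/CSV with a header of feature ids and first column of
    individual ids.  The separator is inferred from the extension unless given.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    return DataMatrix(df.to_numpy(dtype=float), df.index.astype(str),
                      df.columns.astype(str))


def write_edge_list(network: Network, path) -> None:
    p = len(network.feature_ids)
    iu, ju = np.triu_indices(p, 1)
    df = pd.DataFrame({
        "node_i": [network.feature_ids[i] for i in iu],
        "node_j": [network.feature_ids[j] for j in ju],
        "weight": network.weights[iu, ju],
    })
    df.to_csv(path, sep="\t", index=False)


def write_isn_table(networks: Sequence[Network], path) -> None:
    """Long-format TSV (individual, node_i, node_j, weight) for an ISN set."""
    frames = []
    for net in networks:
        p = len(net.feature_ids)
        iu, ju = np.triu_indices(p, 1)
        frames.append(pd.DataFrame({
            "individual": net.individual if net.individual else net.role,
            "node_i": [net.feature_ids[i] for i in iu],
            "node_j": [net.feature_ids[j] for j in ju],
            "weight": net.weights[iu, ju],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
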