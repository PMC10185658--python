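"""Dirichlet-multinomial compositional benchmark (microbiome scenario).

Per-taxon concentration masses are drawn from a Pareto distribution
(threshold 1, alpha 0.7 for high heterogeneity or alpha 4 for mild) or set
uniformly to 1 (no heterogeneity), giving the control concentration vector D
over p taxa.  Cases inflate a random subset of taxa (``perc_increase`` of p)
by the multiplier ``mult`` and the inflated vector is renormalized to the
same total mass as D::

    e*_i = e1_i * sum(D) / sum(E1)

so cases differ in composition, not scale.  Both vectors are then multiplied
by the intensity Int = 3, used as Dirichlet concentrations, and each
individual's taxon probabilities feed a multinomial with 5000 reads.  Counts
(plus a pseudocount) are CLR-transformed; the network is sampled ten times
bigger than the target module (p = 10 k) to avoid bias toward perfect
negative correlations, and only at the very end is the module of k taxa —
guaranteed to contain at least one inflated taxon — extracted.

The full grid crosses N in {100, 500, 1000}, M in {1, 5, 10},
k in {2, 5, 11, 17}, three heterogeneity levels, mult in {1.1, 1.5, 2} and
perc_increase in {10%, 25%, 40%}: 972 settings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .networks import DataMatrix, ModuleSpec
from .simulate_normal import GroundTruth

__all__ = [
    "CompSetting",
    "ConcentrationVectors",
    "sample_concentration",
    "inflate_and_normalize",
    "dirichlet_multinomial",
    "clr_transform",
    "generate_compositional",
    "comp_grid",
    "HETEROGENEITY_LEVELS",
]

HETEROGENEITY_LEVELS = ("uniform", "pareto_alpha4", "pareto_alpha0.7")
COMP_N = (100, 500, 1000)
COMP_M = (1, 5, 10)
COMP_K = (2, 5, 11, 17)
COMP_MULT = (1.1, 1.5, 2.0)
COMP_PERC = (0.10, 0.25, 0.40)


@dataclass(frozen=True)
class CompSetting:
    """One row of the compositional experimental grid."""

    N: int
    M: int
    k: int
    heterogeneity: str = "uniform"
    mult: float = 1.5
    perc_increase: float = 0.25
    intensity: float = 3.0
    reads: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.M >= self.N or self.M < 0:
            raise ValueError("need 0 <= M < N")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.heterogeneity not in HETEROGENEITY_LEVELS:
            raise ValueError(f"heterogeneity must be one of {HETEROGENEITY_LEVELS}")
        if not 0 < self.perc_increase <= 1:
            raise ValueError("perc_increase must be in (0, 1]")
        if self.mult <= 0 or self.reads < 1:
            raise ValueError("invalid mult or reads")

    @property
    def p(self) -> int:
        """Total taxa sampled: ten times the target module size."""
        return 10 * self.k

    @property
    def setting_id(self) -> str:
        return (f"comp_N{self.N}_M{self.M}_k{self.k}_{self.heterogeneity}"
                f"_mult{self.mult:g}_perc{int(round(self.perc_increase * 100))}")


@dataclass(frozen=True)
class ConcentrationVectors:
    """Control (D), inflated (E1) and renormalized (E*) concentrations."""

    D: np.ndarray
    E1: np.ndarray
    E_star: np.ndarray
    inflated_idx: np.ndarray

    def __post_init__(self) -> None:
        for name in ("D", "E1", "E_star"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "inflated_idx",
                           np.asarray(self.inflated_idx, dtype=int))


def sample_concentration(p: int, heterogeneity: str,
                         seed=None) -> np.ndarray:
    """Per-taxon concentration masses D.

    'uniform' returns all ones (every taxon equally abundant on average);
    the Pareto modes draw i.i.d. Pareto(threshold=1, alpha) masses — small
    alpha gives a heavy tail: few dominant taxa, many rare ones.
    """
    if heterogeneity == "uniform":
        return np.ones(p)
    rng = np.random.default_rng(seed)
    alpha = {"pareto_alpha4": 4.0, "pareto_alpha0.7": 0.7}.get(heterogeneity)
    if alpha is None:
        raise ValueError(f"unknown heterogeneity {heterogeneity!r}")
    # numpy's pareto is the Lomax form; +1 gives the classical Pareto with
    # threshold 1 (support [1, inf))
    return 1.0 + rng.pareto(alpha, size=p)


def inflate_and_normalize(d: np.ndarray, mult: float, perc_increase: float,
                          seed=None, intensity: float = 1.0,
                          inflated_idx: np.ndarray | None = None,
                          ) -> ConcentrationVectors:
    """Case/control differentiation with scale preserved.

    A ``perc_increase`` fraction of taxa (rounded, at least one) is inflated
    by ``mult`` to produce E1; E* renormalizes E1 back to sum(D) so cases and
    controls differ only compositionally.  Both D and E* are finally scaled
    by ``intensity`` (the returned D reflects this too).
    """
    d = np.asarray(d, dtype=float)
    p = d.size
    n_inflate = max(1, int(round(perc_increase * p)))
    if n_inflate > p:
        raise ValueError("perc_increase implies more inflated taxa than taxa")
    if inflated_idx is None:
        rng = np.random.default_rng(seed)
        inflated_idx = rng.choice(p, size=n_inflate, replace=False)
    else:
        inflated_idx = np.asarray(inflated_idx, dtype=int)
    e1 = d.copy()
    e1[inflated_idx] *= mult
    e_star = e1 * (d.sum() / e1.sum())
    return ConcentrationVectors(D=d * intensity, E1=e1,
                                E_star=e_star * intensity,
                                inflated_idx=np.sort(inflated_idx))


def dirichlet_multinomial(conc: np.ndarray, n_individuals: int, reads: int,
                          seed=None) -> np.ndarray:
    """Counts for ``n_individuals``: probabilities ~ Dirichlet(conc), then
    counts ~ Multinomial(reads, probabilities).  Rows sum to ``reads``."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(conc, dtype=float)
    pr = rng.dirichlet(conc, size=n_individuals)
    # guard against exact zeros from extreme concentrations
    pr = np.clip(pr, 1e-300, None)
    pr /= pr.sum(axis=1, keepdims=True)
    return rng.multinomial(reads, pr)


def clr_transform(counts: np.ndarray, pseudocount: float = 1.0,
                  individual_ids=None, feature_ids=None) -> DataMatrix:
    """Centered log-ratio transform: log(x + pseudocount) minus the row mean
    of logs; every transformed row sums to zero."""
    x = np.asarray(counts, dtype=float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("counts + pseudocount must be strictly positive")
    logx = np.log(x)
    values = logx - logx.mean(axis=1, keepdims=True)
    n, p = values.shape
    if individual_ids is None:
        individual_ids = [f"ind_{i + 1:05d}" for i in range(n)]
    if feature_ids is None:
        feature_ids = [f"taxon_{j + 1:03d}" for j in range(p)]
    return DataMatrix(values, individual_ids, feature_ids)


def generate_compositional(setting: CompSetting, seed: int | None = None,
                           max_rejections: int = 1000,
                           ) -> tuple[DataMatrix, DataMatrix, GroundTruth,
                                      ModuleSpec, np.ndarray]:
    """Full compositional pipeline for one run.

    Returns (module-restricted data, full CLR data, labels, module spec,
    counts).  The module and the inflated-taxa assignment are resampled until
    the module contains at least one inflated taxon, so the case/control
    differentiation is guaranteed to touch the module.
    """
    rng = np.random.default_rng(setting.seed if seed is None else seed)
    p, k = setting.p, setting.k
    n_inflate = max(1, int(round(setting.perc_increase * p)))
    if n_inflate < 1:
        raise ValueError("perc_increase * p < 1: no taxon can be inflated")
    d = sample_concentration(p, setting.heterogeneity, rng)
    module_idx = inflated = None
    for _ in range(max_rejections):
        cand_inflated = rng.choice(p, size=n_inflate, replace=False)
        cand_module = rng.choice(p, size=k, replace=False)
        if np.intersect1d(cand_inflated, cand_module).size:
            inflated, module_idx = cand_inflated, np.sort(cand_module)
            break
    if module_idx is None:
        raise RuntimeError("could not place an inflated taxon in the module")
    conc = inflate_and_normalize(d, setting.mult, setting.perc_increase,
                                 intensity=setting.intensity,
                                 inflated_idx=inflated)
    n, m = setting.N, setting.M
    counts_ctrl = dirichlet_multinomial(conc.D, n - m, setting.reads, rng)
    counts_case = dirichlet_multinomial(conc.E_star, m, setting.reads, rng) \
        if m > 0 else np.empty((0, p), dtype=int)
    counts = np.vstack([counts_ctrl, counts_case])
    labels = np.concatenate([np.zeros(n - m, dtype=int), np.ones(m, dtype=int)])
    order = rng.permutation(n)
    counts, labels = counts[order], labels[order]
    full = clr_transform(counts)
    module = ModuleSpec(tuple(full.feature_ids[j] for j in module_idx))
    return (full.restrict(module.nodes), full, GroundTruth(labels), module,
            counts)


def comp_grid() -> list[CompSetting]:
    """The full 3 x 3 x 4 x 3 x 3 x 3 = 972-setting grid, deterministic order."""
    return [CompSetting(N=n, M=m, k=k, heterogeneity=h, mult=mu,
                        perc_increase=pc)
            for n, m, k, h, mu, pc in itertools.product(
                COMP_N, COMP_M, COMP_K, HETEROGENEITY_LEVELS, COMP_MULT,
                COMP_PERC)]
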