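"""Multivariate-normal benchmark generator (gene co-expression scenario).

Controls are drawn i.i.d. from N(0, Sigma_ctrl); the M outliers ("cases")
from N(0, Sigma_out), either one shared outlier covariance ("common" mode) or
an independent covariance per outlier ("specific" mode).  Both covariances
are random correlation matrices from a C-vine construction with
Beta-distributed partial correlations, tuned so the average |off-diagonal|
sits around 0.3-0.5 — the concentration typical of a co-expression module.
Custom covariances can be injected to override the defaults.

The full experimental grid crosses N in {100, 500, 1000, 2000},
M in {1, 5, 10}, k in {2, 3, 5, 7, 9, 11, 17} and the two outlier modes:
168 settings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .networks import DataMatrix

__all__ = [
    "NormalSetting",
    "GroundTruth",
    "random_correlation_vine",
    "generate_normal",
    "normal_grid",
    "GRID_N", "GRID_M", "GRID_K", "GRID_MODES",
]

GRID_N = (100, 500, 1000, 2000)
GRID_M = (1, 5, 10)
GRID_K = (2, 3, 5, 7, 9, 11, 17)
GRID_MODES = ("common", "specific")

#: Beta(a, a) concentration of the vine partial correlations; a = 1 draws
#: every partial correlation uniformly on (-1, 1) and gives mean
#: |off-diagonal| ~ 0.40-0.45 across module sizes 5-17, the moderate
#: concentration typical of a co-expression module.
VINE_BETA_A = 1.0


@dataclass(frozen=True)
class NormalSetting:
    """One row of the normal-scheme experimental grid."""

    N: int
    M: int
    k: int
    outlier_mode: str = "common"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.M >= self.N:
            raise ValueError("M must be < N")
        if self.M < 0 or self.k < 2:
            raise ValueError("need M >= 0 and k >= 2")
        if self.outlier_mode not in GRID_MODES:
            raise ValueError(f"outlier_mode must be one of {GRID_MODES}")

    @property
    def setting_id(self) -> str:
        return f"normal_N{self.N}_M{self.M}_k{self.k}_{self.outlier_mode}"


@dataclass(frozen=True)
class GroundTruth:
    """Binary outlier labels, one per individual (1 = outlier)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary")
        object.__setattr__(self, "labels", lab)

    @property
    def n_outliers(self) -> int:
        return int(self.labels.sum())


def random_correlation_vine(k: int, rng: np.random.Generator,
                            beta_a: float = VINE_BETA_A) -> np.ndarray:
    """Random correlation matrix via the C-vine / onion construction.

    Partial correlations are drawn Beta(a, a) rescaled to (-1, 1) and
    propagated through the vine recursion; the result is a valid correlation
    matrix for any draw.  Smaller ``beta_a`` pushes partials toward +/-1 and
    yields stronger marginal correlations.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    partials = np.zeros((k, k))
    tri = rng.beta(beta_a, beta_a, size=k * (k - 1) // 2) * 2.0 - 1.0
    partials[np.triu_indices(k, 1)] = tri
    r = np.eye(k)
    for i in range(k - 1):
        for j in range(i + 1, k):
            rho = partials[i, j]
            # fold in the conditioning variables i-1 ... 0
            for m in range(i - 1, -1, -1):
                rho = (rho * np.sqrt((1 - partials[m, i] ** 2)
                                     * (1 - partials[m, j] ** 2))
                       + partials[m, i] * partials[m, j])
            r[i, j] = r[j, i] = rho
    # numerical guard: clip tiny negative eigenvalues from round-off
    vals, vecs = np.linalg.eigh(r)
    if vals.min() < 1e-12:
        vals = np.clip(vals, 1e-12, None)
        r = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
    return r


def _mvn(rng: np.random.Generator, cov: np.ndarray, n: int) -> np.ndarray:
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    return rng.standard_normal((n, cov.shape[0])) @ chol.T


def generate_normal(setting: NormalSetting, seed: int | None = None,
                    sigma_ctrl: np.ndarray | None = None,
                    sigma_out: np.ndarray | list[np.ndarray] | None = None,
                    ) -> tuple[DataMatrix, GroundTruth]:
    """Sample one dataset of analysis (N x k) plus its outlier labels.

    Rows are shuffled after concatenating controls and cases so outliers are
    not positionally identifiable.  Identical (setting, seed) pairs reproduce
    the dataset bit-for-bit.
    """
    rng = np.random.default_rng(setting.seed if seed is None else seed)
    n, m, k = setting.N, setting.M, setting.k
    if sigma_ctrl is None:
        sigma_ctrl = random_correlation_vine(k, rng)
    controls = _mvn(rng, sigma_ctrl, n - m)
    cases = np.empty((m, k))
    if m > 0:
        if setting.outlier_mode == "common":
            covs = [random_correlation_vine(k, rng)] if sigma_out is None \
                else [np.asarray(sigma_out)]
            cases = _mvn(rng, covs[0], m)
        else:  # specific: an independent covariance per outlier
            if sigma_out is None:
                covs = [random_correlation_vine(k, rng) for _ in range(m)]
            else:
                covs = [np.asarray(s) for s in sigma_out]
                if len(covs) != m:
                    raise ValueError("specific mode needs one sigma_out per case")
            cases = np.vstack([_mvn(rng, c, 1) for c in covs])
    values = np.vstack([controls, cases])
    labels = np.concatenate([np.zeros(n - m, dtype=int), np.ones(m, dtype=int)])
    order = rng.permutation(n)
    values, labels = values[order], labels[order]
    ids = [f"ind_{i + 1:05d}" for i in range(n)]
    feats = [f"gene_{j + 1:03d}" for j in range(k)]
    return DataMatrix(values, ids, feats), GroundTruth(labels)


def normal_grid() -> list[NormalSetting]:
    """The full 4 x 3 x 7 x 2 = 168-setting grid, deterministic order."""
    return [NormalSetting(N=n, M=m, k=k, outlier_mode=mode)
            for n, m, k, mode in itertools.product(GRID_N, GRID_M, GRID_K,
                                                   GRID_MODES)]
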