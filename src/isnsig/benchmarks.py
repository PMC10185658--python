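"""Desk-scale benchmark suites over the two simulation schemes.

The full simulation study behind the headline tables is cluster-scale
(168 settings x 200 runs for the normal scheme; 972 x 150 for the
compositional one).  The suites here run stratified subsets at 20-30 runs
per setting, sized to finish in minutes on one CPU while preserving each
scheme's structure (both sample sizes regimes, small to large modules, one
and several outliers, all heterogeneity levels).  The empirical-null tests
use 300 null datasets per run here; p-value resolution of 1/301 is ample
for ranking-based AUC evaluation.

Each suite returns the long-format record table; aggregation follows the
two-stage scheme (per-setting median over runs, then median/mean across
settings).
"""

from __future__ import annotations

import itertools

import pandas as pd

from .detectors import DetectorConfig, METHOD_NAMES
from .evaluation import records_frame, run_grid
from .simulate_compositional import CompSetting, HETEROGENEITY_LEVELS
from .simulate_normal import NormalSetting

__all__ = [
    "normal_table_settings",
    "comp_mult2_settings",
    "comp_null_settings",
    "run_normal_benchmark",
    "run_comp_mult2_benchmark",
    "run_comp_null_benchmark",
    "BENCH_CONFIG",
]

#: null-test repetitions for benchmark runs (desk-scale choice)
BENCH_CONFIG = DetectorConfig(rep=300)

NORMAL_METHODS = ("Cook's med", "mOTS cosine", "kNN 5,sqrt(N)",
                  "kNN log(N),P", "Optics 5", "Optics sqrt(N)")
COMP_METHODS = ("LOO-ISN", "kNN 5,sqrt(N)", "OTS cosine")


def normal_table_settings() -> list[NormalSetting]:
    """Stratified modular subset of the normal grid: N in {100, 500},
    k in {5, 11, 17}, M in {1, 5}, both outlier modes (24 settings)."""
    return [NormalSetting(N=n, M=m, k=k, outlier_mode=o)
            for n, m, k, o in itertools.product(
                (100, 500), (1, 5), (5, 11, 17), ("common", "specific"))]


def comp_mult2_settings() -> list[CompSetting]:
    """Compositional subset at multiplier 2: N in {100, 500}, k in {2, 5, 11},
    M in {1, 5}, 25% inflated taxa, all three heterogeneity levels (36)."""
    return [CompSetting(N=n, M=m, k=k, heterogeneity=h, mult=2.0,
                        perc_increase=0.25)
            for n, m, k, h in itertools.product(
                (100, 500), (1, 5), (2, 5, 11), HETEROGENEITY_LEVELS)]


def comp_null_settings() -> list[CompSetting]:
    """Near-null compositional subset: multiplier 1.1, same strata."""
    return [CompSetting(N=n, M=m, k=k, heterogeneity=h, mult=1.1,
                        perc_increase=0.25)
            for n, m, k, h in itertools.product(
                (100, 500), (1, 5), (2, 5, 11), HETEROGENEITY_LEVELS)]


def run_normal_benchmark(seed: int, reps: int = 30,
                         methods=NORMAL_METHODS,
                         progress: bool = False) -> pd.DataFrame:
    records = run_grid(normal_table_settings(), list(methods), reps, seed,
                       config=BENCH_CONFIG, progress=progress)
    return records_frame(records)


def run_comp_mult2_benchmark(seed: int, reps: int = 30,
                             methods=COMP_METHODS,
                             progress: bool = False) -> pd.DataFrame:
    records = run_grid(comp_mult2_settings(), list(methods), reps, seed,
                       config=BENCH_CONFIG, progress=progress)
    return records_frame(records)


def run_comp_null_benchmark(seed: int, reps: int = 20,
                            methods=METHOD_NAMES,
                            progress: bool = False) -> pd.DataFrame:
    records = run_grid(comp_null_settings(), list(methods), reps, seed,
                       config=BENCH_CONFIG, progress=progress)
    return records_frame(records)
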