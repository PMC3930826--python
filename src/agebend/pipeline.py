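"""End-to-end convenience driver for the five-step trend analysis.

Steps: (1) sex correction, (2) dataset-level age-association screen,
(3) per-probe quadratic filtering, (4) absolute-correlation k-means of the
centered smoothed trends, (5) age-position detection with cross-k ranges.
Each step is available separately from its own module; this wrapper wires
the default path together for scripts and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ageposition import AgePosition, position_range
from .dataio import ExpressionDataset
from .preprocess import GlobalTestResult, correct_sex, global_age_test
from .trendcluster import TrendMatrix, default_age_grid, trend_matrix_from_table
from .trendfit import filter_probes

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    global_test: GlobalTestResult | None
    significant_probe_ids: list
    fit_table: object
    trends: TrendMatrix | None
    positions: list


def run_pipeline(
    dataset: ExpressionDataset,
    alpha: float = 0.05,
    k_values=(2, 3, 4),
    metric: str = "abscorrelation",
    restarts: int = 25,
    seed: int = 0,
    screen: bool = False,
    n_screen_permutations: int = 999,
) -> PipelineResult:
    """Run sex correction, filtering, clustering and age-position detection.

    With ``screen=True`` the dataset-level permutation test is run first and
    its result attached (the pipeline proceeds regardless; interpreting
    positions from a non-age-regulated dataset is the caller's risk, as such
    positions are expected to be unstable).
    """
    rng = np.random.default_rng(seed)
    if len(set(dataset.sex)) > 1:
        dataset = correct_sex(dataset)
    gt = None
    if screen:
        gt = global_age_test(dataset, n_permutations=n_screen_permutations,
                             seed=int(rng.integers(2**31 - 1)))
    significant, table = filter_probes(dataset, alpha=alpha)
    if len(significant) < max(k_values) + 1:
        return PipelineResult(gt, significant, table, None, [])
    grid = default_age_grid(float(dataset.ages.min()), float(dataset.ages.max()))
    trends = trend_matrix_from_table(table, grid, probe_ids=significant)
    positions: list[AgePosition] = position_range(
        trends, k_values=k_values, metric=metric, restarts=restarts,
        seed=int(rng.integers(2**31 - 1)),
    )
    positions.sort(key=lambda p: p.age)
    return PipelineResult(gt, significant, table, trends, positions)
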