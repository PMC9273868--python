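"""Per-comparison differential effects.

For every gene in a case-control comparison we record the log2 fold
change (case mean minus control mean, both already on the log2 scale)
and a two-sided p-value from Welch's unequal-variance t-test. Welch is
deliberate: the cohorts pooled downstream mix microarray, RNA-seq and
SWATH-MS matrices with very unequal arm sizes, and no distributional
claim beyond approximate normality of log2 values is warranted. The
test is pluggable for callers who want something else.

No multiple-testing correction is applied here: downstream consumers
(directional consistency, candidate tables) work on raw per-comparison
p-values.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ComparisonDataset
from .errors import InsufficientReplicationError

__all__ = ["compute_effects", "welch_test"]

EFFECT_COLUMNS = ("gene", "lfc", "p_value")


def welch_test(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values, row-wise.

    Rows where both arms have zero variance get p = 1: with no spread
    there is no evidence of a location difference, and NaN would poison
    downstream sign counting.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(case, control, axis=1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def compute_effects(
    comparison: ComparisonDataset,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_test,
) -> pd.DataFrame:
    """Compute per-gene effects for one comparison.

    Returns a DataFrame with columns ``gene``, ``lfc``, ``p_value``,
    one row per gene in the comparison's matrix (input order preserved).

    Raises
    ------
    InsufficientReplicationError
        If either arm has fewer than two samples.
    """
    case_cols = comparison.case_samples
    ctrl_cols = comparison.control_samples
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise InsufficientReplicationError(
            f"{comparison.source_name or comparison.group_id}: need >= 2 samples "
            f"per arm, got {len(case_cols)} case / {len(ctrl_cols)} control"
        )
    case = comparison.matrix[case_cols].to_numpy(dtype=float)
    ctrl = comparison.matrix[ctrl_cols].to_numpy(dtype=float)
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    p = test(case, ctrl)
    return pd.DataFrame(
        {"gene": comparison.matrix.index, "lfc": lfc, "p_value": p}
    ).reset_index(drop=True)


def write_effects(effects: pd.DataFrame, path) -> None:
    """Write an effects table as TSV (gene, lfc, p_value)."""
    effects.to_csv(path, sep="\t", index=False)


def read_effects(path) -> pd.DataFrame:
    """Read an effects TSV written by :func:`write_effects`."""
    return pd.read_csv(path, sep="\t")
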