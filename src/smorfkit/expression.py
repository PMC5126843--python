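"""Expression specificity from condition x TU read-count matrices.

The unique expression factor (UEF) of a transcriptional unit is the ratio of
its read count under the condition with the highest expression to the count
under the second-highest condition.  A TU with UEF near 1 is expressed evenly;
a high UEF marks a strongly condition-specific response.  Raw dRNA-seq TSS
counts can contain zeros, so a pseudocount (default 1) is added to numerator
and denominator; pseudocount 0 restores the literal ratio and flags division
by zero as an undefined (infinite) UEF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class UefResult:
    tu_id: str
    uef: float
    max_condition: str
    tied: bool = False


def uef(
    counts: Sequence[float],
    condition_ids: Sequence[str],
    tu_id: str = "",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> UefResult:
    """UEF of one TU: (highest + c) / (second highest + c).

    ``max_condition`` is the argmax; exact ties resolve to the first condition
    in the configured order and are flagged ``tied``.
    """
    values = np.asarray(counts, dtype=float)
    if values.size != len(condition_ids):
        raise ValueError("counts and condition_ids differ in length")
    if values.size < 2:
        raise ValueError("UEF requires at least 2 conditions")
    if (values < 0).any():
        raise ValueError("negative counts")
    order = np.argsort(-values, kind="stable")
    top, second = values[order[0]], values[order[1]]
    denom = second + pseudocount
    ratio = float("inf") if denom == 0 else (top + pseudocount) / denom
    return UefResult(
        tu_id=tu_id,
        uef=float(ratio),
        max_condition=str(condition_ids[order[0]]),
        tied=bool(top == second),
    )


def uef_table(matrix: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-TU UEF table for a counts matrix (rows = TUs, columns = conditions)."""
    if matrix.shape[1] < 2:
        raise ValueError("UEF requires at least 2 conditions")
    rows = [
        uef(matrix.loc[tu].to_numpy(), list(matrix.columns), tu_id=str(tu), pseudocount=pseudocount)
        for tu in matrix.index
    ]
    return pd.DataFrame(
        [{"tu_id": r.tu_id, "uef": r.uef, "max_condition": r.max_condition, "tied": r.tied} for r in rows],
        columns=["tu_id", "uef", "max_condition", "tied"],
    )


def condition_max_census(matrix: pd.DataFrame) -> pd.Series:
    """How many TUs reach their maximum expression under each condition.

    Ties resolve to the first condition in column order; the counts always sum
    to the number of TUs (every condition appears, possibly with count 0).
    """
    census = pd.Series(0, index=matrix.columns, dtype=int)
    if len(matrix):
        argmax = matrix.idxmax(axis=1)  # first column on ties
        counts = argmax.value_counts()
        census.loc[counts.index] = counts
    census.name = "n_tus"
    return census


def rank_by_uef(
    matrix: pd.DataFrame,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """TUs maximal under ``condition``, sorted by descending UEF (ties by tu_id)."""
    if condition not in matrix.columns:
        raise KeyError(f"unknown condition {condition!r}")
    table = uef_table(matrix, pseudocount=pseudocount)
    sel = table[table["max_condition"] == condition].copy()
    sel = sel.sort_values(["uef", "tu_id"], ascending=[False, True], kind="stable")
    sel["rank"] = np.arange(1, len(sel) + 1)
    return sel.reset_index(drop=True)


def library_size_scaling(matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional per-condition library-size normalization (off by default in
    the pipeline): scales each column to the mean column sum."""
    sums = matrix.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("cannot scale a condition with zero total counts")
    return matrix * (sums.mean() / sums)
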