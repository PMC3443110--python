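"""The four-criterion differential-expression filter.

A gene is called differentially expressed between two groups of arrays
(reference group A, test group B) only if it passes all of:

1. **Fold**: the mean of the high-expression group exceeds the mean of the
   low-expression group by more than ``fold_threshold`` (default 2), means
   taken as arithmetic means of floored log2 signals (geometric means on
   the linear scale).
2. **Detection**: the high-expression group carries at least
   ``min_present_high`` Present calls (capped at the group's size, so a
   3-member group needs 3/3 Present).
3. **Rank test**: the exact two-tailed Mann-Whitney p is <= an effective
   threshold. With ``adaptive_min_p`` the threshold is raised to the
   design's minimum achievable p when ``p_max`` is unattainable — for the
   3 vs 3 design p_max=0.057 is impossible and the rule becomes p <= 0.1.
4. **Pairwise consistency**: of the m*n cross-group sample pairs (m >= n),
   at least (m-1)*n individually show a same-direction fold of at least
   ``pairwise_fold`` on floored signals. This stands in for instrument
   change calls, which require probe-level data.

Genes passing all four are labelled Increased or Decreased by the sign of
mean(B) - mean(A); everything else is Unchanged. No multiple-testing
correction is applied — the procedure is a fixed filter, not an FDR
controller, and is reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import DECREASED, INCREASED, UNCHANGED
from .io import ExpressionMatrix
from .normalization import ScalingConfig
from .rank_stats import exact_rank_sum_matrix, min_achievable_p

__all__ = [
    "FilterConfig",
    "compare_groups",
    "summarize_contrast",
    "rank_by_fold",
    "effect_map",
    "COMPARISON_COLUMNS",
]

#: Column schema of the per-gene comparison frame returned by compare_groups.
COMPARISON_COLUMNS = [
    "mean_log2_a", "mean_log2_b", "fold", "n_present_high",
    "p_two_tailed", "pairwise_valid",
    "pass_fold", "pass_detection", "pass_rank_test", "pass_pairwise",
    "effect",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the four selection criteria.

    fold_threshold
        Criterion 1: required ratio of group means (strictly greater-than).
    min_present_high
        Criterion 2: Present calls required in the high-expression group
        (capped at the group size).
    p_max
        Criterion 3: nominal two-tailed p cutoff.
    adaptive_min_p
        When True, the effective cutoff is max(p_max, minimum achievable p
        of the design) — small designs fall back to their floor p.
    pairwise_rule, pairwise_fold
        Criterion 4: require >= (m-1)*n of the m*n sample pairs to show a
        same-direction fold >= pairwise_fold; set pairwise_rule=False to
        disable (the pair counts are still reported).
    """

    fold_threshold: float = 2.0
    min_present_high: int = 3
    p_max: float = 0.057
    adaptive_min_p: bool = True
    pairwise_rule: bool = True
    pairwise_fold: float = 2.0

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValueError("fold_threshold must be > 1")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max must be in (0, 1]")
        if self.min_present_high < 0:
            raise ValueError("min_present_high must be >= 0")
        if not self.pairwise_fold >= 1:
            raise ValueError("pairwise_fold must be >= 1")

    def effective_p(self, m: int, n: int) -> float:
        """Criterion-3 threshold for a given design (adaptive floor applied)."""
        if self.adaptive_min_p:
            return max(self.p_max, min_achievable_p(m, n))
        return self.p_max


def compare_groups(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    config: FilterConfig = FilterConfig(),
    scaling: ScalingConfig = ScalingConfig(),
) -> pd.DataFrame:
    """Apply the four criteria to every gene for the contrast B vs A.

    Group A is the reference (e.g. WT), group B the test group (e.g. the
    conditional knockout); ``fold`` is B over A, so fold < 1 means decreased
    in B. Signals are expected to be globally scaled already; this function
    only applies the log-transform floor.

    Returns a DataFrame indexed by gene id with :data:`COMPARISON_COLUMNS`.
    """
    set_a, set_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    missing = (set_a | set_b) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"sample ids not in matrix: {sorted(missing)}")

    na, nb = len(group_a), len(group_b)
    m, n = max(na, nb), min(na, nb)

    floored_a = np.maximum(matrix.signals[group_a].to_numpy(dtype=float), scaling.floor)
    floored_b = np.maximum(matrix.signals[group_b].to_numpy(dtype=float), scaling.floor)
    log_a = np.log2(floored_a)
    log_b = np.log2(floored_b)
    mean_a = log_a.mean(axis=1)
    mean_b = log_b.mean(axis=1)
    fold = 2.0 ** (mean_b - mean_a)
    increased = mean_b >= mean_a

    # criterion 1: strict > threshold on the high/low ratio
    extremity = np.maximum(fold, 1.0 / fold)
    pass_fold = extremity > config.fold_threshold

    # criterion 2: Present calls in the higher-expression group
    present_a = (matrix.calls[group_a].to_numpy() == "P").sum(axis=1)
    present_b = (matrix.calls[group_b].to_numpy() == "P").sum(axis=1)
    n_present_high = np.where(increased, present_b, present_a)
    high_size = np.where(increased, nb, na)
    pass_detection = n_present_high >= np.minimum(config.min_present_high, high_size)

    # criterion 3: exact rank-sum on floored log2 signals
    _, p = exact_rank_sum_matrix(log_a, log_b)
    pass_rank = p <= config.effective_p(m, n) + 1e-12

    # criterion 4: same-direction >= pairwise_fold on individual pairs
    ratio = floored_b[:, None, :] / floored_a[:, :, None]  # (genes, na, nb)
    n_up_pairs = (ratio >= config.pairwise_fold).sum(axis=(1, 2))
    n_down_pairs = (ratio <= 1.0 / config.pairwise_fold).sum(axis=(1, 2))
    pairwise_valid = np.where(increased, n_up_pairs, n_down_pairs)
    pass_pairwise = (
        pairwise_valid >= (m - 1) * n
        if config.pairwise_rule
        else np.ones(matrix.n_genes, dtype=bool)
    )

    all_pass = pass_fold & pass_detection & pass_rank & pass_pairwise
    effect = np.where(
        all_pass & (mean_b > mean_a), INCREASED,
        np.where(all_pass & (mean_b < mean_a), DECREASED, UNCHANGED),
    )

    return pd.DataFrame(
        {
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "fold": fold,
            "n_present_high": n_present_high,
            "p_two_tailed": p,
            "pairwise_valid": pairwise_valid,
            "pass_fold": pass_fold,
            "pass_detection": pass_detection,
            "pass_rank_test": pass_rank,
            "pass_pairwise": pass_pairwise,
            "effect": effect,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def summarize_contrast(comparisons: pd.DataFrame) -> tuple[int, int]:
    """(number Increased, number Decreased) in one contrast."""
    eff = comparisons["effect"]
    return int((eff == INCREASED).sum()), int((eff == DECREASED).sum())


def effect_map(comparisons: pd.DataFrame) -> dict[str, str]:
    """Gene id -> effect label, the input unit for concordance analyses."""
    return dict(comparisons["effect"])


def rank_by_fold(
    comparisons: pd.DataFrame,
    direction: str,
    k: int,
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Top-k genes of one direction ordered by extremity of fold.

    Decreases sort ascending by fold (most extreme first, fold -> 0),
    increases descending; ties break by gene id so output is deterministic.
    When an annotation table is supplied, symbol and description columns
    are merged in, mirroring published top-gene tables.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if direction not in (INCREASED, DECREASED):
        raise ValueError(f"direction must be {INCREASED!r} or {DECREASED!r}")
    sel = comparisons[comparisons["effect"] == direction].reset_index()
    sel = sel.rename(columns={sel.columns[0]: "gene_id"})
    ascending = direction == DECREASED
    sel = sel.sort_values(["fold", "gene_id"], ascending=[ascending, True]).head(k)
    out = sel[["gene_id", "mean_log2_a", "mean_log2_b", "fold"]].reset_index(drop=True)
    if annotations is not None:
        out = out.merge(
            annotations[["gene_id", "symbol", "description"]], on="gene_id", how="left"
        )
        out = out[["gene_id", "symbol", "description", "mean_log2_a", "mean_log2_b", "fold"]]
    return out
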