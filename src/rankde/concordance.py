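"""Cross-contrast concordance and overlap-enrichment analyses.

Once each contrast has labelled every gene Increased / Decreased /
Unchanged, three questions follow:

* How do the labels of the two knockout contrasts (one per age) distribute
  jointly, and how does that joint distribution stratify by the
  developmental contrast (adult WT vs immature WT)? That is the 3x3x3
  cross-tabulation built here, the in-memory form of the published
  "distribution of modulated genes" table.
* How many genes change concordantly (same non-Unchanged direction at both
  ages), and what fraction of knockout-modulated genes also change during
  normal maturation?
* Is the overlap between two independent gene-label sets larger than chance?
  Tested with Pearson's chi-square on the 3x3 direction table (df = 4, no
  continuity correction) and reported per concordant cell as fold
  enrichment over the independence expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .effects import DECREASED, EFFECT_LEVELS, INCREASED, UNCHANGED

__all__ = [
    "CrossTab3",
    "OverlapResult",
    "OverlapEnrichment",
    "build_crosstab",
    "concordant_counts",
    "modulated_overlap_percent",
    "pearson_chi2",
    "overlap_enrichment",
    "venn_sets",
    "render_crosstab",
]

_LEVEL_INDEX = {lvl: i for i, lvl in enumerate(EFFECT_LEVELS)}
_LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class CrossTab3:
    """3x3x3 gene-count tensor over (first contrast, second contrast,
    developmental contrast), each axis ordered (Increased, Decreased,
    Unchanged)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (3, 3, 3):
            raise ValueError("counts must be a 3x3x3 tensor")
        if (counts < 0).any() or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def n_genes(self) -> int:
        return int(self.counts.sum())

    def marginal(self, axis: int) -> dict[str, int]:
        """Gene counts per level of one axis (0, 1 or 2), summed over the rest."""
        other = tuple(i for i in range(3) if i != axis)
        sums = self.counts.sum(axis=other)
        return {lvl: int(sums[i]) for i, lvl in enumerate(EFFECT_LEVELS)}


@dataclass(frozen=True)
class OverlapResult:
    """Observed vs independence-expected count for one concordant cell,
    together with the global chi-square of the full direction table."""

    observed: int
    expected: float
    fold_enrichment: float
    chi2: float
    df: int
    p: float
    log10_p: float


@dataclass(frozen=True)
class OverlapEnrichment:
    """Per-cell enrichment for (Inc,Inc) and (Dec,Dec) plus the global test."""

    concordant_increase: OverlapResult
    concordant_decrease: OverlapResult
    table: pd.DataFrame
    chi2: float
    df: int
    p: float
    log10_p: float


def _as_index_array(effects: Mapping[str, str], genes: list[str]) -> np.ndarray:
    out = np.empty(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        label = effects[g]
        try:
            out[i] = _LEVEL_INDEX[label]
        except KeyError:
            raise ValueError(f"unknown effect class {label!r} for gene {g!r}") from None
    return out


def _common_universe(*effect_maps: Mapping[str, str]) -> list[str]:
    keysets = [set(m) for m in effect_maps]
    universe = keysets[0]
    for ks in keysets[1:]:
        if ks != universe:
            diff = (universe ^ ks)
            raise ValueError(
                f"effect maps must cover the same gene universe; "
                f"{len(diff)} gene(s) differ, e.g. {sorted(diff)[:3]}"
            )
    return sorted(universe)


def build_crosstab(
    effects_pn11: Mapping[str, str],
    effects_pn56: Mapping[str, str],
    effects_dev: Mapping[str, str],
) -> CrossTab3:
    """Count genes by their (PN11, PN56, developmental) label triple.

    The three maps must be keyed by exactly the same gene ids; a gene
    present in one map but not another raises ValueError.
    """
    genes = _common_universe(effects_pn11, effects_pn56, effects_dev)
    counts = np.zeros((3, 3, 3), dtype=np.int64)
    i = _as_index_array(effects_pn11, genes)
    j = _as_index_array(effects_pn56, genes)
    k = _as_index_array(effects_dev, genes)
    np.add.at(counts, (i, j, k), 1)
    return CrossTab3(counts)


def concordant_counts(tab: CrossTab3) -> tuple[int, int]:
    """Genes Increased in both contrasts, and Decreased in both,
    summed over the developmental axis."""
    inc = _LEVEL_INDEX[INCREASED]
    dec = _LEVEL_INDEX[DECREASED]
    return int(tab.counts[inc, inc, :].sum()), int(tab.counts[dec, dec, :].sum())


def modulated_overlap_percent(tab: CrossTab3) -> tuple[float, float]:
    """Developmental-overlap percentages for modulated vs unaffected genes.

    First value: of the genes with a non-Unchanged label in either knockout
    contrast, the percentage that also carry a non-Unchanged developmental
    label. Second value: the same percentage among genes Unchanged in both
    knockout contrasts.
    """
    unch = _LEVEL_INDEX[UNCHANGED]
    counts = tab.counts
    modulated = counts.sum() - counts[unch, unch, :].sum()
    modulated_dev = (
        counts[:, :, :unch].sum() - counts[unch, unch, :unch].sum()
    )
    unaffected = counts[unch, unch, :].sum()
    unaffected_dev = counts[unch, unch, :unch].sum()
    if modulated == 0 or unaffected == 0:
        raise ValueError("empty denominator: no modulated or no unaffected genes")
    return (
        100.0 * float(modulated_dev) / float(modulated),
        100.0 * float(unaffected_dev) / float(unaffected),
    )


def pearson_chi2(table: np.ndarray) -> tuple[float, int, float, float]:
    """Pearson chi-square of independence, no continuity correction.

    Returns ``(chi2, df, p, log10_p)``; log10_p comes from the log survival
    function so extreme statistics (p far below float underflow) still
    report a meaningful magnitude.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    total = obs.sum()
    if total <= 0:
        raise ValueError("table must contain counts")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError("zero expected count; drop empty rows/columns first")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    log10_p = float(stats.chi2.logsf(chi2, df) / _LN10)
    return chi2, df, p, log10_p


def overlap_enrichment(
    labels_x: Mapping[str, str], labels_y: Mapping[str, str]
) -> OverlapEnrichment:
    """Test two gene-label sets for non-independence of their directions.

    Builds the 3x3 contingency table of x-labels vs y-labels over the
    common gene universe, computes the global Pearson chi-square (df=4),
    and reports the (Increased, Increased) and (Decreased, Decreased) cells
    as observed count, expected count under independence (row total x
    column total / N) and fold enrichment.
    """
    genes = _common_universe(labels_x, labels_y)
    xi = _as_index_array(labels_x, genes)
    yi = _as_index_array(labels_y, genes)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    chi2, df, p, log10_p = pearson_chi2(table)

    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)

    def cell(level: str) -> OverlapResult:
        i = _LEVEL_INDEX[level]
        expected = row[i] * col[i] / n
        if expected == 0:
            raise ValueError(f"zero expected count for concordant {level} cell")
        observed = int(table[i, i])
        return OverlapResult(
            observed=observed,
            expected=float(expected),
            fold_enrichment=observed / float(expected),
            chi2=chi2, df=df, p=p, log10_p=log10_p,
        )

    frame = pd.DataFrame(table, index=list(EFFECT_LEVELS), columns=list(EFFECT_LEVELS))
    return OverlapEnrichment(
        concordant_increase=cell(INCREASED),
        concordant_decrease=cell(DECREASED),
        table=frame,
        chi2=chi2, df=df, p=p, log10_p=log10_p,
    )


def venn_sets(
    list_a: Iterable[tuple[str, str]], list_b: Iterable[tuple[str, str]]
) -> tuple[set, set, set]:
    """Direction-aware partition of two (gene, direction) lists.

    A gene counts as shared only when it appears in both lists with the
    same direction; the same gene with opposite directions lands in both
    "only" sets.
    """
    a, b = set(list_a), set(list_b)
    return a - b, b - a, a & b


def render_crosstab(tab: CrossTab3) -> pd.DataFrame:
    """Flat table of the 3x3x3 tensor in the published nested layout:
    rows are (second-contrast effect, developmental change), columns the
    first contrast's effects. Plain integers only."""
    rows = []
    for j, pn56 in enumerate(EFFECT_LEVELS):
        for k, dev in enumerate(EFFECT_LEVELS):
            row = {"pn56_effect": pn56, "developmental_change": dev}
            for i, pn11 in enumerate(EFFECT_LEVELS):
                row[f"pn11_{pn11}"] = int(tab.counts[i, j, k])
            rows.append(row)
    return pd.DataFrame(rows)
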