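"""Keyword tallies over Gene Ontology Biological Process text.

A crude but transparent functional readout: count the genes whose GO BP
annotation contains any of a set of case-insensitive substrings (the
classic example being "immun" / "inflamm", which as prefixes catch
"immune", "immunity", "autoimmune", "inflammatory", ...), then count how
many of those genes were Increased or Decreased in any of the supplied
contrasts. No GO graph traversal or term enrichment — plain substring
matching, exactly as performed on spreadsheet annotation columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .effects import DECREASED, INCREASED

__all__ = ["KeywordTally", "keyword_tally", "DEFAULT_KEYWORDS"]

DEFAULT_KEYWORDS = ("immun", "inflamm")


@dataclass(frozen=True)
class KeywordTally:
    """Result of a keyword scan.

    n_up and n_down count matching genes with the corresponding effect in
    ANY supplied contrast, so a gene up at one age and down at the other
    contributes to both; each is bounded by n_matching but their sum may
    exceed it.
    """

    keywords: tuple[str, ...]
    n_matching: int
    n_up: int
    n_down: int
    matching_genes: tuple[str, ...] = field(repr=False, default=())

    @property
    def pct_up(self) -> float:
        """100 * n_up / n_matching, rounded to one decimal."""
        if self.n_matching == 0:
            return 0.0
        return round(100.0 * self.n_up / self.n_matching, 1)


def keyword_tally(
    annotations: pd.DataFrame,
    effect_maps: Sequence[Mapping[str, str]],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
) -> KeywordTally:
    """Tally genes whose go_bp_text contains any keyword (case-insensitive).

    Parameters
    ----------
    annotations
        Table with columns ``gene_id`` and ``go_bp_text``.
    effect_maps
        One gene-id -> effect mapping per contrast; a matching gene counts
        as up (down) if it is Increased (Decreased) in at least one of them.
    keywords
        Non-empty list of substrings; matching ignores case and word
        boundaries.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    text = annotations["go_bp_text"].fillna("").str.lower()
    mask = text.apply(lambda t: any(k in t for k in lowered))
    genes = list(annotations.loc[mask, "gene_id"])

    n_up = sum(
        any(m.get(g) == INCREASED for m in effect_maps) for g in genes
    )
    n_down = sum(
        any(m.get(g) == DECREASED for m in effect_maps) for g in genes
    )
    return KeywordTally(
        keywords=tuple(keywords),
        n_matching=len(genes),
        n_up=n_up,
        n_down=n_down,
        matching_genes=tuple(genes),
    )
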