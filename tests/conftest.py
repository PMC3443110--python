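"""Shared fixtures: a published-style cross-tabulation and small matrices."""

import numpy as np
import pandas as pd
import pytest

from rankde import CrossTab3, ExpressionMatrix

# 3x3x3 gene-count grid from a published mouse-cornea Klf5 knockout study's
# "distribution of modulated genes" table, used as worked-example input.
# Keyed by (PN56 effect, developmental change); values are counts for the
# PN11 effect in axis order (Increased, Decreased, Unchanged).
PUBLISHED_CROSSTAB_CELLS = {
    ("Increased", "Increased"): (37, 0, 16),
    ("Increased", "Decreased"): (99, 1, 175),
    ("Increased", "Unchanged"): (230, 1, 194),
    ("Decreased", "Increased"): (0, 25, 47),
    ("Decreased", "Decreased"): (0, 3, 17),
    ("Decreased", "Unchanged"): (1, 44, 73),
    ("Unchanged", "Increased"): (58, 31, 1360),
    ("Unchanged", "Decreased"): (62, 55, 1503),
    ("Unchanged", "Unchanged"): (227, 139, 17417),
}

_LEVELS = ("Increased", "Decreased", "Unchanged")


def published_crosstab() -> CrossTab3:
    counts = np.zeros((3, 3, 3), dtype=np.int64)
    for (pn56, dev), row in PUBLISHED_CROSSTAB_CELLS.items():
        j, k = _LEVELS.index(pn56), _LEVELS.index(dev)
        for i, value in enumerate(row):
            counts[i, j, k] = value
    return CrossTab3(counts)


@pytest.fixture
def table1() -> CrossTab3:
    return published_crosstab()


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Two genes x two samples, calls P/A, for I/O round-trip checks."""
    idx = pd.Index(["g1", "g2"], name="gene_id")
    signals = pd.DataFrame({"s1": [150.0, 12.5], "s2": [0.0, 900.0]}, index=idx)
    calls = pd.DataFrame({"s1": ["P", "A"], "s2": ["A", "P"]}, index=idx)
    return ExpressionMatrix(signals, calls)


def random_matrix(rng: np.random.Generator, n_genes: int, sample_ids: list[str]) -> ExpressionMatrix:
    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    signals = pd.DataFrame(
        rng.lognormal(5.0, 1.0, size=(n_genes, len(sample_ids))),
        index=idx, columns=sample_ids,
    )
    calls = pd.DataFrame(
        rng.choice(["P", "M", "A"], size=(n_genes, len(sample_ids))),
        index=idx, columns=sample_ids,
    )
    return ExpressionMatrix(signals, calls)
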