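"""Tabular I/O with strict validation.

Three tab-delimited formats move data in and out of the pipeline:

* **Expression pivot table** — one row per gene; first column ``gene_id``,
  then for each array a ``<sample_id>.Signal`` column (non-negative
  linear-scale intensity) and a ``<sample_id>.Detection`` column
  (P/M/A detection call). This mirrors the summary-level "pivot" exports
  of instrument software such as GCOS/MAS5; probe-level binary formats
  (CEL/CHP) are deliberately out of scope.
* **Sample sheet** — ``sample_id  genotype  age  replicate`` with the closed
  vocabularies genotype in {WT, KO} and age in {PN11, PN56}.
* **Annotation table** — ``gene_id  symbol  description  go_bp_text`` where
  ``go_bp_text`` is free Gene Ontology Biological Process text (may be empty).

Parsing never silently drops rows: every input row either becomes a record
or raises an error naming the offending row and column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PivotFormatError",
    "read_pivot",
    "write_pivot",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_annotations",
    "samples_for",
]

DETECTION_CALLS = ("P", "M", "A")
GENOTYPES = ("WT", "KO")
AGES = ("PN11", "PN56")

_CALL_ALIASES = {
    "P": "P", "M": "M", "A": "A",
    "PRESENT": "P", "MARGINAL": "M", "ABSENT": "A",
}


class PivotFormatError(ValueError):
    """A pivot file's header does not declare the expected column pairs."""


@dataclass
class ExpressionMatrix:
    """Genes x samples of linear-scale signals plus per-cell detection calls.

    Parameters
    ----------
    signals
        Float DataFrame, index = gene ids, columns = sample ids. All values
        must be finite and >= 0 (linear scale, not logged).
    calls
        String DataFrame of identical shape/labels with values in
        ``{"P", "M", "A"}`` (Present / Marginal / Absent).
    """

    signals: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        sig, calls = self.signals, self.calls
        if list(sig.index) != list(calls.index) or list(sig.columns) != list(calls.columns):
            raise ValueError("signals and calls must share gene and sample labels")
        if sig.index.has_duplicates:
            dup = sig.index[sig.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if sig.columns.has_duplicates:
            dup = sig.columns[sig.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = sig.to_numpy(dtype=float, copy=False)
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("signals must be finite")
        if values.size and values.min() < 0:
            raise ValueError("signals must be non-negative")
        bad = ~calls.isin(DETECTION_CALLS)
        if bad.to_numpy().any():
            gi, si = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"invalid detection call {calls.iat[gi, si]!r} for gene "
                f"{calls.index[gi]!r}, sample {calls.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.signals.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.signals.columns)

    @property
    def n_genes(self) -> int:
        return self.signals.shape[0]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.signals.columns]
        if missing:
            raise KeyError(f"unknown sample ids {missing}")
        return ExpressionMatrix(self.signals[sample_ids], self.calls[sample_ids])


def _normalize_call(raw: object, gene: object, column: str) -> str:
    token = str(raw).strip().upper()
    call = _CALL_ALIASES.get(token)
    if call is None:
        raise ValueError(
            f"invalid detection call {raw!r} in row for gene {gene!r}, column {column!r}"
        )
    return call


def read_pivot(path) -> ExpressionMatrix:
    """Read an expression pivot TSV into a validated :class:`ExpressionMatrix`.

    Row order is preserved; detection strings are normalized to P/M/A
    (full words Present/Marginal/Absent are accepted, case-insensitive).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns.size == 0 or raw.columns[0] != "gene_id":
        raise PivotFormatError("first column must be 'gene_id'")
    sample_ids = [c[: -len(".Signal")] for c in raw.columns if c.endswith(".Signal")]
    expected = ["gene_id"]
    for sid in sample_ids:
        expected += [f"{sid}.Signal", f"{sid}.Detection"]
        if f"{sid}.Detection" not in raw.columns:
            raise PivotFormatError(f"missing Detection column for sample {sid!r}")
    extra = [c for c in raw.columns if c not in expected]
    if extra:
        raise PivotFormatError(f"unexpected columns {extra}")

    genes = raw["gene_id"]
    if genes.duplicated().any():
        raise ValueError(f"duplicate gene id {genes[genes.duplicated()].iloc[0]!r}")

    signals = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    calls = pd.DataFrame(index=signals.index)
    for sid in sample_ids:
        col = f"{sid}.Signal"
        parsed = np.empty(len(raw), dtype=float)
        for i, (token, gene) in enumerate(zip(raw[col], genes)):
            try:
                # float() is correctly rounded, so full-precision reprs
                # written by write_pivot round-trip bit-for-bit
                parsed[i] = float(token)
            except ValueError:
                raise ValueError(
                    f"non-numeric signal {token!r} in column {col!r} for gene {gene!r}"
                ) from None
            if not np.isfinite(parsed[i]):
                raise ValueError(f"non-finite signal in column {col!r} for gene {gene!r}")
            if parsed[i] < 0:
                raise ValueError(f"negative signal in column {col!r} for gene {gene!r}")
        signals[sid] = parsed
        dcol = f"{sid}.Detection"
        calls[sid] = [
            _normalize_call(v, g, dcol) for v, g in zip(raw[dcol], genes)
        ]
    matrix = ExpressionMatrix(signals, calls)
    assert matrix.n_genes == len(raw), "parser must not drop rows"
    return matrix


def write_pivot(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as a pivot TSV re-readable by :func:`read_pivot`.

    Signals are rendered at full round-trip precision (Python float repr),
    so read(write(m)) reproduces m bit-for-bit.
    """
    out = pd.DataFrame({"gene_id": matrix.gene_ids})
    for sid in matrix.sample_ids:
        out[f"{sid}.Signal"] = [repr(float(v)) for v in matrix.signals[sid]]
        out[f"{sid}.Detection"] = matrix.calls[sid].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet.

    Returns a DataFrame with columns sample_id, genotype, age, replicate.
    Unknown genotype/age tokens, duplicate sample ids and non-positive
    replicate numbers raise ValueError.
    """
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str, "age": str})
    required = ["sample_id", "genotype", "age", "replicate"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise PivotFormatError(f"sample sheet missing columns {missing}")
    return validate_sample_sheet(sheet[required])


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    bad_gt = set(sheet["genotype"]) - set(GENOTYPES)
    if bad_gt:
        raise ValueError(f"unknown genotype token(s) {sorted(bad_gt)}; expected {GENOTYPES}")
    bad_age = set(sheet["age"]) - set(AGES)
    if bad_age:
        raise ValueError(f"unknown age token(s) {sorted(bad_age)}; expected {AGES}")
    reps = pd.to_numeric(sheet["replicate"], errors="coerce")
    if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
        raise ValueError("replicate must be a positive integer")
    sheet = sheet.copy()
    sheet["replicate"] = reps.astype(int)
    return sheet.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


def samples_for(sheet: pd.DataFrame, genotype: str, age: str) -> list[str]:
    """Sample ids of one (genotype, age) group, in sheet order."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    if age not in AGES:
        raise ValueError(f"unknown age {age!r}")
    mask = (sheet["genotype"] == genotype) & (sheet["age"] == age)
    return list(sheet.loc[mask, "sample_id"])


def read_annotations(path) -> pd.DataFrame:
    """Read a gene-annotation table (gene_id, symbol, description, go_bp_text).

    go_bp_text may be empty; gene_id must be unique.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_id", "symbol", "description", "go_bp_text"]
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise PivotFormatError(f"annotation table missing columns {missing}")
    if ann["gene_id"].duplicated().any():
        dup = ann.loc[ann["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in annotation table")
    return ann[required].reset_index(drop=True)
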