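"""Tabular input/output and per-gene scaling.

Three plain-text formats cover everything the pipeline touches:

* expression matrices — tab-separated, genes in rows, first column
  ``gene_id``, one column per sample;
* sample annotation — comma-separated with the six columns
  ``sample_id, subject_id, subset, diagnosis, centre, batch``;
* gene signatures — standard GMT (one set per line: name, description,
  then tab-separated gene identifiers).

Gene and sample identifiers are opaque, case-sensitive strings.
Matrices must be complete: a missing or non-numeric cell is a format
error with coordinates, never a value to impute.  Writers emit the same
dialects they read, so a write/read round trip is the identity on
identifiers and (within float formatting) on values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("sample_id", "subject_id", "subset", "diagnosis", "centre", "batch")


class FormatError(ValueError):
    """A file violates the expected dialect or an identifier invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, e.g. a published 21-gene type-1-interferon signature.

    Parameters
    ----------
    name : str
        Signature name (first GMT field).
    genes : tuple of str
        Member gene identifiers, order-preserving, no duplicates.
    description : str
        Free-text second GMT field.
    """

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise FormatError(f"signature {self.name!r} is empty")
        dup = _duplicates(self.genes)
        if dup:
            raise FormatError(f"signature {self.name!r} has duplicate genes: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


class ExpressionMatrix:
    """Log2 gene expression for one leucocyte subset, genes x samples.

    Wraps a float DataFrame indexed by gene id with sample ids as
    columns.  Construction validates the container invariants: unique
    identifiers on both axes, no missing values, numeric body.
    """

    def __init__(self, values: pd.DataFrame, subset: str = ""):
        dup_g = _duplicates(values.index)
        if dup_g:
            raise FormatError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(values.columns)
        if dup_s:
            raise FormatError(f"duplicate sample ids: {sorted(dup_s)}")
        try:
            df = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric expression values: {exc}") from exc
        if df.isna().any().any():
            gene, sample = _first_nan(df)
            raise FormatError(f"missing value at gene {gene!r}, sample {sample!r}")
        self._df = df
        self._df.index = self._df.index.astype(str)
        self._df.columns = self._df.columns.astype(str)
        self.subset = str(subset)

    # -- accessors ---------------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> np.ndarray:
        """Genes x samples float array (a view on the backing frame)."""
        return self._df.to_numpy()

    @property
    def n_genes(self) -> int:
        return self._df.shape[0]

    @property
    def n_samples(self) -> int:
        return self._df.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._df.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self._df.loc[:, list(sample_ids)], subset=self.subset)

    def select_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self._df.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return ExpressionMatrix(self._df.loc[list(gene_ids)], subset=self.subset)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ExpressionMatrix(subset={self.subset!r}, "
                f"n_genes={self.n_genes}, n_samples={self.n_samples})")


class SampleAnnotation:
    """Per-sample metadata table indexed by sample id.

    Columns: subject_id, subset, diagnosis, centre, batch.  Sample ids
    are unique; subset/diagnosis vocabularies are enforced at read time
    (or via :meth:`validate_vocab`).
    """

    def __init__(self, df: pd.DataFrame):
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        missing = [c for c in ANNOTATION_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise FormatError(f"annotation missing required columns: {missing}")
        dup = _duplicates(df.index)
        if dup:
            raise FormatError(f"duplicate sample ids in annotation: {sorted(dup)}")
        self._df = df.copy()
        self._df.index = self._df.index.astype(str)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list[str]:
        return list(self._df.index)

    def __len__(self) -> int:
        return len(self._df)

    def column(self, name: str, sample_ids: Sequence[str] | None = None) -> pd.Series:
        s = self._df[name]
        if sample_ids is not None:
            missing = [x for x in sample_ids if x not in self._df.index]
            if missing:
                raise KeyError(f"samples not annotated: {missing}")
            s = s.loc[list(sample_ids)]
        return s

    def samples_where(self, **conditions: str) -> list[str]:
        """Sample ids matching every column=value condition."""
        mask = pd.Series(True, index=self._df.index)
        for col, value in conditions.items():
            mask &= self._df[col] == value
        return list(self._df.index[mask])

    def validate_vocab(self, vocab: Mapping[str, Sequence[str]]) -> None:
        """Check categorical columns against allowed value lists."""
        for col, allowed in vocab.items():
            if col not in self._df.columns:
                raise FormatError(f"annotation has no column {col!r}")
            bad = sorted(set(self._df[col]) - set(allowed))
            if bad:
                raise FormatError(
                    f"annotation column {col!r} has values {bad} outside the "
                    f"allowed vocabulary {sorted(allowed)}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SampleAnnotation(n_samples={len(self)})"


@dataclass(frozen=True)
class JoinReport:
    """Outcome of joining an annotation table to an expression matrix.

    ``matched`` ∪ ``orphan_matrix`` = matrix samples and
    ``matched`` ∪ ``orphan_annotation`` = annotated samples, exactly.
    """

    matched: tuple[str, ...]
    orphan_matrix: tuple[str, ...]
    orphan_annotation: tuple[str, ...]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, subset_label: str = "") -> ExpressionMatrix:
    """Read a genes x samples TSV (header ``gene_id<TAB>sample...``).

    Raises :class:`FormatError` for duplicate identifiers and for any
    missing or non-numeric cell (named by gene and sample id).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    body = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")  # "" coerces to NaN
        bad = converted.isna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric or missing value at gene {gene!r}, sample {col!r}")
        body[col] = converted
    return ExpressionMatrix(body, subset=subset_label)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.df.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_annotation(path: str | Path,
                           vocab: Mapping[str, Sequence[str]] | None = None
                           ) -> SampleAnnotation:
    """Read the sample annotation CSV and validate vocabularies.

    ``vocab`` maps a column name (typically ``subset`` and
    ``diagnosis``) to its allowed values; out-of-vocabulary entries are
    a :class:`FormatError` listing the allowed values.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing required columns: {missing}")
    annot = SampleAnnotation(df)
    if vocab:
        annot.validate_vocab(vocab)
    return annot


def write_sample_annotation(annot: SampleAnnotation, path: str | Path) -> None:
    annot.df.to_csv(path, index_label="sample_id")


def read_gene_signatures(path: str | Path) -> list[GeneSignature]:
    """Parse a GMT file into one :class:`GeneSignature` per line.

    Duplicate identifiers within a line are dropped (keeping first
    occurrence) with a logged warning; a line without any gene is a
    format error.
    """
    signatures: list[GeneSignature] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.strip() == "":
                raise FormatError(f"{path}:{lineno}: empty GMT line")
            fields = line.split("\t")
            if len(fields) < 3 or all(f.strip() == "" for f in fields[2:]):
                raise FormatError(f"{path}:{lineno}: GMT line has no genes")
            name, description = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g == "":
                    continue
                if g in seen:
                    logger.warning("signature %r: duplicate gene %r dropped", name, g)
                    continue
                seen.add(g)
                genes.append(g)
            signatures.append(GeneSignature(name=name, genes=tuple(genes),
                                            description=description))
    return signatures


def write_gene_signatures(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description, *sig.genes]) + "\n")


def join_samples(m: ExpressionMatrix, annot: SampleAnnotation) -> JoinReport:
    """Join matrix samples to annotation without silently dropping any.

    Returns the matched ids plus the orphans on each side; the three
    sets partition the union of both id sets exactly.
    """
    matrix_ids = set(m.sample_ids)
    annot_ids = set(annot.sample_ids)
    matched = tuple(s for s in m.sample_ids if s in annot_ids)
    orphan_matrix = tuple(s for s in m.sample_ids if s not in annot_ids)
    orphan_annotation = tuple(s for s in annot.sample_ids if s not in matrix_ids)
    return JoinReport(matched=matched, orphan_matrix=orphan_matrix,
                      orphan_annotation=orphan_annotation)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


def zscore_rows(values: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scores and a boolean mask of zero-variance rows.

    Zero-variance rows come back as all-zeros so gene indices stay
    aligned across downstream operations.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = (sd[:, 0] == 0.0) | ~np.isfinite(sd[:, 0])
    sd[degenerate, 0] = 1.0
    z = (values - mean) / sd
    z[degenerate, :] = 0.0
    return z, degenerate


def scale_by_gene(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene row to mean 0 and unit sample (n-1) standard deviation.

    Zero-variance rows are set to all-zeros with a logged warning rather
    than dropped.  Requires at least two samples.
    """
    if m.n_samples < 2:
        raise ValueError("scale_by_gene requires at least 2 samples")
    z, degenerate = zscore_rows(m.values, ddof=1)
    if degenerate.any():
        names = [m.gene_ids[i] for i in np.nonzero(degenerate)[0][:20]]
        logger.warning("scale_by_gene: %d zero-variance genes set to zero rows "
                       "(first few: %s)", int(degenerate.sum()), names)
    return ExpressionMatrix(pd.DataFrame(z, index=m.gene_ids, columns=m.sample_ids),
                            subset=m.subset)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _duplicates(items: Iterable) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _first_nan(df: pd.DataFrame) -> tuple[str, str]:
    mask = df.isna().to_numpy()
    i, j = np.argwhere(mask)[0]
    return str(df.index[i]), str(df.columns[j])
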