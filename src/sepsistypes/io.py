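"""Readers, writers and basic preprocessing for expression cohorts.

Formats are deliberately plain text: tab-delimited expression matrices
(first column gene ID, header row of sample IDs, empty cell or ``NA`` =
missing), CSV clinical tables keyed by ``sample_id``, GMT gene-set files,
and one-symbol-per-line gene lists.  Matrices are assumed to hold
normalized log2 intensities; normalization itself is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, MissingValuesError

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "RestrictionReport",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "filter_high_missing_samples",
    "impute_missing",
    "restrict_to_gene_list",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 intensities.

    Missing entries are stored as NaN in ``values``; ``missing_mask`` is
    derived from them so the two can never fall out of sync.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise FormatError(f"duplicate {kind} IDs: {dupes[:5]}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), list(self.gene_ids), list(self.sample_ids))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row subset in the given order; every gene must be present."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(self.values[rows], list(genes), list(self.sample_ids))

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in samples]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(samples))


@dataclass
class ClinicalTable:
    """Per-sample clinical attributes (binary and continuous)."""

    data: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate sample IDs in clinical table")
        self.data.index = self.data.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.data.columns)

    def is_binary(self, attribute: str) -> bool:
        col = self.data[attribute].dropna()
        return set(np.unique(col)) <= {0, 1, True, False}


@dataclass
class GeneSetCollection:
    """Named gene sets, typically read from a GMT file."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


class RestrictionReport(NamedTuple):
    n_requested: int
    n_found: int
    missing: list[str]


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (gene rows, sample columns)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise FormatError(f"{path}: {exc}") from exc
    df = df.apply(pd.to_numeric, errors="coerce")
    return ExpressionMatrix(df.to_numpy(float), [str(i) for i in df.index], [str(c) for c in df.columns])


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_dataframe().to_csv(path, sep="\t", na_rep="", index_label="gene_id")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: clinical CSV must have a 'sample_id' column")
    df = df.set_index("sample_id")
    for col in df.columns:  # numeric where possible, leave text columns alone
        converted = pd.to_numeric(df[col], errors="coerce")
        if not (converted.isna() & df[col].notna()).any():
            df[col] = converted
    return ClinicalTable(df)


def write_clinical(t: ClinicalTable, path: str | Path) -> None:
    t.data.to_csv(path, index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(c: GeneSetCollection, path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = [
        "\t".join([name, descriptions.get(name, "na"), *members])
        for name, members in c.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines skipped; duplicates kept (callers dedupe)."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(str(g) for g in genes) + "\n")


# ---------------------------------------------------------------------------
# preprocessing


def filter_high_missing_samples(
    m: ExpressionMatrix, threshold: float = 0.80
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples whose missing fraction is strictly above ``threshold``.

    The strict inequality matters: a sample with exactly 80% missing values
    is retained at the default threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    frac = m.missing_mask.mean(axis=0)
    keep = frac <= threshold
    removed = [s for s, k in zip(m.sample_ids, keep) if not k]
    if not keep.any():
        raise DegenerateInputError("every sample exceeds the missingness threshold")
    if not removed:
        return m, []
    kept_ids = [s for s, k in zip(m.sample_ids, keep) if k]
    return ExpressionMatrix(m.values[:, keep], list(m.gene_ids), kept_ids), removed


def impute_missing(m: ExpressionMatrix, method: str = "gene_median") -> ExpressionMatrix:
    """Replace missing entries by the gene's median over observed samples."""
    if method != "gene_median":
        raise ValueError(f"unknown imputation method {method!r}")
    if not m.has_missing:
        return m.copy()
    mask = m.missing_mask
    all_missing = mask.all(axis=1)
    if all_missing.any():
        bad = [g for g, b in zip(m.gene_ids, all_missing) if b]
        raise DegenerateInputError(f"genes with no observed values: {bad[:10]}")
    values = m.values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(values, axis=1)
    rows, cols = np.nonzero(mask)
    values[rows, cols] = medians[rows]
    return ExpressionMatrix(values, list(m.gene_ids), list(m.sample_ids))


def restrict_to_gene_list(
    m: ExpressionMatrix, genes: Sequence[str]
) -> tuple[ExpressionMatrix, RestrictionReport]:
    """Row-subset the matrix to a candidate gene list.

    List members absent from the platform are silently dropped (the report
    carries the counts); duplicates in the list keep their first occurrence.
    """
    seen: set[str] = set()
    deduped = []
    for g in genes:
        g = str(g)
        if g not in seen:
            seen.add(g)
            deduped.append(g)
    on_platform = set(m.gene_ids)
    found = [g for g in deduped if g in on_platform]
    missing = [g for g in deduped if g not in on_platform]
    if not found:
        raise DegenerateInputError("gene list does not intersect the platform")
    report = RestrictionReport(n_requested=len(deduped), n_found=len(found), missing=missing)
    return m.subset_genes(found), report


def require_complete(m: ExpressionMatrix, context: str = "this operation") -> None:
    """Raise if the matrix still contains missing values."""
    if m.has_missing:
        raise MissingValuesError(
            f"{context} requires a complete matrix; run impute_missing() first"
        )
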