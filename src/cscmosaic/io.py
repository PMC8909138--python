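"""Reading, validating and filtering expression matrices and gene sets.

Every downstream stage of the pipeline consumes the types defined here: a
genes x cells TPM matrix (:class:`ExpressionMatrix`) and named gene lists
(:class:`GeneSet`, :class:`GeneSetCollection`).  Supported on-disk formats
are dense TSV (genes x cells, header row of cell ids), Matrix Market
coordinate files with sibling plain-text gene/cell name files, and the GMT
gene-set format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: allowed unit tags for an ExpressionMatrix
UNIT_TPM = "TPM"
UNIT_LOG2_TPM1 = "LOG2_TPM1"
UNIT_ZSCORE = "ZSCORE"
_UNITS = (UNIT_TPM, UNIT_LOG2_TPM1, UNIT_ZSCORE)


class ParseError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed data violate an invariant of the domain type."""


@dataclass
class ExpressionMatrix:
    """A genes x cells (or genes x samples) abundance matrix.

    Parameters
    ----------
    values
        2-D float array, one row per gene, one column per cell.
    gene_ids, cell_ids
        Ordered, unique identifiers matching the array dimensions.
    unit
        One of ``"TPM"``, ``"LOG2_TPM1"``, ``"ZSCORE"``.  TPM matrices must
        be non-negative; all matrices must be finite.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    unit: str = UNIT_TPM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.unit not in _UNITS:
            raise ValidationError(f"unknown unit tag {self.unit!r}; expected one of {_UNITS}")
        if self.values.ndim != 2:
            raise ValidationError("expression values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {label} identifiers: {dupes[:5]}")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")
        if self.unit == UNIT_TPM and (self.values < 0).any():
            raise ValidationError("TPM values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    # -- accessors ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        """Expression of one gene across all cells."""
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            near = [g for g in self.gene_ids if gene.lower() in g.lower() or g.lower() in gene.lower()]
            raise KeyError(f"gene {gene!r} not in matrix; near matches: {near[:5]}") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(self.values[idx], list(genes), list(self.cell_ids), self.unit)

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._cell_index[c] for c in cells]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(cells), self.unit)

    def cell_indices(self, cells: Iterable[str]) -> np.ndarray:
        return np.array([self._cell_index[c] for c in cells], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.name:
            raise ValidationError("gene set needs a non-empty name")
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered list of gene sets with unique names."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate gene-set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(
    path: str | Path,
    format: str | None = None,
    *,
    transpose: bool = False,
    sep: str = "\t",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a TPM expression matrix from dense TSV or Matrix Market files.

    The dense layout is genes x cells with a header row of cell ids and the
    gene id in the first column.  The MTX layout expects sibling name files
    ``<stem>.genes.txt`` / ``<stem>.cells.txt`` next to the matrix unless
    explicit paths are given.  ``transpose=True`` handles cells x genes
    sources.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"could not parse {path} as dense {sep!r}-separated matrix: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ParseError(f"non-numeric column(s) in {path}: {bad[:5]}")
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        stem = path.with_suffix("")
        gp = Path(genes_path) if genes_path else stem.with_suffix(".genes.txt")
        cp = Path(cells_path) if cells_path else stem.with_suffix(".cells.txt")
        for p in (gp, cp):
            if not p.exists():
                raise FileNotFoundError(f"MTX matrix {path} requires sibling name file {p}")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"could not parse {path} as Matrix Market: {exc}") from exc
        values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        row_ids = gp.read_text().split()
        col_ids = cp.read_text().split()
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'tsv'")

    if transpose:
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids, UNIT_TPM)


def write_expression(m: ExpressionMatrix, path: str | Path, format: str = "tsv", sep: str = "\t") -> None:
    """Write a matrix as dense TSV or as MTX plus sibling name files."""
    path = Path(path)
    if format == "tsv":
        m.to_frame().to_csv(path, sep=sep, index_label="gene")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        stem = path.with_suffix("")
        stem.with_suffix(".genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        stem.with_suffix(".cells.txt").write_text("\n".join(m.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    The description column is discarded; duplicate genes within a line are
    deduplicated with a logged warning.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
            sets.append(GeneSet(name, frozenset(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# filtering / transforms


def filter_genes(
    m: ExpressionMatrix, mean_tpm_min: float = 0.2, min_cells: int = 30
) -> ExpressionMatrix:
    """Keep genes with mean TPM above ``mean_tpm_min`` that are expressed
    (TPM > 0) in at least ``min_cells`` cells.

    Both rules apply jointly; cell set and gene order are unchanged.
    """
    if m.unit != UNIT_TPM:
        raise ValidationError(f"filter_genes expects TPM input, got {m.unit}")
    mean_ok = m.values.mean(axis=1) > mean_tpm_min
    cells_ok = (m.values > 0).sum(axis=1) >= min_cells
    keep = mean_ok & cells_ok
    if not keep.any():
        raise ValidationError(
            f"no gene passes mean TPM > {mean_tpm_min} in >= {min_cells} cells; "
            "review the thresholds for this matrix"
        )
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return ExpressionMatrix(m.values[keep], genes, list(m.cell_ids), UNIT_TPM)


def log2_tpm1(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform; the working scale for DEG and PCA."""
    if m.unit != UNIT_TPM:
        raise ValidationError(f"log2_tpm1 expects TPM input, got {m.unit}")
    return ExpressionMatrix(np.log2(m.values + 1.0), list(m.gene_ids), list(m.cell_ids), UNIT_LOG2_TPM1)
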