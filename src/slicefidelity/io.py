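"""Domain types and readers/writers for single-cell count data and pipeline tables.

Count matrices follow the conventional 10X triplet layout: a Matrix Market
coordinate file (genes as rows, cells as columns, 1-based indices) plus
tab-separated ``features`` and ``barcodes`` companion files.  Gzip-compressed
inputs are detected by the ``.gz`` extension and decompressed transparently.
Internally everything is 0-based.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import FormatError

__all__ = [
    "TIMEPOINTS",
    "CountMatrix",
    "CellAnnotation",
    "DETable",
    "DispersionEstimate",
    "SignatureMatrix",
    "CorrelationMatrix",
    "CompositionTable",
    "AggregateFidelity",
    "read_count_matrix",
    "write_count_matrix",
    "read_cell_annotations",
    "write_cell_annotations",
    "read_de_table",
    "write_de_table",
]

#: The two timepoints of a paired culture experiment.
TIMEPOINTS = ("day0", "day14")

#: Accepted spellings for each timepoint, lower-cased and stripped of spaces/underscores.
_TIMEPOINT_ALIASES = {
    "day0": "day0",
    "d0": "day0",
    "0": "day0",
    "day14": "day14",
    "d14": "day14",
    "14": "day14",
}

#: Number of significant digits preserved by CSV round trips.
_FLOAT_FORMAT = "%.12g"

#: Column order of the on-disk differential-expression CSV.
DE_CSV_COLUMNS = [
    "gene_id",
    "gene_name",
    "cell_type",
    "mean_in",
    "mean_out",
    "log2_fold_change",
    "p_value",
    "adjusted_p_value",
]


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class CountMatrix:
    """Sparse gene x cell matrix of non-negative integer UMI counts.

    Attributes
    ----------
    counts
        ``scipy.sparse`` matrix, genes as rows and cells as columns.
    gene_ids
        Unique identifier per gene row.
    gene_names
        Display name per gene row (defaults to the id when absent on disk).
    cell_barcodes
        Unique identifier per cell column.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    gene_names: list[str]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.gene_names = [str(g) for g in self.gene_names]
        self.cell_barcodes = [str(b) for b in self.cell_barcodes]
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"matrix declares {n_genes} genes but {len(self.gene_ids)} feature records given"
            )
        if len(self.gene_names) != n_genes:
            raise FormatError("gene_names length does not match the number of gene rows")
        if len(self.cell_barcodes) != n_cells:
            raise FormatError(
                f"matrix declares {n_cells} cells but {len(self.cell_barcodes)} barcode records given"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_barcodes)) != n_cells:
            raise ValueError("cell barcodes are not unique")
        data = self.counts.data
        if data.size:
            if not np.issubdtype(data.dtype, np.integer):
                if not np.allclose(data, np.rint(data), atol=0, rtol=0):
                    raise ValueError("counts must be integers; found fractional values")
                self.counts = self.counts.astype(np.int64)
                data = self.counts.data
            if data.min() < 0:
                raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Dense ``float64`` copy of the counts (genes x cells)."""
        return np.asarray(self.counts.todense(), dtype=np.float64)

    def subset_cells(self, column_index: np.ndarray) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given cell columns."""
        column_index = np.asarray(column_index)
        return CountMatrix(
            counts=self.counts[:, column_index],
            gene_ids=list(self.gene_ids),
            gene_names=list(self.gene_names),
            cell_barcodes=[self.cell_barcodes[i] for i in column_index],
        )


def normalize_timepoint(token: str) -> str:
    """Map a timepoint spelling such as ``Day 0``/``d14`` onto ``day0``/``day14``."""
    key = str(token).strip().lower().replace(" ", "").replace("_", "")
    try:
        return _TIMEPOINT_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unrecognized timepoint {token!r}; allowed values are {TIMEPOINTS}"
        ) from None


@dataclass
class CellAnnotation:
    """Per-cell sample, timepoint, and cell-type labels.

    Stored as a DataFrame with columns ``barcode``, ``sample_id``,
    ``timepoint`` and ``cell_type``.  ``(sample_id, timepoint, barcode)``
    triples must be unique and timepoints must be one of :data:`TIMEPOINTS`.
    """

    df: pd.DataFrame

    REQUIRED = ("barcode", "sample_id", "timepoint", "cell_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"annotation is missing required columns: {missing}")
        df = self.df.loc[:, list(self.REQUIRED)].copy()
        df["timepoint"] = df["timepoint"].map(normalize_timepoint)
        for col in self.REQUIRED:
            df[col] = df[col].astype(str)
        dup = df.duplicated(subset=["sample_id", "timepoint", "barcode"])
        if dup.any():
            offending = df.loc[dup, ["sample_id", "timepoint", "barcode"]].iloc[0]
            raise ValueError(
                "duplicate (sample_id, timepoint, barcode) triple: "
                f"{tuple(offending)}"
            )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.df["cell_type"].unique())

    def for_timepoint(self, timepoint: str) -> pd.DataFrame:
        """Rows for one timepoint (spelling normalized first)."""
        return self.df[self.df["timepoint"] == normalize_timepoint(timepoint)]

    def check_against(self, matrix: CountMatrix) -> None:
        """Raise if any annotated barcode is absent from ``matrix``."""
        known = set(matrix.cell_barcodes)
        unknown = [b for b in self.df["barcode"] if b not in known]
        if unknown:
            raise ValueError(
                f"{len(unknown)} annotated barcodes absent from the count matrix "
                f"(first: {unknown[0]!r})"
            )


@dataclass
class DETable:
    """One-vs-rest differential expression results for a single cell type.

    ``df`` holds one row per tested gene with columns ``gene_id``,
    ``gene_name``, ``mean_in``, ``mean_out``, ``log2_fold_change``,
    ``p_value`` and ``adjusted_p_value``.  Only genes passing the
    low-expression filter appear; all of them are retained regardless of
    significance so that signature vectors can be assembled later.
    """

    cell_type: str
    df: pd.DataFrame

    REQUIRED = (
        "gene_id",
        "gene_name",
        "mean_in",
        "mean_out",
        "log2_fold_change",
        "p_value",
        "adjusted_p_value",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"DE table is missing required columns: {missing}")
        df = self.df.loc[:, list(self.REQUIRED)].reset_index(drop=True)
        for col in ("p_value", "adjusted_p_value"):
            vals = df[col].to_numpy(dtype=float)
            if len(vals) and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
                raise ValueError(f"{col} outside [0, 1]")
        if len(df) and (df["adjusted_p_value"].to_numpy() + 1e-15 < df["p_value"].to_numpy()).any():
            raise ValueError("adjusted_p_value below raw p_value")
        self.df = df

    def significant_genes(self, alpha: float = 0.05) -> list[str]:
        """Gene ids with BH-adjusted p-value strictly below ``alpha``."""
        mask = self.df["adjusted_p_value"].to_numpy(dtype=float) < alpha
        return self.df.loc[mask, "gene_id"].tolist()


@dataclass
class DispersionEstimate:
    """Per-gene NB dispersions before and after shrinkage toward a common target."""

    per_gene_mom: np.ndarray
    shrinkage_target: float
    shrunken: np.ndarray
    shrinkage_weight: float

    def __post_init__(self) -> None:
        self.per_gene_mom = np.asarray(self.per_gene_mom, dtype=float)
        self.shrunken = np.asarray(self.shrunken, dtype=float)
        if not 0.0 <= self.shrinkage_weight <= 1.0:
            raise ValueError("shrinkage_weight must lie in [0, 1]")
        if (self.per_gene_mom < 0).any() or (self.shrunken < 0).any():
            raise ValueError("dispersions must be non-negative")


@dataclass
class SignatureMatrix:
    """Genes x cell-types matrix of log2 fold changes for one timepoint.

    Rows follow the significant-gene union order, columns the sorted
    cell-type labels.  Entries are always finite.
    """

    timepoint: str
    genes: list[str]
    cell_types: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timepoint = normalize_timepoint(self.timepoint)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cell_types)):
            raise ValueError("signature matrix shape does not match gene / cell-type labels")
        if not np.isfinite(self.values).all():
            raise ValueError("signature matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.cell_types)


@dataclass
class CorrelationMatrix:
    """Day-0 cell types (rows) x day-14 cell types (columns) correlation values."""

    day0_types: list[str]
    day14_types: list[str]
    values: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.day0_types), len(self.day14_types)):
            raise ValueError("correlation matrix shape does not match labels")
        if len(self.values) and (np.abs(self.values) > 1 + 1e-12).any():
            raise ValueError("correlations outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.day0_types, columns=self.day14_types)

    def lookup(self, day0_type: str, day14_type: str) -> float:
        return float(
            self.values[self.day0_types.index(day0_type), self.day14_types.index(day14_type)]
        )


@dataclass
class CompositionTable:
    """Relative cell-type proportions per (sample, timepoint).

    ``df`` columns: ``sample_id``, ``timepoint``, ``cell_type``, ``n_cells``,
    ``n_total``, ``proportion``.  Proportions within one (sample, timepoint)
    sum to 1 up to 1e-12.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.df.groupby(["sample_id", "timepoint"])["proportion"].sum()
        if len(sums) and (np.abs(sums.to_numpy() - 1.0) > 1e-12).any():
            raise ValueError("proportions do not sum to 1 within a (sample, timepoint) group")


@dataclass
class AggregateFidelity:
    """Cross-sample aggregation of per-cell-type diagonal correlations.

    For each cell type: the contributing per-sample values, their mean, the
    standard error of the mean (``None`` when only one sample contributes) and
    the number of contributing samples.
    """

    values: dict[str, list[float]]
    mean: dict[str, float] = field(default_factory=dict)
    sem: dict[str, float | None] = field(default_factory=dict)
    n_samples: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell_type, vals in self.values.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ValueError(f"no values for cell type {cell_type!r}")
            self.mean[cell_type] = float(arr.mean())
            self.n_samples[cell_type] = int(arr.size)
            self.sem[cell_type] = (
                float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
            )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell_type in sorted(self.values):
            rows.append(
                {
                    "cell_type": cell_type,
                    "mean": self.mean[cell_type],
                    "sem": np.nan if self.sem[cell_type] is None else self.sem[cell_type],
                    "n_samples": self.n_samples[cell_type],
                    "values": ";".join(_FLOAT_FORMAT % v for v in self.values[cell_type]),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_lines(path: str | Path) -> list[list[str]]:
    with _open_maybe_gzip(path) as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.strip()]


def read_count_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CountMatrix:
    """Read a Matrix Market + features + barcodes triplet into a :class:`CountMatrix`.

    The features file may have 1 (id), 2 (id, name) or 3 (id, name, type)
    columns; names default to ids.  Entries absent from the coordinate file
    are zero.  Header/record-count mismatches raise :class:`FormatError`;
    negative or fractional counts raise :class:`ValueError`.
    """
    with _open_maybe_gzip(matrix_path, "rb") as fh:
        try:
            mat = scipy.io.mmread(_io.BytesIO(fh.read()))
        except Exception as exc:  # malformed MTX
            raise FormatError(f"could not parse Matrix Market file {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)

    features = _read_tsv_lines(features_path)
    barcodes = _read_tsv_lines(barcodes_path)
    if len(features) != mat.shape[0]:
        raise FormatError(
            f"matrix declares {mat.shape[0]} genes but features file has {len(features)} records"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"matrix declares {mat.shape[1]} cells but barcodes file has {len(barcodes)} records"
        )
    gene_ids = [row[0] for row in features]
    gene_names = [row[1] if len(row) > 1 and row[1] else row[0] for row in features]
    cell_barcodes = [row[0] for row in barcodes]
    return CountMatrix(mat, gene_ids, gene_names, cell_barcodes)


def write_count_matrix(cm: CountMatrix, out_dir: str | Path, gzip_output: bool = False) -> dict:
    """Write the 10X-style triplet under ``out_dir``; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip_output else ""
    matrix_path = out_dir / f"matrix.mtx{suffix}"
    features_path = out_dir / f"features.tsv{suffix}"
    barcodes_path = out_dir / f"barcodes.tsv{suffix}"

    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, sp.coo_matrix(cm.counts), field="integer")
    with _open_maybe_gzip(matrix_path, "wb") as fh:
        fh.write(buf.getvalue())
    with _open_maybe_gzip(features_path, "wt") as fh:
        for gid, name in zip(cm.gene_ids, cm.gene_names):
            fh.write(f"{gid}\t{name}\tGene Expression\n")
    with _open_maybe_gzip(barcodes_path, "wt") as fh:
        for bc in cm.cell_barcodes:
            fh.write(f"{bc}\n")
    return {"matrix": matrix_path, "features": features_path, "barcodes": barcodes_path}


def read_cell_annotations(tsv_path: str | Path) -> CellAnnotation:
    """Read a per-cell annotation TSV with header barcode/sample_id/timepoint/cell_type."""
    with _open_maybe_gzip(tsv_path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    return CellAnnotation(df)


def write_cell_annotations(ann: CellAnnotation, tsv_path: str | Path) -> None:
    ann.df.to_csv(tsv_path, sep="\t", index=False)


def write_de_table(table: DETable, csv_path: str | Path) -> None:
    """Write a DE table as CSV (12 significant digits; round trips losslessly)."""
    df = table.df.copy()
    df["cell_type"] = table.cell_type
    df[DE_CSV_COLUMNS].to_csv(csv_path, index=False, float_format=_FLOAT_FORMAT)


def read_de_table(csv_path: str | Path) -> DETable:
    df = pd.read_csv(csv_path, dtype={"gene_id": str, "gene_name": str, "cell_type": str})
    missing = [c for c in DE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DE CSV {csv_path} is missing columns: {missing}")
    cell_types = df["cell_type"].unique().tolist() if len(df) else [""]
    if len(cell_types) != 1:
        raise FormatError(f"DE CSV {csv_path} mixes multiple cell types: {cell_types}")
    return DETable(cell_type=cell_types[0], df=df.drop(columns=["cell_type"]))


def write_de_tables(tables: Sequence[DETable], out_dir: str | Path, prefix: str = "de") -> list[Path]:
    """Write one CSV per cell type; file names are ``<prefix>_<cell_type>.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for table in tables:
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in table.cell_type)
        path = out_dir / f"{prefix}_{safe}.csv"
        write_de_table(table, path)
        paths.append(path)
    return paths
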