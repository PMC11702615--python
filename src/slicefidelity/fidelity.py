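"""Signature construction, day-0 x day-14 correlation, and composition analysis.

The preservation of a cell type's transcriptional identity in culture is
measured by correlating its one-vs-rest log2 fold-change signature at day 14
with the day-0 signatures, over one shared gene list: the union of genes
significantly differentially expressed (BH-adjusted p < alpha) in at least
one cell type at either timepoint.  The diagonal of the resulting
correlation matrix — each type against its own day-0 counterpart — is the
fidelity statistic; off-diagonal entries measure confusion between types.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DEFAULT_PSEUDOCOUNT, compute_size_factors
from .exceptions import ConfigurationError, NoSignificantGenesError
from .io import (
    AggregateFidelity,
    CellAnnotation,
    CompositionTable,
    CorrelationMatrix,
    CountMatrix,
    DETable,
    SignatureMatrix,
)

__all__ = [
    "significant_gene_union",
    "build_signature_matrix",
    "correlate_signatures",
    "diagonal_fidelity",
    "aggregate_across_samples",
    "cell_type_proportions",
    "score_clusters_by_markers",
]

logger = logging.getLogger(__name__)


def significant_gene_union(
    tables_day0: Sequence[DETable],
    tables_day14: Sequence[DETable],
    alpha: float = 0.05,
) -> list[str]:
    """Sorted union of genes significant (padj < alpha) in any cell type at either timepoint.

    Raises :class:`NoSignificantGenesError` when the union is empty, because
    the downstream signature correlation is undefined without genes.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    union: set[str] = set()
    for table in list(tables_day0) + list(tables_day14):
        union.update(table.significant_genes(alpha))
    if not union:
        raise NoSignificantGenesError(
            f"no gene reached adjusted p < {alpha} in any cell type at either timepoint"
        )
    return sorted(union)


def build_signature_matrix(
    tables: Sequence[DETable],
    union_genes: Sequence[str],
    timepoint: str,
    fallback_means: Mapping[str, pd.DataFrame] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SignatureMatrix:
    """Assemble the |union| x K log2 fold-change signature matrix for one timepoint.

    A union gene missing from a table (filtered out at this timepoint but
    significant via the other) is never dropped or zero-imputed: its log2FC
    is recomputed as ``log2((mean_in + eps) / (mean_out + eps))`` from the
    ``fallback_means`` of :func:`slicefidelity.diffexp.normalized_group_means`.
    Without a fallback such a gene raises ``ValueError``.
    """
    union_genes = list(union_genes)
    cell_types = sorted(t.cell_type for t in tables)
    by_type = {t.cell_type: t for t in tables}
    values = np.empty((len(union_genes), len(cell_types)))
    for j, cell_type in enumerate(cell_types):
        table = by_type[cell_type]
        lfc = pd.Series(
            table.df["log2_fold_change"].to_numpy(), index=table.df["gene_id"]
        )
        col = lfc.reindex(union_genes)
        missing = col.index[col.isna()]
        if len(missing):
            if fallback_means is None or cell_type not in fallback_means:
                raise ValueError(
                    f"union gene {missing[0]!r} absent from the {cell_type!r} table "
                    "and no fallback means supplied"
                )
            means = fallback_means[cell_type]
            unknown = [g for g in missing if g not in means.index]
            if unknown:
                raise ValueError(f"gene {unknown[0]!r} unknown to this timepoint's matrix")
            sub = means.loc[missing]
            col.loc[missing] = np.log2(
                (sub["mean_in"].to_numpy() + pseudocount)
                / (sub["mean_out"].to_numpy() + pseudocount)
            )
        values[:, j] = col.to_numpy(dtype=float)
    return SignatureMatrix(
        timepoint=timepoint, genes=union_genes, cell_types=cell_types, values=values
    )


def _column_correlations(x: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
        y = np.apply_along_axis(stats.rankdata, 0, y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    yn = np.linalg.norm(yc, axis=0)
    r = (xc.T @ yc) / np.outer(xn, yn)
    # Bitwise-identical signatures correlate at exactly 1 by definition;
    # override to avoid the last-ulp wobble of the normalization.
    for i in range(x.shape[1]):
        for j in range(y.shape[1]):
            if np.array_equal(xc[:, i], yc[:, j]):
                r[i, j] = 1.0
    return np.clip(r, -1.0, 1.0)


def correlate_signatures(
    day0: SignatureMatrix,
    day14: SignatureMatrix,
    method: str = "pearson",
) -> CorrelationMatrix:
    """Correlate every day-0 signature column with every day-14 column.

    Both matrices must be built over the identical gene union.  A
    zero-variance column makes the correlation undefined and raises
    ``ValueError`` naming the degenerate cell type.
    """
    if day0.genes != day14.genes:
        raise ValueError("signature matrices were built over different gene unions")
    for sig in (day0, day14):
        variances = sig.values.var(axis=0)
        for label, var in zip(sig.cell_types, variances):
            if var == 0:
                raise ValueError(
                    f"zero-variance signature for cell type {label!r} at {sig.timepoint}"
                )
    r = _column_correlations(day0.values, day14.values, method)
    return CorrelationMatrix(
        day0_types=list(day0.cell_types),
        day14_types=list(day14.cell_types),
        values=r,
        n_genes=len(day0.genes),
    )


def diagonal_fidelity(corr: CorrelationMatrix) -> tuple[list[tuple[str, float]], list[str]]:
    """Per-cell-type self-correlation for types present at both timepoints.

    Returns ``(matched, absent)``: ``matched`` is a list of ``(cell_type,
    r)`` for label-matched row/column pairs, ``absent`` lists types present
    at only one timepoint.  No matched label at all raises ``ValueError``.
    """
    rows, cols = set(corr.day0_types), set(corr.day14_types)
    matched_labels = sorted(rows & cols)
    if not matched_labels:
        raise ValueError("no cell type present at both timepoints")
    matched = [(label, corr.lookup(label, label)) for label in matched_labels]
    absent = sorted(rows ^ cols)
    return matched, absent


def aggregate_across_samples(
    per_sample: Iterable[Sequence[tuple[str, float]]],
) -> AggregateFidelity:
    """Pool per-sample diagonal fidelities by cell type: mean, SEM, n.

    SEM uses the n-1 sample standard deviation and is undefined (``None``)
    for cell types contributed by a single sample.
    """
    values: dict[str, list[float]] = {}
    n_lists = 0
    for diag in per_sample:
        n_lists += 1
        for cell_type, r in diag:
            values.setdefault(cell_type, []).append(float(r))
    if n_lists == 0 or not values:
        raise ValueError("no per-sample fidelity values to aggregate")
    return AggregateFidelity(values=values)


def cell_type_proportions(annotations: CellAnnotation) -> CompositionTable:
    """Relative cell-type proportions within each (sample, timepoint) group."""
    df = annotations.df
    if df.empty:
        raise ValueError("empty annotation")
    counts = (
        df.groupby(["sample_id", "timepoint", "cell_type"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = counts.groupby(["sample_id", "timepoint"])["n_cells"].transform("sum")
    counts["n_total"] = totals
    counts["proportion"] = counts["n_cells"] / totals
    return CompositionTable(counts)


def score_clusters_by_markers(
    cm: CountMatrix,
    cluster_labels: Sequence[str],
    marker_lists: Mapping[str, Sequence[str]],
) -> dict[str, str]:
    """Assign each cluster a cell type by marker-gene expression.

    A deterministic surrogate for manual marker-based annotation: per
    cluster, each candidate type is scored by the mean (over its markers) of
    the cluster's mean size-factor-normalized expression, z-scored per gene
    across clusters; the argmax wins.  Ties and clusters where every marker
    of every type is missing map to ``"unassigned"``.  Markers absent from
    the matrix are warned about and skipped; a type whose marker list is
    empty is a configuration error.
    """
    for cell_type, markers in marker_lists.items():
        if not list(markers):
            raise ConfigurationError(f"empty marker list for cell type {cell_type!r}")
    labels = pd.Series([str(c) for c in cluster_labels])
    if len(labels) != cm.n_cells:
        raise ValueError("cluster labels length does not match the number of cells")
    clusters = sorted(labels.unique())

    dense = cm.dense()
    factors = compute_size_factors(dense)
    valid = ~np.isnan(factors)
    norm = dense[:, valid] / factors[valid]
    labels = labels[valid].reset_index(drop=True)

    cluster_means = np.column_stack(
        [norm[:, (labels == cl).to_numpy()].mean(axis=1) for cl in clusters]
    )
    mu = cluster_means.mean(axis=1, keepdims=True)
    sd = cluster_means.std(axis=1, keepdims=True)
    z = np.divide(cluster_means - mu, sd, out=np.zeros_like(cluster_means), where=sd > 0)

    gene_index = {g: i for i, g in enumerate(cm.gene_ids)}
    type_rows: dict[str, np.ndarray] = {}
    for cell_type, markers in marker_lists.items():
        present = [gene_index[g] for g in markers if g in gene_index]
        skipped = [g for g in markers if g not in gene_index]
        if skipped:
            logger.warning(
                "cell type %r: %d marker(s) absent from the matrix (e.g. %r)",
                cell_type,
                len(skipped),
                skipped[0],
            )
        type_rows[cell_type] = np.array(present, dtype=int)

    assignment: dict[str, str] = {}
    for ci, cluster in enumerate(clusters):
        scores = {
            cell_type: (z[rows, ci].mean() if rows.size else np.nan)
            for cell_type, rows in type_rows.items()
        }
        finite = {t: s for t, s in scores.items() if np.isfinite(s)}
        if not finite:
            assignment[cluster] = "unassigned"
            continue
        best = max(finite.values())
        winners = [t for t, s in finite.items() if abs(s - best) <= 1e-12 * max(1.0, abs(best))]
        assignment[cluster] = winners[0] if len(winners) == 1 else "unassigned"
    return assignment
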