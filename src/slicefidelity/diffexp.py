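"""One-vs-rest differential expression with an exact negative-binomial test.

The test conditions on the total count of a gene across both groups.  When
every cell's count is NB with a common mean and dispersion ``phi`` (variance
``mu + phi * mu**2``), each group sum is NB with size ``n_g / phi``, and the
group-A sum given the total ``T`` follows a beta-binomial distribution
``BetaBinom(T, n_a / phi, n_b / phi)`` — a binomial with success probability
``n_a / (n_a + n_b)`` in the Poisson limit ``phi = 0``.  The two-sided
p-value sums the conditional probabilities of all outcomes no more likely
than the observed one (probability-mass method).  For large totals the same
conditional distribution is replaced by a normal approximation with
continuity correction.

Unequal sequencing depth is handled by pseudo-count equalization: counts are
divided by per-cell size factors, the normalized group sums are rounded back
to integers, and the effective group sizes are the group cell counts.

Dispersions are per-gene method-of-moments estimates from normalized counts
(pooled within the two groups), truncated at zero and shrunk toward their
common mean with a fixed weight.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CellAnnotation, CountMatrix, DETable, DispersionEstimate, normalize_timepoint

__all__ = [
    "compute_size_factors",
    "filter_low_expression",
    "estimate_dispersions",
    "nb_exact_test",
    "bh_adjust",
    "one_vs_rest_de",
    "normalized_group_means",
    "DEFAULT_SHRINKAGE_WEIGHT",
    "DEFAULT_EXACT_THRESHOLD",
    "DEFAULT_PSEUDOCOUNT",
]

logger = logging.getLogger(__name__)

DEFAULT_SHRINKAGE_WEIGHT = 0.7
DEFAULT_EXACT_THRESHOLD = 5000
DEFAULT_PSEUDOCOUNT = 1.0

_TIE_RTOL = 1e-12
_TINY = np.finfo(float).tiny


def _as_dense(counts) -> np.ndarray:
    if isinstance(counts, CountMatrix):
        return counts.dense()
    if hasattr(counts, "todense"):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


def compute_size_factors(counts) -> np.ndarray:
    """Per-cell depth factors: total count divided by the median positive total.

    Cells with zero total get ``NaN`` (they carry no information and are
    excluded from every downstream computation); a warning is logged.
    Raises ``ValueError`` when all cells are empty.
    """
    dense = _as_dense(counts)
    totals = dense.sum(axis=0)
    positive = totals[totals > 0]
    if positive.size == 0:
        raise ValueError("all cells have zero total count")
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d cells with zero total count excluded from analysis", n_zero)
    factors = totals / np.median(positive)
    factors[totals == 0] = np.nan
    return factors


def filter_low_expression(counts, threshold: float = 1.0) -> np.ndarray:
    """Boolean gene mask keeping genes whose mean raw count per cell >= ``threshold``.

    Genes below the threshold ("minimal expression") are removed from
    testing; the default of one count per cell on average mirrors common
    browser-export filtering.
    """
    dense = _as_dense(counts)
    if dense.size == 0:
        raise ValueError("empty count matrix")
    return dense.mean(axis=1) >= threshold


def estimate_dispersions(
    counts,
    group_a: np.ndarray,
    size_factors: np.ndarray,
    shrinkage_weight: float = DEFAULT_SHRINKAGE_WEIGHT,
) -> DispersionEstimate:
    """Method-of-moments NB dispersions with shrinkage toward the common mean.

    Parameters
    ----------
    counts
        Raw counts, genes x cells (pre-filtered to the tested genes).
    group_a
        Boolean mask over cells selecting the target group; the complement is
        the rest group.  Both groups need at least two cells.
    size_factors
        Per-cell factors from :func:`compute_size_factors`; NaN entries
        (zero-total cells) are dropped.
    shrinkage_weight
        Weight ``w`` of the common target: ``shrunken = (1 - w) * mom + w *
        target``.  ``w = 0`` keeps the raw per-gene values, ``w = 1``
        collapses all genes onto the target.
    """
    dense = _as_dense(counts)
    group_a = np.asarray(group_a, dtype=bool)
    size_factors = np.asarray(size_factors, dtype=float)
    valid = ~np.isnan(size_factors)
    dense, group_a, size_factors = dense[:, valid], group_a[valid], size_factors[valid]
    n_a, n_b = int(group_a.sum()), int((~group_a).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >= 2 cells (got {n_a} and {n_b})")

    norm = dense / size_factors
    mean = norm.mean(axis=1)
    # Pooled within-group variance (df = n - 2) so the group mean difference
    # does not inflate the dispersion estimate.
    ss = 0.0
    for mask in (group_a, ~group_a):
        sub = norm[:, mask]
        ss = ss + ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss / (n_a + n_b - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mom = np.where(mean > 0, (pooled_var - mean) / mean**2, 0.0)
    mom = np.maximum(mom, 0.0)
    target = float(mom.mean()) if mom.size else 0.0
    shrunken = (1.0 - shrinkage_weight) * mom + shrinkage_weight * target
    return DispersionEstimate(
        per_gene_mom=mom,
        shrinkage_target=target,
        shrunken=shrunken,
        shrinkage_weight=shrinkage_weight,
    )


def _conditional_logpmf(t: int, n_eff_a: float, n_eff_b: float, phi: float) -> np.ndarray:
    """Log pmf of the group-A sum given total ``t`` over support 0..t."""
    support = np.arange(t + 1)
    if phi == 0:
        return stats.binom.logpmf(support, t, n_eff_a / (n_eff_a + n_eff_b))
    return stats.betabinom.logpmf(support, t, n_eff_a / phi, n_eff_b / phi)


def nb_exact_test(
    sum_a: int,
    sum_b: int,
    n_eff_a: float,
    n_eff_b: float,
    phi: float,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> float:
    """Two-sided exact NB test p-value for two group sums sharing mean and dispersion.

    Conditional on ``T = sum_a + sum_b`` the group-A sum has the
    beta-binomial law described in the module docstring; the p-value is the
    total conditional probability of outcomes whose probability does not
    exceed the observed one (relative tie tolerance 1e-12).  For ``T >
    exact_threshold`` the same conditional distribution is approximated by a
    normal with matching mean and variance, continuity-corrected, two-sided
    via doubling the smaller tail.  The returned p lies in (0, 1].
    """
    if sum_a < 0 or sum_b < 0:
        raise ValueError("group sums must be non-negative")
    if n_eff_a <= 0 or n_eff_b <= 0:
        raise ValueError("effective group sizes must be positive")
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    sum_a, sum_b = int(sum_a), int(sum_b)
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    if t > exact_threshold:
        p = _normal_approx_p(
            np.array([sum_a]), np.array([t]), float(n_eff_a), float(n_eff_b), np.array([float(phi)])
        )[0]
        return float(p)
    logpmf = _conditional_logpmf(t, float(n_eff_a), float(n_eff_b), float(phi))
    pmf = np.exp(logpmf)
    p_obs = pmf[sum_a]
    included = pmf <= p_obs * (1.0 + _TIE_RTOL)
    if included.all():
        return 1.0  # observed outcome is modal; the sum over all outcomes is 1
    p = pmf[included].sum()
    return float(min(1.0, max(p, _TINY)))


def _normal_approx_p(
    sum_a: np.ndarray, t: np.ndarray, n_eff_a: float, n_eff_b: float, phi: np.ndarray
) -> np.ndarray:
    """Vectorized normal approximation of the conditional two-sided test."""
    t = t.astype(float)
    frac = n_eff_a / (n_eff_a + n_eff_b)
    mean = t * frac
    base_var = t * frac * (1.0 - frac)
    ab = np.where(phi > 0, (n_eff_a + n_eff_b) / np.where(phi > 0, phi, 1.0), np.inf)
    with np.errstate(over="ignore", invalid="ignore"):
        inflation = np.where(np.isfinite(ab), (ab + t) / (ab + 1.0), 1.0)
    sd = np.sqrt(base_var * inflation)
    sd = np.maximum(sd, _TINY)
    lower = stats.norm.cdf((sum_a + 0.5 - mean) / sd)
    upper = stats.norm.sf((sum_a - 0.5 - mean) / sd)
    p = 2.0 * np.minimum(lower, upper)
    return np.clip(p, _TINY, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    ``padj_(i) = min_{j >= i} (m / j) * p_(j)``, capped at 1.  Inputs outside
    [0, 1] raise ``ValueError``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    raw = (m / np.arange(1, m + 1)) * p[order]
    stepped = np.minimum.accumulate(raw[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(stepped, 1.0)
    return adjusted


def _group_stats(norm: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    sub = norm[:, mask]
    return sub.sum(axis=1), (sub**2).sum(axis=1), int(mask.sum())


def _batch_p_values(
    sums_a: np.ndarray,
    sums_b: np.ndarray,
    n_eff_a: float,
    n_eff_b: float,
    phi: np.ndarray,
    exact_threshold: int,
) -> np.ndarray:
    """Per-gene p-values; exact enumeration below the threshold, normal above."""
    t = sums_a + sums_b
    p = np.ones(sums_a.size)
    big = t > exact_threshold
    if big.any():
        p[big] = _normal_approx_p(sums_a[big], t[big], n_eff_a, n_eff_b, phi[big])
    for i in np.flatnonzero(~big):
        p[i] = nb_exact_test(
            int(sums_a[i]), int(sums_b[i]), n_eff_a, n_eff_b, float(phi[i]), exact_threshold
        )
    return p


def _timepoint_matrix(
    cm: CountMatrix, annotations: CellAnnotation, timepoint: str
) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Dense counts and labels for the cells annotated at one timepoint."""
    timepoint = normalize_timepoint(timepoint)
    ann_tp = annotations.for_timepoint(timepoint)
    if ann_tp.empty:
        raise ValueError(f"no cells annotated at {timepoint}")
    col_of = {bc: i for i, bc in enumerate(cm.cell_barcodes)}
    missing = [b for b in ann_tp["barcode"] if b not in col_of]
    if missing:
        raise ValueError(f"annotated barcode {missing[0]!r} absent from count matrix")
    cols = np.array([col_of[b] for b in ann_tp["barcode"]])
    dense = _as_dense(cm.counts[:, cols])
    return dense, cols, ann_tp["cell_type"].reset_index(drop=True)


def one_vs_rest_de(
    cm: CountMatrix,
    annotations: CellAnnotation,
    timepoint: str,
    *,
    shrinkage_weight: float = DEFAULT_SHRINKAGE_WEIGHT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
    filter_threshold: float = 1.0,
) -> list[DETable]:
    """Exact-NB one-vs-rest differential expression for every cell type at a timepoint.

    For each cell type the timepoint's cells are split into (type) vs (all
    other types), low-expression genes are removed, counts are depth
    normalized, dispersions estimated and shrunk, each gene tested, and BH
    correction applied across the comparison's genes.  All filtered genes are
    retained in the output table regardless of significance.  ``log2FC =
    log2((mean_in + eps) / (mean_out + eps))`` with ``eps`` the pseudo-count
    on the normalized-mean scale.
    """
    dense, _, labels = _timepoint_matrix(cm, annotations, timepoint)
    cell_types = sorted(labels.unique())
    if len(cell_types) < 2:
        raise ValueError("one-vs-rest undefined: a single cell type at this timepoint")

    size_factors = compute_size_factors(dense)
    valid = ~np.isnan(size_factors)
    dense = dense[:, valid]
    labels = labels[valid].reset_index(drop=True)
    size_factors = size_factors[valid]

    gene_mask = filter_low_expression(dense, threshold=filter_threshold)
    kept = np.flatnonzero(gene_mask)
    filtered = dense[kept]
    norm = filtered / size_factors
    gene_ids = [cm.gene_ids[i] for i in kept]
    gene_names = [cm.gene_names[i] for i in kept]

    tables = []
    for cell_type in cell_types:
        mask = (labels == cell_type).to_numpy()
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in < 2 or n_out < 2:
            raise ValueError(
                f"cell type {cell_type!r} needs >= 2 cells on each side of the comparison"
            )
        disp = estimate_dispersions(filtered, mask, size_factors, shrinkage_weight)
        sum_in, _, _ = _group_stats(norm, mask)
        sum_out, _, _ = _group_stats(norm, ~mask)
        mean_in = sum_in / n_in
        mean_out = sum_out / n_out
        p = _batch_p_values(
            np.rint(sum_in),
            np.rint(sum_out),
            float(n_in),
            float(n_out),
            disp.shrunken,
            exact_threshold,
        )
        padj = bh_adjust(p)
        log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
        tables.append(
            DETable(
                cell_type=cell_type,
                df=pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "gene_name": gene_names,
                        "mean_in": mean_in,
                        "mean_out": mean_out,
                        "log2_fold_change": log2fc,
                        "p_value": p,
                        "adjusted_p_value": padj,
                    }
                ),
            )
        )
    return tables


def normalized_group_means(
    cm: CountMatrix, annotations: CellAnnotation, timepoint: str
) -> dict[str, pd.DataFrame]:
    """Per-cell-type in/out normalized means over ALL genes (no expression filter).

    Used to back-fill log2 fold changes for union genes that were filtered
    out of a timepoint's DE tables.  Returns ``{cell_type: DataFrame}`` with
    the frame indexed by gene_id and columns ``mean_in`` / ``mean_out``.
    """
    dense, _, labels = _timepoint_matrix(cm, annotations, timepoint)
    size_factors = compute_size_factors(dense)
    valid = ~np.isnan(size_factors)
    dense = dense[:, valid]
    labels = labels[valid].reset_index(drop=True)
    norm = dense / size_factors[valid]
    out = {}
    for cell_type in sorted(labels.unique()):
        mask = (labels == cell_type).to_numpy()
        out[cell_type] = pd.DataFrame(
            {
                "mean_in": norm[:, mask].mean(axis=1),
                "mean_out": norm[:, ~mask].mean(axis=1),
            },
            index=pd.Index(cm.gene_ids, name="gene_id"),
        )
    return out
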