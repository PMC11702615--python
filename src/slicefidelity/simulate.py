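"""Synthetic paired day-0 / day-14 snRNA-seq experiment generator.

The generator emulates the design of a paired culture experiment: one tissue
sample profiled once shortly after resection (day 0) and once after fourteen
days in culture (day 14).  Each cell type carries a sparse log2 "effect
vector" of marker up-regulation on top of a shared per-gene baseline; day-14
effect vectors are an attenuated, Gaussian-perturbed copy of the day-0
vectors, so the loss of transcriptional identity in culture is a controllable
parameter with a known closed form (the correlation between a type's day-0
and day-14 effect vectors is ``lam * sd(e) / sqrt(lam^2 var(e) + tau^2)``).

Counts are negative binomial with variance ``mu + phi * mu**2`` (the
mean/dispersion convention used by exact NB tests), sampled as a
gamma-Poisson mixture, with per-cell lognormal library-size factors.

Randomness: every operation builds its own ``numpy`` Generator from the
configured seed plus a fixed operation tag, and per-cell-type sub-streams are
derived from the type's position in the sorted label order, so results do not
depend on dict iteration order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .exceptions import ConfigurationError
from .io import (
    CellAnnotation,
    CountMatrix,
    write_cell_annotations,
    write_count_matrix,
)
import pandas as pd

__all__ = [
    "CellTypeSpec",
    "SyntheticConfig",
    "ReferenceProfiles",
    "build_reference_profiles",
    "drift_profiles",
    "simulate_counts",
    "simulate_paired_experiment",
    "write_synthetic_dataset",
]

# Operation tags keeping RNG streams of the individual stages disjoint.
_STREAM_BASELINE = 0
_STREAM_MARKERS = 1
_STREAM_DRIFT = 2
_STREAM_COUNTS = 3
_STREAM_COMPOSITION = 4
_STREAM_MARKERS_DAY14 = 5


@dataclass
class CellTypeSpec:
    """A cell-type population: label and cell counts at the two timepoints."""

    name: str
    n_day0: int
    n_day14: int

    def __post_init__(self) -> None:
        if self.n_day0 < 0 or self.n_day14 < 0:
            raise ConfigurationError(f"negative cell count for {self.name!r}")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic paired experiment.

    Defaults describe one tissue with three annotated cell types of 2,000
    nuclei each per timepoint and 2,000 genes.  Marker genes (5% of genes per
    type, disjoint across types) are up-regulated by ``marker_log2_effect`` =
    4 log2 units in their own type.  Counts are NB with dispersion ``phi`` =
    0.5.  The day-14 identity drift ``drift_sd`` (tau) defaults to 0.5 log2
    units with no attenuation, which puts the expected day0/day14 signature
    correlation near 0.87 — the order of magnitude observed for
    well-preserved cell types in cultured brain tissue.
    """

    n_genes: int = 2000
    cell_types: list[CellTypeSpec] = field(
        default_factory=lambda: [
            CellTypeSpec("astrocyte", 2000, 2000),
            CellTypeSpec("microglia", 2000, 2000),
            CellTypeSpec("tumor", 2000, 2000),
        ]
    )
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    marker_fraction: float = 0.05
    marker_log2_effect: float = 4.0
    dispersion: float = 0.5
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.3
    drift_sd: float = 0.5
    attenuation: float = 1.0
    #: Draw per-type cell counts multinomially with the configured counts as
    #: expected values, instead of using them verbatim.
    multinomial_composition: bool = False
    #: Re-draw day-14 marker sets from scratch (complete identity scrambling).
    independent_day14_markers: bool = False
    sample_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = [
            ct if isinstance(ct, CellTypeSpec) else CellTypeSpec(**ct) for ct in self.cell_types
        ]
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not self.cell_types:
            raise ConfigurationError("at least one cell type is required")
        names = [ct.name for ct in self.cell_types]
        if len(set(names)) != len(names):
            raise ConfigurationError("cell type names must be unique")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.drift_sd < 0:
            raise ConfigurationError("drift_sd must be >= 0")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ConfigurationError("attenuation must lie in [0, 1]")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise ConfigurationError("marker_fraction must lie in [0, 1]")

    @property
    def type_names(self) -> list[str]:
        return [ct.name for ct in self.cell_types]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReferenceProfiles:
    """Baseline (natural-log scale) and per-type marker effect vectors (log2 scale)."""

    baseline: np.ndarray
    effects: dict[str, np.ndarray]
    marker_sets: dict[str, np.ndarray]


def _rng(seed: int, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream), *map(int, key)])


def build_reference_profiles(config: SyntheticConfig) -> ReferenceProfiles:
    """Draw the per-gene baseline and assign disjoint marker sets per cell type.

    Each type receives ``round(marker_fraction * n_genes)`` marker genes with
    effect ``marker_log2_effect``; all other entries are zero.  Marker sets
    are disjoint across types; a total demand exceeding the number of genes
    is a configuration error.
    """
    G = config.n_genes
    n_markers = int(round(config.marker_fraction * G))
    names = config.type_names
    if n_markers * len(names) > G:
        raise ConfigurationError(
            f"marker demand {n_markers} x {len(names)} types exceeds {G} genes"
        )
    baseline = _rng(config.seed, _STREAM_BASELINE).normal(
        config.baseline_log_mean, config.baseline_log_sd, size=G
    )
    perm = _rng(config.seed, _STREAM_MARKERS).permutation(G)
    effects: dict[str, np.ndarray] = {}
    marker_sets: dict[str, np.ndarray] = {}
    for k, name in enumerate(sorted(names)):
        markers = np.sort(perm[k * n_markers : (k + 1) * n_markers])
        e = np.zeros(G)
        e[markers] = config.marker_log2_effect
        effects[name] = e
        marker_sets[name] = markers
    return ReferenceProfiles(baseline=baseline, effects=effects, marker_sets=marker_sets)


def drift_profiles(
    effects: dict[str, np.ndarray],
    drift_sd: float,
    attenuation: float,
    seed: int,
) -> dict[str, np.ndarray]:
    """Perturb effect vectors into their day-14 counterparts.

    ``e14[g] = attenuation * e0[g] + N(0, drift_sd**2)`` independently per
    (type, gene).  ``drift_sd = 0, attenuation = 1`` is the identity.
    """
    if drift_sd < 0:
        raise ConfigurationError("drift_sd must be >= 0")
    if not 0.0 <= attenuation <= 1.0:
        raise ConfigurationError("attenuation must lie in [0, 1]")
    drifted = {}
    for k, name in enumerate(sorted(effects)):
        e = np.asarray(effects[name], dtype=float)
        noise = _rng(seed, _STREAM_DRIFT, k).normal(0.0, drift_sd, size=e.shape) if drift_sd else 0.0
        drifted[name] = attenuation * e + noise
    return drifted


def expected_effect_correlation(effect: np.ndarray, drift_sd: float, attenuation: float) -> float:
    """Closed-form Pearson correlation between an effect vector and its drifted copy.

    Treating genes as i.i.d. draws: ``corr = lam * sd(e) / sqrt(lam^2 var(e)
    + tau^2)``.  Used as an oracle for the drift operation.
    """
    var = float(np.var(effect))
    denom = np.sqrt(attenuation**2 * var + drift_sd**2)
    if denom == 0:
        return 1.0
    return attenuation * np.sqrt(var) / denom


def simulate_counts(
    baseline: np.ndarray,
    effects: dict[str, np.ndarray],
    cell_counts: dict[str, int],
    libsize_log_mean: float,
    libsize_log_sd: float,
    dispersion: float,
    seed: int,
    *,
    sample_id: str = "S1",
    timepoint: str = "day0",
    gene_ids: list[str] | None = None,
) -> tuple[CountMatrix, CellAnnotation]:
    """Sample a count matrix for one timepoint.

    Cell ``c`` of type ``k`` has library factor ``s_c ~ LogNormal`` and
    ``count(g, c) ~ NB(mu = s_c * exp(b[g]) * 2**e_k[g], var = mu + phi *
    mu**2)`` (Poisson when ``phi = 0``).  Types with zero requested cells are
    simply absent from the output.
    """
    baseline = np.asarray(baseline, dtype=float)
    G = baseline.size
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    base_rate = np.exp(baseline)
    names = sorted(n for n in cell_counts if cell_counts[n] > 0)
    if names and all(
        not np.any(base_rate * np.exp2(np.asarray(effects[n], dtype=float))) for n in names
    ):
        raise ConfigurationError("expected expression is zero for every gene")
    if gene_ids is None:
        gene_ids = [f"gene{g:05d}" for g in range(G)]

    blocks: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    labels: list[str] = []
    offset = 0
    for k, name in enumerate(sorted(effects)):
        n_c = int(cell_counts.get(name, 0))
        if n_c == 0:
            continue
        rng = _rng(seed, _STREAM_COUNTS, k)
        s = rng.lognormal(libsize_log_mean, libsize_log_sd, size=n_c)
        mu = (base_rate * np.exp2(np.asarray(effects[name], dtype=float)))[:, None] * s[None, :]
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(mu)
        blocks.append(sp.csr_matrix(counts))
        barcodes.extend(f"{timepoint}_c{offset + i:06d}" for i in range(n_c))
        labels.extend([name] * n_c)
        offset += n_c
    if not blocks:
        raise ConfigurationError("no cells requested")
    cm = CountMatrix(
        counts=sp.hstack(blocks, format="csr"),
        gene_ids=gene_ids,
        gene_names=gene_ids,
        cell_barcodes=barcodes,
    )
    ann = CellAnnotation(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "sample_id": sample_id,
                "timepoint": timepoint,
                "cell_type": labels,
            }
        )
    )
    return cm, ann


def _realized_counts(config: SyntheticConfig, timepoint: str) -> dict[str, int]:
    requested = {
        ct.name: (ct.n_day0 if timepoint == "day0" else ct.n_day14) for ct in config.cell_types
    }
    if not config.multinomial_composition:
        return requested
    total = sum(requested.values())
    if total == 0:
        return requested
    names = sorted(requested)
    probs = np.array([requested[n] for n in names], dtype=float) / total
    rng = _rng(config.seed, _STREAM_COMPOSITION, 0 if timepoint == "day0" else 1)
    draws = rng.multinomial(total, probs)
    return dict(zip(names, (int(d) for d in draws)))


def simulate_paired_experiment(config: SyntheticConfig) -> dict:
    """Simulate both timepoints of a paired experiment.

    Returns a dict with keys ``day0`` and ``day14`` (each a ``(CountMatrix,
    CellAnnotation)`` pair sharing one gene list) and ``truth`` holding the
    baseline and the effect vectors actually used at each timepoint, for
    parameter-recovery tests.
    """
    profiles = build_reference_profiles(config)
    if config.independent_day14_markers:
        # Fresh marker assignment: same marginal structure, unrelated identity.
        perm = _rng(config.seed, _STREAM_MARKERS_DAY14).permutation(config.n_genes)
        n_markers = int(round(config.marker_fraction * config.n_genes))
        effects14 = {}
        for k, name in enumerate(sorted(config.type_names)):
            e = np.zeros(config.n_genes)
            e[perm[k * n_markers : (k + 1) * n_markers]] = config.marker_log2_effect
            effects14[name] = e
    else:
        effects14 = drift_profiles(
            profiles.effects, config.drift_sd, config.attenuation, config.seed
        )

    gene_ids = [f"gene{g:05d}" for g in range(config.n_genes)]
    result = {}
    for timepoint, effects in (("day0", profiles.effects), ("day14", effects14)):
        counts = _realized_counts(config, timepoint)
        result[timepoint] = simulate_counts(
            profiles.baseline,
            effects,
            counts,
            config.libsize_log_mean,
            config.libsize_log_sd,
            config.dispersion,
            # separate count streams per timepoint
            config.seed * 2 + (0 if timepoint == "day0" else 1),
            sample_id=config.sample_id,
            timepoint=timepoint,
            gene_ids=gene_ids,
        )
    result["truth"] = {
        "baseline": profiles.baseline,
        "effects_day0": profiles.effects,
        "effects_day14": effects14,
        "marker_sets": profiles.marker_sets,
    }
    return result


def write_synthetic_dataset(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Simulate and write MTX triplets, a combined annotation TSV and a truth JSON.

    Layout: ``day0/`` and ``day14/`` matrix triplets, ``annotations.tsv``
    covering both timepoints, ``truth.json`` with the effect vectors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_paired_experiment(config)
    paths = {}
    ann_frames = []
    for timepoint in ("day0", "day14"):
        cm, ann = sim[timepoint]
        paths[timepoint] = {
            k: str(v) for k, v in write_count_matrix(cm, out_dir / timepoint).items()
        }
        ann_frames.append(ann.df)
    combined = CellAnnotation(pd.concat(ann_frames, ignore_index=True))
    ann_path = out_dir / "annotations.tsv"
    write_cell_annotations(combined, ann_path)
    truth = sim["truth"]
    truth_json = {
        "baseline": truth["baseline"].tolist(),
        "effects_day0": {k: v.tolist() for k, v in truth["effects_day0"].items()},
        "effects_day14": {k: v.tolist() for k, v in truth["effects_day14"].items()},
    }
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth_json))
    paths["annotations"] = str(ann_path)
    paths["truth"] = str(truth_path)
    return paths
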