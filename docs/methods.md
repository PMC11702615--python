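# Methods

## The question and the statistic

`slicefidelity` quantifies how well the cell types of a tissue sample keep
their transcriptional identities between two timepoints of a paired
experiment — typically a sample profiled by single-nucleus RNA-seq shortly
after resection ("day 0") and again after two weeks in organotypic culture
("day 14").  A cell type's *identity* at a timepoint is defined relative to
the other cell types of the same timepoint: its one-vs-rest log2 fold-change
vector over a shared gene list.  Fidelity is the Pearson correlation between
a type's day-14 signature and the day-0 signatures; the diagonal of the
resulting day-0 × day-14 matrix (each type against its own counterpart) is
the headline statistic, and off-diagonal entries measure confusion between
types.

The pipeline per sample:

1. **One-vs-rest differential expression** within each timepoint, for every
   annotated cell type against all other cells of that timepoint.
2. **Significant-gene union**: all genes with BH-adjusted p < α (default
   0.05) in at least one cell type at either timepoint, one shared ordered
   list per sample.
3. **Signature matrices**: |union| × K log2FC matrices per timepoint.
4. **Correlation matrix** of day-0 columns against day-14 columns.
5. **Diagonal fidelity** for label-matched types, **composition tables**
   per (sample, timepoint), and **cross-sample aggregation** (mean, SEM).

## The exact negative-binomial test

Counts in the two groups are modeled as NB with a common per-cell mean and a
common dispersion φ (variance μ + φμ²).  The sum over a group of *n* cells
is then NB with size n/φ, and conditioning on the total count T makes the
group-A sum Beta-Binomial(T, n_a/φ, n_b/φ) — exactly Binomial(T,
n_a/(n_a+n_b)) in the Poisson limit φ = 0.  The conditional law does not
depend on the unknown mean, which is what makes the test exact.

The two-sided p-value uses the probability-mass method: the total
conditional probability of all outcomes whose probability does not exceed
the observed one, with a relative tie tolerance of 1e-12.  When the observed
outcome is modal and every outcome is included, p is returned as exactly 1.
For totals above `exact_threshold` (default 5,000) enumeration is replaced
by a normal approximation with the beta-binomial's mean and variance,
continuity-corrected, two-sided by doubling the smaller tail.  p-values are
clamped away from 0 (smallest positive double).

**Depth normalization (pseudo-count equalization).** Cells differ in
sequencing depth, so counts are divided by per-cell size factors (total
count over the median positive total; zero-total cells are excluded with a
warning).  The per-group sums of normalized counts are rounded to integers
and used as the test's group sums, with the group cell counts as effective
sizes.  This preserves the exact-test structure while accounting for depth.

**Dispersion.** Per gene, a method-of-moments estimate from normalized
counts with the variance pooled within the two groups (df = n − 2, so the
group mean difference does not inflate it), truncated at 0, then shrunk
toward the across-gene mean with a fixed weight w (default 0.7):
`shrunken = (1 − w)·mom + w·target`.  A fixed weight keeps the test
deterministic and transparent; w is a configuration knob, and the full
SSE-minimizing weight of shrinkage-based exact tests is deliberately not
estimated.

**Filtering and BH.** Genes with mean raw count per cell below 1 across the
timepoint's cells are removed before testing (the threshold is inclusive:
mean exactly 1 is kept).  BH correction is applied per one-vs-rest
comparison across its tested genes, not pooled across cell types; pooling is
a plausible alternative reading of browser exports and could be added as an
option, but per-comparison matches the per-cluster CSV workflow the pipeline
mirrors.  `bh_adjust` implements the step-up formula
`padj_(i) = min_{j≥i} (m/j)·p_(j)` directly, with exactly that arithmetic.

**log2 fold change.** `log2((mean_in + 1)/(mean_out + 1))` on
size-factor-normalized means; the pseudo-count of 1 prevents infinities and
follows the common single-cell browser convention.

## Signatures and correlation

All tested genes are retained in the DE tables so that signature columns can
be assembled for any union gene.  A union gene that was filtered out at one
timepoint (but significant via the other) gets its log2FC recomputed from
that timepoint's normalized group means with the same pseudo-count — never
imputed as 0, which would bias correlations toward zero.

Correlation is Pearson on the log2FC columns by default (Spearman is a
config option).  Two numerical choices: correlations are clipped to
[−1, 1], and two bitwise-identical centered columns correlate at exactly
1.0 by definition rather than through the normalization arithmetic, so a
day-14 dataset that is a verbatim copy of day 0 yields a diagonal of exact
ones.  A zero-variance signature column makes Pearson undefined and raises
an error naming the degenerate cell type.  Cell types present at only one
timepoint are reported as absent, not as NaN correlations.

Aggregation across samples uses the arithmetic mean and SEM = sd/√n with the
n−1 sample standard deviation; SEM is undefined (not 0) when a single sample
contributes.

## Marker-based cluster scoring

As a deterministic surrogate for manual marker-based annotation,
`score_clusters_by_markers` scores each cluster × candidate-type pair by the
mean, over the type's marker genes, of the cluster's mean normalized
expression z-scored per gene across clusters, and assigns the argmax.
Exact ties and clusters with no usable markers are "unassigned"; markers
missing from the matrix are skipped with a warning, an empty marker list is
a configuration error.

## The synthetic generator

The generator emulates the paired study design with known ground truth; its
defaults are the reference study conditions used throughout the tests: one
sample, three cell types with 2,000 cells per type per timepoint, 2,000
genes.  Per-gene baseline expression is log-normal (log-mean 0, log-sd 1,
i.e. a median of one count per cell — genes span roughly 0.1–10 counts per
cell, the range that survives the mean ≥ 1 filter in appreciable numbers).
Each type has 5% of genes as markers, disjoint across types, up-regulated by
f = 4 log2 units — strong, cleanly separable identities, as for well-defined
brain cell types.  Counts are NB with φ = 0.5 (typical droplet-data
overdispersion), sampled as a gamma–Poisson mixture, with lognormal
library-size factors (log-sd 0.3).

Day-14 effect vectors are `λ·e + N(0, τ²)` per gene.  τ (default 0.5 log2
units, λ = 1) controls identity loss; the expected correlation between an
effect vector and its drifted copy has the closed form
`λ·sd(e)/√(λ²·var(e) + τ²)` ≈ 0.87 at the defaults, the order of magnitude
reported for well-preserved cell types in cultured brain tissue.  The
estimated pipeline diagonal is somewhat higher (≈ 0.94) because the
signatures also share the stable negative one-vs-rest structure of the
non-marker genes.  Setting `independent_day14_markers` re-draws the marker
assignment at day 14, destroying identity (diagonal ≈ 0); setting
`multinomial_composition` draws per-type cell counts multinomially with the
configured counts as expectations, making composition recovery a stochastic
quantity with binomial error.

Every operation seeds its own generator from the configured seed plus a
fixed operation tag, with per-cell-type sub-streams keyed by the type's
position in sorted label order; outputs are bitwise reproducible and
independent of iteration order.

**What the generator does not emulate:** doublets, ambient RNA,
batch/chemistry effects between samples, UMI saturation, gene–gene
correlation beyond the type structure, zero inflation beyond NB sampling,
and real marker architectures (graded, overlapping, partially redundant).
Passing tests therefore demonstrate correctness of the statistical machinery
and recoverability of a known drift signal — not that any particular real
tissue preserves identity.

## Problem sizes and runtime choices

The reference conditions (3 × 2,000 cells, 2,000 genes) are desk-scale by
design: one full pipeline run takes seconds, the five-point drift sweep with
five seeds per point a few minutes.  With thousands of cells per group, gene
totals exceed the exact-enumeration threshold and the normal approximation
path is used; the exact path dominates only for small groups or rare genes.
Unit tests use further reduced sizes (hundreds of cells) where the property
under test does not depend on scale.

## Known limitations

- The exact behavior of proprietary browser DE exports is undocumented;
  pseudo-count equalization and the fixed shrinkage weight are this
  package's own documented choices within the exact-test family.
- BH per comparison (not pooled across the cell-type grid) is one of two
  defensible readings of the per-cluster CSV workflow.
- The union spans both timepoints' significant genes by default; a
  day-0-only union is available via `significant_gene_union(tables0, [], α)`.
- The `fidelity` CLI subcommand rebuilds signatures from DE CSVs alone and
  therefore requires the two timepoints' tables to share a gene universe;
  the library path (and `run`) back-fills filtered union genes from the
  count matrices instead.
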