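# slicefidelity

Quantify how well cell types in cultured *ex vivo* tissue preserve their
transcriptional identities, from paired single-nucleus RNA-seq count
matrices.

Organotypic slice culture keeps living human brain tissue *ex vivo* for
weeks, but its value as a model depends on whether the constituent cell
types — neurons, glia, vascular cells, tumor cells — still look like
themselves transcriptionally after time in culture.  `slicefidelity`
implements the analysis that answers this for a paired design (the same
sample profiled at "day 0" and after culture at "day 14"):

1. **One-vs-rest differential expression** per cell type within each
   timepoint, using an exact negative-binomial test: conditional on the
   total count *T*, the target-group sum follows
   BetaBinom(*T*, *n₁*/φ, *n₂*/φ), with a method-of-moments dispersion φ
   shrunk toward the across-gene mean.  Genes with mean raw count < 1 per
   cell are filtered; p-values are Benjamini–Hochberg adjusted.
2. **Signature vectors**: for each cell type, the log₂ fold-change vector
   log₂((μ_in + 1)/(μ_out + 1)) over the union of genes significant
   (adjusted p < 0.05) in *any* cell type at *either* timepoint.
3. **Fidelity**: the Pearson correlation matrix of day-0 signatures ×
   day-14 signatures.  The diagonal — each type against its own
   counterpart — measures identity preservation; composition tables and a
   cross-sample aggregate (mean ± SEM) complete the picture.

A synthetic paired-experiment generator (NB counts, disjoint marker sets
per type, controllable day-14 identity drift `e₁₄ = λ·e₀ + N(0, τ²)` with a
closed-form expected correlation) provides ground truth for every stage.

## Worked example

```python
import slicefidelity as sf

# one synthetic tissue: 3 cell types x 2,000 cells per timepoint, 2,000 genes,
# identity drift tau = 0.5 log2 units
cfg = sf.SyntheticConfig(seed=3)
sim = sf.simulate_paired_experiment(cfg)

tables = {tp: sf.one_vs_rest_de(*sim[tp], tp) for tp in ("day0", "day14")}
union = sf.significant_gene_union(tables["day0"], tables["day14"])
sigs = {
    tp: sf.build_signature_matrix(
        tables[tp], union, tp, sf.normalized_group_means(*sim[tp], tp)
    )
    for tp in ("day0", "day14")
}
corr = sf.correlate_signatures(sigs["day0"], sigs["day14"])
print(len(union))
print(corr.to_frame().round(3))
```

prints

```
1255
           astrocyte  microglia  tumor
astrocyte      0.948     -0.429 -0.476
microglia     -0.422      0.945 -0.407
tumor         -0.468     -0.397  0.942
```

1,255 genes were significantly differentially expressed in at least one
cell type at one of the timepoints.  Each day-14 cell type correlates
strongly (r ≈ 0.94) with its own day-0 signature and negatively with the
others: identities drifted (τ = 0.5) but remain clearly preserved and
mutually distinguishable.  With τ = 0 the diagonal approaches 1; with
independently regenerated day-14 markers it collapses to ≈ 0.

The same analysis runs from the command line on 10X-style MTX exports or
synthetic data, driven by a YAML config:

```sh
slicefidelity simulate --outdir data/ --seed 3
slicefidelity run --config config.yaml --outdir results/ --seed 3
```

`run` writes per-sample DE CSVs, signature matrices, the correlation
matrix, diagonal fidelities, composition tables, a cross-sample aggregate
and a reproducibility manifest.

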