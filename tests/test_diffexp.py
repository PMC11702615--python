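"""Statistical core: size factors, filtering, dispersion, the exact NB test, BH."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import slicefidelity as sf
from slicefidelity.diffexp import estimate_dispersions

from conftest import make_annotation, make_count_matrix


def nb_conditional_pvalue_brute_force(sum_a, sum_b, n_a, n_b, phi, mu=1.7):
    """Independent oracle: normalize products of NB (or Poisson) pmfs over the support.

    The conditional law must not depend on the common per-cell mean ``mu``.
    """
    t = sum_a + sum_b
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi == 0:
        la = stats.poisson.logpmf(a, n_a * mu)
        lb = stats.poisson.logpmf(t - a, n_b * mu)
    else:
        ra, rb = n_a / phi, n_b / phi
        la = stats.nbinom.logpmf(a, ra, ra / (ra + n_a * mu))
        lb = stats.nbinom.logpmf(t - a, rb, rb / (rb + n_b * mu))
    logp = la + lb
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    p_obs = pmf[sum_a]
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())


def bh_step_up_reference(p):
    """Naive O(n^2) step-up: padj_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adjusted_sorted = np.empty(m)
    for i in range(m):
        adjusted_sorted[i] = min(
            min((m / (j + 1)) * sorted_p[j] for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


class TestSizeFactors:
    def test_equal_totals_give_unit_factors(self):
        cm = make_count_matrix([[2, 2, 2], [3, 3, 3]])
        assert sf.compute_size_factors(cm).tolist() == [1, 1, 1]

    def test_median_scaling(self):
        cm = make_count_matrix([[100, 200, 100]])
        assert sf.compute_size_factors(cm).tolist() == [1, 2, 1]

    def test_zero_total_cell_flagged_nan(self, caplog):
        cm = make_count_matrix([[4, 0, 4]])
        factors = sf.compute_size_factors(cm)
        assert np.isnan(factors[1]) and factors[0] == 1.0

    def test_all_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            sf.compute_size_factors(make_count_matrix([[0, 0], [0, 0]]))


class TestLowExpressionFilter:
    @pytest.mark.parametrize(
        "row, kept",
        [((0, 0, 0, 0), False), ((1, 1, 1, 2), True), ((1, 1, 1, 0), False), ((1, 1, 1, 1), True)],
    )
    def test_mean_threshold_inclusive(self, row, kept):
        cm = make_count_matrix([row, (5, 5, 5, 5)])
        assert sf.filter_low_expression(cm).tolist() == [kept, True]


class TestDispersionEstimation:
    def test_constant_counts_truncate_to_zero(self):
        cm = make_count_matrix(np.full((3, 8), 4))
        est = estimate_dispersions(cm.dense(), np.arange(8) < 4, np.ones(8))
        assert est.per_gene_mom.tolist() == [0, 0, 0]

    def test_weight_extremes(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(20, 40))
        groups = np.arange(40) < 20
        mom = estimate_dispersions(counts, groups, np.ones(40), shrinkage_weight=0.0)
        full = estimate_dispersions(counts, groups, np.ones(40), shrinkage_weight=1.0)
        assert np.array_equal(mom.shrunken, mom.per_gene_mom)
        assert np.allclose(full.shrunken, full.shrinkage_target)

    def test_poisson_counts_give_small_dispersion(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(300, 2000))
        est = estimate_dispersions(counts, np.arange(2000) < 1000, np.ones(2000))
        assert est.shrunken.mean() < 0.05

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            estimate_dispersions(np.ones((2, 4)), np.array([True, False, False, False]), np.ones(4))


class TestNBExactTest:
    def test_symmetric_balanced_case_is_one(self):
        assert sf.nb_exact_test(7, 7, 10, 10, 0.3) == 1.0

    def test_matches_binomial_half_at_zero_dispersion(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = int(rng.integers(1, 51))
            a = int(rng.integers(0, t + 1))
            ours = sf.nb_exact_test(a, t - a, 12, 12, 0.0)
            ref = stats.binomtest(a, t, 0.5).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 1.0])
    def test_matches_brute_force_enumeration(self, phi):
        rng = np.random.default_rng(3)
        for _ in range(60):
            t = int(rng.integers(0, 51))
            a = int(rng.integers(0, t + 1))
            n_a, n_b = (int(v) for v in rng.integers(2, 40, 2))
            ours = sf.nb_exact_test(a, t - a, n_a, n_b, phi)
            ref = nb_conditional_pvalue_brute_force(a, t - a, n_a, n_b, phi)
            assert ours == pytest.approx(ref, abs=1e-8)

    @given(
        a=st.integers(0, 40),
        b=st.integers(0, 40),
        n_a=st.integers(2, 30),
        n_b=st.integers(2, 30),
        phi=st.sampled_from([0.0, 0.25, 1.0]),
    )
    def test_swapping_groups_leaves_p_unchanged(self, a, b, n_a, n_b, phi):
        assert sf.nb_exact_test(a, b, n_a, n_b, phi) == pytest.approx(
            sf.nb_exact_test(b, a, n_b, n_a, phi), rel=1e-12
        )

    def test_monotone_in_imbalance(self):
        t = 30
        p = [sf.nb_exact_test(a, t - a, 8, 8, 0.2) for a in range(t // 2, t + 1)]
        assert all(x >= y - 1e-12 for x, y in zip(p, p[1:]))
        assert all(v > 0 for v in p)

    def test_large_total_switches_to_normal_approximation(self):
        exact = sf.nb_exact_test(3000, 3200, 100, 100, 0.1, exact_threshold=10_000)
        approx = sf.nb_exact_test(3000, 3200, 100, 100, 0.1, exact_threshold=5000)
        assert approx == pytest.approx(exact, rel=0.05)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            sf.nb_exact_test(-1, 2, 3, 3, 0.1)


class TestBHAdjust:
    def test_worked_example(self):
        assert sf.bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert sf.bh_adjust([1.0, 1.0, 1.0]).tolist() == [1, 1, 1]

    def test_single_value_identity(self):
        assert sf.bh_adjust([0.04]).tolist() == [0.04]

    def test_matches_reference_formula_exactly(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            p = rng.uniform(size=int(rng.integers(1, 120)))
            assert np.array_equal(sf.bh_adjust(p), bh_step_up_reference(p))

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        assert np.allclose(sf.bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_order_equivariant_and_bounded(self, p):
        p = np.asarray(p)
        adj = sf.bh_adjust(p)
        assert ((adj >= p - 1e-15) & (adj <= 1.0)).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.array_equal(sf.bh_adjust(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sf.bh_adjust([0.5, 1.5])


@pytest.fixture(scope="module")
def marker_sim():
    cfg = sf.SyntheticConfig(
        seed=9,
        n_genes=400,
        cell_types=[sf.CellTypeSpec("a", 400, 400), sf.CellTypeSpec("b", 400, 400)],
    )
    return cfg, sf.simulate_paired_experiment(cfg)


class TestOneVsRest:

    def test_identical_input_identical_tables(self, marker_sim):
        _, sim = marker_sim
        cm, ann = sim["day0"]
        df14 = ann.df.copy()
        df14["timepoint"] = "day14"
        t0 = sf.one_vs_rest_de(cm, ann, "day0")
        t14 = sf.one_vs_rest_de(cm, sf.CellAnnotation(df14), "day14")
        for a, b in zip(t0, t14):
            assert a.df.equals(b.df)

    def test_markers_detected_with_positive_log2fc(self, marker_sim):
        cfg, sim = marker_sim
        cm, ann = sim["day0"]
        tables = {t.cell_type: t for t in sf.one_vs_rest_de(cm, ann, "day0")}
        truth = sim["truth"]
        for name, table in tables.items():
            markers = {f"gene{g:05d}" for g in np.flatnonzero(truth["effects_day0"][name])}
            hits = table.df[table.df["gene_id"].isin(markers)]
            assert len(hits) > 0
            assert (hits["adjusted_p_value"] < 0.05).mean() > 0.9
            assert (hits["log2_fold_change"] > 0).all()

    def test_invariant_to_cell_and_gene_order(self, marker_sim):
        _, sim = marker_sim
        cm, ann = sim["day0"]
        rng = np.random.default_rng(0)
        cell_perm = rng.permutation(cm.n_cells)
        gene_perm = rng.permutation(cm.n_genes)
        shuffled = sf.CountMatrix(
            cm.counts[gene_perm][:, cell_perm],
            [cm.gene_ids[i] for i in gene_perm],
            [cm.gene_names[i] for i in gene_perm],
            [cm.cell_barcodes[i] for i in cell_perm],
        )
        ref = sf.one_vs_rest_de(cm, ann, "day0")
        out = sf.one_vs_rest_de(shuffled, ann, "day0")
        for a, b in zip(ref, out):
            merged = a.df.set_index("gene_id").join(
                b.df.set_index("gene_id"), lsuffix="_ref", rsuffix="_shuf"
            )
            assert np.allclose(merged["p_value_ref"], merged["p_value_shuf"], rtol=1e-9)
            assert np.allclose(
                merged["log2_fold_change_ref"], merged["log2_fold_change_shuf"], rtol=1e-9
            )

    def test_single_cell_type_rejected(self):
        cm = make_count_matrix(np.ones((5, 6), dtype=int) * 2)
        ann = make_annotation([f"bc{i}" for i in range(6)], ["only"] * 6)
        with pytest.raises(ValueError, match="one-vs-rest undefined"):
            sf.one_vs_rest_de(cm, ann, "day0")

    def test_null_type_I_rate_controlled(self):
        """Two groups from one NB law: raw p < 0.05 in at most 7% of genes."""
        cfg = sf.SyntheticConfig(
            seed=13,
            n_genes=800,
            marker_log2_effect=0.0,
            cell_types=[sf.CellTypeSpec("g1", 300, 300), sf.CellTypeSpec("g2", 300, 300)],
        )
        prof = sf.build_reference_profiles(cfg)
        cm, ann = sf.simulate_counts(
            prof.baseline, prof.effects, {"g1": 300, "g2": 300},
            cfg.libsize_log_mean, cfg.libsize_log_sd, cfg.dispersion, seed=13,
        )
        table = sf.one_vs_rest_de(cm, ann, "day0")[0]
        assert (table.df["p_value"] < 0.05).mean() <= 0.07
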