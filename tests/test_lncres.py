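import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netlnc.errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from netlnc.io_formats import GeneSetCollection, PurityVector
from netlnc.lncres import (
    LncRESRecord,
    RankedGeneList,
    call_significant,
    compute_lncres,
    gsea_es,
    gsea_permutation_p,
    lncres_score,
    partial_correlation,
    rank_genes,
    rank_score,
)

from conftest import make_expression
import pandas as pd


def residual_partial_corr_oracle(l, g, purity):
    """Correlation of OLS residuals after regressing purity out of both."""

    def residual(y, x):
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    rl = residual(l, purity)
    rg = residual(g, purity)
    return float(np.corrcoef(rl, rg)[0, 1])


def es_brute_force(genes, rs, members, exponent=1.0):
    """Literal running-sum enumeration over the full ranked list."""
    members = set(members)
    n = len(genes)
    hit_w = sum(abs(r) ** exponent for gene, r in zip(genes, rs) if gene in members)
    n_hit = sum(1 for gene in genes if gene in members)
    running = 0.0
    best = 0.0
    for gene, r in zip(genes, rs):
        if gene in members:
            running += (abs(r) ** exponent / hit_w) if hit_w > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


class TestPartialCorrelation:
    def test_orthogonal_purity_collapses_to_pearson(self, rng):
        l = rng.normal(size=40)
        g = 0.5 * l + rng.normal(size=40)
        raw = rng.normal(size=40)
        # Gram-Schmidt purity against both vectors so R_LP = R_GP = 0 exactly
        basis = np.column_stack(
            [np.ones(40), l - l.mean(), (g - g.mean())]
        )
        q, _ = np.linalg.qr(basis)
        purity = raw - q @ (q.T @ raw)
        pc = partial_correlation(l, g, purity)
        assert pc.pcc == pytest.approx(float(np.corrcoef(l, g)[0, 1]), abs=1e-10)

    def test_identical_vectors_give_unity(self, rng):
        l = rng.normal(size=25)
        purity = rng.uniform(0, 1, size=25)
        pc = partial_correlation(l, l.copy(), purity)
        assert pc.pcc == pytest.approx(1.0)

    def test_matches_residual_regression_oracle(self, rng):
        for _ in range(25):
            l = rng.normal(size=30)
            purity = rng.uniform(0, 1, size=30)
            g = 0.3 * l + 0.5 * purity + rng.normal(size=30)
            pc = partial_correlation(l, g, purity)
            assert pc.pcc == pytest.approx(residual_partial_corr_oracle(l, g, purity), abs=1e-10)

    def test_pairwise_complete_triples(self, rng):
        l = rng.normal(size=20)
        g = rng.normal(size=20)
        purity = rng.uniform(0, 1, size=20)
        l2, g2 = l.copy(), g.copy()
        l2[3] = np.nan
        g2[7] = np.nan
        pc = partial_correlation(l2, g2, purity)
        assert pc.n_obs == 18
        keep = [i for i in range(20) if i not in (3, 7)]
        ref = partial_correlation(l[keep], g[keep], purity[keep])
        assert pc.pcc == pytest.approx(ref.pcc)

    def test_too_few_triples_raises(self):
        with pytest.raises(InsufficientDataError):
            partial_correlation(np.arange(3.0), np.arange(3.0), np.ones(3) * 0.5)

    def test_collinear_purity_raises(self, rng):
        l = rng.normal(size=15)
        g = rng.normal(size=15)
        with pytest.raises(DegenerateDataError):
            partial_correlation(l, g, 0.1 + 0.01 * (l - l.min()) / np.ptp(l))


class TestRankScore:
    def test_p_001_positive(self):
        assert rank_score(0.01, 0.5) == pytest.approx(2.0)

    def test_p_one_is_zero(self):
        assert rank_score(1.0, 0.9) == 0.0
        assert rank_score(1.0, -0.9) == 0.0

    def test_negative_sign_flip(self):
        assert rank_score(0.001, -0.2) == pytest.approx(-3.0)

    def test_zero_pcc(self):
        assert rank_score(0.5, 0.0) == 0.0

    def test_underflow_floored(self):
        assert rank_score(0.0, 1.0) == pytest.approx(300.0)


def fixed_ranked(n=10):
    genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
    rs = np.linspace(5.0, -5.0, n)
    return RankedGeneList("LX", genes, rs)


class TestGseaES:
    def test_top_gene_exponent_zero(self):
        ranked = fixed_ranked(10)
        assert gsea_es(ranked, {"g00"}, exponent=0.0) == pytest.approx(1.0)

    def test_bottom_gene_exponent_zero_matches_enumeration(self):
        ranked = fixed_ranked(10)
        expected = es_brute_force(ranked.genes, ranked.rs, {"g09"}, exponent=0.0)
        assert gsea_es(ranked, {"g09"}, exponent=0.0) == pytest.approx(expected)
        assert expected == pytest.approx(-1.0)  # the running sum bottoms out at -1

    def test_three_gene_set_matches_brute_force(self):
        ranked = fixed_ranked(10)
        members = {"g01", "g04", "g07"}
        assert gsea_es(ranked, members) == pytest.approx(
            es_brute_force(ranked.genes, ranked.rs, members), abs=1e-12
        )

    def test_random_instances_match_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            genes = np.array([f"g{i}" for i in range(n)], dtype=object)
            rs = np.sort(rng.normal(0, 3, n))[::-1]
            ranked = RankedGeneList("L", genes, rs)
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            assert gsea_es(ranked, members) == pytest.approx(
                es_brute_force(genes, rs, members), abs=1e-12
            )

    def test_es_bounded(self, rng):
        ranked = fixed_ranked(20)
        for _ in range(20):
            k = int(rng.integers(1, 19))
            members = set(rng.choice(ranked.genes, size=k, replace=False))
            assert abs(gsea_es(ranked, members)) <= 1.0 + 1e-12

    def test_no_overlap_raises(self):
        with pytest.raises(ConfigurationError):
            gsea_es(fixed_ranked(5), {"absent"})

    def test_universe_set_raises(self):
        ranked = fixed_ranked(4)
        with pytest.raises(DegenerateDataError):
            gsea_es(ranked, set(ranked.genes))


class TestGseaPermutation:
    def test_determinism(self):
        ranked = fixed_ranked(50)
        members = {"g03", "g07", "g11", "g42"}
        out1 = gsea_permutation_p(ranked, members, n_perm=200, seed=42)
        out2 = gsea_permutation_p(ranked, members, n_perm=200, seed=42)
        assert out1 == out2

    def test_planted_top_set_saturates(self, rng):
        n = 500
        genes = np.array([f"g{i:03d}" for i in range(n)], dtype=object)
        rs = np.sort(rng.normal(0, 1, n))[::-1] + np.linspace(8, 0, n)
        ranked = RankedGeneList("L", genes, rs)
        members = set(genes[:20])  # the top 20
        es, p = gsea_permutation_p(ranked, members, n_perm=1000, seed=5)
        assert es > 0.8
        # saturated signed-tail p: 1 / (1 + #same-sign nulls)
        assert p <= 3.0 / 500

    def test_calibration_quick(self, rng):
        from scipy import stats

        ps = []
        for rep in range(60):
            n = 200
            genes = np.array([f"g{i}" for i in range(n)], dtype=object)
            rs = np.sort(rng.normal(0, 2, n))[::-1]
            ranked = RankedGeneList("L", genes, rs)
            members = set(rng.choice(genes, size=20, replace=False))
            _, p = gsea_permutation_p(ranked, members, n_perm=200, seed=rep)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_n_perm_floor(self):
        with pytest.raises(ConfigurationError):
            gsea_permutation_p(fixed_ranked(10), {"g01"}, n_perm=50, seed=1)


class TestLncresScore:
    def test_paper_threshold_value(self):
        assert lncres_score(0.0025, 1.0) == pytest.approx(0.995)

    def test_midpoint_is_zero(self):
        assert lncres_score(0.5, 1.0) == pytest.approx(0.0)
        assert lncres_score(0.5, -1.0) == pytest.approx(0.0)

    def test_limits(self):
        assert lncres_score(0.0, 0.3) == 1.0
        assert lncres_score(0.0, -0.3) == -1.0

    def test_es_zero_convention(self):
        assert lncres_score(0.01, 0.0) == 0.0

    @given(
        st.floats(min_value=1e-12, max_value=1.0),
        st.floats(min_value=-1.0, max_value=1.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_antisymmetry_and_bounds(self, p, es):
        score = lncres_score(p, es)
        assert -1.0 <= score <= 1.0
        assert lncres_score(p, -es) == pytest.approx(-score)
        # sign(lncRES) agrees with sign(ES) whenever p < 0.5 (the formula
        # flips it for p > 0.5, which never passes the significance filter)
        if es != 0 and p < 0.5:
            assert np.sign(score) == np.sign(es)

    @given(
        st.floats(min_value=1e-9, max_value=0.49),
        st.floats(min_value=1e-4, max_value=0.01),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_p_below_half(self, p, delta):
        assert lncres_score(p, 1.0) > lncres_score(min(p + delta, 0.5), 1.0) - 1e-15


class TestCallSignificant:
    def _rec(self, lncres, fdr):
        return LncRESRecord("L", "P", np.sign(lncres) or 1.0, 0.01, fdr, lncres, False)

    def test_threshold_boundary_not_significant(self):
        out = call_significant([self._rec(0.995, 0.01)])
        assert not out[0].significant

    def test_interior_point_significant(self):
        out = call_significant([self._rec(0.996, 0.049)])
        assert out[0].significant

    def test_fdr_boundary_not_significant(self):
        out = call_significant([self._rec(0.999, 0.05)])
        assert not out[0].significant

    def test_negative_lncres_counts_by_magnitude(self):
        out = call_significant([self._rec(-0.9999, 0.001)])
        assert out[0].significant


class TestRankGenes:
    def test_order_is_rs_desc_then_id(self, small_expr, uniform_purity):
        ranked = rank_genes(small_expr, "L1", uniform_purity)
        assert set(ranked.genes) == {"G1", "G2", "G3"}
        for i in range(len(ranked) - 1):
            assert (ranked.rs[i], ranked.genes[i + 1]) >= (ranked.rs[i + 1], ranked.genes[i])

    def test_universe_all_excludes_anchor(self, small_expr, uniform_purity):
        ranked = rank_genes(small_expr, "L1", uniform_purity, universe="all")
        assert "L1" not in set(ranked.genes)
        assert "L2" in set(ranked.genes)

    def test_dense_matches_scalar_path(self, rng, uniform_purity, small_expr):
        # the vectorized path must agree with per-pair partial_correlation
        ranked = rank_genes(small_expr, "L1", uniform_purity)
        pur = uniform_purity.aligned_to(small_expr.sample_ids)
        l = small_expr.vector("L1")
        for gene, rs in zip(ranked.genes, ranked.rs):
            pc = partial_correlation(l, small_expr.vector(gene), pur)
            assert rs == pytest.approx(rank_score(pc.p, pc.pcc), abs=1e-9)

    def test_missing_values_fall_back(self, uniform_purity):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(5, 30))
        vals[2, 4] = np.nan
        expr = make_expression(vals, ["L1", "L2", "G1", "G2", "G3"])
        ranked = rank_genes(expr, "L1", uniform_purity)
        assert set(ranked.genes) == {"G1", "G2", "G3"}


class TestComputeLncres:
    def _toy(self, seed=0, m=80):
        rng = np.random.default_rng(seed)
        factor = rng.normal(size=m)
        ids = ["Lsig"] + [f"Lnull{i}" for i in range(3)]
        rows = [factor + 0.3 * rng.normal(size=m)]
        rows += [rng.normal(size=m) for _ in range(3)]
        genes = [f"G{i:03d}" for i in range(120)]
        gene_rows = []
        for i, gid in enumerate(genes):
            if i < 15:  # pathway members track the signal lncRNA
                gene_rows.append(0.8 * factor + 0.6 * rng.normal(size=m))
            else:
                gene_rows.append(rng.normal(size=m))
        expr = make_expression(np.array(rows + gene_rows), ids + genes)
        purity = PurityVector(
            values=pd.Series(rng.uniform(0.2, 0.9, size=m), index=expr.sample_ids)
        )
        sets = GeneSetCollection(
            sets={
                "PLANTED": frozenset(genes[:15]),
                "RAND_A": frozenset(genes[40:55]),
                "RAND_B": frozenset(genes[60:75]),
            }
        )
        return expr, purity, ids, sets

    def test_planted_pair_recovered(self):
        expr, purity, ids, sets = self._toy()
        records = compute_lncres(expr, purity, ids, sets, n_perm=500, seed=9)
        by_key = {(r.lncRNA, r.pathway): r for r in records}
        planted = by_key[("Lsig", "PLANTED")]
        assert planted.ES > 0.8
        assert planted.significant
        assert planted.lncRES > 0.995

    def test_deterministic_given_seed(self):
        expr, purity, ids, sets = self._toy()
        r1 = compute_lncres(expr, purity, ids, sets, n_perm=200, seed=4)
        r2 = compute_lncres(expr, purity, ids, sets, n_perm=200, seed=4)
        assert r1 == r2

    def test_fdr_is_bh_over_grid(self):
        from netlnc.coexpression import bh_adjust

        expr, purity, ids, sets = self._toy()
        records = compute_lncres(expr, purity, ids, sets, n_perm=200, seed=4)
        adj = bh_adjust([r.p_value for r in records])
        for rec, q in zip(records, adj):
            assert rec.FDR == pytest.approx(float(q), abs=1e-12)

    def test_missing_lncrna_raises(self):
        expr, purity, ids, sets = self._toy()
        with pytest.raises(ConfigurationError):
            compute_lncres(expr, purity, ["NOPE"], sets, n_perm=200, seed=1)

    def test_empty_candidates_raise(self):
        expr, purity, ids, sets = self._toy()
        with pytest.raises(ConfigurationError):
            compute_lncres(expr, purity, [], sets, n_perm=200, seed=1)

    def test_lncres_consistency_invariants(self):
        expr, purity, ids, sets = self._toy()
        for rec in compute_lncres(expr, purity, ids, sets, n_perm=200, seed=4):
            assert abs(rec.lncRES) == pytest.approx(abs(1 - 2 * rec.p_value))
            if rec.ES != 0 and rec.p_value < 0.5:
                assert np.sign(rec.lncRES) == np.sign(rec.ES)
            assert 0 < rec.p_value <= 1
            assert rec.FDR >= rec.p_value - 1e-12
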