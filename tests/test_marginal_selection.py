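"""Marginal statistics against independent oracles, plus selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special

from comarker import bh_adjust, fold_change, select_fdr, select_top_k, t_test
from comarker.marginal_selection import compute_marginal_stats

from conftest import make_gene_matrix


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def welch_oracle(a, b):
    """Closed-form Welch statistic; p via numerical integration of the
    t density (independent of scipy.stats.ttest_ind)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))

    def density(x):
        return (
            special.gamma((df + 1) / 2)
            / (np.sqrt(df * np.pi) * special.gamma(df / 2))
            * (1 + x**2 / df) ** (-(df + 1) / 2)
        )

    tail, _ = integrate.quad(density, abs(t), np.inf)
    return t, df, 2 * tail


def bh_oracle(p):
    """Step-up BH from its definition: q_(j) = min_{k>=j} p_(k) m / k."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = min(running, 1.0)
    return q


# ---------------------------------------------------------------------------
# Fold change
# ---------------------------------------------------------------------------


class TestFoldChange:
    def test_examples(self, gene_matrix_factory):
        gm = gene_matrix_factory(
            [[3, 3, 1, 1], [2, 2, 2, 2], [1, 1, 2, 2]],
            ["case", "case", "control", "control"],
        )
        fc = fold_change(gm)
        assert fc["fc_ratio"].tolist() == pytest.approx([4.0, 1.0, 0.5])
        assert fc["fc_magnitude"].tolist() == pytest.approx([4.0, 1.0, 2.0])
        assert fc["direction"].tolist() == ["up", "up", "down"]

    def test_shift_invariance(self, gene_matrix_factory):
        rng = np.random.default_rng(1)
        values = rng.normal(8, 1, size=(10, 8))
        labels = ["case"] * 4 + ["control"] * 4
        a = fold_change(gene_matrix_factory(values, labels))
        b = fold_change(gene_matrix_factory(values + 3.7, labels))
        np.testing.assert_allclose(
            a["fc_ratio"].to_numpy(), b["fc_ratio"].to_numpy()
        )

    def test_requires_log2_flag(self, gene_matrix_factory):
        gm = gene_matrix_factory([[1, 2]], ["case", "control"])
        gm.log2 = False
        with pytest.raises(ValueError, match="log2"):
            fold_change(gm)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------


class TestTTest:
    def test_welch_against_integration_oracle(self, gene_matrix_factory):
        cases, controls = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        gm = gene_matrix_factory(
            [cases + controls], ["case"] * 3 + ["control"] * 3
        )
        res = t_test(gm)
        t_exp, df_exp, p_exp = welch_oracle(cases, controls)
        assert df_exp == pytest.approx(4.0)
        assert t_exp == pytest.approx(-3.6742, abs=1e-4)
        assert p_exp == pytest.approx(0.0213, abs=5e-4)
        assert res["t_stat"].iloc[0] == pytest.approx(t_exp, rel=1e-12)
        assert res["p_value"].iloc[0] == pytest.approx(p_exp, rel=1e-9)

    def test_random_genes_match_oracle(self, gene_matrix_factory):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, size=(25, 13))
        labels = ["case"] * 6 + ["control"] * 7
        res = t_test(gene_matrix_factory(values, labels))
        for i in range(25):
            t_exp, _, p_exp = welch_oracle(values[i, :6], values[i, 6:])
            assert res["t_stat"].iloc[i] == pytest.approx(t_exp, rel=1e-10)
            assert res["p_value"].iloc[i] == pytest.approx(p_exp, rel=1e-8)

    def test_identical_groups_give_p_one(self, gene_matrix_factory):
        gm = gene_matrix_factory(
            [[1.0, 1.0, 1.0, 1.0]], ["case", "case", "control", "control"]
        )
        res = t_test(gm)
        assert res["t_stat"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_degenerate_separation_gives_p_zero(self, gene_matrix_factory):
        gm = gene_matrix_factory(
            [[2.0, 2.0, 1.0, 1.0]], ["case", "case", "control", "control"]
        )
        res = t_test(gm)
        assert res["p_value"].iloc[0] == 0.0
        assert np.isinf(res["t_stat"].iloc[0])

    def test_group_of_one_rejected(self, gene_matrix_factory):
        gm = gene_matrix_factory([[1, 2, 3]], ["case", "control", "control"])
        with pytest.raises(ValueError, match=">=2 samples"):
            t_test(gm)

    def test_location_scale_invariance_of_p(self, gene_matrix_factory):
        rng = np.random.default_rng(3)
        values = rng.normal(5, 2, size=(8, 10))
        labels = ["case"] * 5 + ["control"] * 5
        p0 = t_test(gene_matrix_factory(values, labels))["p_value"]
        p1 = t_test(gene_matrix_factory(values * 2.5 + 7, labels))["p_value"]
        np.testing.assert_allclose(p0.to_numpy(), p1.to_numpy(), rtol=1e-10)

    def test_student_variant_pools_variance(self, gene_matrix_factory):
        # pooled t for equal-sized groups with equal variance matches Welch
        gm = gene_matrix_factory(
            [[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], ["case"] * 3 + ["control"] * 3
        )
        w = t_test(gm, variant="welch")
        s = t_test(gm, variant="student")
        assert w["t_stat"].iloc[0] == pytest.approx(s["t_stat"].iloc[0])


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


class TestBHAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_is_identity(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3] * 7), [0.3] * 7)

    def test_matches_definition_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            m = int(rng.integers(1, 200))
            p = rng.random(m)
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 2)
            np.testing.assert_allclose(
                bh_adjust(p), bh_oracle(p), atol=1e-12
            )

    def test_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = rng.random(150)
        q = bh_adjust(p)
        order_p = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order_p]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_q_in_unit_interval_and_oracle_equal(self, ps):
        q = bh_adjust(ps)
        assert ((0 <= q) & (q <= 1)).all()
        np.testing.assert_allclose(q, bh_oracle(ps), atol=1e-12)


# ---------------------------------------------------------------------------
# Selection rules
# ---------------------------------------------------------------------------


def stats_from_magnitudes(magnitudes, gene_matrix_factory):
    """Build MarginalStats whose fc_magnitude matches the given dict."""
    genes = list(magnitudes)
    # log2 difference of log2(mag) gives fc_ratio == magnitude
    values = np.array(
        [[np.log2(m), np.log2(m), 0.0, 0.0] for m in magnitudes.values()]
    )
    gm = gene_matrix_factory(
        values + 5.0, ["case", "case", "control", "control"], genes=genes
    )
    return compute_marginal_stats(gm)


class TestSelectTopK:
    def test_top_k_by_magnitude(self, gene_matrix_factory):
        stats = stats_from_magnitudes(
            {"A": 3, "B": 2, "C": 10, "D": 1, "E": 5}, gene_matrix_factory
        )
        sel = select_top_k(stats, "fc", k=3)
        assert sel.genes == {"C", "E", "A"}

    def test_k_larger_than_gene_count_returns_all(self, gene_matrix_factory):
        stats = stats_from_magnitudes(
            {"A": 3, "B": 2, "C": 10, "D": 1, "E": 5}, gene_matrix_factory
        )
        assert len(select_top_k(stats, "fc", k=10).genes) == 5

    def test_lexicographic_tie_break(self, gene_matrix_factory):
        stats = stats_from_magnitudes(
            {"A": 2, "B": 2, "C": 3}, gene_matrix_factory
        )
        assert select_top_k(stats, "fc", k=2).genes == {"C", "A"}

    def test_selection_independent_of_gene_order(self, gene_matrix_factory):
        mags = {"A": 2, "B": 2, "C": 3, "D": 2, "E": 1}
        s1 = stats_from_magnitudes(mags, gene_matrix_factory)
        s2 = stats_from_magnitudes(
            dict(reversed(list(mags.items()))), gene_matrix_factory
        )
        assert (
            select_top_k(s1, "fc", k=3).genes == select_top_k(s2, "fc", k=3).genes
        )

    def test_ratio_mode_ranks_upregulation_only(self, gene_matrix_factory):
        # magnitude 4 down-regulated vs magnitude 3 up-regulated
        values = np.array([[-1.0, -1.0, 1.0, 1.0], [np.log2(3), np.log2(3), 0, 0]])
        gm = gene_matrix_factory(
            values + 6, ["case", "case", "control", "control"], genes=["DN", "UP"]
        )
        stats = compute_marginal_stats(gm)
        assert select_top_k(stats, "fc", k=1, fc_mode="magnitude").genes == {"DN"}
        assert select_top_k(stats, "fc", k=1, fc_mode="ratio").genes == {"UP"}

    def test_t_p_ranking(self, gene_matrix_factory):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, size=(20, 12))
        values[3, :6] += 4  # one clearly significant gene
        gm = gene_matrix_factory(values, ["case"] * 6 + ["control"] * 6)
        stats = compute_marginal_stats(gm)
        sel = select_top_k(stats, "t_p", k=1)
        assert sel.genes == {"G3"}


class TestSelectFdr:
    def test_threshold_is_inclusive(self, gene_matrix_factory):
        rng = np.random.default_rng(7)
        gm = gene_matrix_factory(
            rng.normal(0, 1, (5, 10)), ["case"] * 5 + ["control"] * 5
        )
        stats = compute_marginal_stats(gm)
        stats.table["q_value"] = [0.0005, 0.001, 0.002, 0.5, 1.0]
        sel = select_fdr(stats, alpha=0.001)
        assert sel.genes == {"G0", "G1"}

    def test_alpha_one_selects_everything(self, gene_matrix_factory):
        rng = np.random.default_rng(8)
        gm = gene_matrix_factory(
            rng.normal(0, 1, (6, 10)), ["case"] * 5 + ["control"] * 5
        )
        stats = compute_marginal_stats(gm)
        assert len(select_fdr(stats, alpha=1.0).genes) == 6

    def test_nothing_significant_is_valid(self, gene_matrix_factory):
        rng = np.random.default_rng(9)
        gm = gene_matrix_factory(
            rng.normal(0, 1, (6, 10)), ["case"] * 5 + ["control"] * 5
        )
        stats = compute_marginal_stats(gm)
        assert select_fdr(stats, alpha=1e-9).genes == frozenset()
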