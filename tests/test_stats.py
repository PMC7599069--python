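"""ANOVA, cluster permutation, within-subject SEM, Spearman, sensitivity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from saccvig.stats import (
    cluster_permutation,
    rm_anova,
    sensitivity_mdes,
    spearman,
    within_subject_sem,
)


def cell_table(n_subj, factors, rng, effects=None):
    """Balanced cell-means table with optional additive effects."""
    levels = {f: ("a", "b") for f in factors}
    rows = []
    for i in range(n_subj):
        offset = rng.standard_normal()
        for combo in itertools.product(*levels.values()):
            val = offset + rng.standard_normal()
            if effects:
                val += effects(dict(zip(levels, combo)))
            rows.append({"participant_id": f"P{i:02d}",
                         **dict(zip(levels, combo)), "value": val})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_three_way_df_structure(self, rng):
        # 26 participants × 2×2×2 cells: 208 rows, 8 fixed effects → (1, 200)
        tab = cell_table(26, ["drug", "contingency", "motivation"], rng)
        res = rm_anova(tab, dv="value", within=["drug", "contingency", "motivation"])
        assert len(res) == 7
        assert (res["df_num"] == 1).all()
        assert (res["df_den"] == 200).all()

    def test_two_way_df_structure(self, rng):
        tab = cell_table(29, ["contingency", "motivation"], rng)
        res = rm_anova(tab, dv="value", within=["contingency", "motivation"])
        assert (res["df_den"] == 112).all()

    def test_partial_eta_squared_identity(self, rng):
        tab = cell_table(12, ["a_f", "b_f"], rng)
        res = rm_anova(tab, dv="value", within=["a_f", "b_f"])
        expected = res["F"] * res["df_num"] / (res["F"] * res["df_num"] + res["df_den"])
        assert np.allclose(res["partial_eta_sq"], expected)

    def test_single_factor_equals_squared_paired_t(self, rng):
        tab = cell_table(15, ["cond"], rng)
        res = rm_anova(tab, dv="value", within=["cond"])
        wide = tab.pivot(index="participant_id", columns="cond", values="value")
        t = sps.ttest_rel(wide["a"], wide["b"]).statistic
        assert res["F"].iloc[0] == pytest.approx(t**2, rel=1e-9)

    def test_agrees_with_mixedlm_wald(self, rng):
        """Independent cross-check: statsmodels MixedLM REML Wald t²."""
        import statsmodels.formula.api as smf

        tab = cell_table(10, ["f1", "f2"], rng,
                         effects=lambda c: 0.5 * (c["f1"] == "a"))
        res = rm_anova(tab, dv="value", within=["f1", "f2"])
        md = smf.mixedlm(
            "value ~ C(f1, Sum) * C(f2, Sum)", tab, groups=tab["participant_id"]
        ).fit(reml=True)
        for effect, term in [
            ("f1", "C(f1, Sum)[S.a]"),
            ("f2", "C(f2, Sum)[S.a]"),
            ("f1 * f2", "C(f1, Sum)[S.a]:C(f2, Sum)[S.a]"),
        ]:
            f_mine = res.loc[res["effect"] == effect, "F"].iloc[0]
            t_sm = md.tvalues[term]
            assert f_mine == pytest.approx(t_sm**2, rel=1e-3)

    def test_unbalanced_table_names_offender(self, rng):
        tab = cell_table(8, ["cond"], rng)
        tab = tab[~((tab.participant_id == "P03") & (tab.cond == "b"))]
        with pytest.raises(ValueError, match="P03"):
            rm_anova(tab, dv="value", within=["cond"])

    def test_null_calibration(self):
        """Under the null, each effect rejects at ≈ the nominal 5% rate."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sets = 300
        for _ in range(n_sets):
            tab = cell_table(26, ["drug", "cont", "mot"], rng)
            res = rm_anova(tab, dv="value", within=["drug", "cont", "mot"])
            rejections += float(res["p"].iloc[-1]) < 0.05
        rate = rejections / n_sets
        assert 0.01 < rate < 0.10


class TestClusterPermutation:
    def test_all_zero_differences(self):
        res = cluster_permutation(np.zeros((10, 50)), n_perm=200)
        assert res.clusters == []

    def test_constant_effect_hits_permutation_floor(self):
        rng = np.random.default_rng(0)
        data = 5.0 + 0.1 * rng.standard_normal((20, 50))
        res = cluster_permutation(data, n_perm=500, rng=rng, exact=False)
        assert len(res.clusters) == 1
        assert len(res.clusters[0].indices) == 50
        assert res.clusters[0].p == pytest.approx(1 / 501)

    def test_exact_enumeration_invariant_to_relabeling(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 30)) + 0.8
        p1 = cluster_permutation(data, exact=True).clusters
        p2 = cluster_permutation(data[::-1], exact=True).clusters
        assert [c.p for c in p1] == [c.p for c in p2]

    def test_random_subset_agrees_with_exact(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((10, 40)) + 0.45
        exact = cluster_permutation(data, exact=True)
        approx = cluster_permutation(data, n_perm=3000, rng=rng, exact=False)
        pe = exact.clusters[0].p
        pa = approx.clusters[0].p
        assert abs(pe - pa) < 4 * np.sqrt(pe * (1 - pe) / 3000) + 1e-3

    def test_2d_block_effect_found(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((15, 20, 20))
        data[:, 5:10, 5:10] += 2.0
        res = cluster_permutation(data, n_perm=400, rng=rng)
        assert res.significant
        top = res.significant[0]
        rows, cols = np.unravel_index(top.indices, (20, 20))
        assert rows.min() >= 4 and rows.max() <= 11
        assert cols.min() >= 4 and cols.max() <= 11

    def test_2d_four_connectivity_separates_corner_blocks(self):
        # two strong blocks touching only at a corner stay separate clusters
        data = 0.01 * np.random.default_rng(4).standard_normal((12, 10, 10))
        data[:, :5, :5] += 3.0
        data[:, 5:, 5:] += 3.0
        res = cluster_permutation(data, n_perm=100, rng=np.random.default_rng(5))
        big = [c for c in res.clusters if len(c.indices) >= 20]
        assert len(big) == 2

    def test_nan_cells_never_cluster(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((10, 20, 20)) + 1.5
        for d in data:
            np.fill_diagonal(d, np.nan)
        res = cluster_permutation(data, n_perm=100, rng=rng)
        diag = {i * 20 + i for i in range(20)}
        for c in res.clusters:
            assert not (set(c.indices.tolist()) & diag)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((4, 50)))


class TestWithinSubjectSem:
    def test_offsets_removed(self):
        pattern = np.array([1.0, 2.0, 3.0, 4.0])
        offsets = np.array([0.0, 10.0, -5.0, 100.0, 2.0])[:, None]
        y = pattern[None, :] + offsets
        sem = within_subject_sem(y)
        assert np.allclose(sem, 0.0, atol=1e-12)
        raw = y.std(axis=0, ddof=1) / np.sqrt(len(y))
        assert raw.min() > 1.0  # the raw SEM would be large

    def test_morey_factor_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((10, 4))
        centred = y - y.mean(axis=1, keepdims=True) + y.mean()
        manual = centred.std(axis=0, ddof=1) * np.sqrt(4 / 3) / np.sqrt(10)
        assert np.allclose(within_subject_sem(y), manual)

    def test_identical_participants_trivially_equal(self):
        y = np.tile([1.0, 2.0, 3.0], (6, 1))
        assert np.allclose(within_subject_sem(y), 0.0)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        rho, _ = spearman(x, x)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_dataset(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.0, 1.0, 4.0, 3.0]
        rho, p = spearman(x, y)
        assert rho == pytest.approx(0.6)
        # exact p by explicit enumeration of the 24 rank orders
        ranks = np.array([1.0, 2.0, 3.0, 4.0])
        rhos = []
        for perm in itertools.permutations([2.0, 1.0, 4.0, 3.0]):
            r = np.corrcoef(ranks, perm)[0, 1]
            rhos.append(r)
        expected_p = np.mean(np.abs(rhos) >= 0.6 - 1e-12)
        assert p == pytest.approx(expected_p)

    def test_matches_scipy_for_large_n(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestSensitivity:
    def test_published_sample_sizes(self):
        assert round(sensitivity_mdes(30), 2) == 0.46
        assert round(sensitivity_mdes(26), 1) == 0.5

    def test_large_n_normal_limit(self):
        d = sensitivity_mdes(10000)
        z = sps.norm.ppf(0.95) + sps.norm.ppf(0.8)
        assert d == pytest.approx(z / 100.0, rel=0.01)

    def test_power_attained_in_simulation(self):
        """A paired t at d = MDES(n) rejects in ~80% of replicates."""
        n = 24
        d = sensitivity_mdes(n)
        rng = np.random.default_rng(7)
        draws = rng.standard_normal((10000, n)) + d
        t = draws.mean(axis=1) / (draws.std(axis=1, ddof=1) / np.sqrt(n))
        rate = np.mean(t > sps.t.ppf(0.95, n - 1))
        assert rate == pytest.approx(0.80, abs=0.02)

    def test_invalid_power(self):
        with pytest.raises(ValueError):
            sensitivity_mdes(30, power=1.5)
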