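import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fdlung.errors import ParameterError, ValidationError
from fdlung.group_stats import compare_groups, kruskal_wallis, mann_whitney


class TestKruskalWallis:
    def test_worked_rank_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_identical_constant_groups(self):
        res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_statistic_matches_scipy(self, rng):
        groups = [rng.normal(size=6), rng.normal(size=5), rng.normal(size=7)]
        ours = kruskal_wallis(groups)
        h, p = sps.kruskal(*groups)
        assert ours.statistic == pytest.approx(h)
        assert ours.p_value == pytest.approx(p)  # n=18 -> chi-square path

    def test_exact_permutation_matches_monte_carlo_oracle(self, rng):
        groups = [rng.normal(size=4), rng.normal(size=4), rng.normal(size=4)]
        exact = kruskal_wallis(groups, method="exact")
        assert exact.method == "kw_exact"
        pooled = np.concatenate(groups)
        perm_rng = np.random.default_rng(1)
        n_perm = 20_000
        count = 0
        for _ in range(n_perm):
            x = perm_rng.permutation(pooled)
            h, _ = sps.kruskal(x[:4], x[4:8], x[8:])
            count += h >= exact.statistic - 1e-12
        assert abs(exact.p_value - count / n_perm) < 0.02

    def test_chi_square_approaches_permutation_at_moderate_n(self, rng):
        """Monte-Carlo permutation oracle vs the chi-square reference."""
        groups = [rng.normal(size=20), rng.normal(size=20), rng.normal(size=20)]
        res = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        h_obs = res.statistic
        count = 0
        n_perm = 4000
        perm_rng = np.random.default_rng(0)
        for _ in range(n_perm):
            x = perm_rng.permutation(pooled)
            h, _ = sps.kruskal(x[:20], x[20:40], x[40:])
            count += h >= h_obs - 1e-12
        assert abs(res.p_value - count / n_perm) <= 0.02

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(size=5), rng.normal(size=6)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert a.statistic == pytest.approx(b.statistic)

    def test_needs_two_groups_of_two(self):
        with pytest.raises(ParameterError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ParameterError):
            kruskal_wallis([[1], [2, 3]])


class TestMannWhitney:
    def test_enumeration_of_six_assignments(self):
        res = mann_whitney([1, 2], [3, 4], mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_have_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3], mode="exact")
        assert res.p_value == 1.0

    @pytest.mark.parametrize("n_a,n_b", list(itertools.product(range(2, 7), repeat=2)))
    def test_exact_p_matches_scipy_enumeration_full_sweep(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        a = rng.normal(size=n_a)
        b = rng.normal(size=n_b)
        ours = mann_whitney(a, b, mode="exact")
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.statistic == pytest.approx(u)
        assert ours.p_value == pytest.approx(p)

    def test_exact_p_at_5_6_matches_brute_force(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=6)
        ours = mann_whitney(a, b, mode="exact")
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        u_obs = ours.statistic
        le = ge = 0
        for combo in itertools.combinations(range(11), 5):
            u = ranks[list(combo)].sum() - 15
            le += u <= u_obs + 1e-12
            ge += u >= u_obs - 1e-12
        total = comb(11, 5)
        assert ours.p_value == pytest.approx(min(1.0, 2 * min(le, ge) / total))

    def test_auto_uses_normal_approximation_for_large_or_tied_data(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert mann_whitney(a, b).method == "mw_normal"
        assert mann_whitney([1, 1, 2], [2, 3, 3]).method == "mw_normal"

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        r1 = mann_whitney(a, b, mode="exact")
        r2 = mann_whitney(np.exp(a), np.exp(b), mode="exact")
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_empty_side_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1, 2])


def _table(rng, shift_b=0.0, n=(5, 5, 6), sd=0.08):
    rows = []
    means = {"g1": shift_b, "g2": 0.0, "g3": 0.0}
    for g, m in zip(means, n):
        for i in range(m):
            rows.append(
                {"group": g, "subject": f"{g}-{i}",
                 "height_b": rng.normal(1.3 + means[g], sd),
                 "width_b": rng.normal(1500, 100)}
            )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_shifted_parameter_flagged_with_high_power(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            table = _table(rng, shift_b=0.4)
            comp = compare_groups(table, ["height_b"], alpha=0.05)
            hits += comp.flagged("height_b", "g1", "g2") and comp.flagged("height_b", "g1", "g3")
        assert hits / 200 >= 0.80

    def test_null_type_one_rate_within_band(self):
        rejections = 0
        n_rep = 2000
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            table = _table(rng)
            comp = compare_groups(table, ["height_b"], alpha=0.05)
            rejections += comp.comparisons["height_b"].kw.p_value < 0.05
        assert 0.025 <= rejections / n_rep <= 0.085

    def test_two_group_kw_consistent_with_exact_mw(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        table = pd.DataFrame(
            [{"group": "a", "subject": i, "v": x} for i, x in enumerate(a)]
            + [{"group": "b", "subject": i, "v": x} for i, x in enumerate(b)]
        )
        comp = compare_groups(table, ["v"])
        kw_p = comp.comparisons["v"].kw.p_value  # exact permutation (n = 10)
        mw_p = comp.comparisons["v"].pairs[0].test.p_value
        assert abs(kw_p - mw_p) < 0.01

    def test_missing_parameter_is_named(self, rng):
        with pytest.raises(ParameterError, match="nope"):
            compare_groups(_table(rng), ["nope"])

    def test_holm_correction_only_removes_flags(self, rng):
        table = _table(rng, shift_b=0.2)
        raw = compare_groups(table, ["height_b", "width_b"])
        holm = compare_groups(table, ["height_b", "width_b"], correction="holm")
        for par in ("height_b", "width_b"):
            for p_raw, p_adj in zip(raw.comparisons[par].pairs, holm.comparisons[par].pairs):
                assert not (p_adj.significant and not p_raw.significant)

    def test_single_group_table_rejected(self):
        table = pd.DataFrame({"group": ["a", "a"], "subject": [1, 2], "v": [1.0, 2.0]})
        with pytest.raises(ValidationError):
            compare_groups(table, ["v"])
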