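"""ANOVA + SNK post hoc, t-tests against zero, and dose selection."""

import numpy as np
import pytest
from scipy import stats as sps

from fluxdeconv import anova_snk, select_titration_dose, simulate_titration, t_test_vs_zero
from fluxdeconv.assay_model import DataError
from fluxdeconv.stats import snk_critical_q


def _permutation_f_pvalue(groups, n_perm=10_000, seed=0):
    """Label-permutation null of the one-way F statistic (independent oracle)."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    f_obs = sps.f_oneway(*groups).statistic
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        parts = np.split(pooled, np.cumsum(sizes)[:-1])
        if sps.f_oneway(*parts).statistic >= f_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestAnovaSnk:
    def test_identical_groups_yield_no_significant_pairs(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(5.0, 1.0, 8) for k in "abc"}
        cmp = anova_snk(groups)
        assert not cmp.significant.any()
        assert len(set(cmp.letters)) == 1  # one homogeneous subset

    def test_strong_separation_all_pairs_significant(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 0.1, 5) for m in (0.0, 10.0, 20.0)]
        cmp = anova_snk(groups)
        assert cmp.significant.sum() == 6  # all 3 pairs, symmetric
        assert cmp.letters == ["a", "b", "c"]
        # permutation oracle agrees the global null is untenable
        assert _permutation_f_pvalue(groups) < 0.001
        assert cmp.p < 0.001

    def test_f_and_p_match_scipy(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, n) for m, n in ((0, 7), (1, 8), (0.5, 8))]
        cmp = anova_snk(groups)
        ref = sps.f_oneway(*groups)
        assert cmp.f == pytest.approx(ref.statistic, rel=1e-9)
        assert cmp.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_groups_match_pooled_t_test_exactly(self):
        """At k = 2 the SNK decision is the pooled two-sample t-test (q = t*sqrt(2))."""
        rng = np.random.default_rng(4)
        for trial in range(200):
            n1, n2 = rng.integers(3, 9, 2)
            shift = rng.uniform(0.0, 1.5)
            a, b = rng.normal(0, 1, n1), rng.normal(shift, 1, n2)
            cmp = anova_snk([a, b])
            t_p = sps.ttest_ind(a, b).pvalue
            assert bool(cmp.significant[0, 1]) == (t_p < 0.05), f"trial {trial}"

    def test_published_studentized_range_quantiles(self):
        """Numerical q(0.05; r, df) against the standard printed tables."""
        table = {(2, 10): 3.151, (3, 10): 3.877, (2, 20): 2.950, (6, 20): 4.445,
                 (2, 30): 2.888, (4, 30): 3.845}
        for (r, df), want in table.items():
            assert snk_critical_q(0.05, r, df) == pytest.approx(want, abs=0.002)

    def test_snk_at_least_as_powerful_as_tukey(self):
        """Every pair Tukey HSD rejects, SNK also rejects (step-down property)."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            k, n = 5, 8
            groups = [rng.normal(rng.uniform(0, 3), 1.0, n) for _ in range(k)]
            cmp = anova_snk(groups)
            mse = np.mean([g.var(ddof=1) for g in groups])
            crit_tukey = snk_critical_q(0.05, k, k * (n - 1))
            for i in range(k):
                for j in range(i + 1, k):
                    q = abs(groups[i].mean() - groups[j].mean()) / np.sqrt(mse / n)
                    if q > crit_tukey:
                        assert cmp.significant[i, j]

    def test_family_wise_error_controlled_under_global_null(self):
        rng = np.random.default_rng(6)
        n_rep, rejections = 1000, 0
        for _ in range(n_rep):
            groups = [rng.normal(0, 1, 8) for _ in range(6)]
            rejections += anova_snk(groups).significant.any()
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rejections / n_rep <= 0.05 + 2 * mc_se

    def test_degenerate_zero_variance_flagged(self):
        cmp = anova_snk([[1.0, 1.0], [2.0, 2.0]])
        assert cmp.degenerate
        assert cmp.significant[0, 1]

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            anova_snk([[1.0], [2.0, 3.0]])


class TestTTestVsZero:
    def test_symmetric_scatter_not_significant(self):
        res = t_test_vs_zero([0.1, -0.1, 0.05, -0.05])
        assert not res.significant

    def test_clear_offset_significant_matches_closed_form(self):
        vals = np.array([5.0, 5.1, 4.9])
        res = t_test_vs_zero(vals)
        t_manual = vals.mean() / (vals.std(ddof=1) / np.sqrt(3))
        assert res.t == pytest.approx(t_manual, rel=1e-12)
        assert res.significant

    def test_p_monotone_in_effect_size(self):
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 1.0, 10)
        ps = [t_test_vs_zero(noise + shift).p for shift in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_single_observation_rejected(self):
        with pytest.raises(DataError):
            t_test_vs_zero([1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            t_test_vs_zero([2.0, 2.0, 2.0])


class _Curve:
    def __init__(self, doses, responses, dead):
        self.doses, self.responses, self.dead = doses, responses, dead


class TestDoseSelection:
    def test_max_nonlethal_response(self):
        curve = _Curve([1.0, 1.875, 2.5], [50.0, 80.0, 81.0], [False, False, True])
        assert select_titration_dose(curve) == 1.875

    def test_strictly_increasing_nonlethal_takes_highest(self):
        curve = _Curve([1, 2, 3], [10.0, 20.0, 30.0], [False] * 3)
        assert select_titration_dose(curve) == 3

    def test_plateau_takes_lowest_plateau_dose(self):
        curve = _Curve([1, 2, 3], [80.0, 80.0, 80.0], [False] * 3)
        assert select_titration_dose(curve) == 1

    def test_all_lethal_rejected(self):
        curve = _Curve([1, 2], [5.0, 6.0], [True, True])
        with pytest.raises(DataError):
            select_titration_dose(curve)

    @pytest.mark.parametrize(
        "agent, hpf, doses, expected",
        [
            ("fccp", 7, [0.5, 1.0, 1.875, 2.5], 1.875),
            ("fccp", 24, [0.5, 1.0, 1.875, 2.5, 5.0], 2.5),
            ("sodium_azide", 24, [0.25, 1.25, 6.25, 12.5], 6.25),
            ("sodium_azide", 48, [0.25, 1.25, 6.25], 1.25),
            ("oligomycin", 12, [1.0, 5.0, 9.4, 20.0], 9.4),
        ],
    )
    def test_simulated_titrations_select_working_concentrations(self, agent, hpf, doses, expected):
        curve = simulate_titration(agent, hpf, doses, seed=0)
        assert select_titration_dose(curve) == expected
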