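"""Summary-statistic ANOVA, Tukey-Kramer, percent differences, outliers."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import efieldstats as es
from efieldstats.group_stats import GroupSummary


def random_groups(rng, k=None):
    k = k or rng.integers(2, 6)
    return {
        f"g{i}": rng.normal(rng.uniform(-10, 10), rng.uniform(0.5, 5), rng.integers(2, 30))
        for i in range(k)
    }


class TestAnovaFromSummaries:
    def test_cohort_vs_singleton_templates(self):
        # frozen from the summary-statistic oracle: 195-subject group plus
        # two singleton template observations
        res = es.anova_from_summaries(
            [
                GroupSummary("individual", 195, 85.26, 15.54),
                GroupSummary("MNI-152", 1, 78.16),
                GroupSummary("Ernie", 1, 81.46),
            ]
        )
        assert (res.df_between, res.df_within) == (2, 194)
        assert res.f_stat == pytest.approx(0.13302099028144188, rel=1e-10)
        assert round(res.f_stat, 2) == 0.13
        assert res.eta_p2 == pytest.approx(0.0013694723887435888, rel=1e-10)

    def test_five_group_diagnosis_anova(self, diagnosis_summaries):
        res = es.anova_from_summaries(diagnosis_summaries[es.Protocol.motor_TMS])
        assert (res.df_between, res.df_within) == (4, 190)
        assert res.f_stat == pytest.approx(6.09131721332787, rel=1e-10)
        assert res.eta_p2 == pytest.approx(0.11366239029133235, rel=1e-10)

    def test_identical_means_give_zero_f(self):
        groups = [GroupSummary(f"g{i}", 10, 5.0, 1.0 + i) for i in range(3)]
        res = es.anova_from_summaries(groups)
        assert res.f_stat == 0.0
        assert res.eta_p2 == 0.0
        assert res.p_value == 1.0

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            es.anova_from_summaries([GroupSummary("a", 1, 1.0), GroupSummary("b", 1, 2.0)])

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            es.anova_from_summaries([GroupSummary("a", 10, 1.0, 1.0)])

    def test_template_value_swap_leaves_f_unchanged(self):
        base = [GroupSummary("individual", 195, 85.26, 15.54)]
        a = es.anova_from_summaries(base + [GroupSummary("t1", 1, 78.16), GroupSummary("t2", 1, 81.46)])
        b = es.anova_from_summaries(base + [GroupSummary("t1", 1, 81.46), GroupSummary("t2", 1, 78.16)])
        assert a.f_stat == pytest.approx(b.f_stat, rel=1e-14)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3), shift=st.floats(-100, 100))
    def test_affine_invariance_of_f_and_eta(self, scale, shift):
        groups = [
            GroupSummary("a", 12, 3.0, 1.5),
            GroupSummary("b", 20, 4.5, 2.0),
            GroupSummary("c", 7, 2.0, 1.0),
        ]
        rescaled = [
            GroupSummary(g.label, g.n, scale * g.mean + shift, scale * g.sd) for g in groups
        ]
        r0 = es.anova_from_summaries(groups)
        r1 = es.anova_from_summaries(rescaled)
        assert r1.f_stat == pytest.approx(r0.f_stat, rel=1e-9)
        assert r1.eta_p2 == pytest.approx(r0.eta_p2, rel=1e-9)

    def test_adding_group_at_grand_mean_preserves_ss_between(self):
        groups = [GroupSummary("a", 10, 3.0, 1.0), GroupSummary("b", 30, 6.0, 2.0)]
        r0 = es.anova_from_summaries(groups)
        grand = (10 * 3.0 + 30 * 6.0) / 40
        r1 = es.anova_from_summaries(groups + [GroupSummary("c", 5, grand, 1.0)])
        assert r1.ss_between <= r0.ss_between + 1e-9


class TestAnovaFromRaw:
    def test_matches_summaries_route(self):
        raw = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]}
        r_raw = es.anova_from_raw(raw)
        r_sum = es.anova_from_summaries(
            [GroupSummary.from_values(k, v) for k, v in raw.items()]
        )
        assert r_raw.f_stat == pytest.approx(r_sum.f_stat, rel=1e-12)
        assert r_raw.p_value == pytest.approx(r_sum.p_value, rel=1e-12)

    def test_duplicated_group_gives_zero_f(self):
        vals = [1.0, 2.5, 3.5, 7.0]
        res = es.anova_from_raw({"a": vals, "b": vals})
        assert res.f_stat == pytest.approx(0.0, abs=1e-25)

    def test_scipy_f_oneway_cross_check(self):
        rng = np.random.default_rng(3)
        groups = random_groups(rng, k=4)
        res = es.anova_from_raw(groups)
        f, p = stats.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(float(f), rel=1e-10)
        assert res.p_value == pytest.approx(float(p), rel=1e-8)

    def test_sex_plus_templates_df(self, default_cohort, default_config):
        proto = es.Protocol.motor_TMS
        men = [r.efield[proto] for r in default_cohort if r.sex == es.Sex.male]
        women = [r.efield[proto] for r in default_cohort if r.sex == es.Sex.female]
        groups = [
            GroupSummary.from_values("men", men),
            GroupSummary.from_values("women", women),
        ] + default_config.template_summaries(proto)
        res = es.anova_from_summaries(groups)
        assert (res.df_between, res.df_within) == (3, 193)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            es.anova_from_raw({"a": [1.0, 2.0], "b": []})


class TestTukeyKramer:
    def test_monte_carlo_studentized_range_oracle(self):
        # balanced three-group design; p_adj checked against a direct
        # simulation of the studentized-range distribution (1e6 draws)
        rng = np.random.default_rng(12)
        k, n = 3, 10
        groups = [
            GroupSummary.from_values(f"g{i}", rng.normal(i * 0.8, 1.0, n)) for i in range(k)
        ]
        comps = es.tukey_kramer(groups)
        df = k * (n - 1)
        z = rng.standard_normal((1_000_000, k))
        s = np.sqrt(rng.chisquare(df, 1_000_000) / df)
        q_null = (z.max(axis=1) - z.min(axis=1)) / s
        for c in comps:
            p_mc = float((q_null >= c.q_stat).mean())
            tol = 4 * np.sqrt(max(p_mc * (1 - p_mc), 1e-6) / 1_000_000) + 1e-4
            assert c.p_adj == pytest.approx(p_mc, abs=tol)

    def test_equal_n_matches_classical_hsd_q(self):
        groups = [
            GroupSummary("a", 10, 1.0, 1.0),
            GroupSummary("b", 10, 2.0, 1.0),
            GroupSummary("c", 10, 3.5, 1.0),
        ]
        comps = {(c.group_a, c.group_b): c for c in es.tukey_kramer(groups)}
        # classical HSD: q = |diff| / sqrt(MSw / n), MSw = 1
        assert comps[("a", "b")].q_stat == pytest.approx(1.0 / np.sqrt(1 / 10), rel=1e-12)
        assert comps[("a", "c")].q_stat == pytest.approx(2.5 / np.sqrt(1 / 10), rel=1e-12)

    def test_singleton_group_instructs_exclusion(self):
        groups = [
            GroupSummary("a", 10, 1.0, 1.0),
            GroupSummary("b", 10, 2.0, 1.0),
            GroupSummary("template", 1, 1.5),
        ]
        with pytest.raises(ValueError, match="exclude template"):
            es.tukey_kramer(groups)

    def test_two_groups_reduce_to_pooled_t_test(self):
        a = GroupSummary("a", 12, 4.0, 1.5)
        b = GroupSummary("b", 9, 5.2, 1.8)
        (comp,) = es.tukey_kramer([a, b])
        t_res = stats.ttest_ind_from_stats(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
        )
        assert comp.p_adj == pytest.approx(float(t_res.pvalue), rel=1e-9)

    def test_p_monotone_in_mean_difference(self):
        base = [GroupSummary("a", 15, 0.0, 1.0), GroupSummary("b", 15, 0.0, 1.0),
                GroupSummary("c", 15, 5.0, 1.0)]
        ps = []
        for diff in (0.5, 1.0, 1.5, 2.0):
            groups = [GroupSummary("a", 15, 0.0, 1.0), GroupSummary("b", 15, diff, 1.0),
                      GroupSummary("c", 15, 5.0, 1.0)]
            comp = [c for c in es.tukey_kramer(groups) if {c.group_a, c.group_b} == {"a", "b"}][0]
            ps.append(comp.p_adj)
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_diff_antisymmetric_under_label_swap(self):
        groups = [GroupSummary("a", 10, 1.0, 1.0), GroupSummary("b", 10, 3.0, 1.0),
                  GroupSummary("c", 10, 2.0, 1.0)]
        fwd = {(c.group_a, c.group_b): c.diff for c in es.tukey_kramer(groups)}
        rev = {(c.group_a, c.group_b): c.diff for c in es.tukey_kramer(groups[::-1])}
        assert fwd[("a", "b")] == pytest.approx(-rev[("b", "a")], rel=1e-14)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "template, group, expected",
        [
            (78.16, 85.26, 8.3),  # motor TMS template deficit
            (0.244, 0.299, 18.4),  # prefrontal tES template deficit
            (5.0, 5.0, 0.0),
        ],
    )
    def test_examples(self, template, group, expected):
        assert round(es.percent_difference(template, group), 1) == expected

    def test_nonpositive_group_mean_rejected(self):
        with pytest.raises(ValueError):
            es.percent_difference(1.0, 0.0)
        with pytest.raises(ValueError):
            es.percent_difference(1.0, -2.0)


class TestOutliersBeyondKSd:
    def test_all_equal_gives_zero(self):
        count, labels = es.outliers_beyond_k_sd([3.0] * 10, k=2.0)
        assert count == 0 and labels == []

    def test_constructed_outlier_found_by_enumeration(self):
        values = [10.0] * 9 + [10.0]
        values[-1] = 10.0 + 30.0  # displaced well beyond 2 sample SD
        count, labels = es.outliers_beyond_k_sd(values, k=2.0)
        arr = np.asarray(values)
        brute = [
            i for i, v in enumerate(values)
            if abs(v - arr.mean()) > 2.0 * arr.std(ddof=1)
        ]
        assert count == len(brute) == 1
        assert labels == [str(i) for i in brute]

    def test_gaussian_tail_rate(self):
        rng = np.random.default_rng(4)
        count, _ = es.outliers_beyond_k_sd(rng.normal(0, 1, 100_000), k=2.0)
        # two-sided normal tail beyond 2 SD is ~4.55%
        assert count == pytest.approx(4550, abs=300)
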