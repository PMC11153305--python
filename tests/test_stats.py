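import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from glycotrial.simulate import SimulationConfig, simulate_cohort
from glycotrial.stats import (
    DegenerateTableError,
    association_test,
    benjamini_hochberg,
    expected_counts,
    fisher_exact_2x2,
    fit_treatment_effect,
    select_analysis_set,
    two_sample_t_test,
)


def fisher_brute_force(table) -> float:
    """Oracle: enumerate every table with the observed margins exactly."""
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def prob(k):
        # hypergeometric probability via the factorial formula, exactly
        return Fraction(
            math.factorial(r1) * math.factorial(r2) * math.factorial(c1) * math.factorial(n - c1),
            math.factorial(n)
            * math.factorial(k)
            * math.factorial(r1 - k)
            * math.factorial(c1 - k)
            * math.factorial(r2 - c1 + k),
        )

    observed = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(k)
        if p <= observed:
            total += p
    return float(total)


class TestFisherExact:
    def test_published_stopped_medication_table(self):
        # 7/43 vs 2/39 stopped all medication; min expected count < 5
        assert round(fisher_exact_2x2([[7, 36], [2, 37]]), 2) == 0.16

    def test_degenerate_margin_p_one(self):
        assert fisher_exact_2x2([[0, 10], [0, 10]]) == 1.0

    def test_two_extreme_tables(self):
        # only the two diagonal tables are as improbable as observed
        assert fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(
            2 / math.comb(10, 5), abs=1e-15
        )

    @given(
        st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=4)
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_enumeration(self, cells):
        table = [cells[:2], cells[2:]]
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_brute_force(table), abs=1e-12
        )

    @given(
        st.lists(st.integers(min_value=1, max_value=15), min_size=4, max_size=4)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_scipy_cross_check(self, cells):
        """Independent library implementation agrees (same two-sided convention)."""
        table = [cells[:2], cells[2:]]
        assert fisher_exact_2x2(table) == pytest.approx(
            scipy.stats.fisher_exact(table).pvalue, rel=1e-9
        )


class TestAssociationTest:
    def test_3x2_uses_plain_chi_squared(self):
        res = association_test([[23, 10, 10], [3, 13, 23]])
        assert res.test_used == "chi_squared"
        assert res.df == 2
        assert res.p_value < 0.001

    def test_2x2_low_expected_falls_back_to_fisher(self):
        res = association_test([[7, 36], [2, 37]])
        assert res.test_used == "fisher_exact"
        assert res.min_expected < 5
        assert res.statistic is None

    def test_2x2_adequate_expected_uses_yates(self):
        res = association_test([[1, 42], [10, 29]])
        assert res.test_used == "chi_squared_yates"
        assert res.min_expected >= 5
        assert round(res.p_value, 3) == 0.006

    def test_identical_rows_p_one(self):
        res = association_test([[10, 5, 5], [10, 5, 5]])
        assert res.p_value == pytest.approx(1.0)

    def test_row_column_swap_invariance(self):
        t = np.array([[8, 15], [20, 7]])
        p = association_test(t).p_value
        assert association_test(t[::-1]).p_value == pytest.approx(p)
        assert association_test(t.T).p_value == pytest.approx(p)

    def test_zero_column_degenerate(self):
        with pytest.raises(DegenerateTableError):
            association_test([[5, 0], [3, 0]])

    def test_expected_counts_formula(self):
        exp = expected_counts([[10, 10], [20, 20]])
        assert exp == pytest.approx(np.array([[10, 10], [20, 20]]) * 1.0)


class TestBenjaminiHochberg:
    def test_step_up_all_rejected(self):
        adjusted, reject = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()
        # step-up adjusted values: min over j>=i of (m/j) p_(j)
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        adjusted, _ = benjamini_hochberg([0.2])
        assert adjusted == pytest.approx([0.2])

    def test_all_ones_none_rejected(self):
        adjusted, reject = benjamini_hochberg([1.0, 1.0, 1.0])
        assert not reject.any()
        assert adjusted == pytest.approx([1.0, 1.0, 1.0])

    def test_empty_input(self):
        adjusted, reject = benjamini_hochberg([])
        assert len(adjusted) == 0 and len(reject) == 0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_rejections_monotone_in_q(self, ps):
        _, r_small = benjamini_hochberg(ps, q=0.05)
        _, r_large = benjamini_hochberg(ps, q=0.20)
        assert (r_large | ~r_small).all()  # small-q rejections are a subset


class TestTTest:
    def test_hand_computed_example(self):
        a, b = [1.0, 2.0], [3.0, 5.0]
        # textbook pooled-variance arithmetic, independent of the implementation
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        t_expected = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 2 + 1 / 2))
        stat, p = two_sample_t_test(a, b)
        assert stat == pytest.approx(t_expected)
        assert p == pytest.approx(2 * scipy.stats.t.sf(abs(t_expected), df=2))

    def test_identical_groups_p_one(self):
        stat, p = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_both_groups_flagged(self):
        with pytest.raises(ValueError):
            two_sample_t_test([2.0, 2.0], [2.0, 2.0])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(200):
            _, p = two_sample_t_test(rng.normal(size=500), rng.normal(size=500))
            ps.append(p)
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


def _completion_cohort():
    """49 FMD + 43 control with baselines; 30 compliant FMD and 39 control completers."""
    rows = []
    for i in range(49):
        pid = f"F{i:03d}"
        compliant = i < 30
        completes = i < 30 or 30 <= i < 40  # some non-compliant participants still finish
        rows.append(dict(participant_id=pid, arm="FMD", compliant=compliant, timepoint_months=0))
        if completes:
            rows.append(dict(participant_id=pid, arm="FMD", compliant=compliant, timepoint_months=12))
    for i in range(43):
        pid = f"C{i:03d}"
        completes = i < 39
        rows.append(dict(participant_id=pid, arm="control", compliant=True, timepoint_months=0))
        if completes:
            rows.append(dict(participant_id=pid, arm="control", compliant=True, timepoint_months=12))
    return pd.DataFrame(rows)


class TestAnalysisSets:
    def test_pp_keeps_compliant_fmd_and_control_completers(self):
        cohort = _completion_cohort()
        pp = select_analysis_set(cohort, "PP")
        base = pp[pp["timepoint_months"] == 0]
        assert (base["arm"] == "FMD").sum() == 30
        assert (base["arm"] == "control").sum() == 39

    def test_itt_keeps_everyone_with_baseline(self):
        cohort = _completion_cohort()
        itt = select_analysis_set(cohort, "ITT")
        assert itt[itt["timepoint_months"] == 0].shape[0] == 92

    def test_all_compliant_completers_itt_equals_pp(self):
        cohort = _completion_cohort()
        full = cohort.groupby("participant_id").filter(lambda g: len(g) == 2)
        full = full.assign(compliant=True)
        itt = select_analysis_set(full, "ITT")
        pp = select_analysis_set(full, "PP")
        assert set(itt["participant_id"]) == set(pp["participant_id"])

    def test_zero_compliant_pp_fmd_arm_empty(self):
        cohort = _completion_cohort().assign(
            compliant=lambda d: d["arm"] != "FMD"
        )
        pp = select_analysis_set(cohort, "PP")
        assert (pp["arm"] == "FMD").sum() == 0
        assert (pp.loc[pp["timepoint_months"] == 0, "arm"] == "control").sum() == 39

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError):
            select_analysis_set(_completion_cohort(), "mITT")


class TestMixedModel:
    def test_null_effect_near_zero(self):
        cfg = SimulationConfig(
            n_participants=500,
            hba1c_effect={6: 0.0, 12: 0.0},
            weight_effect={6: 0.0, 12: 0.0},
        )
        cohort = simulate_cohort(cfg, seed=314)
        eff = fit_treatment_effect(cohort, "hba1c_mmol_mol", timepoint=12)
        assert abs(eff.estimate) < 2 * (eff.ci_high - eff.estimate) / 1.96

    def test_arm_label_permutation_flips_sign(self, small_simulated_cohort):
        cohort = small_simulated_cohort
        flipped = cohort.assign(
            arm=cohort["arm"].map({"FMD": "control", "control": "FMD"})
        )
        eff = fit_treatment_effect(cohort, "weight_kg", timepoint=12)
        eff_flipped = fit_treatment_effect(flipped, "weight_kg", timepoint=12)
        assert eff_flipped.estimate == pytest.approx(-eff.estimate, rel=1e-3)

    def test_ci_brackets_estimate_and_model_spec_recorded(self, small_simulated_cohort):
        eff = fit_treatment_effect(small_simulated_cohort, "hba1c_mmol_mol", timepoint=12)
        assert eff.ci_low <= eff.estimate <= eff.ci_high
        assert "C(time)" in eff.model_spec and "participant" in eff.model_spec

    def test_single_timepoint_rejected(self, small_simulated_cohort):
        base_only = small_simulated_cohort[small_simulated_cohort["timepoint_months"] == 0]
        with pytest.raises(ValueError):
            fit_treatment_effect(base_only, "hba1c_mmol_mol")
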