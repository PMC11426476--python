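"""Efficacy threshold, satisfaction index and its interim prediction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psdesign import (
    BetaPrior,
    InterimData,
    TrialDesign,
    efficacy_threshold,
    flat_prior,
    prediction_of_satisfaction,
    ps_table,
    satisfaction_index,
)

from _oracles import binom_cdf_sum, binom_sf_sum, ps_enumeration


class TestEfficacyThreshold:
    @pytest.mark.parametrize(
        "n_max, theta0, alpha, expected",
        [
            (50, 0.3, 0.05, 20),
            (50, 0.3, 0.10, 19),
            (40, 0.3, 0.05, 17),
            (40, 0.07, 0.05, 6),
        ],
    )
    def test_published_thresholds(self, n_max, theta0, alpha, expected):
        assert efficacy_threshold(n_max, theta0, alpha).t_eff == expected

    def test_brute_force_strict_tail_scan(self):
        # smallest u with P(Z > u | 27, 0.3) <= 0.10, by direct tail summation
        expected = next(
            u for u in range(28) if binom_sf_sum(u + 1, 27, 0.3) <= 0.10
        )
        assert efficacy_threshold(27, 0.3, 0.10).t_eff == expected == 11

    def test_degenerate_null_rate(self):
        assert efficacy_threshold(30, 0.0, 0.05).t_eff == 0

    def test_literal_dialect_is_weak_tail(self):
        # literal threshold is calibrated + 1 whenever the boundary pmf is positive
        assert efficacy_threshold(50, 0.3, 0.05, "literal").t_eff == 21

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            efficacy_threshold(50, 0.3, 0.0)


class TestSatisfactionIndex:
    def test_below_threshold_is_zero(self):
        t = efficacy_threshold(50, 0.3, 0.05)
        assert satisfaction_index(t.t_eff - 1, 50, 0.3, t) == 0.0

    def test_at_threshold_is_one_minus_p_value(self):
        t = efficacy_threshold(50, 0.3, 0.05)
        assert t.t_eff == 20
        assert satisfaction_index(20, 50, 0.3, t) == pytest.approx(
            1.0 - binom_sf_sum(20, 50, 0.3), abs=1e-12
        )
        assert satisfaction_index(20, 50, 0.3, t) == pytest.approx(0.91520, abs=5e-6)

    def test_full_success_closed_form(self):
        t = efficacy_threshold(50, 0.3, 0.05)
        assert satisfaction_index(50, 50, 0.3, t) == pytest.approx(1.0 - 0.3**50, abs=1e-15)


class TestPredictionOfSatisfaction:
    @pytest.mark.parametrize(
        "z, n_max, expected",
        [
            (1, 27, 0.01051750),
            (2, 27, 0.07231145),
            (3, 27, 0.25504505),
            (3, 32, 0.26315640),
        ],
    )
    def test_flat_prior_first_look_values(self, z, n_max, expected, table1_design_27):
        design = TrialDesign(
            theta0=0.3, theta1=0.5, alpha=0.10, power_target=0.8, gamma=0.5,
            n_max=n_max, looks=(10, n_max), prior=flat_prior(),
        )
        pi = prediction_of_satisfaction(InterimData(10, z), design)
        assert pi == pytest.approx(expected, abs=1e-7)

    def test_matches_exhaustive_path_enumeration(self):
        """Eq-style predictive average equals a full enumeration over future sequences."""
        for prior, z, n, n_max in [
            (flat_prior(), 2, 15, 27),
            (BetaPrior(49.5, 49.5), 4, 17, 27),
            (BetaPrior(2.5, 7.5), 0, 8, 20),
        ]:
            design = TrialDesign(
                theta0=0.3, theta1=0.5, alpha=0.10, power_target=0.8, gamma=0.5,
                n_max=n_max, looks=(n, n_max), prior=prior,
            )
            t = efficacy_threshold(n_max, 0.3, 0.10)
            oracle = ps_enumeration(z, n, n_max, 0.3, t.t_eff, prior.a, prior.b)
            ours = prediction_of_satisfaction(InterimData(n, z), design)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_unreachable_threshold_gives_zero(self, table1_design_27):
        # at n=25 of 27 with z=0, two remaining patients cannot reach t_eff=11
        d = TrialDesign(
            theta0=0.3, theta1=0.5, alpha=0.10, power_target=0.8, gamma=0.5,
            n_max=27, looks=(25, 27), prior=flat_prior(),
        )
        assert prediction_of_satisfaction(InterimData(25, 0), d) == 0.0

    def test_null_rate_zero_gives_certainty(self):
        d = TrialDesign(
            theta0=1e-12, theta1=0.5, alpha=0.10, power_target=0.8, gamma=0.5,
            n_max=20, looks=(5, 20), prior=flat_prior(),
        )
        # t_eff=0 and the cdf weights are ~1: the whole predictive mass counts
        assert prediction_of_satisfaction(InterimData(5, 0), d) == pytest.approx(1.0, abs=1e-9)

    def test_completed_trial_rejected(self, table1_design_27):
        with pytest.raises(ValueError, match="satisfaction_index"):
            prediction_of_satisfaction(InterimData(27, 12), table1_design_27)

    @given(n=st.integers(5, 20), data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_monotone_nondecreasing_in_z(self, n, data):
        n_max = data.draw(st.integers(n + 1, 40))
        design = TrialDesign(
            theta0=0.3, theta1=0.5, alpha=0.10, power_target=0.8, gamma=0.5,
            n_max=n_max, looks=(n, n_max), prior=flat_prior(),
        )
        vals = [prediction_of_satisfaction(InterimData(n, z), design) for z in range(n + 1)]
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in vals)
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_literal_dialect_differs_and_is_smaller(self, table1_design_27):
        lit = TrialDesign(
            theta0=0.3, theta1=0.5, alpha=0.10, power_target=0.8, gamma=0.5,
            n_max=27, looks=(10, 27), prior=flat_prior(), dialect="literal",
        )
        z = InterimData(10, 3)
        assert prediction_of_satisfaction(z, lit) < prediction_of_satisfaction(
            z, table1_design_27
        )


class TestPsTable:
    def test_columns_monotone_and_published_cells(self, table1_design_27, informative_prior):
        scenarios = [
            ("flat27", flat_prior(), 27),
            ("inf27", informative_prior, 27),
        ]
        tab = ps_table(table1_design_27, 10, scenarios)
        assert list(tab.index) == list(range(11))
        for col in tab:
            assert tab[col].is_monotonic_increasing
            assert tab[col].iloc[10] >= tab[col].iloc[0]
        assert tab.loc[2, "flat27"] == pytest.approx(0.07231145, abs=1e-7)

    def test_interim_must_precede_final(self, table1_design_27):
        with pytest.raises(ValueError):
            ps_table(table1_design_27, 27)
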