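import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kmopt.lifetable import (
    CensorVector,
    CurvePoints,
    InfeasibleTableError,
    LifeTable,
    build_life_table,
    chisq_to_p,
    events_from_survival,
    expected_events,
    km_step,
    p_to_chisq,
    summarise,
)


class TestKMStep:
    @pytest.mark.parametrize(
        "s_prev, e, n, expected",
        [(1.0, 0, 10, 1.0), (1.0, 2, 10, 0.8), (0.8, 4, 8, 0.4)],
    )
    def test_product_limit_step(self, s_prev, e, n, expected):
        assert km_step(s_prev, e, n) == pytest.approx(expected)

    def test_events_without_risk_set_is_domain_error(self):
        with pytest.raises(ValueError):
            km_step(1.0, 2, 0)

    @pytest.mark.parametrize(
        "n, s, s_prev, expected",
        [(10, 0.8, 1.0, 2.0), (50, 0.5, 0.5, 0.0), (8, 0.4, 0.8, 4.0)],
    )
    def test_inversion(self, n, s, s_prev, expected):
        assert events_from_survival(n, s, s_prev) == pytest.approx(expected)

    def test_inversion_from_zero_survival_is_domain_error(self):
        with pytest.raises(ValueError):
            events_from_survival(10, 0.0, 0.0)

    @given(
        n=st.floats(min_value=0.5, max_value=500),
        frac=st.floats(min_value=0.0, max_value=1.0),
        s_prev=st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_round_trip_recovers_events(self, n, frac, s_prev):
        e = n * frac
        s = km_step(s_prev, e, n)
        assert events_from_survival(n, s, s_prev) == pytest.approx(e, abs=1e-10)


class TestBuildLifeTable:
    def test_zero_censoring_recursion(self):
        points = CurvePoints([0, 1, 2], [1, 0.8, 0.4], [1, 0.8, 0.4])
        table = build_life_table(points, CensorVector.zeros(3), 10, 10)
        np.testing.assert_allclose(table.e1, [0, 2, 4])
        np.testing.assert_allclose(table.n1, [10, 10, 8])

    def test_flat_curves_give_no_events(self):
        points = CurvePoints([0, 1, 2], [1, 1, 1], [1, 1, 1])
        censors = CensorVector([0, 1, 2], [0, 0.5, 1])
        table = build_life_table(points, censors, 10, 10)
        np.testing.assert_allclose(table.e1, 0, atol=1e-12)
        np.testing.assert_allclose(table.e2, 0, atol=1e-12)

    def test_censoring_depletes_next_risk_set(self):
        points = CurvePoints([0, 1, 2], [1, 0.8, 0.4], [1, 1, 1])
        censors = CensorVector([0, 2, 0], [0, 0, 0])
        table = build_life_table(points, censors, 10, 10)
        # n(t2) = 10 - (e1 + c1) = 10 - (2 + 2)
        assert table.n1[2] == pytest.approx(6)
        assert table.e1[2] == pytest.approx(6 * (1 - 0.4 / 0.8))

    def test_overcensoring_raises_when_strict(self):
        points = CurvePoints([0, 1, 2], [1, 0.8, 0.4], [1, 0.8, 0.4])
        censors = CensorVector([0, 20, 0], [0, 0, 0])
        with pytest.raises(InfeasibleTableError):
            build_life_table(points, censors, 10, 10)
        relaxed = build_life_table(points, censors, 10, 10, strict=False)
        assert relaxed.n1[2] < 0  # smooth extension, no exception

    @given(
        drops=st.lists(
            st.floats(min_value=0.0, max_value=0.2), min_size=2, max_size=8
        ),
        n0=st.integers(min_value=10, max_value=500),
    )
    def test_no_censoring_identity(self, drops, n0):
        """Without censoring, e_j = N * (S_{j-1} - S_j) exactly."""
        s = np.concatenate([[1.0], 1.0 - np.cumsum(drops)])
        s = np.clip(s, 0.0, 1.0)
        times = np.arange(s.size, dtype=float)
        points = CurvePoints(times, s, s)
        table = build_life_table(points, CensorVector.zeros(s.size), n0, n0)
        np.testing.assert_allclose(table.e1, n0 * -np.diff(s, prepend=1.0), atol=1e-8)

    def test_zero_survival_final_consumes_all_at_risk(self):
        points = CurvePoints([0, 1, 2], [1, 0.5, 0.0], [1, 0.5, 0.5])
        table = build_life_table(points, CensorVector.zeros(3), 10, 10)
        assert table.e1[2] == pytest.approx(table.n1[2])


class TestExpectedEvents:
    @pytest.mark.parametrize(
        "n1, n2, e_total, exp1, exp2",
        [(10, 10, 2, 1, 1), (30, 10, 4, 3, 1), (10, 10, 0, 0, 0)],
    )
    def test_proportional_allocation(self, n1, n2, e_total, exp1, exp2):
        table = LifeTable(
            times=np.array([0.0, 1.0]),
            n1=np.array([n1, n1], dtype=float),
            e1=np.array([0.0, e_total / 2]),
            c1=np.zeros(2),
            n2=np.array([n2, n2], dtype=float),
            e2=np.array([0.0, e_total / 2]),
            c2=np.zeros(2),
            n1_0=n1,
            n2_0=n2,
        )
        out = expected_events(table)
        assert out.exp1[1] == pytest.approx(exp1)
        assert out.exp2[1] == pytest.approx(exp2)

    def test_events_with_empty_risk_set_rejected(self):
        table = LifeTable(
            times=np.array([0.0, 1.0]),
            n1=np.array([0.0, 0.0]),
            e1=np.array([0.0, 1.0]),
            c1=np.zeros(2),
            n2=np.array([0.0, 0.0]),
            e2=np.zeros(2),
            c2=np.zeros(2),
            n1_0=1,
            n2_0=1,
        )
        with pytest.raises(ValueError):
            expected_events(table)


def _table_with_totals(o1, e1_exp, o2, e2_exp):
    return LifeTable(
        times=np.array([0.0, 1.0]),
        n1=np.array([50.0, 50.0]),
        e1=np.array([0.0, o1]),
        c1=np.zeros(2),
        n2=np.array([50.0, 50.0]),
        e2=np.array([0.0, o2]),
        c2=np.zeros(2),
        n1_0=50,
        n2_0=50,
        exp1=np.array([0.0, e1_exp]),
        exp2=np.array([0.0, e2_exp]),
    )


class TestSummarise:
    def test_observed_equals_expected_is_null(self):
        stats = summarise(_table_with_totals(5, 5, 5, 5))
        assert stats.hr == pytest.approx(1.0)
        assert stats.ln_hr == pytest.approx(0.0)
        assert stats.chi_sq == pytest.approx(0.0)
        assert stats.p_achieved == pytest.approx(1.0)

    def test_worked_example(self):
        stats = summarise(_table_with_totals(10, 5, 5, 10))
        assert stats.hr == pytest.approx(4.0)
        assert stats.chi_sq == pytest.approx(25 / 5 + 25 / 10)

    def test_variance_conventions(self):
        stats = summarise(_table_with_totals(8, 10, 12, 10))
        assert stats.var_ln_hr == pytest.approx(0.2)
        obs = summarise(_table_with_totals(8, 10, 12, 10), variance="observed")
        assert obs.var_ln_hr == pytest.approx(1 / 8 + 1 / 12)

    def test_degenerate_arm_signals_infinite_ln_hr(self):
        stats = summarise(_table_with_totals(0, 2, 4, 2))
        assert stats.hr == 0.0
        assert stats.ln_hr == -np.inf

    def test_conservation_after_allocation(self, cohort100):
        from kmopt.synthetic import oracle_table

        points, censors, _, _ = oracle_table(cohort100)
        table = expected_events(
            build_life_table(points, censors, cohort100.n1, cohort100.n2)
        )
        stats = summarise(table)
        assert stats.o1 + stats.o2 == pytest.approx(stats.e1 + stats.e2, abs=1e-8)


class TestChiSquareQuantile:
    def test_significance_boundary(self):
        assert p_to_chisq(0.05) == pytest.approx(3.841, abs=5e-4)

    def test_upper_bracket_boundary(self):
        assert p_to_chisq(0.95) == pytest.approx(3.9e-3, rel=0.05)

    def test_whole_mass(self):
        assert p_to_chisq(1.0) == 0.0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            p_to_chisq(bad)

    @given(p=st.floats(min_value=1e-10, max_value=1.0))
    def test_exact_inverse_of_survival_function(self, p):
        assert chisq_to_p(p_to_chisq(p)) == pytest.approx(p, abs=1e-10)

    def test_strictly_decreasing(self):
        ps = np.linspace(0.01, 1.0, 50)
        xs = [p_to_chisq(p) for p in ps]
        assert all(a > b for a, b in zip(xs, xs[1:]))
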