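"""Behaviour-trait derivation, correlations, rank stability and the
interaction matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penmates.behaviour import (aggregate_traits, derive_daily_traits,
                                interaction_matrix, pair_distance,
                                phenotypic_correlations, rank_stability,
                                standardize)
from penmates.simulate import (SimulationParams, default_behaviour_correlations,
                               simulate_behaviour)


def _visits(rows):
    return pd.DataFrame(rows, columns=["animal", "pen", "start",
                                       "duration_min", "intake_g"])


class TestDailyTraits:
    def test_single_visit_day(self):
        daily = derive_daily_traits(_visits(
            [("a", "p", "2012-01-01 09:00", 10.0, 200.0)]))
        row = daily.iloc[0]
        assert row.FF == 1 and row.OT == 10.0 and row.FR == 20.0
        assert np.isnan(row.FInt)

    def test_two_visit_arithmetic(self):
        daily = derive_daily_traits(_visits(
            [("a", "p", "2012-01-01 09:00", 10.0, 200.0),
             ("a", "p", "2012-01-01 10:00", 5.0, 100.0)]))
        row = daily.iloc[0]
        assert row.FF == 2 and row.OT == 15.0 and row.FR == 20.0
        assert row.FInt == 50.0  # gap from 09:10 to 10:00

    def test_bad_records_rejected_with_warning(self):
        with pytest.warns(UserWarning, match="rejected"):
            daily = derive_daily_traits(_visits(
                [("a", "p", "2012-01-01 09:00", -5.0, 100.0),
                 ("a", "p", "2012-01-01 10:00", 10.0, 100.0)]))
        assert daily.iloc[0].FF == 1

    def test_sub_minute_reentry_same_hour_block_merged(self):
        daily = derive_daily_traits(_visits(
            [("a", "p", "2012-01-01 09:00", 4.0, 100.0),
             ("a", "p", "2012-01-01 09:04:30", 4.0, 100.0),   # 30 s gap
             ("a", "p", "2012-01-01 09:30", 4.0, 100.0)]))    # distinct
        assert daily.iloc[0].FF == 2
        assert daily.iloc[0].OT == 12.0

    def test_empty_day_not_counted(self):
        daily = derive_daily_traits(_visits(
            [("a", "p", "2012-01-01 09:00", 10.0, 200.0),
             ("a", "p", "2012-01-03 09:00", 10.0, 200.0)]))
        assert len(daily) == 2  # Jan 2 yields no row


class TestAggregate:
    def test_mean_of_constants_and_two_days(self):
        daily = pd.DataFrame({
            "animal": ["a", "a"], "date": pd.to_datetime(
                ["2012-01-01", "2012-01-02"]),
            "FF": [4, 6], "OT": [30.0, 30.0], "FR": [20.0, 20.0],
            "FInt": [40.0, 50.0]})
        out = aggregate_traits(daily, "overall")
        assert out.iloc[0].FF == 5 and out.iloc[0].OT == 30.0
        assert out.iloc[0].FInt == 45.0
        assert out.iloc[0].days_observed == 2

    def test_ten_weeks_make_five_periods(self):
        dates = pd.date_range("2012-01-02", periods=70, freq="D")
        daily = pd.DataFrame({"animal": "a", "date": dates, "FF": 5,
                              "OT": 30.0, "FR": 20.0, "FInt": 40.0})
        out = aggregate_traits(daily, "period")
        assert sorted(out["period"]) == [0, 1, 2, 3, 4]
        assert (out["days_observed"] == 14).all()

    def test_absent_animal_missing_not_zero(self):
        daily = pd.DataFrame({
            "animal": ["a", "b"],
            "date": pd.to_datetime(["2012-01-01", "2012-02-01"]),
            "FF": [5, 5], "OT": [30.0, 30.0], "FR": [20.0, 20.0],
            "FInt": [40.0, 40.0]})
        out = aggregate_traits(daily, "period")
        assert len(out) == 2  # no zero-filled (animal, period) cells


class TestCorrelations:
    def test_self_and_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        tab = pd.DataFrame({"animal": range(50), "FR": x, "FF": -x,
                            "OT": rng.normal(size=50),
                            "FInt": rng.normal(size=50)})
        R = phenotypic_correlations(tab)
        assert R.loc["FR", "FR"] == pytest.approx(1.0)
        assert R.loc["FR", "FF"] == pytest.approx(-1.0)

    def test_target_correlation_recovered_at_n5000(self):
        # sampling error bound from Fisher z at n = 5000 is ~0.02
        rng = np.random.default_rng(1)
        R = default_behaviour_correlations().to_numpy()
        Z = rng.standard_normal((5000, 4)) @ np.linalg.cholesky(R).T
        tab = pd.DataFrame(Z, columns=["FR", "FF", "OT", "FInt"])
        tab.insert(0, "animal", range(5000))
        est = phenotypic_correlations(tab).loc["FR", "FF"]
        assert abs(est - 0.56) < 0.03


class TestRankStability:
    def test_identical_and_reversed_ranks(self):
        base = pd.DataFrame({"animal": range(10), "period": 0,
                             "FR": np.arange(10.0), "FF": np.arange(10.0),
                             "OT": np.arange(10.0), "FInt": np.arange(10.0)})
        nxt = base.assign(period=1)
        rho = rank_stability(pd.concat([base, nxt]))
        assert np.allclose(rho.loc[(0, 1)], 1.0)
        rev = base.assign(period=1, FR=base.FR[::-1].values)
        rho = rank_stability(pd.concat([base, rev]))
        assert rho.loc[(0, 1), "FR"] == pytest.approx(-1.0)

    def test_persistent_trait_lands_in_band(self):
        params = SimulationParams(behaviour_persistence=0.75, seed=9)
        periods, _ = simulate_behaviour(params, [f"a{i}" for i in range(600)],
                                        np.random.default_rng(9))
        rho = rank_stability(periods)
        assert ((rho > 0.6) & (rho < 0.9)).all().all()


class TestStandardize:
    def test_basic_and_idempotent(self):
        z = standardize([1.0, 2.0, 3.0])
        assert np.allclose(z, [-np.sqrt(1.5), 0, np.sqrt(1.5)])
        assert np.allclose(z.mean(), 0) and np.allclose(z.std(), 1)
        assert np.allclose(standardize(z), z)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize([2.0, 2.0, 2.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    def test_moments_property(self, xs):
        xs = np.asarray(xs)
        if xs.std() < 1e-6:
            return
        z = standardize(xs)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1) < 1e-9


class TestPairDistance:
    @pytest.mark.parametrize("zi,zj,expected", [
        (1.0, -1.0, 2.0),
        ([1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0], 1.0),
        ([1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0], 2.0),
        ([0.3, -0.7], [0.3, -0.7], 0.0),
    ])
    def test_examples(self, zi, zj, expected):
        assert pair_distance(zi, zj) == pytest.approx(expected)

    def test_missing_component_errors(self):
        with pytest.raises(ValueError, match="missing"):
            pair_distance([1.0, np.nan], [0.0, 0.0])


class TestInteractionMatrix:
    def test_classical_blocks_and_row_sums(self):
        pens = pd.Series({1: "A", 2: "A", 3: "A", 4: "B", 5: "B"})
        C = interaction_matrix(pd.DataFrame(), pens, "CLASSICAL")
        i1 = C.position(1)
        row = C.C[i1]
        assert row[C.position(2)] == 1 and row[C.position(3)] == 1
        assert row[C.position(4)] == 0 and row[C.position(5)] == 0
        # each animal interacts with pen size - 1 mates
        sums = C.C.sum(axis=1)
        expected = pens.map(pens.value_counts()).to_numpy() - 1
        assert np.array_equal(sums, expected)

    def test_hand_computed_two_pen_example(self):
        # single-trait records (0, 1 | 0, 3): within-pen distances are
        # proportional to (1, 3) after global standardization, so the
        # standardized degrees are exactly (-1, +1)
        traits = pd.DataFrame({"animal": [1, 2, 3, 4],
                               "OT": [0.0, 1.0, 0.0, 3.0]})
        pens = pd.Series({1: "A", 2: "A", 3: "B", 4: "B"})
        C = interaction_matrix(traits, pens, "OT")
        assert C.C[C.position(1), C.position(2)] == pytest.approx(-1.0)
        assert C.C[C.position(3), C.position(4)] == pytest.approx(1.0)

    def test_standardized_mode_invariants(self):
        rng = np.random.default_rng(5)
        n = 60
        traits = pd.DataFrame({
            "animal": range(n), "FR": rng.normal(25, 5, n),
            "FF": rng.normal(12, 4, n), "OT": rng.normal(80, 18, n),
            "FInt": rng.normal(60, 20, n)})
        pens = pd.Series({i: f"p{i % 5}" for i in range(n)})
        for mode in ("FR", "ALL"):
            C = interaction_matrix(traits, pens, mode)
            entries = C.within_pen_pairs()
            assert abs(entries.mean()) < 1e-9
            assert abs(entries.std() - 1.0) < 1e-9
            assert np.allclose(C.C, C.C.T)
            assert np.allclose(np.diag(C.C), 0.0)
            # cross-pen blocks are exactly zero
            for i in range(n):
                for j in range(n):
                    if pens[i] != pens[j]:
                        assert C.C[C.position(i), C.position(j)] == 0.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        n = 24
        traits = pd.DataFrame({"animal": range(n),
                               "OT": rng.normal(80, 18, n)})
        pens = pd.Series({i: f"p{i % 3}" for i in range(n)})
        C1 = interaction_matrix(traits, pens, "OT")
        perm = rng.permutation(n)
        C2 = interaction_matrix(traits.iloc[perm], pens.iloc[perm], "OT")
        for i in range(n):
            for j in range(n):
                assert C1.C[C1.position(i), C1.position(j)] == pytest.approx(
                    C2.C[C2.position(i), C2.position(j)])

    def test_missing_trait_hard_error_and_fallback(self):
        traits = pd.DataFrame({"animal": [1, 2, 3, 4, 5, 6],
                               "OT": [80.0, 90.0, np.nan, 85.0, 70.0, 95.0]})
        pens = pd.Series({1: "A", 2: "A", 3: "B", 4: "B", 5: "C", 6: "C"})
        with pytest.raises(ValueError, match="missing behaviour"):
            interaction_matrix(traits, pens, "OT")
        C = interaction_matrix(traits, pens, "OT", fallback_classical=True)
        assert C.C[C.position(3), C.position(4)] == 1.0
        assert C.C[C.position(1), C.position(2)] != 1.0
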