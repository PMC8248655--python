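"""Baseline medians and PPP score decomposition."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselppp import (
    Baseline,
    BaselineError,
    MedianPolicy,
    ScoringError,
    VesselType,
    compute_baseline,
    default_params,
    score_arrival,
    score_batch,
)
from vesselppp.wetted_area import arrival_twsa

from conftest import arrival


def make_baseline(med_bwd=1000.0, med_twsa=10_000.0, policy=MedianPolicy()):
    return Baseline(
        med_bwd=med_bwd, med_twsa=med_twsa,
        window_start=dt.date(2015, 1, 1), window_end=dt.date(2017, 12, 31),
        n_arrivals=100, n_discharging=40, policy=policy,
    )


class TestComputeBaseline:
    def test_discharge_median_over_discharging_only(self):
        pop = [arrival(i, bwd=b) for i, b in enumerate([0, 0, 500, 1000, 1500])]
        b = compute_baseline(pop)
        assert b.med_bwd == 1000
        assert b.n_arrivals == 5
        assert b.n_discharging == 3

    def test_twsa_median_is_odd_count_median(self, params_table):
        pop = [
            arrival(1, gt=10_000, bwd=100),
            arrival(2, gt=50_000, bwd=100),
            arrival(3, gt=90_000, bwd=100),
        ]
        b = compute_baseline(pop)
        assert b.med_twsa == arrival_twsa(pop[1], params_table)

    def test_even_count_median_is_midpoint(self):
        pop = [arrival(i, bwd=b) for i, b in enumerate([100, 200, 300, 400])]
        assert compute_baseline(pop).med_bwd == 250

    def test_all_zero_discharges_error_names_policy(self):
        pop = [arrival(i, bwd=0.0) for i in range(4)]
        with pytest.raises(BaselineError, match="discharging"):
            compute_baseline(pop)

    def test_all_policy_uses_every_arrival(self):
        pop = [arrival(i, bwd=b) for i, b in enumerate([0, 400, 600, 800, 900])]
        b = compute_baseline(pop, MedianPolicy(discharge="all"))
        assert b.med_bwd == 600

    def test_all_policy_zero_median_errors(self):
        pop = [arrival(i, bwd=b) for i, b in enumerate([0, 0, 0, 500, 900])]
        with pytest.raises(BaselineError, match="positive median"):
            compute_baseline(pop, MedianPolicy(discharge="all"))

    def test_empty_population(self):
        with pytest.raises(BaselineError, match="empty"):
            compute_baseline([])

    def test_per_vessel_basis_collapses_repeat_visits(self):
        # vessel V1 visits 3 times with large discharges; per-vessel basis
        # counts it once via its own median.
        pop = (
            [arrival(i, bwd=9000, vessel="V1") for i in range(3)]
            + [arrival(10, bwd=100, vessel="V2"),
               arrival(11, bwd=200, vessel="V3"),
               arrival(12, bwd=300, vessel="V4")]
        )
        per_arrival = compute_baseline(pop).med_bwd
        per_vessel = compute_baseline(
            pop, MedianPolicy(basis="vessel")
        ).med_bwd
        assert per_arrival == 4650  # midpoint of 300 and 9000
        assert per_vessel == 250  # median of {9000, 100, 200, 300}

    def test_window_is_population_date_range(self):
        pop = [
            arrival(1, bwd=100, date=dt.date(2015, 2, 3)),
            arrival(2, bwd=100, date=dt.date(2017, 11, 30)),
        ]
        b = compute_baseline(pop)
        assert (b.window_start, b.window_end) == (dt.date(2015, 2, 3),
                                                  dt.date(2017, 11, 30))

    def test_roundtrip_json(self, tmp_path):
        pop = [arrival(i, bwd=100 * (i + 1)) for i in range(5)]
        b = compute_baseline(pop)
        path = tmp_path / "baseline.json"
        b.to_json(path)
        assert Baseline.from_json(path) == b


class TestScoreArrival:
    def test_score_is_two_at_both_medians(self, params_table):
        a = arrival(1, "container", gt=50_000, bwd=800.0)
        twsa = arrival_twsa(a, params_table)
        b = make_baseline(med_bwd=800.0, med_twsa=twsa)
        s = score_arrival(a, b)
        assert s.ppp_score == pytest.approx(2.0, rel=1e-12)
        assert s.bw_component == pytest.approx(1.0)
        assert s.bf_component == pytest.approx(1.0)

    def test_zero_discharge_scores_biofouling_alone(self):
        s = score_arrival(arrival(1, bwd=0.0), make_baseline())
        assert s.bw_component == 0.0
        assert s.ppp_score == s.bf_component

    def test_hand_arithmetic_example(self, params_table):
        # BWD 2000 / med 800 = 2.5; TWSA 12094 / med 8000 = 1.51175
        # composite arrival whose component WSAs give TWSA exactly 12094
        barge = 10_000.0
        tug = (12_094.0 - barge * 1.033) / 1.25
        a = arrival(1, "atb", bwd=2000.0,
                    precomputed_wsa=barge, tug_precomputed_wsa=tug)
        s = score_arrival(a, make_baseline(med_bwd=800.0, med_twsa=8000.0))
        assert s.twsa == pytest.approx(12_094.0, rel=1e-12)
        assert s.ppp_score == pytest.approx(4.01175, rel=1e-12)

    def test_score_components_always_sum(self):
        s = score_arrival(arrival(1, bwd=1234.5), make_baseline())
        assert s.ppp_score == s.bw_component + s.bf_component

    def test_unresolvable_arrival_raises_scoring_error_with_id(self):
        a = arrival(7, "container", gt=10_000, bwd=0.0)
        table = {k: v for k, v in default_params().items()
                 if k != VesselType.CONTAINER}
        with pytest.raises(ScoringError) as exc:
            score_arrival(a, make_baseline(), table=table)
        assert exc.value.arrival_id == "A0007"

    @given(scale=st.floats(0.01, 100))
    @settings(deadline=None)
    def test_scale_invariance_of_components(self, scale):
        # multiplying all discharges (arrival and median) by c changes nothing
        a = arrival(1, bwd=1500.0)
        s1 = score_arrival(a, make_baseline(med_bwd=750.0))
        a2 = arrival(1, bwd=1500.0 * scale)
        s2 = score_arrival(a2, make_baseline(med_bwd=750.0 * scale))
        assert s2.bw_component == pytest.approx(s1.bw_component, rel=1e-12)

    def test_strictly_increasing_in_discharge_and_tonnage(self):
        b = make_baseline()
        s_low = score_arrival(arrival(1, gt=30_000, bwd=100.0), b)
        s_hi_bwd = score_arrival(arrival(1, gt=30_000, bwd=200.0), b)
        s_hi_gt = score_arrival(arrival(1, gt=60_000, bwd=100.0), b)
        assert s_hi_bwd.ppp_score > s_low.ppp_score
        assert s_hi_gt.ppp_score > s_low.ppp_score

    def test_pure_function_bit_identical(self):
        a = arrival(1, bwd=321.0)
        b = make_baseline()
        assert score_arrival(a, b) == score_arrival(a, b)


class TestScoreBatch:
    def test_empty_batch(self):
        res = score_batch([], make_baseline())
        assert res.scored == [] and res.failures == []

    def test_identical_arrivals_identical_scores(self):
        batch = [arrival(1, bwd=500.0)] * 3
        res = score_batch(batch, make_baseline())
        assert len({s.ppp_score for s in res.scored}) == 1

    def test_order_preserving_and_failures_collected(self):
        table = {k: v for k, v in default_params().items()
                 if k != VesselType.TANKER}
        batch = [
            arrival(1, "container", bwd=100.0),
            arrival(2, "tanker", bwd=100.0),
            arrival(3, "bulker", bwd=100.0),
        ]
        res = score_batch(batch, make_baseline(), table=table)
        assert [s.arrival_id for s in res.scored] == ["A0001", "A0003"]
        assert [f.arrival_id for f in res.failures] == ["A0002"]

    def test_strict_mode_raises_first_failure(self):
        table = {k: v for k, v in default_params().items()
                 if k != VesselType.TANKER}
        batch = [arrival(2, "tanker", bwd=100.0)]
        with pytest.raises(ScoringError):
            score_batch(batch, make_baseline(), table=table, strict=True)

    def test_median_biofouling_component_is_one_on_own_population(
        self, toy_population, params_table
    ):
        b = compute_baseline(toy_population)
        res = score_batch(toy_population, b)
        bfs = sorted(s.bf_component for s in res.scored)
        assert bfs[len(bfs) // 2] == pytest.approx(1.0, rel=1e-12)
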