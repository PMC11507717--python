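"""Behavioral metrics: occupancy, rate constants, latency, half-evacuation."""

import numpy as np
import pytest

import lawnscreen as ls
from lawnscreen.behavior import OccupancyCurve, WormEventLog

H = 3600.0


def make_log(events, worm="w0", duration_h=18.0, condition="exposed"):
    return WormEventLog(worm_id=worm, line_id="N2", condition=condition,
                        events=tuple(events), duration_s=duration_h * H)


class TestEventLogValidation:
    def test_rejects_entry_before_contact(self):
        with pytest.raises(ValueError, match="w0.*illegal event"):
            make_log([(10.0, "exit"), (20.0, "entry")])

    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_log([(10.0, "exit"), (10.0, "contact")])

    def test_rejects_event_after_duration(self):
        with pytest.raises(ValueError, match="beyond assay end"):
            make_log([(19 * H, "exit")])

    def test_state_walk(self):
        log = make_log([(1 * H, "exit"), (2 * H, "contact"), (3 * H, "entry")])
        assert log.state_at(0.5 * H) == "on_lawn"
        assert log.state_at(1.5 * H) == "off_lawn"
        assert log.state_at(2.5 * H) == "at_edge"
        assert log.state_at(3.5 * H) == "on_lawn"


class TestOccupancy:
    def test_no_events_full_occupancy(self):
        logs = [make_log([], worm=f"w{i}") for i in range(10)]
        curve = ls.compute_occupancy(logs)
        assert (curve.fraction_on == 1.0).all()
        assert curve.n_worms == 10

    def test_single_exit_steps_to_zero(self):
        curve = ls.compute_occupancy([make_log([(1 * H, "exit")])])
        assert (curve.fraction_on[curve.times < 1.0] == 1.0).all()
        assert (curve.fraction_on[curve.times >= 1.0] == 0.0).all()

    def test_edge_state_counts_off_lawn_by_default(self):
        log = make_log([(1 * H, "exit"), (2 * H, "contact")])
        on = ls.compute_occupancy([log], edge_counts_as_on=False)
        assert on.fraction_on[on.times >= 2.0].max() == 0.0
        edge_on = ls.compute_occupancy([log], edge_counts_as_on=True)
        assert (edge_on.fraction_on[edge_on.times >= 2.0] == 1.0).all()

    def test_adding_resident_worm_raises_curve(self):
        logs = ls.simulate_event_logs(ls.BehaviorRegime.pathogen(), 10, 12.0,
                                      seed=4)
        base = ls.compute_occupancy(logs)
        more = ls.compute_occupancy(logs + [make_log([], duration_h=12.0)])
        assert (more.fraction_on >= base.fraction_on - 1e-12).all()

    def test_empty_and_inconsistent_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            ls.compute_occupancy([])
        with pytest.raises(ValueError, match="inconsistent"):
            ls.compute_occupancy([make_log([], duration_h=10.0),
                                  make_log([], duration_h=12.0)])


class TestEventRate:
    def test_no_events_zero_rate(self):
        logs = [make_log([], worm=f"w{i}") for i in range(5)]
        assert ls.event_rate_constant(logs, "exit", (0, 18)).value == 0.0

    def test_definition_arithmetic(self):
        # 10 worms, 4 exits in a 2 h window -> 0.2 exits/worm-hour
        logs = [make_log([((10.0 + 0.1 * i) * H, "exit")], worm=f"w{i}")
                for i in range(4)]
        logs += [make_log([], worm=f"q{i}") for i in range(6)]
        est = ls.event_rate_constant(logs, "exit", (10.0, 12.0))
        assert est.value == pytest.approx(0.2)
        assert est.n_events == 4 and est.n_worms == 10

    def test_one_event_per_worm_per_bin(self):
        # two exits 40 s apart fall in one 1-min bin and count once
        log = make_log([(600.0, "exit"), (610.0, "contact"), (620.0, "entry"),
                        (640.0, "exit")])
        est = ls.event_rate_constant([log], "exit", (0.0, 1.0))
        assert est.n_events == 1
        wide = ls.event_rate_constant([log], "exit", (0.0, 1.0), bin_min=0.1)
        assert wide.n_events == 2

    def test_relabeling_invariance(self):
        logs = ls.simulate_event_logs(ls.BehaviorRegime.pathogen(), 8, 12.0,
                                      seed=0)
        relabeled = [WormEventLog(worm_id=f"x{i}", line_id=log.line_id,
                                  condition=log.condition, events=log.events,
                                  duration_s=log.duration_s)
                     for i, log in enumerate(logs)]
        a = ls.event_rate_constant(logs, "exit", (4, 12))
        b = ls.event_rate_constant(relabeled, "exit", (4, 12))
        assert a.value == b.value

    def test_additive_over_disjoint_windows(self):
        logs = ls.simulate_event_logs(ls.BehaviorRegime.pathogen(), 20, 18.0,
                                      seed=1)
        whole = ls.event_rate_constant(logs, "exit", (6, 18))
        left = ls.event_rate_constant(logs, "exit", (6, 12))
        right = ls.event_rate_constant(logs, "exit", (12, 18))
        assert whole.value == pytest.approx((left.value * 6 + right.value * 6) / 12)

    def test_window_outside_assay(self):
        with pytest.raises(ValueError, match="window"):
            ls.event_rate_constant([make_log([])], "exit", (10, 20))

    def test_plateau_estimator_unbiased_at_large_n(self):
        # renewal-model prediction: ~1 exit per (total) worm-hour late in
        # the assay under the pathogen default
        logs = ls.simulate_event_logs(ls.BehaviorRegime.pathogen(), 500, 18.0,
                                      seed=11)
        est = ls.event_rate_constant(logs, "exit", (10.0, 18.0))
        assert est.value == pytest.approx(1.0, abs=0.08)


class TestLatency:
    def test_single_pair(self):
        log = make_log([(50.0, "exit"), (100.0, "contact"), (160.0, "entry")])
        summary = ls.latency_to_reentry([log])
        assert summary.latencies_min == pytest.approx([1.0])
        assert summary.n_censored == 0

    def test_censored_contact_reported_separately(self):
        log = make_log([(50.0, "exit"), (100.0, "contact")])
        summary = ls.latency_to_reentry([log])
        assert summary.n == 0 and summary.n_censored == 1
        assert np.isnan(summary.mean_min)

    def test_shift_invariance(self):
        ev = [(1000.0, "exit"), (1100.0, "contact"), (1500.0, "entry")]
        shifted = [(t + 7200.0, k) for t, k in ev]
        a = ls.latency_to_reentry([make_log(ev)])
        b = ls.latency_to_reentry([make_log(shifted)])
        assert np.array_equal(a.latencies_min, b.latencies_min)

    def test_per_worm_mean_aggregation(self):
        w1 = make_log([(100.0, "exit"), (200.0, "contact"), (260.0, "entry"),
                       (400.0, "exit"), (500.0, "contact"), (680.0, "entry")],
                      worm="w1")
        w2 = make_log([(100.0, "exit"), (200.0, "contact"), (800.0, "entry")],
                      worm="w2")
        per_event = ls.latency_to_reentry([w1, w2], aggregate="per_event")
        per_worm = ls.latency_to_reentry([w1, w2], aggregate="per_worm_mean")
        assert per_event.n == 3
        # w1 mean (1+3)/2 = 2 min, w2 10 min
        assert sorted(per_worm.latencies_min) == pytest.approx([2.0, 10.0])

    def test_contact_window_restriction(self):
        early = make_log([(1 * H, "exit"), (1.1 * H, "contact"),
                          (1.2 * H, "entry")], worm="a")
        late = make_log([(12 * H, "exit"), (12.1 * H, "contact"),
                         (12.2 * H, "entry")], worm="b")
        summary = ls.latency_to_reentry([early, late], window=(11.0, 13.0))
        assert summary.n == 1
        assert summary.latencies_min[0] == pytest.approx(6.0)


class TestHalfOccupancy:
    def test_constant_curve_censored(self):
        curve = OccupancyCurve(times=np.arange(10.0), fraction_on=np.ones(10),
                               n_worms=5)
        assert ls.time_to_half_occupancy(curve) is None

    def test_linear_decay_crosses_at_midpoint(self):
        t = np.linspace(0, 16, 33)
        curve = OccupancyCurve(times=t, fraction_on=1 - t / 16, n_worms=10)
        assert ls.time_to_half_occupancy(curve) == pytest.approx(8.0)

    def test_requires_start_above_half(self):
        curve = OccupancyCurve(times=np.arange(3.0),
                               fraction_on=np.array([0.4, 0.3, 0.2]), n_worms=5)
        with pytest.raises(ValueError):
            ls.time_to_half_occupancy(curve)

    def test_interpolates_between_grid_points(self):
        curve = OccupancyCurve(times=np.array([0.0, 1.0, 2.0]),
                               fraction_on=np.array([1.0, 0.75, 0.25]),
                               n_worms=4)
        assert ls.time_to_half_occupancy(curve) == pytest.approx(1.5)
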