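"""Event measurement and the four-criterion acceptance filter."""

import numpy as np
import pytest

from psckit.events import (EventTable, FilterCriteria, PSCEvent,
                           filter_events, interevent_intervals, measure_event)
from psckit.kernels import rise_20_80
from psckit.simulate import (GroundTruthEvent, SimulationConfig, _tau_rise,
                             generate_event_train, render_trace)
from psckit.trace import Trace

FS = 10_000.0


def _rendered_event(amplitude=20.0, rise=1.0, onset=0.5, duration=2.0,
                    baseline=0.0):
    cfg = SimulationConfig(duration=duration, noise_sd=0.0, seed=1,
                           baseline_pA=baseline)
    ev = GroundTruthEvent(onset, amplitude, "fast", rise,
                         _tau_rise(rise, 12.0), 12.0)
    return render_trace([ev], cfg, "c"), ev


class TestMeasureEvent:
    def test_noise_free_amplitude_recovered_within_one_percent(self):
        tr, ev = _rendered_event(amplitude=20.0)
        m = measure_event(tr, int(ev.onset * FS))
        assert m.amplitude == pytest.approx(20.0, abs=0.2)

    @pytest.mark.parametrize("rise", [0.5, 1.0, 3.0])
    def test_rise_time_matches_continuous_kernel_root_finding(self, rise):
        tr, ev = _rendered_event(rise=rise)
        m = measure_event(tr, int(ev.onset * FS))
        expected = rise_20_80(ev.tau_rise_ms, ev.tau_decay_ms)
        assert m.rise_20_80 == pytest.approx(expected, abs=0.1)

    def test_halfwidth_exceeds_rise_on_clean_kernel(self):
        tr, ev = _rendered_event(rise=1.0)
        m = measure_event(tr, int(ev.onset * FS))
        assert m.halfwidth > m.rise_20_80

    def test_onset_at_trace_end_rejected(self):
        tr, _ = _rendered_event()
        with pytest.raises(ValueError):
            measure_event(tr, tr.n_samples - 1)

    def test_event_running_off_window_flagged_truncated(self):
        tr, ev = _rendered_event(onset=1.995, duration=2.0)
        m = measure_event(tr, int(1.995 * FS))
        assert m.accepted is False
        assert m.reject_reason == "truncated"

    def test_amplitude_invariant_to_baseline_offset(self):
        tr, ev = _rendered_event(amplitude=15.0)
        shifted = Trace(tr.samples - 33.0, FS)
        a = measure_event(tr, int(ev.onset * FS)).amplitude
        b = measure_event(shifted, int(ev.onset * FS)).amplitude
        assert a == pytest.approx(b, abs=1e-9)


def _event(corr=0.7, amp=10.0, rise=1.0, hw=3.0, onset=0.0, cell="c1"):
    return PSCEvent(onset, onset + 0.003, amp, rise, hw, corr, cell_id=cell)


class TestFilterEvents:
    @pytest.mark.parametrize("event,reason", [
        (_event(corr=0.5), "correlation"),
        (_event(amp=2.0), "amplitude"),          # below the 3 pA noise floor
        (_event(rise=6.0, hw=8.0), "rise_time"),  # 20-80% rise above 5 ms
        (_event(rise=2.0, hw=1.5), "halfwidth"),  # halfwidth must exceed rise
        (_event(), ""),
    ])
    def test_first_failed_criterion_recorded(self, event, reason):
        table = filter_events([event])
        row = table.frame.iloc[0]
        assert row["reject_reason"] == reason
        assert row["accepted"] == (reason == "")

    def test_toy_table_counts_accepted_events(self):
        events = [
            _event(onset=0.1),                       # accepted
            _event(onset=0.2, corr=0.55),            # correlation
            _event(onset=0.3, amp=1.0),              # amplitude
            _event(onset=0.4),                       # accepted
            _event(onset=0.5, rise=5.5, hw=7.0),     # rise time
            _event(onset=0.6),                       # accepted
            _event(onset=0.7, amp=3.5, rise=0.8),    # accepted
        ]
        table = filter_events(events)
        assert int(table.frame["accepted"].sum()) == 4

    def test_filtering_idempotent_and_order_independent(self, rng):
        events = [_event(onset=o, corr=c, amp=a, rise=r, hw=h)
                  for o, c, a, r, h in zip(
                      np.arange(0.1, 2.1, 0.1),
                      rng.uniform(0.4, 1.0, 20),
                      rng.uniform(1.0, 20.0, 20),
                      rng.uniform(0.3, 6.0, 20),
                      rng.uniform(0.5, 9.0, 20))]
        base = filter_events(events).frame
        shuffled = list(events)
        rng.shuffle(shuffled)
        again = filter_events(shuffled).frame
        assert base.equals(again)
        # accepted events stored with the invariant intact
        acc = base[base["accepted"]]
        assert (acc["halfwidth_ms"] > acc["rise_ms"]).all()

    def test_boundary_values_are_exclusive(self):
        # exactly at each threshold fails the strict inequality
        assert not filter_events([_event(corr=0.6)]).frame["accepted"].iloc[0]
        assert not filter_events([_event(amp=3.0)]).frame["accepted"].iloc[0]
        assert not filter_events([_event(rise=5.0, hw=6.0)]).frame["accepted"].iloc[0]


class TestIntereventIntervals:
    def _table(self, onsets, cell="c1"):
        return filter_events([_event(onset=o, cell=cell) for o in onsets])

    def test_successive_differences(self):
        table = self._table([0.1, 0.3, 0.9])
        assert np.allclose(interevent_intervals(table, "c1"), [0.2, 0.6])

    def test_single_event_yields_empty_with_warning(self):
        table = self._table([0.5])
        with pytest.warns(UserWarning):
            ieis = interevent_intervals(table, "c1")
        assert ieis.size == 0

    def test_poisson_train_iei_mean_matches_exponential(self):
        cfg = SimulationConfig(duration=120.0, event_rate=5.0,
                               rate_dispersion=0.0, seed=8)
        events = generate_event_train(cfg, "c1")
        table = self._table([e.onset for e in events])
        ieis = interevent_intervals(table, "c1")
        se = 0.2 / np.sqrt(ieis.size)  # exponential: sd = mean = 1/rate
        assert abs(ieis.mean() - 0.2) < 3 * se

    def test_iei_count_is_accepted_count_minus_one(self):
        table = self._table([0.1, 0.2, 0.5, 1.0, 1.7])
        assert interevent_intervals(table, "c1").size == 4


class TestEventTableIO:
    def test_csv_round_trip(self, tmp_path):
        table = filter_events([_event(onset=0.1), _event(onset=0.4, amp=2.0)])
        path = tmp_path / "events.csv"
        table.to_csv(path)
        back = EventTable.from_csv(path)
        assert back.frame["accepted"].tolist() == table.frame["accepted"].tolist()
        assert np.allclose(back.frame["amplitude_pA"], table.frame["amplitude_pA"])
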