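"""Event-triggered averaging, onset scalars, QC, and suppression."""

import numpy as np
import pytest

from visuomotor import (
    BehaviorTraces,
    BoutParams,
    Eta,
    NeuronModel,
    OnsetCriteria,
    ResponseWindows,
    baseline_subtract,
    detect_running_onsets,
    event_triggered_average,
    generate_behavior,
    insert_mismatches,
    onset_response,
    population_response,
    render_calcium,
    session_qc,
    suppression_index,
)
from visuomotor.synthetic import EventTable, SessionData


def naive_onset_scan(speed, dt, criteria):
    """Exhaustive per-sample scan for threshold crossings with the
    quiescence/persistence requirements."""
    thr = criteria.speed_threshold
    q = int(round(criteria.min_quiescence_s / dt))
    r = int(round(criteria.min_running_s / dt))
    onsets = []
    n = len(speed)
    for i in range(1, n):
        if not (speed[i] > thr and speed[i - 1] <= thr):
            continue
        if i - q < 0 or i + r > n:
            continue
        if any(speed[j] > thr for j in range(i - q, i)):
            continue
        if any(speed[j] <= thr for j in range(i, i + r)):
            continue
        onsets.append(i * dt)
    return np.asarray(onsets)


def _session_from_traces(traces, dt=0.1):
    n = traces.shape[1]
    behavior = BehaviorTraces(
        np.arange(n) * dt, np.zeros(n), np.zeros(n), "dark", dt
    )
    return SessionData(behavior, EventTable(), traces, dt)


class TestDetectRunningOnsets:
    def test_zero_speed_no_onsets(self):
        assert detect_running_onsets(np.zeros(1000), 0.1).size == 0

    def test_single_step_gives_one_onset_at_crossing(self):
        speed = np.zeros(1000)
        speed[500:] = 1.0
        onsets = detect_running_onsets(speed, 0.1)
        np.testing.assert_allclose(onsets, [50.0])

    def test_bout_trace_matches_exhaustive_scan(self):
        b = generate_behavior(600, 0.1, "dark", seed=21)
        criteria = OnsetCriteria()
        fast = detect_running_onsets(b.running_speed, 0.1, criteria)
        slow = naive_onset_scan(b.running_speed, 0.1, criteria)
        np.testing.assert_array_equal(fast, slow)

    def test_brief_blips_rejected_by_persistence(self):
        speed = np.zeros(1000)
        speed[500:503] = 1.0  # 0.3 s of running < 1 s persistence
        assert detect_running_onsets(speed, 0.1).size == 0


class TestEventTriggeredAverage:
    def test_single_event_returns_raw_snippet(self, rng):
        traces = rng.normal(0, 1, (3, 500))
        session = _session_from_traces(traces)
        eta = event_triggered_average(session, [25.0], pre_s=1.0, post_s=2.0)
        np.testing.assert_array_equal(eta.mean, traces[:, 240:271])
        assert eta.n_events == 1

    def test_opposite_snippets_cancel(self):
        traces = np.zeros((1, 400))
        traces[0, 95:125] = 1.0
        traces[0, 295:325] = -1.0
        session = _session_from_traces(traces)
        eta = event_triggered_average(session, [10.0, 30.0], pre_s=0.5, post_s=2.0)
        np.testing.assert_allclose(eta.mean, 0.0)

    def test_many_events_match_naive_loop(self, rng):
        traces = rng.normal(0, 1, (5, 3000))
        session = _session_from_traces(traces)
        times = rng.uniform(20, 280, 20)
        eta = event_triggered_average(session, times, pre_s=1.0, post_s=4.0)
        snippets = []
        for t0 in times:
            i = int(round(t0 / 0.1))
            snippets.append(traces[:, i - 10 : i + 41])
        np.testing.assert_allclose(eta.mean, np.mean(snippets, axis=0), rtol=1e-12)

    def test_out_of_bounds_events_dropped_and_counted(self, rng):
        session = _session_from_traces(rng.normal(0, 1, (2, 100)))
        eta = event_triggered_average(session, [0.2, 5.0, 9.9], pre_s=1.0, post_s=2.0)
        assert eta.n_events == 1 and eta.n_dropped == 2

    def test_error_kinds_distinguished(self, rng):
        session = _session_from_traces(rng.normal(0, 1, (2, 100)))
        with pytest.raises(ValueError):
            event_triggered_average(session, [], pre_s=1.0, post_s=2.0)
        with pytest.raises(RuntimeError):
            event_triggered_average(session, [0.1], pre_s=5.0, post_s=20.0)


class TestOnsetResponse:
    def _eta(self, mean):
        time = np.arange(-10, 41) * 0.1
        return Eta(time, mean, n_events=5)

    def test_zero_eta_gives_zero(self):
        assert onset_response(self._eta(np.zeros((2, 51))))[0] == 0.0

    def test_unit_response_window(self):
        mean = np.zeros((1, 51))
        mean[0, 11:26] = 1.0  # +0.1 .. +1.5 s
        np.testing.assert_allclose(onset_response(self._eta(mean)), [1.0])

    def test_matches_closed_form_kernel_window_mean(self):
        """A noiseless mismatch impulse of known amplitude yields a
        response equal to the window mean of the sampled exponential."""
        dt, tau, m_amp = 0.1, 0.6, 0.5
        n = 600
        behavior = BehaviorTraces(
            np.arange(n) * dt, np.zeros(n), np.zeros(n), "closed_loop", dt
        )
        events = EventTable(["mismatch"], np.array([30.0]), [{}])
        model = NeuronModel(w_run=0, w_flow=0, m_amp=m_amp, tau_ca=tau, noise_sd=0)
        session = render_calcium([model], behavior, events)
        eta = event_triggered_average(session, [30.0], pre_s=1.0, post_s=4.0)
        resp = onset_response(eta)[0]
        # impulse lands at the onset sample; window [+0.1, +1.5) = samples 1..14
        expected = np.mean([m_amp * np.exp(-k * dt / tau) for k in range(1, 15)])
        np.testing.assert_allclose(resp, expected, rtol=1e-12)

    def test_linearity_over_superposed_traces(self, rng):
        a = rng.normal(0, 1, (3, 51))
        b = rng.normal(0, 1, (3, 51))
        ra = onset_response(self._eta(a))
        rb = onset_response(self._eta(b))
        rab = onset_response(self._eta(a + b))
        np.testing.assert_allclose(rab, ra + rb, rtol=1e-10, atol=1e-12)

    def test_shift_invariance(self, rng):
        a = rng.normal(0, 1, (3, 51))
        shifted = onset_response(self._eta(a + 7.3))
        np.testing.assert_allclose(shifted, onset_response(self._eta(a)), atol=1e-10)

    def test_population_summary(self):
        per_neuron = np.array([1.0, 2.0, 3.0])
        mean, sem = population_response(per_neuron)
        assert mean == 2.0
        np.testing.assert_allclose(sem, np.std(per_neuron, ddof=1) / np.sqrt(3))


class TestSessionQc:
    @pytest.mark.parametrize(
        "counts,include,reason_contains",
        [
            ({"running_onset": 3, "mismatch": 3}, True, ""),
            ({"running_onset": 2, "mismatch": 10}, False, "running_onset"),
            ({"running_onset": 10, "mismatch": 2}, False, "mismatch"),
            ({"running_onset": 0, "mismatch": 0}, False, ""),
            ({"running_onset": 5}, True, ""),  # dark session: no mismatch count
        ],
    )
    def test_boundary_rule(self, counts, include, reason_contains):
        result = session_qc(counts)
        assert result.include is include
        assert reason_contains in result.reason


class TestSuppressionIndex:
    def _eta(self, mean):
        time = np.arange(-10, 41) * 0.1
        return Eta(time, mean, n_events=4)

    def test_identical_etas_give_zero(self, rng):
        mean = rng.normal(0, 1, (4, 51))
        out = suppression_index(self._eta(mean), self._eta(mean.copy()))
        np.testing.assert_allclose(out, 0.0)

    def test_sustained_dark_vs_decayed_closed_loop(self):
        dark = np.ones((1, 51))
        closed = np.full((1, 51), 0.3)
        out = suppression_index(self._eta(dark), self._eta(closed))
        np.testing.assert_allclose(out, [0.7])

    def test_mismatched_time_axes_rejected(self, rng):
        a = self._eta(rng.normal(0, 1, (2, 51)))
        b = Eta(np.arange(-5, 46) * 0.1, rng.normal(0, 1, (2, 51)), 4)
        with pytest.raises(ValueError):
            suppression_index(a, b)

    def test_recovers_flow_inhibition_ordering_noiseless(self):
        """Without noise the estimated suppression is exactly ordered by
        the generative flow-inhibition magnitude."""
        b = generate_behavior(900, 0.1, "closed_loop",
                              BoutParams(rate_per_min=3, mean_bout_s=10), seed=31)
        dark = BehaviorTraces(b.t, b.running_speed, np.zeros(len(b)), "dark", b.dt)
        w_flows = [-0.005, -0.015, -0.03]
        models = [
            NeuronModel(w_run=0.02, w_flow=w, noise_sd=0.0) for w in w_flows
        ]
        onsets = detect_running_onsets(b.running_speed, b.dt)
        assert onsets.size >= 3
        eta_cl = baseline_subtract(
            event_triggered_average(render_calcium(models, b), onsets)
        )
        eta_dark = baseline_subtract(
            event_triggered_average(render_calcium(models, dark), onsets)
        )
        sup = suppression_index(eta_dark, eta_cl)
        assert np.all(np.diff(sup) > 0)  # stronger inhibition, larger suppression
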