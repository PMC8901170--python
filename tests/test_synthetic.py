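"""Tests of the synthetic session generator against independent oracles."""

import numpy as np
import pytest

from visuomotor import (
    BehaviorTraces,
    BoutParams,
    EventTable,
    NeuronModel,
    calcium_kernel,
    generate_behavior,
    generate_grating_session,
    generate_population,
    insert_mismatches,
    render_calcium,
)


class TestGenerateBehavior:
    def test_no_bout_limit_gives_zero_speed_and_dark_flow(self):
        b = generate_behavior(60, 0.1, "dark", BoutParams(rate_per_min=0.0), seed=0)
        assert np.all(b.running_speed == 0)
        assert np.all(b.visual_flow == 0)

    def test_closed_loop_identity_coupling(self):
        b = generate_behavior(120, 0.1, "closed_loop", gain=1.0, seed=3)
        np.testing.assert_array_equal(b.visual_flow, b.running_speed)

    def test_closed_loop_gain_coupling(self):
        b = generate_behavior(120, 0.1, "closed_loop", gain=2.5, seed=3)
        np.testing.assert_allclose(b.visual_flow, 2.5 * b.running_speed)

    def test_open_loop_flow_decoupled_from_speed(self):
        b = generate_behavior(600, 0.1, "open_loop", seed=4)
        # replayed flow has bout structure but is not the current speed
        assert b.visual_flow.max() > 0
        assert not np.allclose(b.visual_flow, b.running_speed)

    def test_running_occupancy_matches_bout_process_expectation(self):
        """Monte-Carlo occupancy across seeds matches the analytic
        run-bout occupancy mean_bout / (mean_bout + mean_rest) within 5%."""
        params = BoutParams(rate_per_min=3.0, mean_bout_s=10.0)
        occ = np.mean(
            [
                (generate_behavior(600, 0.1, "dark", params, seed=s).running_speed > 1e-2).mean()
                for s in range(100)
            ]
        )
        expected = params.run_occupancy
        assert abs(occ - expected) / expected < 0.05

    def test_determinism(self):
        a = generate_behavior(300, 0.1, "closed_loop", seed=7)
        b = generate_behavior(300, 0.1, "closed_loop", seed=7)
        np.testing.assert_array_equal(a.running_speed, b.running_speed)
        np.testing.assert_array_equal(a.visual_flow, b.visual_flow)

    @pytest.mark.parametrize("kwargs", [
        {"duration_s": -1, "dt": 0.1},
        {"duration_s": 10, "dt": 0.0},
        {"duration_s": 10, "dt": 0.1, "condition": "limbo"},
    ])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            generate_behavior(**kwargs)


class TestInsertMismatches:
    def test_zero_rate_leaves_behavior_unchanged(self):
        b = generate_behavior(300, 0.1, "closed_loop", seed=1)
        out, events = insert_mismatches(b, 0.0, seed=2)
        np.testing.assert_array_equal(out.visual_flow, b.visual_flow)
        assert len(events) == 0

    def test_flow_halted_during_and_only_during_mismatches(self):
        b = generate_behavior(600, 0.1, "closed_loop", seed=5)
        out, events = insert_mismatches(b, 2.0, duration_s=1.0, seed=6)
        assert len(events) > 0
        in_mismatch = np.zeros(len(b), dtype=bool)
        for t0 in events.times_of("mismatch"):
            i0 = int(np.ceil(t0 / b.dt - 1e-9))
            i1 = int(np.ceil((t0 + 1.0) / b.dt - 1e-9))
            in_mismatch[i0:i1] = True
        assert np.all(out.visual_flow[in_mismatch] == 0)
        np.testing.assert_array_equal(
            out.visual_flow[~in_mismatch], b.visual_flow[~in_mismatch]
        )

    def test_events_non_overlapping_and_sorted(self):
        b = generate_behavior(600, 0.1, "closed_loop", seed=8)
        _, events = insert_mismatches(b, 6.0, seed=9)
        times = events.times_of("mismatch")
        assert np.all(np.diff(times) >= 1.0)

    def test_count_matches_poisson_rate(self):
        """Mean mismatch count over 200 seeds lies in the 95% band for
        the mean of 200 Poisson(20) draws."""
        b = generate_behavior(600, 0.1, "closed_loop", seed=0)
        counts = [len(insert_mismatches(b, 2.0, seed=s)[1]) for s in range(200)]
        mean = np.mean(counts)
        half_width = 1.96 * np.sqrt(20.0 / 200)
        assert abs(mean - 20.0) < half_width

    def test_requires_closed_loop(self):
        b = generate_behavior(60, 0.1, "dark", seed=1)
        with pytest.raises(ValueError):
            insert_mismatches(b, 1.0, seed=1)


class TestGratingSession:
    def test_minimal_duration_gives_exactly_one_onset(self):
        _, events = generate_grating_session(5.0, 0.1, [0, 90], seed=3)
        assert events.count("grating_onset") == 1

    def test_epoch_durations_within_stated_ranges(self):
        behavior, events = generate_grating_session(10_000.0, 0.1, [0, 45, 90, 270], seed=4)
        on = events.times_of("grating_onset")
        off = events.times_of("grating_offset")
        assert len(on) > 500
        durations = off - on
        gaps = on[1:] - off[:-1]
        assert np.all((durations >= 3.0) & (durations <= 8.0))
        assert np.all((gaps >= 2.0) & (gaps <= 6.0))

    def test_mean_on_duration_matches_uniform_3_8(self):
        """Mean of uniform(3, 8) is 5.5; the empirical mean over ~1e4
        epochs must agree within 0.1 s."""
        durations = []
        for s in range(10):
            _, events = generate_grating_session(10_000.0, 0.1, [0.0], seed=s)
            durations.append(events.times_of("grating_offset") - events.times_of("grating_onset"))
        mean = np.concatenate(durations).mean()
        assert len(np.concatenate(durations)) >= 10_000 * 0.9
        assert abs(mean - 5.5) < 0.1

    def test_direction_attrs_populated_from_input_list(self):
        directions = [0.0, 45.0, 90.0, 270.0]
        _, events = generate_grating_session(500.0, 0.1, directions, seed=5)
        drawn = {a["direction"] for a in events.attrs}
        assert drawn <= set(directions)
        assert len(drawn) > 1

    def test_errors(self):
        with pytest.raises(ValueError):
            generate_grating_session(100.0, 0.1, [], seed=1)
        with pytest.raises(ValueError):
            generate_grating_session(1.0, 0.1, [0.0], seed=1)


class TestGeneratePopulation:
    def test_pure_opponent_mix_signs(self):
        models = generate_population(40, {"opponent": 1.0}, seed=1)
        assert all(m.w_run > 0 and m.w_flow < 0 and m.m_amp > 0 for m in models)

    def test_empty_population(self):
        assert generate_population(0, {"opponent": 1.0}, seed=1) == []

    def test_counts_follow_largest_remainder_rounding(self):
        mix = {"opponent": 0.5, "visual": 0.3, "coupled": 0.2}
        models = generate_population(500, mix, seed=2)
        counts = {k: sum(m.archetype == k for m in models) for k in mix}
        assert counts == {"opponent": 250, "visual": 150, "coupled": 100}
        # non-divisible case: 7 neurons in thirds -> remainders fill to 7
        models = generate_population(7, {"opponent": 1 / 3, "visual": 1 / 3, "coupled": 1 / 3}, seed=3)
        assert len(models) == 7

    def test_invalid_mix(self):
        with pytest.raises(ValueError):
            generate_population(10, {"opponent": 0.7, "visual": 0.7}, seed=1)
        with pytest.raises(ValueError):
            generate_population(10, {"opponent": -0.5, "visual": 1.5}, seed=1)


def _constant_speed_behavior(n=400, dt=0.1, speed=1.0):
    return BehaviorTraces(
        t=np.arange(n) * dt,
        running_speed=np.full(n, speed),
        visual_flow=np.zeros(n),
        condition="dark",
        dt=dt,
    )


class TestRenderCalcium:
    def test_zero_weights_zero_noise_gives_zero_traces(self):
        b = generate_behavior(60, 0.1, "closed_loop", seed=1)
        models = [NeuronModel(w_run=0, w_flow=0, noise_sd=0)]
        session = render_calcium(models, b)
        assert np.all(session.traces == 0)

    def test_steady_state_matches_brute_force_convolution(self):
        """Unit running weight on constant unit speed: the trace equals a
        direct convolution loop sample-for-sample and settles at the
        kernel gain."""
        b = _constant_speed_behavior()
        model = NeuronModel(w_run=1.0, w_flow=0.0, noise_sd=0.0, tau_ca=0.6)
        session = render_calcium([model], b)
        kernel = calcium_kernel(0.6, 0.1)
        n = len(b)
        oracle = np.zeros(n)
        drive = np.ones(n)
        for i in range(n):
            for j in range(max(0, i - kernel.size + 1), i + 1):
                oracle[i] += drive[j] * kernel[i - j]
        np.testing.assert_allclose(session.traces[0], oracle, rtol=1e-12)
        assert abs(session.traces[0][-1] - kernel.sum()) < 1e-9

    def test_opponent_neuron_rises_at_every_mismatch(self):
        b = generate_behavior(600, 0.1, "closed_loop",
                              BoutParams(rate_per_min=60.0, mean_bout_s=60.0), seed=2)
        b, events = insert_mismatches(b, 3.0, seed=3)
        model = NeuronModel(w_run=0.02, w_flow=-0.02, m_amp=0.4, noise_sd=0.0)
        session = render_calcium([model], b, events)
        trace = session.traces[0]
        for t0 in events.times_of("mismatch"):
            i = int(np.ceil(t0 / b.dt - 1e-9))
            assert trace[i] > trace[i - 1]

    def test_determinism_bit_identical(self):
        b = generate_behavior(120, 0.1, "closed_loop", seed=1)
        models = generate_population(10, {"opponent": 0.5, "visual": 0.5}, seed=2)
        s1 = render_calcium(models, b, seed=3)
        s2 = render_calcium(models, b, seed=3)
        np.testing.assert_array_equal(s1.traces, s2.traces)

    def test_empty_models_error(self):
        b = generate_behavior(10, 0.1, "dark", seed=1)
        with pytest.raises(ValueError):
            render_calcium([], b)


class TestDomainTypes:
    def test_dark_condition_rejects_nonzero_flow(self):
        n = 10
        with pytest.raises(ValueError):
            BehaviorTraces(np.arange(n) * 0.1, np.zeros(n), np.ones(n), "dark", 0.1)

    def test_event_table_rejects_unknown_kind(self):
        with pytest.raises(ValueError):
            EventTable(["teleport"], np.array([1.0]), [{}])

    def test_neuron_model_invariants(self):
        with pytest.raises(ValueError):
            NeuronModel(w_run=0.1, w_flow=0.0, tau_ca=0.0)
        with pytest.raises(ValueError):
            NeuronModel(w_run=0.1, w_flow=0.0, noise_sd=-1.0)
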