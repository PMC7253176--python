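"""Simulator: CTMC statistics, photophysics forward model, dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fretcycle as fc
from fretcycle import presets
from fretcycle.schemes import KineticScheme


class TestKineticScheme:
    def test_rows_sum_to_zero_and_validation(self):
        s = presets.composite_scheme(2.0, 3.0)
        assert np.allclose(s.rate_matrix.sum(axis=1), 0.0)
        with pytest.raises(ValueError):
            KineticScheme(("A", "B"), (0.3, 0.8), np.array([[0.0, -1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            KineticScheme(("A", "B"), (0.0, 0.8), np.zeros((2, 2)))

    def test_degenerate_fret_means_allowed(self):
        # pre/post OF states share E=0.92 by construction
        s = fc.build_scheme(fc.CycleParameters(0.2, 0.03, 0.3, 0.03), "WT")
        assert s.fret_means[1] == s.fret_means[2] == 0.92

    def test_stationary_two_state(self):
        s = presets.composite_scheme(2.0, 2.0)
        assert np.allclose(s.stationary_distribution(), [0.5, 0.5])

    def test_restricted_removes_of_entry(self):
        s = presets.five_state_scheme("atp_ltc4")
        sub = s.without_of()
        assert "OF" not in sub.state_labels
        assert np.allclose(sub.rate_matrix.sum(axis=1), 0.0)

    @given(st.floats(0.1, 10), st.floats(0.1, 10))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_composite_scheme_exit_rates(self, t_if, t_of):
        s = presets.composite_scheme(t_if, t_of)
        assert s.exit_rate("IF") == pytest.approx(1.0 / t_if)
        assert s.exit_rate("OF") == pytest.approx(1.0 / t_of)


class TestStatePath:
    def test_single_state_constant(self):
        s = KineticScheme(("A",), np.array([0.5]), np.zeros((1, 1)))
        path = fc.simulate_state_path(s, 10.0, seed=0)
        assert len(path.states) == 1
        assert np.all(path.discretize(0.1) == 0)

    def test_symmetric_two_state_occupancy(self):
        # k12 = k21 = 1/s: stationary occupancy is exactly 1/2 each
        s = KineticScheme.from_dict({
            "state_labels": ["a", "b"], "fret_means": [0.3, 0.7],
            "rate_matrix": [[-1.0, 1.0], [1.0, -1.0]],
        })
        occ = fc.simulate_state_path(s, 1e4, seed=1).occupancy()
        assert occ[0] == pytest.approx(0.5, abs=0.03)

    def test_sojourn_means_match_exit_rates(self):
        # composite IF<->OF at the measured saturating-ATP lifetimes
        s = presets.composite_scheme(16.1, 28.8)
        path = fc.simulate_state_path(s, 4e4, seed=2)
        st_, dur = path.sojourn_durations()
        assert len(dur) >= 1500  # ~2 * duration / (16.1 + 28.8)
        for i, expect in [(0, 16.1), (1, 28.8)]:
            d = dur[st_ == i]
            assert d.mean() == pytest.approx(expect, abs=3 * d.std() / np.sqrt(len(d)))

    def test_jump_probabilities_match_rates(self):
        # 3-state chain: out of state 0, P(->1) = k01/(k01+k02)
        q = np.array([[0.0, 2.0, 1.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        s = KineticScheme(("x", "y", "z"), np.array([0.2, 0.5, 0.8]), q)
        path = fc.simulate_state_path(s, 2e4, seed=3)
        states = path.states
        from0 = states[1:][states[:-1] == 0]
        n = len(from0)
        p1 = np.mean(from0 == 1)
        # chi-square GOF against the 2/3 : 1/3 branching ratio
        chi2 = n * ((p1 - 2 / 3) ** 2 / (2 / 9))
        assert stats.chi2.sf(chi2, df=1) > 0.01

    def test_majority_occupancy_discretization(self):
        # a sojourn covering 60% of a frame claims that frame
        s = presets.composite_scheme(1.0, 1.0, fret_if=0.3, fret_of=0.8)
        path = fc.StatePath(s, np.array([0.0, 0.6]), np.array([0, 1]), 1.0)
        assert path.discretize(1.0).tolist() == [0]
        assert path.discretize(0.5).tolist() == [0, 1]

    def test_negative_duration_rejected(self, two_state_scheme):
        with pytest.raises(ValueError):
            fc.simulate_state_path(two_state_scheme, -1.0, seed=0)


class TestPhotophysics:
    def test_noiseless_forward_model_inverts(self):
        s = presets.composite_scheme(100.0, 100.0, fret_if=0.3, fret_of=0.92)
        path = fc.StatePath(s, np.array([0.0]), np.array([1]), 10.0)
        params = fc.PhotophysicsParams(noise_sigma=0.0, background_sigma=0.0,
                                       k_bleach=0.0, k_blink_off=0.0)
        tr = fc.apply_photophysics(path, params, 0.1, seed=0)
        e = fc.compute_fret(tr)
        assert np.allclose(e.values(), 0.92)

    def test_bleach_time_distribution(self):
        # mean pre-bleach duration = 1/k_bleach; KS against the exponential
        s = presets.composite_scheme(1.0, 1.0)
        params = fc.PhotophysicsParams(k_bleach=0.010, k_blink_off=0.0)
        rng = np.random.default_rng(5)
        times = []
        path = fc.StatePath(s, np.array([0.0]), np.array([0]), 1.0)
        for _ in range(1000):
            tr = fc.apply_photophysics(path, params, 0.3, n_frames=10, rng=rng)
            times.append(tr.truth.bleach_time)
        times = np.array(times)
        assert times.mean() == pytest.approx(100.0, abs=3 * times.std() / np.sqrt(len(times)))
        assert stats.kstest(times, "expon", args=(0, 100.0)).pvalue > 0.01

    def test_fret_scatter_error_propagation(self):
        # sigma_E = (sigma/S) * sqrt(E^2 + (1-E)^2) for independent channel noise
        s = presets.composite_scheme(100.0, 100.0, fret_if=0.5, fret_of=0.9)
        path = fc.StatePath(s, np.array([0.0]), np.array([0]), 4000.0)
        params = fc.PhotophysicsParams(total_intensity=1000.0, noise_sigma=30.0,
                                       k_bleach=0.0, k_blink_off=0.0)
        tr = fc.apply_photophysics(path, params, 1.0, seed=6)
        e = fc.compute_fret(tr).values()
        expected = 30.0 / 1000.0 * np.sqrt(0.5**2 + 0.5**2)
        assert e.std() == pytest.approx(expected, rel=0.1)

    def test_blinks_zero_both_channels(self):
        s = presets.composite_scheme(100.0, 100.0)
        path = fc.StatePath(s, np.array([0.0]), np.array([0]), 100.0)
        params = fc.PhotophysicsParams(noise_sigma=0.0, background_sigma=0.0,
                                       k_bleach=0.0, k_blink_off=0.2, k_blink_on=0.5)
        tr = fc.apply_photophysics(path, params, 0.1, seed=7)
        blink = tr.truth.blink_mask
        assert blink.any()
        assert np.all(tr.donor[blink] == 0.0) and np.all(tr.acceptor[blink] == 0.0)


class TestDataset:
    def test_all_active_flags(self, two_state_scheme):
        cfg = fc.SimulationConfig(scheme=two_state_scheme, n_traces=10, n_frames=50,
                                  frame_interval=0.1, active_fraction=1.0, seed=0)
        ts = fc.simulate_dataset(cfg)
        assert all(t.truth.active for t in ts)

    def test_active_fraction_binomial(self, two_state_scheme):
        cfg = fc.SimulationConfig(scheme=two_state_scheme, n_traces=500, n_frames=30,
                                  frame_interval=0.1, active_fraction=0.6, seed=1)
        ts = fc.simulate_dataset(cfg)
        n_active = sum(t.truth.active for t in ts)
        assert abs(n_active - 300) <= 3 * np.sqrt(500 * 0.6 * 0.4)

    def test_injection_gates_of_states(self):
        # no OF truth states before injection; OF only in active molecules
        scheme = presets.composite_scheme(4.7, 30.8)
        cfg = fc.SimulationConfig(
            scheme=scheme, n_traces=60, n_frames=300, frame_interval=0.3,
            photophysics=fc.PhotophysicsParams(k_bleach=0.0, k_blink_off=0.0),
            active_fraction=0.5, injection_time=10.0, initial_state="IF", seed=2,
        )
        ts = fc.simulate_dataset(cfg)
        of_idx = scheme.index("OF")
        inj = cfg.injection_frame
        saw_active_of = False
        for tr in ts:
            pre = tr.truth.state_path[:inj]
            assert not np.any(pre == of_idx)
            if not tr.truth.active:
                assert not np.any(tr.truth.state_path == of_idx)
            else:
                saw_active_of |= bool(np.any(tr.truth.state_path[inj:] == of_idx))
        assert saw_active_of

    def test_seed_reproducibility(self, two_state_scheme):
        cfg = fc.SimulationConfig(scheme=two_state_scheme, n_traces=5, n_frames=100,
                                  frame_interval=0.1, seed=42)
        a, b = fc.simulate_dataset(cfg), fc.simulate_dataset(cfg)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)
            np.testing.assert_array_equal(ta.truth.state_path, tb.truth.state_path)

    def test_zero_traces_rejected(self, two_state_scheme):
        with pytest.raises(ValueError):
            fc.SimulationConfig(scheme=two_state_scheme, n_traces=0, n_frames=10,
                                frame_interval=0.1)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, clean_two_state_dataset):
        sub = fc.TraceSet(clean_two_state_dataset.traces[:8],
                          config=clean_two_state_dataset.config)
        fc.write_dataset(sub, tmp_path / "ds")
        back = fc.read_dataset(tmp_path / "ds")
        assert len(back) == 8
        for ta, tb in zip(sub, back):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)
            np.testing.assert_array_equal(ta.truth.state_path, tb.truth.state_path)
            assert ta.truth.bleach_frame == tb.truth.bleach_frame
            assert ta.truth.active == tb.truth.active
        assert sub.truth_table().equals(back.truth_table())

    def test_missing_manifest_field_reported(self, tmp_path, clean_two_state_dataset):
        import json
        sub = fc.TraceSet(clean_two_state_dataset.traces[:2])
        d = fc.write_dataset(sub, tmp_path / "ds2")
        manifest = json.loads((d / "manifest.json").read_text())
        del manifest["frame_interval"]
        (d / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="frame_interval"):
            fc.read_dataset(d)

    def test_missing_directory(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fc.read_dataset(tmp_path / "nope")
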