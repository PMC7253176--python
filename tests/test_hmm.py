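"""HMM core: enumeration oracles, EM behavior, SKM idealization, histograms."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

import fretcycle as fc
from fretcycle import presets
from fretcycle.hmm import HMMModel, viterbi_path


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------


def enum_loglik(model, obs):
    """Sum over all K^T hidden paths of the complete-data likelihood."""
    k, t = model.n_states, len(obs)
    total = -np.inf
    for path in itertools.product(range(k), repeat=t):
        lp = np.log(model.initial[path[0]])
        lp += sum(np.log(model.transition[path[i - 1], path[i]]) for i in range(1, t))
        lp += sum(norm.logpdf(obs[i], model.mu[s], model.sigma[s])
                  for i, s in enumerate(path))
        total = np.logaddexp(total, lp)
    return total


def enum_viterbi(model, obs):
    k, t = model.n_states, len(obs)
    best, best_lp = None, -np.inf
    for path in itertools.product(range(k), repeat=t):
        lp = np.log(model.initial[path[0]])
        lp += sum(np.log(model.transition[path[i - 1], path[i]]) for i in range(1, t))
        lp += sum(norm.logpdf(obs[i], model.mu[s], model.sigma[s])
                  for i, s in enumerate(path))
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best), best_lp


def _random_model(k, rng):
    mu = np.sort(rng.uniform(0.1, 0.9, k))
    sigma = rng.uniform(0.04, 0.12, k)
    a = rng.uniform(0.2, 1.0, (k, k))
    a /= a.sum(axis=1, keepdims=True)
    pi = rng.uniform(0.2, 1.0, k)
    pi /= pi.sum()
    return HMMModel(mu, sigma, a, pi)


# ---------------------------------------------------------------------------
# forward likelihood
# ---------------------------------------------------------------------------


class TestForward:
    @pytest.mark.parametrize("k,t", [(2, 4), (2, 8), (3, 5), (3, 7)])
    def test_matches_enumeration(self, k, t):
        rng = np.random.default_rng(10 * k + t)
        model = _random_model(k, rng)
        obs = rng.uniform(0, 1, t)
        assert fc.forward_loglik(model, obs) == pytest.approx(
            enum_loglik(model, obs), abs=1e-9)

    def test_single_state_reduces_to_iid(self):
        model = HMMModel(np.array([0.5]), np.array([0.08]),
                         np.array([[1.0]]), np.array([1.0]))
        obs = np.array([0.4, 0.55, 0.6])
        assert fc.forward_loglik(model, obs) == pytest.approx(
            norm.logpdf(obs, 0.5, 0.08).sum())

    def test_invariant_under_state_relabeling(self):
        rng = np.random.default_rng(7)
        model = _random_model(3, rng)
        obs = rng.uniform(0, 1, 12)
        perm = np.array([2, 0, 1])
        permuted = HMMModel(model.mu[perm], model.sigma[perm],
                            model.transition[np.ix_(perm, perm)], model.initial[perm])
        assert fc.forward_loglik(model, obs) == pytest.approx(
            fc.forward_loglik(permuted, obs), abs=1e-9)

    def test_masked_frames_carry_no_emission(self):
        rng = np.random.default_rng(8)
        model = _random_model(2, rng)
        obs = rng.uniform(0, 1, 6)
        valid = np.array([True, True, False, True, True, True])
        ll = fc.forward_loglik(model, obs, valid)
        # oracle: marginalize over the hidden state at the masked frame
        # by setting its emission density to 1 in the enumeration
        k, t = 2, 6
        total = -np.inf
        for path in itertools.product(range(k), repeat=t):
            lp = np.log(model.initial[path[0]])
            lp += sum(np.log(model.transition[path[i - 1], path[i]]) for i in range(1, t))
            lp += sum(norm.logpdf(obs[i], model.mu[s], model.sigma[s])
                      for i, s in enumerate(path) if valid[i])
            total = np.logaddexp(total, lp)
        assert ll == pytest.approx(total, abs=1e-9)

    def test_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(9)
        model = _random_model(3, rng)
        obs = rng.uniform(0, 1, 200)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = model.initial
        ref.transmat_ = model.transition
        ref.means_ = model.mu[:, None]
        ref.covars_ = (model.sigma**2)[:, None]
        assert fc.forward_loglik(model, obs) == pytest.approx(
            ref.score(obs[:, None]), abs=1e-6)


class TestViterbi:
    @pytest.mark.parametrize("k,t", [(2, 5), (2, 8), (3, 6)])
    def test_matches_enumeration(self, k, t):
        rng = np.random.default_rng(100 * k + t)
        model = _random_model(k, rng)
        obs = rng.uniform(0, 1, t)
        np.testing.assert_array_equal(viterbi_path(model, obs),
                                      enum_viterbi(model, obs)[0])

    def test_noiseless_alternating_trace_exact(self):
        model = HMMModel(np.array([0.23, 0.92]), np.array([0.05, 0.05]),
                         np.array([[0.9, 0.1], [0.1, 0.9]]), np.array([0.5, 0.5]))
        truth = np.array([0, 0, 1, 1, 1, 0, 1, 0, 0])
        obs = model.mu[truth]
        np.testing.assert_array_equal(viterbi_path(model, obs), truth)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


class TestBaumWelch:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(11)
        obs = rng.normal(0.6, 0.07, 500)
        m = fc.baum_welch([obs], 1, n_restarts=1, seed=0)
        assert m.mu[0] == pytest.approx(obs.mean(), abs=1e-6)
        assert m.sigma[0] == pytest.approx(obs.std(), abs=1e-4)

    def test_loglik_monotone(self, five_state_passing):
        m = fc.baum_welch(five_state_passing[:40], 3, n_restarts=1, seed=1)
        diffs = np.diff(m.history)
        assert np.all(diffs > -1e-6 * np.abs(m.history[0]))

    def test_two_state_parameter_recovery(self, clean_two_state_dataset):
        passing, _ = fc.filter_traces(clean_two_state_dataset)
        m = fc.baum_welch(passing, 2, n_restarts=3, seed=2)
        # generator: mu = (0.3, 0.8); frame-to-frame A from rates 1/2, 1/3 /s at 0.1 s
        assert m.mu == pytest.approx([0.3, 0.8], abs=0.02)
        assert m.transition[0, 1] == pytest.approx(1 - np.exp(-0.5 * 0.1), abs=0.05)
        assert m.transition[1, 0] == pytest.approx(1 - np.exp(-0.1 / 3), abs=0.05)

    def test_canonical_order(self, five_state_passing):
        m = fc.baum_welch(five_state_passing[:30], 3, n_restarts=2, seed=3)
        assert np.all(np.diff(m.mu) >= 0)


class TestSelectStates:
    def test_two_state_data_selects_two(self, clean_two_state_dataset):
        passing, _ = fc.filter_traces(clean_two_state_dataset)
        sel = fc.select_states(passing, range(2, 5), n_restarts=2, seed=4)
        assert sel.best_k == 2

    def test_single_level_data_flags_every_extra_state(self):
        # on iid single-level noise every K > 1 is overfit: the extra states
        # are either starved or indistinguishable from their neighbours
        rng = np.random.default_rng(12)
        trajs = [rng.normal(0.5, 0.05, 200) for _ in range(10)]
        sel = fc.select_states(trajs, range(2, 4), n_restarts=2, seed=5)
        assert (sel.table["unpopulated"] | sel.table["degenerate"]).all()


class TestSKM:
    def test_noiseless_idealization_exact(self):
        truth = np.array([0, 0, 0, 1, 1, 0, 1, 1, 1, 0, 0])
        mu = np.array([0.23, 0.92])
        obs = mu[truth]
        ideal, model = fc.idealize_skm([obs], mu)
        np.testing.assert_array_equal(ideal[0].states, truth)

    def test_misassignment_rate_below_2pct(self, five_state_dataset, five_state_passing):
        ideal, model = fc.idealize_skm(five_state_passing, presets.FIVE_STATE_MEANS)
        truth_by_id = {t.molecule_id: t.truth for t in five_state_dataset}
        wrong = total = 0
        for traj in ideal:
            truth = truth_by_id[traj.molecule_id]
            n = min(len(traj.states), len(truth.state_path))
            sel = ~truth.blink_mask[:n]
            wrong += np.sum(traj.states[:n][sel] != truth.state_path[:n][sel])
            total += sel.sum()
        assert total > 10000
        assert wrong / total < 0.02

    def test_short_trajectory_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than 2"):
            ideal, _ = fc.idealize_skm([np.array([0.5]), np.full(50, 0.9)],
                                       [0.23, 0.92])
        assert len(ideal) == 1

    def test_deterministic(self, five_state_passing):
        a = fc.idealize_skm(five_state_passing[:20], presets.FIVE_STATE_MEANS)
        b = fc.idealize_skm(five_state_passing[:20], presets.FIVE_STATE_MEANS)
        for ta, tb in zip(a[0], b[0]):
            np.testing.assert_array_equal(ta.states, tb.states)


class TestFretHistogram:
    def test_counts_conserved(self, five_state_passing):
        h = fc.fret_histogram(five_state_passing, first_n_frames=50)
        assert h.counts.sum() == h.n_frames_counted
        expected = sum(int(t.prebleach()[1][:50].sum()) for t in five_state_passing)
        assert h.counts.sum() == expected

    def test_single_state_mode_within_one_bin(self):
        rng = np.random.default_rng(13)
        trajs = [rng.normal(0.63, 0.04, 300) for _ in range(5)]
        h = fc.fret_histogram(trajs, bin_width=0.03)
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        assert abs(centers[np.argmax(h.counts)] - 0.63) <= 0.03

    def test_five_state_mixture_modes_near_means(self, five_state_passing):
        h = fc.fret_histogram(five_state_passing)
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        dens = h.counts / h.counts.sum()
        for mu in presets.FIVE_STATE_MEANS:
            near = np.abs(centers - mu) <= 0.045
            assert dens[near].sum() > 0.02  # each state visibly populated
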