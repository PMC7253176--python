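"""Gaussian-emission hidden Markov modeling of FRET trajectories.

Implements the idealization stack used for smFRET time series:

* maximum-likelihood fitting (Baum-Welch EM) of K-state models with
  per-state Gaussian emissions on the FRET efficiency,
* state-number selection over K = 2..6 by penalized likelihood (BIC) with
  an "unpopulated state" flag marking the overfitting symptom in which an
  extra state captures <1% of the assigned frames,
* trajectory idealization by the segmental k-means algorithm with the state
  means held fixed across conditions (Viterbi decoding alternated with
  re-estimation of the transition matrix and noise widths).

All recursions are computed for a whole dataset at once on padded arrays,
with a per-frame validity mask: frames flagged invalid by QC (blinks,
sub-floor intensity) contribute no emission likelihood but the hidden state
still evolves through them, keeping frame indexing intact for dwell-time
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .qc import FRETTrajectory

__all__ = [
    "HMMModel",
    "IdealizedTrajectory",
    "StateSelection",
    "FretHistogram",
    "forward_loglik",
    "baum_welch",
    "select_states",
    "idealize_skm",
    "fret_histogram",
]

_LOG2PI = np.log(2.0 * np.pi)
_SIGMA_FLOOR = 1e-3
# Emission widths are bounded: FRET efficiencies live on [0, 1], so a state
# "width" beyond ~0.3 only ever arises when a state starts absorbing ratio
# outliers (near-zero denominators) and turns into a garbage collector.
_SIGMA_CEIL = 0.3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class HMMModel:
    """K-state Gaussian-emission HMM in canonical (mu-ascending) order."""

    mu: np.ndarray  # (K,) state FRET means
    sigma: np.ndarray  # (K,) per-state emission widths
    transition: np.ndarray  # (K, K) frame-to-frame probabilities, rows sum to 1
    initial: np.ndarray  # (K,)
    loglik: float = float("nan")
    occupancy: Optional[np.ndarray] = None  # fraction of frames per state
    n_obs: int = 0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, float)
        self.sigma = np.asarray(self.sigma, float)
        self.transition = np.asarray(self.transition, float)
        self.initial = np.asarray(self.initial, float)
        k = len(self.mu)
        if self.sigma.shape != (k,) or self.transition.shape != (k, k):
            raise ValueError("inconsistent model dimensions")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.mu)

    @property
    def n_params(self) -> int:
        k = self.n_states
        return (k - 1) + k * (k - 1) + 2 * k

    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(max(self.n_obs, 1))

    def canonical(self) -> "HMMModel":
        """Relabel states so that mu is ascending."""
        order = np.argsort(self.mu, kind="stable")
        return HMMModel(
            self.mu[order], self.sigma[order],
            self.transition[np.ix_(order, order)], self.initial[order],
            loglik=self.loglik,
            occupancy=None if self.occupancy is None else self.occupancy[order],
            n_obs=self.n_obs,
        )

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(), "sigma": self.sigma.tolist(),
            "transition": self.transition.tolist(), "initial": self.initial.tolist(),
            "loglik": self.loglik, "n_obs": self.n_obs,
            "occupancy": None if self.occupancy is None else self.occupancy.tolist(),
        }


@dataclass
class IdealizedTrajectory:
    """Per-frame discrete state assignment for one molecule."""

    molecule_id: str
    frame_interval: float
    states: np.ndarray  # (L,) int indices into the model's states
    model: HMMModel

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.size and not (
            0 <= self.states.min() and self.states.max() < self.model.n_states
        ):
            raise ValueError("state indices out of range")

    @property
    def n_frames(self) -> int:
        return len(self.states)

    def fret_path(self) -> np.ndarray:
        return self.model.mu[self.states]


@dataclass
class StateSelection:
    """Outcome of the state-number scan."""

    best_k: int
    models: dict  # K -> HMMModel
    table: pd.DataFrame  # per-K: loglik, bic, min_occupancy, unpopulated

    @property
    def best_model(self) -> HMMModel:
        return self.models[self.best_k]


@dataclass
class FretHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray  # (n_bins,) cumulative over counted frames
    frame_density: np.ndarray  # (first_n_frames, n_bins), row-normalized
    n_frames_counted: int


# ---------------------------------------------------------------------------
# packing and emission terms
# ---------------------------------------------------------------------------


def _as_series(trajectories) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalize inputs to a list of (E values, valid mask) pairs."""
    out = []
    for tr in trajectories:
        if isinstance(tr, FRETTrajectory):
            e, valid = tr.prebleach()
        elif isinstance(tr, IdealizedTrajectory):  # pragma: no cover - guard
            raise TypeError("expected FRET series, got an idealized trajectory")
        else:
            e = np.asarray(tr, dtype=float)
            valid = np.isfinite(e)
        out.append((np.asarray(e, float), np.asarray(valid, bool)))
    return out


def _pack(series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lengths = np.array([len(e) for e, _ in series], dtype=np.int64)
    n, t = len(series), int(lengths.max())
    e = np.zeros((n, t))
    valid = np.zeros((n, t), dtype=bool)
    for i, (ei, vi) in enumerate(series):
        e[i, : len(ei)] = ei
        valid[i, : len(ei)] = vi
    return e, valid, lengths


def _log_emission(e, valid, mu, sigma) -> np.ndarray:
    """(N, T, K) log emission densities; exactly 0 at invalid frames."""
    z = (e[..., None] - mu[None, None, :]) / sigma[None, None, :]
    logb = -0.5 * (z * z) - np.log(sigma)[None, None, :] - 0.5 * _LOG2PI
    logb[~valid] = 0.0
    return logb


# ---------------------------------------------------------------------------
# forward / backward / posterior statistics
# ---------------------------------------------------------------------------


def _forward(logb, lengths, a, pi):
    """Scaled forward pass; returns (alpha, scale, logliks).

    alpha[n, t] is the normalized filtering distribution; scale[n, t] the
    per-step normalizer in log space (including the emission log-offset).
    """
    n, t, k = logb.shape
    offset = logb.max(axis=2)
    b = np.exp(logb - offset[..., None])
    alpha = np.zeros((n, t, k))
    scale = np.zeros((n, t))
    x = pi[None, :] * b[:, 0]
    c = x.sum(axis=1)
    alpha[:, 0] = x / c[:, None]
    scale[:, 0] = np.log(c) + offset[:, 0]
    for i in range(1, t):
        x = (alpha[:, i - 1] @ a) * b[:, i]
        c = x.sum(axis=1)
        c[c == 0] = np.finfo(float).tiny
        alpha[:, i] = x / c[:, None]
        scale[:, i] = np.log(c) + offset[:, i]
    mask = np.arange(t)[None, :] < lengths[:, None]
    logliks = np.where(mask, scale, 0.0).sum(axis=1)
    return alpha, scale, logliks


def _backward(logb, lengths, a):
    n, t, k = logb.shape
    offset = logb.max(axis=2)
    b = np.exp(logb - offset[..., None])
    beta = np.zeros((n, t, k))
    # beta at the last *observed* frame of each sequence is 1
    for i in range(t):
        beta[lengths - 1 == i, i] = 1.0
    for i in range(t - 2, -1, -1):
        upd = lengths - 1 > i
        x = (beta[upd, i + 1] * b[upd, i + 1]) @ a.T
        c = x.sum(axis=1, keepdims=True)
        c[c == 0] = np.finfo(float).tiny
        beta[upd, i] = x / c
    return beta


def forward_loglik(model: HMMModel, e_series, valid=None) -> float:
    """Total log-likelihood of one E series under the model (scaled forward)."""
    e = np.asarray(e_series, float)
    v = np.ones(len(e), bool) if valid is None else np.asarray(valid, bool)
    logb = _log_emission(e[None, :], v[None, :], model.mu, model.sigma)
    _, _, ll = _forward(logb, np.array([len(e)]), model.transition, model.initial)
    return float(ll[0])


# ---------------------------------------------------------------------------
# Baum-Welch EM
# ---------------------------------------------------------------------------


def _em_fit(e, valid, lengths, mu, sigma, a, pi, tol, max_iter, rng):
    n, t = e.shape
    k = len(mu)
    tmask = np.arange(t)[None, :] < lengths[:, None]
    fitmask = tmask & valid
    n_obs = int(fitmask.sum())
    prev_ll = -np.inf
    history = []
    for iteration in range(max_iter):
        logb = _log_emission(e, valid, mu, sigma)
        logb[~tmask] = 0.0
        alpha, _, logliks = _forward(logb, lengths, a, pi)
        ll = float(logliks.sum())
        history.append(ll)
        beta = _backward(logb, lengths, a)
        gamma = alpha * beta
        norm = gamma.sum(axis=2, keepdims=True)
        norm[norm == 0] = np.finfo(float).tiny
        gamma /= norm
        gamma[~tmask] = 0.0

        # transition statistics
        offset = logb.max(axis=2)
        b = np.exp(logb - offset[..., None])
        xi_sum = np.zeros((k, k))
        for i in range(1, t):
            upd = lengths > i
            if not np.any(upd):
                break
            x = alpha[upd, i - 1][:, :, None] * a[None] * (b[upd, i] * beta[upd, i])[:, None, :]
            s = x.sum(axis=(1, 2), keepdims=True)
            s[s == 0] = np.finfo(float).tiny
            xi_sum += (x / s).sum(axis=0)

        # M-step
        pi = gamma[:, 0].sum(axis=0)
        pi /= pi.sum()
        rows = xi_sum.sum(axis=1, keepdims=True)
        rows[rows == 0] = np.finfo(float).tiny
        a = xi_sum / rows
        w = np.where(fitmask[..., None], gamma, 0.0)
        mass = w.sum(axis=(0, 1))
        for j in range(k):
            if mass[j] < 1e-6 * max(n_obs, 1):
                warnings.warn(f"state {j} emptied during EM; reinitializing from data")
                mu[j] = np.quantile(e[fitmask], rng.random())
                sigma[j] = max(np.std(e[fitmask]), _SIGMA_FLOOR)
            else:
                mu[j] = (w[..., j] * e).sum() / mass[j]
                var = (w[..., j] * (e - mu[j]) ** 2).sum() / mass[j]
                sigma[j] = float(np.clip(np.sqrt(var), _SIGMA_FLOOR, _SIGMA_CEIL))

        if iteration > 0 and abs(ll - prev_ll) < tol * (abs(prev_ll) + 1.0):
            prev_ll = ll
            break
        prev_ll = ll
    occ = np.where(fitmask[..., None], gamma, 0.0).sum(axis=(0, 1))
    occ /= max(occ.sum(), np.finfo(float).tiny)
    return mu, sigma, a, pi, prev_ll, occ, n_obs, history


def baum_welch(
    trajectories,
    k: int,
    *,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int = 0,
    init_means: Optional[Sequence[float]] = None,
) -> HMMModel:
    """Maximum-likelihood EM fit of a K-state model with multi-restart.

    The total data log-likelihood is non-decreasing across EM iterations
    (up to the stopping tolerance); the best of ``n_restarts`` randomized
    initializations is kept and returned in canonical mu-ascending order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    series = _as_series(trajectories)
    if not series:
        raise ValueError("need at least one trajectory")
    e, valid, lengths = _pack(series)
    data = e[valid & (np.arange(e.shape[1])[None, :] < lengths[:, None])]
    if data.size == 0:
        raise ValueError("no valid frames to fit")

    best: Optional[HMMModel] = None
    rng_master = np.random.default_rng(seed)
    for _ in range(max(n_restarts, 1)):
        rng = np.random.default_rng(rng_master.integers(2**31))
        if init_means is not None:
            mu = np.asarray(init_means, float).copy()
        else:
            qs = (np.arange(k) + 0.5) / k + rng.uniform(-0.3 / k, 0.3 / k, size=k)
            mu = np.quantile(data, np.clip(qs, 0.0, 1.0))
        sigma = np.full(k, max(np.std(data) / max(k, 2), 0.02))
        a = np.full((k, k), 0.05 / max(k - 1, 1))
        np.fill_diagonal(a, 0.95)
        pi = np.full(k, 1.0 / k)
        mu, sigma, a, pi, ll, occ, n_obs, history = _em_fit(
            e, valid, lengths, mu, sigma, a, pi, tol, max_iter, rng
        )
        model = HMMModel(mu, sigma, a, pi, loglik=ll, occupancy=occ, n_obs=n_obs)
        model.history = history  # per-iteration log-likelihoods (diagnostic)
        if best is None or model.loglik > best.loglik:
            best = model
    out = best.canonical()
    out.history = best.history
    return out


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------


def _viterbi(logb, lengths, a, pi) -> list[np.ndarray]:
    """Batched Viterbi; on exact ties the lowest state index wins."""
    n, t, k = logb.shape
    with np.errstate(divide="ignore"):
        loga = np.log(a)
        logpi = np.log(pi)
    psi = np.zeros((n, t, k), dtype=np.int8)
    delta = logpi[None, :] + logb[:, 0]
    deltas = np.zeros((n, t, k))
    deltas[:, 0] = delta
    for i in range(1, t):
        m = delta[:, :, None] + loga[None]  # (N, from, to)
        psi[:, i] = np.argmax(m, axis=1)  # first max -> lowest index
        delta = np.max(m, axis=1) + logb[:, i]
        deltas[:, i] = delta
    paths = []
    for j in range(n):
        ln = int(lengths[j])
        path = np.empty(ln, dtype=np.int64)
        path[-1] = int(np.argmax(deltas[j, ln - 1]))
        for i in range(ln - 1, 0, -1):
            path[i - 1] = psi[j, i, path[i]]
        paths.append(path)
    return paths


def viterbi_path(model: HMMModel, e_series, valid=None) -> np.ndarray:
    """Most probable state path for one E series."""
    e = np.asarray(e_series, float)
    v = np.ones(len(e), bool) if valid is None else np.asarray(valid, bool)
    logb = _log_emission(e[None, :], v[None, :], model.mu, model.sigma)
    return _viterbi(logb, np.array([len(e)]), model.transition, model.initial)[0]


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def _assignment_occupancy(model, e, valid, lengths) -> np.ndarray:
    logb = _log_emission(e, valid, model.mu, model.sigma)
    paths = _viterbi(logb, lengths, model.transition, model.initial)
    counts = np.zeros(model.n_states)
    for p in paths:
        np.add.at(counts, p, 1)
    return counts / max(counts.sum(), 1)


def select_states(
    trajectories,
    k_range=range(2, 7),
    *,
    n_restarts: int = 5,
    seed: int = 0,
    occupancy_threshold: float = 0.01,
    **fit_kwargs,
) -> StateSelection:
    """Scan candidate state counts and pick the best-supported model.

    Each K is fitted with multi-restart EM; models are ranked by BIC.  Two
    overfitting symptoms are flagged per K: ``unpopulated`` when any state
    claims less than ``occupancy_threshold`` of the Viterbi-assigned frames
    (an extra state exists in the model but is essentially never visited),
    and ``degenerate`` when two state means sit closer than the emission
    width separating them (the extra state splits one population in two
    instead of resolving a new one).
    """
    series = _as_series(trajectories)
    e, valid, lengths = _pack(series)
    models: dict[int, HMMModel] = {}
    rows = []
    for k in k_range:
        model = baum_welch(trajectories, k, n_restarts=n_restarts, seed=seed + k, **fit_kwargs)
        occ = _assignment_occupancy(model, e, valid, lengths)
        model.occupancy = occ
        models[k] = model
        gaps = np.diff(model.mu)
        widths = np.maximum(model.sigma[:-1], model.sigma[1:])
        rows.append(dict(
            K=k, loglik=model.loglik, bic=model.bic(),
            min_occupancy=float(occ.min()),
            unpopulated=bool(occ.min() < occupancy_threshold),
            degenerate=bool(np.any(gaps < widths)) if k > 1 else False,
        ))
    table = pd.DataFrame(rows).set_index("K")
    best_k = int(table["bic"].idxmin())
    return StateSelection(best_k, models, table)


# ---------------------------------------------------------------------------
# segmental k-means idealization
# ---------------------------------------------------------------------------


def idealize_skm(
    trajectories,
    fixed_mu: Sequence[float],
    *,
    init_A: Optional[np.ndarray] = None,
    init_sigma: float | Sequence[float] = 0.06,
    max_iter: int = 100,
    transition_pseudocount: float = 0.01,
    molecule_ids: Optional[Sequence[str]] = None,
) -> tuple[list[IdealizedTrajectory], HMMModel]:
    """Idealize trajectories by segmental k-means with fixed state means.

    Alternates Viterbi decoding with re-estimation of the transition matrix
    and per-state noise widths (the means are held fixed, as when a single
    state model is applied across all experimental conditions).  Converges
    when the decoded paths are identical on two successive iterations, or
    after ``max_iter`` iterations.  Deterministic given the inputs.
    """
    mu = np.sort(np.asarray(fixed_mu, dtype=float))
    k = len(mu)
    series = _as_series(trajectories)
    keep = [i for i, (ei, _) in enumerate(series) if len(ei) >= 2]
    if len(keep) < len(series):
        warnings.warn(f"skipping {len(series) - len(keep)} trajectories shorter than 2 frames")
    series = [series[i] for i in keep]
    if not series:
        raise ValueError("no trajectories of usable length")
    e, valid, lengths = _pack(series)

    sigma = np.full(k, init_sigma, dtype=float) if np.isscalar(init_sigma) \
        else np.asarray(init_sigma, float).copy()
    if init_A is not None:
        a = np.asarray(init_A, float).copy()
    else:
        a = np.full((k, k), 0.05 / max(k - 1, 1))
        np.fill_diagonal(a, 0.95)
    pi = np.full(k, 1.0 / k)

    fitmask_rows = [v for _, v in series]
    prev_paths: Optional[list[np.ndarray]] = None
    paths: list[np.ndarray] = []
    for _ in range(max_iter):
        logb = _log_emission(e, valid, mu, sigma)
        paths = _viterbi(logb, lengths, a, pi)
        if prev_paths is not None and all(
            np.array_equal(p, q) for p, q in zip(paths, prev_paths)
        ):
            break
        prev_paths = paths
        # re-estimate transition matrix, initial distribution, noise widths
        counts = np.full((k, k), transition_pseudocount)
        first = np.full(k, transition_pseudocount)
        res_sum = np.zeros(k)
        res_n = np.zeros(k)
        for (ei, vi), p in zip(series, paths):
            np.add.at(counts, (p[:-1], p[1:]), 1)
            first[p[0]] += 1
            sel = vi[: len(p)]
            np.add.at(res_sum, p[sel], (ei[sel] - mu[p[sel]]) ** 2)
            np.add.at(res_n, p[sel], 1)
        a = counts / counts.sum(axis=1, keepdims=True)
        pi = first / first.sum()
        nonzero = res_n > 1
        sigma[nonzero] = np.clip(np.sqrt(res_sum[nonzero] / res_n[nonzero]),
                                 _SIGMA_FLOOR, _SIGMA_CEIL)

    # final model with total likelihood under the refined parameters
    logb = _log_emission(e, valid, mu, sigma)
    _, _, lls = _forward(logb, lengths, a, pi)
    occ = np.zeros(k)
    for p in paths:
        np.add.at(occ, p, 1)
    occ /= max(occ.sum(), 1)
    model = HMMModel(mu, sigma, a, pi, loglik=float(lls.sum()), occupancy=occ,
                     n_obs=int(sum(v.sum() for v in fitmask_rows)))

    if molecule_ids is None:
        molecule_ids = []
        for i in keep:
            tr = list(trajectories)[i]
            molecule_ids.append(getattr(tr, "molecule_id", f"traj{i:04d}"))
    dts = []
    for i in keep:
        tr = list(trajectories)[i]
        dts.append(getattr(tr, "frame_interval", 1.0))
    idealized = [
        IdealizedTrajectory(mid, dt, p, model)
        for mid, dt, p in zip(molecule_ids, dts, paths)
    ]
    return idealized, model


# ---------------------------------------------------------------------------
# FRET histograms / contour data
# ---------------------------------------------------------------------------


def fret_histogram(
    trajectories,
    first_n_frames: Optional[int] = None,
    bin_width: float = 0.03,
    e_range: tuple[float, float] = (-0.21, 1.23),
) -> FretHistogram:
    """Cumulative FRET histogram and per-frame-index population density.

    Only valid pre-bleach frames are counted, restricted to the first
    ``first_n_frames`` of each trajectory (all frames if None).  The
    ``frame_density`` matrix (frame index x FRET bin, rows normalized to
    each frame's population) is the raw material of the contour plots in
    which photobleaching progressively depopulates later frames.
    """
    series = _as_series(trajectories)
    lo, hi = e_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    nf = first_n_frames or max((len(e) for e, _ in series), default=0)
    counts = np.zeros(len(edges) - 1)
    density = np.zeros((nf, len(edges) - 1))
    total = 0
    for e, v in series:
        e, v = e[:nf], v[:nf]
        vals = np.clip(e[v], lo, hi - 1e-9)
        counts += np.histogram(vals, bins=edges)[0]
        total += len(vals)
        idx = np.flatnonzero(v)
        bins = np.minimum(((e[idx] - lo) / bin_width).astype(int), len(edges) - 2)
        np.add.at(density, (idx, np.maximum(bins, 0)), 1.0)
    row_sums = density.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return FretHistogram(edges, counts, density / row_sums, total)
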