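"""Synthetic smFRET trace generation with known ground truth.

The generator has two layers:

1. a conformational layer — exact stochastic simulation (Gillespie) of a
   continuous-time Markov chain over the states of a :class:`KineticScheme`,
   optionally switching schemes at a ligand-injection time and mixing in a
   fraction of kinetically inactive (IF-only) molecules;
2. a photophysics layer — two-channel Gaussian-noise intensities with
   donor photobleaching (single step, exponential survival) and donor
   blinking (both channels dark while the donor is in its dark state).

Camera integration is emulated by assigning to each frame the state that
occupies the majority of the frame interval, which blurs transitions faster
than the frame time exactly as slow-frame-rate imaging does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .schemes import KineticScheme

__all__ = [
    "StatePath",
    "PhotophysicsParams",
    "SimulationConfig",
    "Trace",
    "TraceTruth",
    "TraceSet",
    "simulate_state_path",
    "apply_photophysics",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class StatePath:
    """A realized continuous-time state trajectory.

    ``times[i]`` is the entry time of sojourn ``i`` in state ``states[i]``
    (indices into ``scheme.state_labels``); the final sojourn ends at
    ``duration``.
    """

    scheme: KineticScheme
    times: np.ndarray  # (n_sojourns,) entry times, times[0] == 0
    states: np.ndarray  # (n_sojourns,) int state indices
    duration: float

    def state_at(self, t: float) -> int:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        return int(self.states[max(i, 0)])

    def occupancy(self) -> np.ndarray:
        """Fraction of total time spent in each state."""
        ends = np.append(self.times[1:], self.duration)
        dt = ends - self.times
        occ = np.zeros(self.scheme.n_states)
        np.add.at(occ, self.states, dt)
        return occ / self.duration

    def sojourn_durations(self) -> tuple[np.ndarray, np.ndarray]:
        """(states, durations) of completed sojourns (the last one, ended by
        the observation window rather than a transition, is excluded)."""
        ends = np.append(self.times[1:], self.duration)
        dur = ends - self.times
        return self.states[:-1].copy(), dur[:-1].copy()

    def discretize(self, frame_interval: float, n_frames: Optional[int] = None) -> np.ndarray:
        """Per-frame state path: the state occupying the majority of each frame."""
        if n_frames is None:
            n_frames = int(np.floor(self.duration / frame_interval))
        occ = _frame_occupancy(self, frame_interval, n_frames)
        return np.argmax(occ, axis=1).astype(np.int64)


def _frame_occupancy(path: StatePath, dt: float, n_frames: int) -> np.ndarray:
    """Time spent in each state within each frame, shape (n_frames, K)."""
    occ = np.zeros((n_frames, path.scheme.n_states))
    t_end_all = n_frames * dt
    ends = np.append(path.times[1:], path.duration)
    for s, t0, t1 in zip(path.states, path.times, ends):
        t1 = min(t1, t_end_all)
        if t1 <= t0:
            continue
        i0 = int(t0 / dt)
        i1 = int(np.ceil(t1 / dt))
        for i in range(i0, min(i1, n_frames)):
            lo = max(t0, i * dt)
            hi = min(t1, (i + 1) * dt)
            if hi > lo:
                occ[i, s] += hi - lo
    return occ


@dataclass
class PhotophysicsParams:
    """Fluorophore/detection parameters of the intensity forward model.

    total_intensity : mean total photon counts per frame (a.u.)
    noise_sigma     : per-channel Gaussian noise width before bleaching (a.u.)
    background_sigma: residual per-channel width after donor bleaching (a.u.)
    k_bleach        : donor photobleaching rate, 1/s
    k_blink_off     : donor bright->dark rate, 1/s
    k_blink_on      : donor dark->bright recovery rate, 1/s
    crosstalk       : fixed donor->acceptor leakage fraction
    """

    total_intensity: float = 1000.0
    noise_sigma: float = 75.0
    background_sigma: float = 50.0
    k_bleach: float = 0.010
    k_blink_off: float = 0.0
    k_blink_on: float = 2.0
    crosstalk: float = 0.0

    def __post_init__(self):
        for name in ("k_bleach", "k_blink_off", "k_blink_on"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        if self.noise_sigma < 0 or self.background_sigma < 0:
            raise ValueError("noise widths must be >= 0")
        if not 0.0 <= self.crosstalk < 1.0:
            raise ValueError("crosstalk must be in [0, 1)")


@dataclass
class TraceTruth:
    """Ground truth carried alongside a simulated trace."""

    state_path: np.ndarray  # per-frame int state index (into scheme labels)
    state_labels: tuple[str, ...]
    bleach_frame: int  # first background frame; == n_frames if unbleached
    bleach_time: float  # continuous bleach time, s (inf if unbleached)
    blink_mask: np.ndarray  # bool per frame, True where donor dark
    active: bool = True


@dataclass
class Trace:
    """One molecule's two-channel intensity time series."""

    molecule_id: str
    frame_interval: float
    donor: np.ndarray
    acceptor: np.ndarray
    truth: Optional[TraceTruth] = None

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be equal-length 1-D series")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("intensities must be finite")
        if self.truth is not None and len(self.truth.state_path) != len(self.donor):
            raise ValueError("truth state path length must equal channel length")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass
class SimulationConfig:
    """Full description of a simulated dataset (the seed determines it)."""

    scheme: KineticScheme  # active-molecule scheme (post-injection when injecting)
    n_traces: int
    n_frames: int
    frame_interval: float  # s (0.025 or 0.300 in the imaging presets)
    photophysics: PhotophysicsParams = field(default_factory=PhotophysicsParams)
    active_fraction: float = 1.0
    injection_time: Optional[float] = None  # s; ligand arrives mid-movie
    pre_injection_scheme: Optional[KineticScheme] = None  # default: IF-only submatrix
    inactive_scheme: Optional[KineticScheme] = None  # default: IF-only submatrix
    # a label, or a sequence of labels drawn uniformly per molecule (e.g. the
    # IF states, emulating molecules first observed before nucleotide acts);
    # None draws from the scheme's stationary distribution
    initial_state: Optional[str | Sequence[str]] = None
    condition: str = ""
    seed: int = 0

    def __post_init__(self):
        if self.n_traces <= 0:
            raise ValueError("n_traces must be >= 1")
        if self.n_frames <= 0 or self.frame_interval <= 0:
            raise ValueError("n_frames and frame_interval must be positive")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.injection_time is not None:
            if not 0.0 < self.injection_time < self.n_frames * self.frame_interval:
                raise ValueError("injection_time must fall inside the movie")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def injection_frame(self) -> Optional[int]:
        if self.injection_time is None:
            return None
        return int(self.injection_time / self.frame_interval)


@dataclass
class TraceSet:
    """A simulated or loaded dataset: traces plus its generating config."""

    traces: list[Trace]
    config: Optional[SimulationConfig] = None
    condition: str = ""

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def truth_table(self):
        """Per-frame ground-truth table (pandas DataFrame), if truth exists."""
        import pandas as pd

        rows = []
        for tr in self.traces:
            if tr.truth is None:
                continue
            labels = tr.truth.state_labels
            for i, s in enumerate(tr.truth.state_path):
                rows.append((tr.molecule_id, i, labels[int(s)]))
        return pd.DataFrame(rows, columns=["molecule_id", "frame_index", "state_label"])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    seed=None,
    *,
    initial_state: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> StatePath:
    """Exact (Gillespie) simulation of the scheme's CTMC for ``duration`` s.

    Sojourns in state ``i`` are exponential with the state's total exit rate;
    the jump target is drawn proportionally to the outgoing rate constants.
    A state with zero exit rate is absorbing and the path simply stays there.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    q = scheme.rate_matrix
    k = scheme.n_states
    if initial_state is not None:
        state = scheme.index(initial_state)
    else:
        state = int(rng.choice(k, p=scheme.stationary_distribution()))

    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        exit_rate = -q[state, state]
        if exit_rate <= 0.0:
            break  # absorbing
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        probs /= exit_rate
        state = int(rng.choice(k, p=probs))
        times.append(t)
        states.append(state)
    return StatePath(scheme, np.asarray(times), np.asarray(states, dtype=np.int64), duration)


def _simulate_blink_mask(
    n_frames: int, dt: float, params: PhotophysicsParams, rng: np.random.Generator
) -> np.ndarray:
    """Frames in which the donor dark state occupies the majority of the frame."""
    mask = np.zeros(n_frames, dtype=bool)
    if params.k_blink_off <= 0:
        return mask
    t = 0.0
    duration = n_frames * dt
    while t < duration:
        t += rng.exponential(1.0 / params.k_blink_off)  # bright sojourn
        if t >= duration:
            break
        if params.k_blink_on <= 0:
            dark = duration - t
        else:
            dark = rng.exponential(1.0 / params.k_blink_on)
        t0, t1 = t, min(t + dark, duration)
        # majority-occupancy per frame, consistent with state discretization
        i0, i1 = int(t0 / dt), int(np.ceil(t1 / dt))
        for i in range(i0, min(i1, n_frames)):
            lo, hi = max(t0, i * dt), min(t1, (i + 1) * dt)
            if hi - lo > dt / 2:
                mask[i] = True
        t = t + dark
    return mask


def apply_photophysics(
    path: StatePath,
    params: PhotophysicsParams,
    frame_interval: float,
    seed=None,
    *,
    n_frames: Optional[int] = None,
    molecule_id: str = "mol",
    active: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> Trace:
    """Render a state path into a noisy two-channel intensity trace.

    Before bleaching, donor = S*(1-E) + N(0, sigma) and acceptor = S*E +
    N(0, sigma) with S the total intensity and E the state's FRET mean.
    Donor photobleaching occurs at an exponential time with rate
    ``k_bleach`` and zeroes both channels to background noise in a single
    step; donor blinking zeroes both channels temporarily.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    dt = frame_interval
    if n_frames is None:
        n_frames = int(np.floor(path.duration / dt))
    frames = path.discretize(dt, n_frames)
    e = path.scheme.fret_means[frames]

    if params.k_bleach > 0:
        bleach_time = rng.exponential(1.0 / params.k_bleach)
    else:
        bleach_time = np.inf
    if np.isinf(bleach_time):
        bleach_frame = n_frames
    else:
        bleach_frame = min(int(bleach_time / dt), n_frames)

    blink = _simulate_blink_mask(n_frames, dt, params, rng)
    blink[bleach_frame:] = False

    s = params.total_intensity
    donor_sig = s * (1.0 - e)
    accept_sig = s * e + params.crosstalk * donor_sig
    dark = blink.copy()
    dark[bleach_frame:] = True
    donor_sig = np.where(dark, 0.0, donor_sig)
    accept_sig = np.where(dark, 0.0, accept_sig)

    sigma = np.where(dark, params.background_sigma, params.noise_sigma)
    donor = donor_sig + rng.normal(0.0, 1.0, n_frames) * sigma
    acceptor = accept_sig + rng.normal(0.0, 1.0, n_frames) * sigma

    truth = TraceTruth(
        state_path=frames,
        state_labels=path.scheme.state_labels,
        bleach_frame=bleach_frame,
        bleach_time=float(bleach_time),
        blink_mask=blink,
        active=active,
    )
    return Trace(molecule_id, dt, donor, acceptor, truth=truth)


def _simulate_switched_path(
    pre: KineticScheme,
    post: KineticScheme,
    injection_time: float,
    duration: float,
    rng: np.random.Generator,
    initial_state: Optional[str],
) -> StatePath:
    """Path under ``pre`` until injection, continuing under ``post`` after.

    The two schemes are matched by state label; the occupied state at the
    injection instant carries over (its label must exist in ``post``).
    """
    head = simulate_state_path(pre, injection_time, rng=rng, initial_state=initial_state)
    label = pre.state_labels[head.state_at(injection_time)]
    tail = simulate_state_path(post, duration - injection_time, rng=rng, initial_state=label)
    # splice, re-indexing head states into the post scheme's label space
    head_idx = np.array([post.index(pre.state_labels[s]) for s in head.states], dtype=np.int64)
    tail_states = tail.states
    tail_times = tail.times + injection_time
    if len(head_idx) and head_idx[-1] == tail_states[0]:
        tail_times = tail_times[1:]
        tail_states = tail_states[1:]
    times = np.concatenate([head.times, tail_times])
    states = np.concatenate([head_idx, tail_states])
    return StatePath(post, times, states, duration)


def simulate_dataset(config: SimulationConfig) -> TraceSet:
    """Generate a full dataset per ``config``; the seed fixes it bit-for-bit.

    A fraction ``active_fraction`` of molecules (Bernoulli per molecule)
    follows the active scheme — switching from the pre-injection scheme at
    ``injection_time`` when one is set — while the rest follow the inactive
    (IF-only) scheme throughout.
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    inactive = config.inactive_scheme
    if inactive is None:
        try:
            inactive = scheme.without_of()
        except ValueError:
            inactive = scheme  # scheme has no OF states at all
    pre = config.pre_injection_scheme
    if config.injection_time is not None and pre is None:
        pre = inactive

    traces = []
    for i in range(config.n_traces):
        is_active = bool(rng.random() < config.active_fraction)
        init0 = config.initial_state
        if init0 is not None and not isinstance(init0, str):
            init0 = str(rng.choice(list(init0)))
        if is_active:
            if config.injection_time is not None:
                path = _simulate_switched_path(
                    pre, scheme, config.injection_time, config.duration, rng, init0
                )
            else:
                path = simulate_state_path(
                    scheme, config.duration, rng=rng, initial_state=init0
                )
        else:
            init = init0
            if init is not None and init not in inactive.state_labels:
                init = None
            path = simulate_state_path(inactive, config.duration, rng=rng, initial_state=init)
            # report truth in the active scheme's label space when possible
            try:
                idx = np.array(
                    [scheme.index(inactive.state_labels[s]) for s in path.states],
                    dtype=np.int64,
                )
                path = StatePath(scheme, path.times, idx, path.duration)
            except KeyError:
                pass
        traces.append(
            apply_photophysics(
                path,
                config.photophysics,
                config.frame_interval,
                n_frames=config.n_frames,
                molecule_id=f"mol{i:04d}",
                active=is_active,
                rng=rng,
            )
        )
    return TraceSet(traces, config=config, condition=config.condition)
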