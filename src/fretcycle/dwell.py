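"""Dwell-time kinetics from idealized trajectories.

Converts per-frame state paths into dwell tables and the kinetic
observables of a transporter cycle: per-state lifetimes, composite
inward-facing (IF) / outward-facing (OF) dwells, post-injection wait times,
active/inactive classification, single-exponential fits with censoring, the
competing-exponential photobleaching correction, and molecule-level
bootstrap errors.

Censoring conventions
---------------------
A dwell is *left-censored* when its start is not observed (it begins at the
trace start, or it was already running when the ligand was injected — its
start predates the condition).  It is *right-censored* when its end is not
observed (the trace ends, almost always by photobleaching).  Naive lifetime
means use only uncensored dwells; under exponential photobleaching those
means estimate 1/(k_state + k_bleach), which the rate-subtraction
correction converts back to the true lifetime.  The censored maximum-
likelihood route (sum of all durations over the number of uncensored
dwells) estimates the true rate directly and is available as a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import IdealizedTrajectory

__all__ = [
    "LifetimeEstimate",
    "ExponentialFit",
    "BleachRateEstimate",
    "extract_dwells",
    "composite_dwells",
    "state_lifetimes",
    "transition_density",
    "classify_active",
    "wait_times",
    "fit_exponential",
    "bleach_correct",
    "estimate_bleach_rate",
    "bootstrap_sem",
]

DWELL_COLUMNS = [
    "molecule_id", "state", "state_label", "start_frame", "n_frames",
    "duration_s", "left_censored", "right_censored",
]


@dataclass
class LifetimeEstimate:
    """A state lifetime with its bootstrap SEM and correction bookkeeping."""

    mean_s: float
    sem_s: float
    n_dwells: int
    corrected: bool = False
    k_bleach_used: float = 0.0


@dataclass
class ExponentialFit:
    tau: float
    sem: float
    n_uncensored: int
    method: str
    ks_statistic: float = float("nan")
    ks_pvalue: float = float("nan")

    @property
    def single_exponential_ok(self) -> bool:
        """KS adequacy check at alpha = 0.01 (False flags multi-component decay)."""
        return bool(np.isnan(self.ks_pvalue) or self.ks_pvalue > 0.01)


@dataclass
class BleachRateEstimate:
    k_bleach: float  # 1/s
    sem: float
    mean_window_s: float  # 1/k, the photobleaching-limited observation window
    n_uncensored: int


# ---------------------------------------------------------------------------
# dwell extraction
# ---------------------------------------------------------------------------


def _rle(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode: (run_states, start_indices, run_lengths)."""
    n = len(states)
    if n == 0:
        return (np.empty(0, np.int64),) * 3
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [n]]))
    return states[starts], starts, lengths


def _dwell_frame(
    idealized: Iterable[IdealizedTrajectory],
    relabel: Optional[Callable[[int], tuple[int, str]]],
    injection_frame: Optional[int],
) -> pd.DataFrame:
    rows = []
    for traj in idealized:
        states = traj.states
        if relabel is not None:
            mapped = np.array([relabel(s)[0] for s in range(traj.model.n_states)])
            labels = {relabel(s)[0]: relabel(s)[1] for s in range(traj.model.n_states)}
            states = mapped[states]
        else:
            labels = {s: f"S{s}" for s in range(traj.model.n_states)}
        run_states, starts, lengths = _rle(states)
        ends = starts + lengths
        n = len(states)
        for s, a, ln, b in zip(run_states, starts, lengths, ends):
            left = a == 0
            if injection_frame is not None and a <= injection_frame < b:
                left = True  # dwell was running when the condition changed
            rows.append((
                traj.molecule_id, int(s), labels[int(s)], int(a), int(ln),
                float(ln * traj.frame_interval), bool(left), bool(b == n),
            ))
    return pd.DataFrame(rows, columns=DWELL_COLUMNS)


def extract_dwells(
    idealized: Iterable[IdealizedTrajectory],
    injection_frame: Optional[int] = None,
    state_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Run-length encode idealized trajectories into a dwell table.

    Dwells tile each trajectory without gaps; durations are in seconds.
    Censoring flags mark dwells whose start (trace start, or spanning the
    injection) or end (trace end / photobleaching) was not observed.
    """
    if state_labels is not None:
        labels = list(state_labels)
        relabel = lambda s: (s, labels[s])  # noqa: E731
    else:
        relabel = None
    return _dwell_frame(idealized, relabel, injection_frame)


def composite_dwells(
    idealized: Iterable[IdealizedTrajectory],
    of_states: Sequence[int],
    injection_frame: Optional[int] = None,
) -> pd.DataFrame:
    """Dwells after collapsing states into composite IF vs OF classes.

    ``of_states`` are the model state indices treated as outward-facing
    (typically the highest-FRET state(s)); everything else is inward-facing.
    Used at coarse frame rates where individual IF substates interconvert
    faster than the camera can resolve.
    """
    of = set(int(s) for s in of_states)
    relabel = lambda s: ((1, "OF") if s in of else (0, "IF"))  # noqa: E731
    return _dwell_frame(idealized, relabel, injection_frame)


# ---------------------------------------------------------------------------
# lifetimes and transition densities
# ---------------------------------------------------------------------------


def _uncensored(dwells: pd.DataFrame) -> pd.DataFrame:
    return dwells[~dwells["left_censored"] & ~dwells["right_censored"]]


def state_lifetimes(
    dwells: pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict[str, LifetimeEstimate]:
    """Mean uncensored dwell duration per state, with molecule-bootstrap SEM."""
    out: dict[str, LifetimeEstimate] = {}
    unc = _uncensored(dwells)
    for label, grp in unc.groupby("state_label"):
        durations = grp["duration_s"].to_numpy()
        by_mol = [g["duration_s"].to_numpy() for _, g in grp.groupby("molecule_id")]
        if len(durations) < 2:
            out[label] = LifetimeEstimate(float(durations.mean()) if len(durations) else
                                          float("nan"), float("nan"), len(durations))
            continue
        sem, _, _ = bootstrap_sem(by_mol, n_boot=n_boot, seed=seed)
        out[label] = LifetimeEstimate(float(durations.mean()), sem, len(durations))
    return out


def transition_density(
    idealized: Iterable[IdealizedTrajectory],
    bin_width: float = 0.03,
    e_range: tuple[float, float] = (0.0, 1.0),
) -> dict:
    """Transition density plot data: one count per state change, located at
    the model means of the departing and arriving states (diagonal empty)."""
    pairs = []
    mu = None
    for traj in idealized:
        mu = traj.model.mu
        s = traj.states
        chg = np.flatnonzero(np.diff(s))
        pairs.extend(zip(s[chg], s[chg + 1]))
    lo, hi = e_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    hist = np.zeros((len(edges) - 1, len(edges) - 1))
    pair_counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        pair_counts[(int(a), int(b))] = pair_counts.get((int(a), int(b)), 0) + 1
        ia = min(int((mu[a] - lo) / bin_width), len(edges) - 2)
        ib = min(int((mu[b] - lo) / bin_width), len(edges) - 2)
        hist[ia, ib] += 1
    return {"counts": hist, "bin_edges": edges, "n_transitions": len(pairs),
            "pair_counts": pair_counts}


# ---------------------------------------------------------------------------
# active/inactive classification and wait times
# ---------------------------------------------------------------------------


def classify_active(
    idealized: Iterable[IdealizedTrajectory],
    injection_frame: int,
    of_states: Sequence[int],
) -> pd.DataFrame:
    """Classify each molecule as active (visits OF after injection) or not.

    Active molecules are those that reach the outward-facing state at least
    once after ligand injection and before photobleaching ends the trace.
    Molecules whose trace ends at or before the injection are unclassifiable
    (``classifiable`` False) and excluded from the reported active fraction.
    """
    of = set(int(s) for s in of_states)
    rows = []
    for traj in idealized:
        classifiable = traj.n_frames > injection_frame
        post = traj.states[injection_frame:]
        active = bool(np.any(np.isin(post, list(of))))
        rows.append((traj.molecule_id, active, classifiable))
    df = pd.DataFrame(rows, columns=["molecule_id", "active", "classifiable"])
    cls = df[df["classifiable"]]
    df.attrs["active_fraction"] = float(cls["active"].mean()) if len(cls) else float("nan")
    return df


def wait_times(
    idealized: Iterable[IdealizedTrajectory],
    injection_frame: int,
    of_states: Sequence[int],
) -> np.ndarray:
    """t_wait: injection to first OF entry, per active molecule, in seconds.

    Molecules already outward-facing at the injection instant are excluded
    (their entry predates the condition) with a warning; molecules that
    never reach OF contribute nothing (an empty input yields an empty
    array, not an error).
    """
    of = set(int(s) for s in of_states)
    waits = []
    n_excluded = 0
    for traj in idealized:
        if traj.n_frames <= injection_frame:
            continue
        if int(traj.states[injection_frame]) in of:
            n_excluded += 1
            continue
        post = traj.states[injection_frame:]
        hits = np.flatnonzero(np.isin(post, list(of)))
        if hits.size:
            waits.append(hits[0] * traj.frame_interval)
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} molecules already in OF at injection")
    return np.asarray(waits)


# ---------------------------------------------------------------------------
# exponential fits, photobleaching correction, bootstrap
# ---------------------------------------------------------------------------


def fit_exponential(
    durations: Sequence[float],
    right_censored: Optional[Sequence[bool]] = None,
    method: str = "mle",
    bin_width: Optional[float] = None,
) -> ExponentialFit:
    """Single-exponential fit of a dwell-time sample.

    method="mle"
        Censored maximum likelihood: tau = sum(durations) / n_uncensored.
        With no censoring this reduces to the sample mean.
    method="naive"
        Mean of uncensored durations only (pair with :func:`bleach_correct`
        to remove the photobleaching contribution, the convention used for
        reporting corrected lifetimes).
    method="histogram"
        Unweighted least squares of log counts on binned uncensored
        durations, for parity with histogram-based fitting.

    A Kolmogorov-Smirnov statistic against the fitted exponential (on the
    uncensored sample) flags multi-component decays.
    """
    d = np.asarray(durations, float)
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    cens = np.zeros(len(d), bool) if right_censored is None \
        else np.asarray(right_censored, bool)
    unc = d[~cens]
    n_unc = len(unc)
    if n_unc == 0:
        raise ValueError("no uncensored dwells; lifetime unidentifiable")

    if method == "mle":
        tau = float(d.sum() / n_unc)
    elif method == "naive":
        tau = float(unc.mean())
    elif method == "histogram":
        nbin = max(int(np.sqrt(n_unc)), 5)
        width = bin_width or (unc.max() / nbin)
        edges = np.arange(0, unc.max() + width, width)
        counts, _ = np.histogram(unc, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        # Poisson weighting: var(log n) ~ 1/n, so weight residuals by sqrt(n)
        slope, intercept = np.polyfit(centers[keep], np.log(counts[keep]), 1,
                                      w=np.sqrt(counts[keep]))
        if slope >= 0:
            raise ValueError("histogram fit found non-decaying counts")
        tau = float(-1.0 / slope)
    else:
        raise ValueError(f"unknown method {method!r}")

    sem = tau / np.sqrt(n_unc)
    ks = stats.kstest(unc, "expon", args=(0, float(unc.mean())))
    return ExponentialFit(tau, float(sem), n_unc, method,
                          float(ks.statistic), float(ks.pvalue))


def bleach_correct(
    tau_obs: float,
    k_bleach: float,
    sem_tau: float = 0.0,
    sem_k: float = 0.0,
) -> LifetimeEstimate:
    """Remove the photobleaching contribution from an observed lifetime.

    Photobleaching competes with the state's own exit as an independent
    exponential process, so observed and true rates add:
    1/tau_true = 1/tau_obs - k_bleach.  The SEM is propagated by the delta
    method from the SEMs of the observed lifetime and the bleaching rate.
    Raises when the observed rate does not exceed the bleaching rate (the
    lifetime is then not resolvable at this bleaching rate).
    """
    if tau_obs <= 0:
        raise ValueError("tau_obs must be positive")
    if k_bleach < 0:
        raise ValueError("k_bleach must be >= 0")
    rate = 1.0 / tau_obs - k_bleach
    if rate <= 0:
        raise ValueError("lifetime not resolvable at this bleaching rate "
                         f"(1/tau_obs = {1.0 / tau_obs:.4g} <= k_bleach = {k_bleach:.4g})")
    tau_true = 1.0 / rate
    # d tau_true / d tau_obs = (tau_true / tau_obs)^2 ; d tau_true / d k = tau_true^2
    var = ((tau_true / tau_obs) ** 2 * sem_tau) ** 2 + (tau_true**2 * sem_k) ** 2
    return LifetimeEstimate(tau_true, float(np.sqrt(var)), 0, corrected=True,
                            k_bleach_used=k_bleach)


def estimate_bleach_rate(
    durations: Sequence[float],
    right_censored: Optional[Sequence[bool]] = None,
) -> BleachRateEstimate:
    """Censored-exponential MLE of the photobleaching rate.

    ``durations`` are per-molecule times to donor photobleaching; traces
    whose fluorophore survived to the end of the movie enter as
    right-censored observations.  Also reports the mean photobleaching-
    limited observation window 1/k.
    """
    d = np.asarray(durations, float)
    cens = np.zeros(len(d), bool) if right_censored is None \
        else np.asarray(right_censored, bool)
    n_unc = int((~cens).sum())
    if n_unc == 0:
        raise ValueError("all observations censored; bleaching rate unidentifiable")
    k = n_unc / d.sum()
    sem = k / np.sqrt(n_unc)
    return BleachRateEstimate(float(k), float(sem), float(1.0 / k), n_unc)


def bootstrap_sem(
    values_by_molecule: Sequence[np.ndarray],
    statistic: Optional[Callable[[np.ndarray], float]] = None,
    n_boot: int = 10000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float, float]:
    """Molecule-level bootstrap SEM and percentile CI of a statistic.

    Molecules (not individual dwells) are resampled with replacement so
    that within-molecule correlation is respected.  The default statistic
    is the mean over all pooled values; pass any callable mapping a pooled
    1-D array to a scalar otherwise.  Deterministic given ``seed``.
    Returns (sem, ci_low, ci_high).
    """
    groups = [np.atleast_1d(np.asarray(g, float)) for g in values_by_molecule]
    m = len(groups)
    if m == 0:
        raise ValueError("no molecules to resample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_boot, m))
    if statistic is None:
        sums = np.array([g.sum() for g in groups])
        counts = np.array([len(g) for g in groups])
        tot = sums[idx].sum(axis=1)
        cnt = counts[idx].sum(axis=1)
        stat = np.divide(tot, cnt, out=np.full(n_boot, np.nan), where=cnt > 0)
    else:
        stat = np.empty(n_boot)
        for b in range(n_boot):
            pooled = np.concatenate([groups[j] for j in idx[b]]) if m else np.array([])
            stat[b] = statistic(pooled)
    stat = stat[np.isfinite(stat)]
    alpha = (1.0 - ci_level) / 2.0
    return (
        float(np.std(stat, ddof=1)),
        float(np.quantile(stat, alpha)),
        float(np.quantile(stat, 1.0 - alpha)),
    )
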