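"""Continuous-time kinetic schemes over labeled conformational states.

A :class:`KineticScheme` is the shared currency of the trace simulator and
the transport-cycle model: a set of named states, each with a mean FRET
efficiency, connected by first-order rate constants.  Two states may share
the same FRET mean (e.g. pre- and post-hydrolysis outward-facing states are
spectroscopically indistinguishable at E = 0.92).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["KineticScheme"]


@dataclass(frozen=True)
class KineticScheme:
    """Labeled-state continuous-time Markov rate matrix with FRET means.

    Parameters
    ----------
    state_labels : sequence of str
        Ordered state names, e.g. ``("IF4", "IF3", "IF2", "IF1", "OF")``.
    fret_means : array-like of float
        Mean FRET efficiency of each state, strictly inside (0, 1).
    rate_matrix : array-like, shape (K, K)
        Off-diagonal entries are rate constants k(i->j) in 1/s; the diagonal
        is set to minus the row sum (any provided diagonal is overwritten).
    """

    state_labels: tuple[str, ...]
    fret_means: np.ndarray
    rate_matrix: np.ndarray
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        labels = tuple(str(s) for s in self.state_labels)
        mu = np.asarray(self.fret_means, dtype=float).copy()
        q = np.asarray(self.rate_matrix, dtype=float).copy()
        k = len(labels)
        if len(set(labels)) != k:
            raise ValueError("state labels must be unique")
        if mu.shape != (k,):
            raise ValueError(f"fret_means must have shape ({k},), got {mu.shape}")
        if q.shape != (k, k):
            raise ValueError(f"rate_matrix must have shape ({k}, {k}), got {q.shape}")
        if np.any((mu <= 0.0) | (mu >= 1.0)):
            raise ValueError("fret_means must lie strictly within (0, 1)")
        off = q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0.0) or not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal rates must be finite and >= 0")
        np.fill_diagonal(q, 0.0)
        q[np.diag_indices(k)] = -q.sum(axis=1)
        mu.setflags(write=False)
        q.setflags(write=False)
        object.__setattr__(self, "state_labels", labels)
        object.__setattr__(self, "fret_means", mu)
        object.__setattr__(self, "rate_matrix", q)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(labels)})

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_rates(
        cls,
        state_labels: Sequence[str],
        fret_means: Sequence[float],
        rates: Mapping[tuple[str, str], float],
    ) -> "KineticScheme":
        """Build a scheme from a ``{(from_label, to_label): k}`` mapping."""
        labels = list(state_labels)
        k = len(labels)
        idx = {s: i for i, s in enumerate(labels)}
        q = np.zeros((k, k))
        for (a, b), rate in rates.items():
            if a not in idx or b not in idx:
                raise KeyError(f"unknown state in rate ({a!r} -> {b!r})")
            if a == b:
                raise ValueError("self-rates are not allowed")
            q[idx[a], idx[b]] = rate
        return cls(tuple(labels), np.asarray(fret_means, float), q)

    # -- queries -------------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def exit_rate(self, state) -> float:
        """Total rate of leaving a state (by index or label), in 1/s."""
        i = state if isinstance(state, (int, np.integer)) else self.index(state)
        return -self.rate_matrix[i, i]

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution p solving p Q = 0, sum(p) = 1.

        For reducible chains this returns the least-squares solution, which
        concentrates on the recurrent states; for an absorbing single state
        it returns the corresponding point mass.
        """
        k = self.n_states
        a = np.vstack([self.rate_matrix.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        p, *_ = np.linalg.lstsq(a, b, rcond=None)
        p = np.clip(p, 0.0, None)
        s = p.sum()
        return p / s if s > 0 else np.full(k, 1.0 / k)

    def of_labels(self, prefix: str = "OF") -> tuple[str, ...]:
        """State labels treated as outward-facing, by naming convention."""
        return tuple(s for s in self.state_labels if s.startswith(prefix))

    def restricted(self, keep_labels: Iterable[str]) -> "KineticScheme":
        """Sub-scheme on ``keep_labels``: rates into dropped states are zeroed.

        Used to derive the inactive-molecule (IF-only) dynamics from an
        active scheme by removing entry into the outward-facing states.
        """
        keep = [s for s in self.state_labels if s in set(keep_labels)]
        if not keep:
            raise ValueError("restriction would remove every state")
        ix = [self.index(s) for s in keep]
        q = self.rate_matrix[np.ix_(ix, ix)].copy()
        np.fill_diagonal(q, 0.0)
        return KineticScheme(tuple(keep), self.fret_means[ix], q)

    def without_of(self, prefix: str = "OF") -> "KineticScheme":
        """The inward-facing-only sub-scheme (inactive-molecule dynamics)."""
        keep = [s for s in self.state_labels if not s.startswith(prefix)]
        return self.restricted(keep)

    def to_dict(self) -> dict:
        return {
            "state_labels": list(self.state_labels),
            "fret_means": self.fret_means.tolist(),
            "rate_matrix": self.rate_matrix.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticScheme":
        for key in ("state_labels", "fret_means", "rate_matrix"):
            if key not in d:
                raise ValueError(f"scheme definition missing field {key!r}")
        return cls(
            tuple(d["state_labels"]),
            np.asarray(d["fret_means"], float),
            np.asarray(d["rate_matrix"], float),
        )
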