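"""Hill dose-response fitting of state occupancy versus ligand concentration.

Occupancy of a conformational state, measured as the fraction of idealized
frames assigned to it, is fitted against ligand concentration with the Hill
function

    occ(c) = floor + (ceiling - floor) * c**n / (EC50**n + c**n)

to estimate the half-maximal effective concentration EC50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dwell import bootstrap_sem
from .hmm import IdealizedTrajectory

__all__ = [
    "DoseResponseFit",
    "hill",
    "simulate_occupancies",
    "occupancy_by_condition",
    "fit_hill",
]


def hill(c, ec50: float, n: float = 1.0, floor: float = 0.0, ceiling: float = 1.0):
    """The Hill dose-response function."""
    c = np.asarray(c, float)
    cn = np.power(c, n)
    return floor + (ceiling - floor) * cn / (np.power(ec50, n) + cn)


@dataclass
class DoseResponseFit:
    ec50: float
    ec50_sem: float
    hill_n: float
    floor: float
    ceiling: float
    covariance: np.ndarray
    concentrations: np.ndarray
    occupancy: np.ndarray
    sem: Optional[np.ndarray]
    residuals: np.ndarray
    identifiable: bool = True

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation confidence interval for EC50."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return (self.ec50 - z * self.ec50_sem, self.ec50 + z * self.ec50_sem)

    def predict(self, c) -> np.ndarray:
        return hill(c, self.ec50, self.hill_n, self.floor, self.ceiling)


def simulate_occupancies(
    concentrations: Sequence[float],
    ec50: float,
    n: float = 1.0,
    floor: float = 0.0,
    ceiling: float = 1.0,
    sem: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic occupancy-vs-concentration points: Hill curve + Gaussian noise.

    ``sem`` emulates the per-concentration bootstrap SEM of an occupancy
    measured over a few hundred molecules; points are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, float)
    occ = hill(c, ec50, n, floor, ceiling) + rng.normal(0.0, sem, len(c))
    return pd.DataFrame({
        "concentration": c,
        "occupancy": np.clip(occ, 0.0, 1.0),
        "sem": np.full(len(c), sem),
    })


def occupancy_by_condition(
    idealized_by_condition: Mapping[float, Iterable[IdealizedTrajectory]],
    state: int,
    normalize: str = "all",
    n_boot: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Fractional occupancy of one state at each ligand concentration.

    normalize="all" divides frames in the state by all valid frames;
    normalize="if" divides by frames in the inward-facing subset only
    (every state except the highest-FRET one) — both readings of "relative
    occupancy" are provided since the choice changes the ceiling but not
    the EC50 location.  SEM per concentration is a molecule-level bootstrap.
    """
    rows = []
    for conc, trajs in sorted(idealized_by_condition.items()):
        trajs = list(trajs)
        per_mol = []
        for traj in trajs:
            s = traj.states
            if normalize == "if":
                of_state = traj.model.n_states - 1
                denom_mask = s != of_state
            elif normalize == "all":
                denom_mask = np.ones(len(s), bool)
            else:
                raise ValueError("normalize must be 'all' or 'if'")
            denom = int(denom_mask.sum())
            if denom == 0:
                continue
            per_mol.append((float((s[denom_mask] == state).sum()), float(denom)))
        num = sum(a for a, _ in per_mol)
        den = sum(b for _, b in per_mol)
        occ = num / den if den else float("nan")
        # molecule bootstrap of the pooled ratio
        arr = np.asarray(per_mol)
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(arr), size=(n_boot, len(arr)))
        boots = arr[idx, 0].sum(axis=1) / np.maximum(arr[idx, 1].sum(axis=1), 1.0)
        rows.append((conc, occ, float(np.std(boots, ddof=1)), len(trajs)))
    return pd.DataFrame(rows, columns=["concentration", "occupancy", "sem", "n_molecules"])


def fit_hill(
    concentrations: Sequence[float],
    occupancy: Sequence[float],
    sem: Optional[Sequence[float]] = None,
    fix_n: Optional[float] = None,
) -> DoseResponseFit:
    """Weighted least-squares Hill fit; EC50 SEM from the fit covariance.

    Requires at least four concentrations spanning the transition.  When
    ``fix_n`` is given the Hill coefficient is held at that value (n = 1 for
    single-site binding); otherwise it is free.  Flat, concentration-
    independent data are flagged unidentifiable rather than returning an
    arbitrary EC50.
    """
    c = np.asarray(concentrations, float)
    occ = np.asarray(occupancy, float)
    w = None if sem is None else np.asarray(sem, float)
    if len(c) < 4:
        raise ValueError("need at least 4 concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")

    span = occ.max() - occ.min()
    noise = np.mean(w) if w is not None else 0.0
    if span < max(3.0 * noise, 1e-3):
        return DoseResponseFit(
            float("nan"), float("nan"), float("nan"), float(occ.mean()),
            float(occ.mean()), np.full((4, 4), np.nan), c, occ, w,
            np.zeros_like(occ), identifiable=False,
        )

    p0_ec50 = float(np.exp(np.mean(np.log(c))))
    if fix_n is None:
        model = lambda x, ec50, n, lo, hi: hill(x, ec50, n, lo, hi)  # noqa: E731
        p0 = [p0_ec50, 1.0, float(occ.min()), float(occ.max())]
        bounds = ([c.min() / 1e3, 0.1, -0.5, -0.5], [c.max() * 1e3, 10.0, 1.5, 1.5])
    else:
        model = lambda x, ec50, lo, hi: hill(x, ec50, fix_n, lo, hi)  # noqa: E731
        p0 = [p0_ec50, float(occ.min()), float(occ.max())]
        bounds = ([c.min() / 1e3, -0.5, -0.5], [c.max() * 1e3, 1.5, 1.5])

    try:
        popt, pcov = curve_fit(
            model, c, occ, p0=p0, sigma=w, absolute_sigma=w is not None,
            bounds=bounds, maxfev=20000,
        )
    except RuntimeError:
        warnings.warn("Hill fit did not converge; flagged unidentifiable")
        return DoseResponseFit(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            np.full((4, 4), np.nan), c, occ, w, np.zeros_like(occ),
            identifiable=False,
        )

    ec50 = float(popt[0])
    ec50_sem = float(np.sqrt(pcov[0, 0]))
    if fix_n is None:
        n_hat, lo, hi = float(popt[1]), float(popt[2]), float(popt[3])
    else:
        n_hat, lo, hi = float(fix_n), float(popt[1]), float(popt[2])
    fitted = hill(c, ec50, n_hat, lo, hi)
    identifiable = np.isfinite(ec50_sem) and ec50_sem < 100 * ec50
    return DoseResponseFit(ec50, ec50_sem, n_hat, lo, hi, pcov, c, occ, w,
                           occ - fitted, identifiable=identifiable)
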