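"""Preset schemes and imaging conditions matching the characterized system.

These presets encode the published experimental world: five FRET states
(four inward-facing substates plus one outward-facing state), composite
IF/OF lifetimes per condition, two imaging modes (25 ms frames with a
~4.1 s photobleaching-limited window; 300 ms frames with a ~101 s window),
and a ~60/40 active/inactive molecule mixture in injection experiments.
"""

from __future__ import annotations

import numpy as np

from .cycle import CycleParameters, build_scheme
from .schemes import KineticScheme
from .simulate import PhotophysicsParams

__all__ = [
    "FIVE_STATE_MEANS",
    "FIVE_STATE_LABELS",
    "TABLE1_LIFETIMES",
    "ACTIVE_FRACTION",
    "K_BLEACH_300MS",
    "OBS_WINDOW_25MS",
    "five_state_scheme",
    "composite_scheme",
    "cycle_scheme",
    "photophysics_preset",
    "of_state_indices",
]

# Mean FRET efficiencies of the five conformational states, low to high:
# IF4, IF3, IF2, IF1 (substrate-bound inward-facing), OF (NBD-dimerized).
FIVE_STATE_MEANS = (0.23, 0.42, 0.63, 0.80, 0.92)
FIVE_STATE_LABELS = ("IF4", "IF3", "IF2", "IF1", "OF")

# Composite lifetimes (t_IF, t_OF) in seconds, photobleaching-corrected,
# with their reported SEMs, per condition.
TABLE1_LIFETIMES = {
    "WT_ATP": {"t_if": 16.1, "t_if_sem": 2.2, "t_of": 28.8, "t_of_sem": 4.8},
    "WT_ATP_LTC4": {"t_if": 4.7, "t_if_sem": 0.8, "t_of": 30.8, "t_of_sem": 5.2},
    "E1454Q_ATP_LTC4": {"t_if": 7.7, "t_if_sem": 1.5, "t_of": 31.7, "t_of_sem": 5.5},
}

ACTIVE_FRACTION = 0.6  # fraction of molecules that cycle after ATP injection
K_BLEACH_300MS = 0.010  # 1/s -> ~101 s observation window at 300 ms frames
OBS_WINDOW_25MS = 4.1  # s -> k_bleach ~ 0.244 1/s at 25 ms frames


def photophysics_preset(name: str = "300ms") -> PhotophysicsParams:
    """Imaging presets.

    "300ms": low laser power, k_bleach = 0.010 1/s (~101 s window).
    "25ms" : high laser power, k_bleach = 1/4.1 1/s (~4.1 s window).
    "clean": like 300ms but blink- and bleach-free (unit tests).
    "dim"  : low signal over a wide background (fails the SNR filter).

    Per-channel noise 75 on a total of 1000 gives a FRET scatter
    sigma_E = (sigma/S) * sqrt(E^2 + (1-E)^2) of about 0.05-0.07 across
    the five states, the scatter regime the five-state model resolves.
    """
    common = dict(total_intensity=1000.0, noise_sigma=75.0, background_sigma=50.0,
                  k_blink_off=0.005, k_blink_on=2.0)
    if name == "300ms":
        return PhotophysicsParams(k_bleach=K_BLEACH_300MS, **common)
    if name == "25ms":
        return PhotophysicsParams(k_bleach=1.0 / OBS_WINDOW_25MS, **common)
    if name == "clean":
        return PhotophysicsParams(total_intensity=1000.0, noise_sigma=75.0,
                                  background_sigma=50.0, k_bleach=0.0, k_blink_off=0.0)
    if name == "dim":
        return PhotophysicsParams(total_intensity=300.0, noise_sigma=60.0,
                                  background_sigma=60.0, k_bleach=K_BLEACH_300MS,
                                  k_blink_off=0.005, k_blink_on=2.0)
    raise ValueError(f"unknown preset {name!r}")


def five_state_scheme(
    condition: str = "atp_ltc4",
    if_lifetime: float = 1.0,
    of_lifetime: float = 30.8,
    of_entry_rate: float = 0.2,
) -> KineticScheme:
    """Five-state scheme: a nearest-neighbour IF ladder plus one OF state.

    The four IF substates interconvert along the ladder IF4-IF3-IF2-IF1
    with per-state lifetimes of about ``if_lifetime`` (~1 s, as observed at
    25 ms resolution).  The outward-facing state is entered from IF1 or IF2
    only — transitions into OF originate overwhelmingly from the two
    highest-FRET IF states — and exits at 1/``of_lifetime``.

    condition="apo"  : IF dynamics only (no OF entry).
    condition="ltc4" : apo ladder with the IF1 lifetime 30% longer
                       (substrate stabilizes the substrate-bound state).
    condition="atp_ltc4": full scheme with OF entry and exit.
    """
    r = 1.0 / if_lifetime
    rates = {
        ("IF4", "IF3"): r,
        ("IF3", "IF4"): r / 2, ("IF3", "IF2"): r / 2,
        ("IF2", "IF3"): r / 2, ("IF2", "IF1"): r / 2,
        ("IF1", "IF2"): r,
    }
    if condition == "ltc4":
        rates[("IF1", "IF2")] = r / 1.3  # IF1 lifetime up ~30% with substrate
    elif condition == "atp_ltc4":
        rates[("IF1", "OF")] = of_entry_rate
        rates[("IF2", "OF")] = of_entry_rate
        rates[("OF", "IF1")] = 1.0 / of_lifetime
    elif condition != "apo":
        raise ValueError(f"unknown condition {condition!r}")
    return KineticScheme.from_rates(FIVE_STATE_LABELS, FIVE_STATE_MEANS, rates)


def composite_scheme(
    t_if: float,
    t_of: float,
    fret_if: float = 0.63,
    fret_of: float = 0.92,
) -> KineticScheme:
    """Two-state composite IF <-> OF scheme with the given mean lifetimes."""
    return KineticScheme.from_rates(
        ("IF", "OF"), (fret_if, fret_of),
        {("IF", "OF"): 1.0 / t_if, ("OF", "IF"): 1.0 / t_of},
    )


def cycle_scheme(row: str = "WT_ATP_LTC4", k2_floor=None) -> KineticScheme:
    """Three-state cycle scheme parameterized from the measured lifetimes."""
    from .cycle import rates_from_lifetimes

    params = rates_from_lifetimes(
        TABLE1_LIFETIMES[row]["t_if"],
        TABLE1_LIFETIMES["WT_ATP_LTC4"]["t_of"],
        TABLE1_LIFETIMES["E1454Q_ATP_LTC4"]["t_of"],
        k2_floor=k2_floor,
    )
    variant = "E1454Q" if row.startswith("E1454Q") else "WT"
    return build_scheme(params, variant)


def of_state_indices(mu, threshold: float = 0.9) -> list[int]:
    """Model state indices treated as outward-facing (mean E >= threshold)."""
    mu = np.asarray(mu, float)
    return [int(i) for i in np.flatnonzero(mu >= threshold)]
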