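"""Standard binding free energy directly from bound/unbound frame statistics.

For a host–guest trajectory in which the guest repeatedly enters and leaves
the host pocket, the standard binding free energy is

    ΔG⁰ = −k_B·T·ln(N_B/N_U) − k_B·T·ln(V/V₀),

where N_B and N_U count bound and unbound frames, V is the simulation box
volume, and V₀ = 1660 ų is the per-molecule volume at the 1 M standard
state.  A frame is bound when the host–guest center-of-mass distance is at
or below a threshold, taken dynamically as the sum of the host and guest
radii of gyration.  The estimate is only defined when both states were
actually visited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KB, STANDARD_VOLUME_A3
from .model_io import Solute, TrajectorySnapshot

__all__ = [
    "DistanceSeries",
    "BindingCounts",
    "StdStateParams",
    "radius_of_gyration",
    "com_distance_series",
    "bound_threshold",
    "classify_and_count",
    "std_state_correction",
    "estimate_dg0",
    "threshold_robustness",
    "UndefinedEstimateError",
]


class UndefinedEstimateError(ValueError):
    """Raised when one of the two states was never observed."""


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame host–guest center-of-mass distance, Å."""

    distances: np.ndarray
    frame_indices: np.ndarray | None = None

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        if d.size == 0:
            raise ValueError("distance series is empty")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n_frames(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class BindingCounts:
    NU: int
    NB: int
    events: int  # bound↔unbound transitions between consecutive frames
    threshold: float  # Å

    @property
    def n_frames(self) -> int:
        return self.NU + self.NB


@dataclass(frozen=True)
class StdStateParams:
    """Box volume (ų), temperature (K), and standard-state volume (ų).

    V0 defaults to the conventional 1660 ų (1 M at 298 K); T defaults to
    300 K, a typical production-thermostat setting.
    """

    volume: float
    temperature: float = 300.0
    v0: float = STANDARD_VOLUME_A3

    def __post_init__(self):
        if self.volume <= 0 or self.temperature <= 0 or self.v0 <= 0:
            raise ValueError("volume, temperature and v0 must be positive")


def radius_of_gyration(
    positions: np.ndarray,
    masses: np.ndarray | None = None,
) -> float:
    """Mass-weighted radius of gyration about the center of mass, Å.

    With ``masses=None`` all atoms are weighted equally (useful for testing
    against closed forms).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(pos) == 0:
        raise ValueError("need at least one atom")
    w = np.ones(len(pos)) if masses is None else np.asarray(masses, dtype=float)
    w = w / w.sum()
    com = w @ pos
    d2 = np.einsum("ij,ij->i", pos - com, pos - com)
    return float(math.sqrt(w @ d2))


def com_distance_series(
    snapshots,
    host_indices,
    guest_indices,
    masses: np.ndarray | None = None,
) -> DistanceSeries:
    """Per-frame distance between host and guest mass-weighted centers."""
    hi = np.asarray(host_indices, dtype=int)
    gi = np.asarray(guest_indices, dtype=int)
    if hi.size == 0 or gi.size == 0:
        raise ValueError("host and guest selections must be nonempty")
    if np.intersect1d(hi, gi).size:
        raise ValueError("host and guest selections overlap")

    def com(pos, idx):
        if masses is None:
            return pos[idx].mean(axis=0)
        w = masses[idx] / masses[idx].sum()
        return w @ pos[idx]

    dists = np.array(
        [float(np.linalg.norm(com(s.positions, hi) - com(s.positions, gi))) for s in snapshots]
    )
    frames = np.array([s.frame_index for s in snapshots])
    return DistanceSeries(distances=dists, frame_indices=frames)


def bound_threshold(host_rg: float, guest_rg: float) -> float:
    """Dynamic bound/unbound threshold: sum of the two radii of gyration, Å."""
    return host_rg + guest_rg


def classify_and_count(series: DistanceSeries, threshold: float) -> BindingCounts:
    """Tally bound (distance ≤ threshold) and unbound frames and transitions."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bound = series.distances <= threshold  # ties count as bound
    nb = int(bound.sum())
    nu = int((~bound).sum())
    events = int(np.count_nonzero(bound[1:] != bound[:-1]))
    return BindingCounts(NU=nu, NB=nb, events=events, threshold=threshold)


def std_state_correction(ss: StdStateParams) -> float:
    """Standard-state (concentration) correction −k_B·T·ln(V/V₀), kcal/mol."""
    return -KB * ss.temperature * math.log(ss.volume / ss.v0)


def estimate_dg0(counts: BindingCounts, ss: StdStateParams) -> float:
    """ΔG⁰ = −k_B·T·ln(NB/NU) + standard-state correction, kcal/mol."""
    if counts.NU < 1 or counts.NB < 1:
        raise UndefinedEstimateError(
            f"both states must be observed (NU={counts.NU}, NB={counts.NB})"
        )
    return -KB * ss.temperature * math.log(counts.NB / counts.NU) + std_state_correction(ss)


def threshold_robustness(
    series: DistanceSeries,
    threshold: float,
    halfwidth: float = 2.0,
    step: float = 0.5,
    ss: StdStateParams | None = None,
) -> dict:
    """Scan the classification threshold ± halfwidth and report ΔG⁰ stability.

    Returns the scanned thresholds, their ΔG⁰ values, and the maximum
    relative change against the central estimate.  A scanned threshold that
    leaves one state empty makes the scan "unstable" and is reported.
    """
    if halfwidth <= 0 or step <= 0:
        raise ValueError("halfwidth and step must be positive")
    if ss is None:
        raise ValueError("standard-state parameters are required")
    n_steps = int(round(halfwidth / step))
    offsets = np.arange(-n_steps, n_steps + 1) * step
    thresholds = threshold + offsets
    central = classify_and_count(series, threshold)
    if central.NU == 0 or central.NB == 0:
        return {
            "stable": False,
            "offending_threshold": float(threshold),
            "thresholds": thresholds,
            "dg0": None,
            "max_relative_change": math.inf,
        }
    ref = estimate_dg0(central, ss)
    values = []
    for t in thresholds:
        counts = classify_and_count(series, float(t))
        if counts.NU == 0 or counts.NB == 0:
            return {
                "stable": False,
                "offending_threshold": float(t),
                "thresholds": thresholds,
                "dg0": None,
                "max_relative_change": math.inf,
            }
        values.append(estimate_dg0(counts, ss))
    values = np.array(values)
    max_rel = float(np.max(np.abs(values - ref)) / abs(ref))
    return {
        "stable": True,
        "thresholds": thresholds,
        "dg0": values,
        "reference_dg0": ref,
        "max_relative_change": max_rel,
    }
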