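"""Pore hydration: water counting, wet/dry state labels, dewetting kinetics.

Pore water is defined geometrically: water oxygens lying between two bounding
planes (each the centre of mass of a ring selection, e.g. the L312 ring above
and the P320 ring below the cavity) and within a lateral cylinder around the
pore axis.  The bounding planes are recomputed every frame, so the region
follows the protein.  The axis used for the lateral test is the line through
the two plane COMs, which makes the count exactly invariant under rigid
transforms of the whole frame.

Dewetting kinetics is quantified by the autocorrelation of the pore-water
count,

    C(tau) = <N(t) N(t+tau)> / <N^2>,

averaged jointly over all trajectories, without mean subtraction; a wet pore
gives a plateau near 1, fast and complete dewetting drives C down.  A
mean-subtracted variant is available behind a flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core_io import AtomIndexSet, AxisFrame, Structure, Trajectory, center_of_mass

__all__ = ["PoreRegion", "HydrationSeries", "StateLabels", "AcfResult",
           "DEFAULT_WATER_RESNAMES", "count_pore_water", "hydration_series",
           "classify_states", "water_acf"]

#: Residue names recognised as water when building water selections.
DEFAULT_WATER_RESNAMES = ("HOH", "TIP3", "SOL", "WAT")


@dataclass
class PoreRegion:
    """The pore-cavity region between two plane-defining ring selections.

    ``top_sel`` defines the upper bounding plane (filter side, smaller z in
    the cavity-positive convention), ``bottom_sel`` the lower plane.  Waters
    further than ``lateral_radius`` from the top-COM -> bottom-COM axis are
    excluded; this cylinder is needed because bulk water in the simulation
    box spans the same axial range as the cavity.
    """

    top_sel: AtomIndexSet
    bottom_sel: AtomIndexSet
    lateral_radius: float = 10.0
    axisframe: Optional[AxisFrame] = None

    def __post_init__(self) -> None:
        if not self.lateral_radius > 0:
            raise ValueError("lateral_radius must be positive")
        if len(self.top_sel) == 0 or len(self.bottom_sel) == 0:
            raise ValueError("bounding selections must be non-empty")

    def plane_coms(self, structure: Structure,
                   coords: Optional[np.ndarray] = None) -> Tuple[np.ndarray, np.ndarray]:
        top = center_of_mass(structure, self.top_sel, coords=coords)
        bottom = center_of_mass(structure, self.bottom_sel, coords=coords)
        return top, bottom


@dataclass
class HydrationSeries:
    """Per-frame pore-water counts with time stamps (ps)."""

    t: np.ndarray
    n_water: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.n_water = np.asarray(self.n_water)
        if len(self.t) != len(self.n_water):
            raise ValueError("t and n_water must have equal length")
        if len(self.t) > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("t must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 1.0


@dataclass
class StateLabels:
    """Per-frame hydration-state labels with the thresholds that produced them."""

    labels: np.ndarray                     # entries in {"wet","semihydrated","dry"}
    wet_reference: float
    dry_frac: float
    semi_frac: float
    smooth_window: int

    def fraction(self, state: str) -> float:
        return float(np.mean(self.labels == state))


@dataclass
class AcfResult:
    """Water-number autocorrelation on a lag grid (ps)."""

    lag: np.ndarray
    C: np.ndarray
    n_series: int
    se: Optional[np.ndarray] = None        # across-series standard error


def count_pore_water(coords: np.ndarray, structure: Structure,
                     region: PoreRegion, water_sel: AtomIndexSet) -> int:
    """Number of selected water oxygens inside the pore region for one frame."""
    water_sel.validate_against(structure)
    top, bottom = region.plane_coms(structure, coords=coords)
    axis = bottom - top
    length = np.linalg.norm(axis)
    if length < 1e-9:
        raise ValueError("bounding planes coincide; pore region undefined")
    u = axis / length
    w = np.asarray(coords)[water_sel.indices] - top
    s = w @ u
    perp = np.linalg.norm(w - np.outer(s, u), axis=1)
    inside = (s >= 0) & (s <= length) & (perp <= region.lateral_radius)
    return int(inside.sum())


def hydration_series(traj: Trajectory, region: PoreRegion,
                     water_sel: AtomIndexSet, stride: int = 1) -> HydrationSeries:
    """Pore-water count for every ``stride``-th frame, planes recomputed per frame."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.arange(0, traj.n_frames, stride)
    counts = np.array([count_pore_water(traj.frames[i], traj.topology,
                                        region, water_sel) for i in idx])
    return HydrationSeries(t=traj.time0 + traj.dt * idx, n_water=counts)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the edges."""
    if window <= 1:
        return x.astype(float)
    half = window // 2
    out = np.empty(len(x), dtype=float)
    for i in range(len(x)):
        lo = max(0, i - half)
        hi = min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def classify_states(series: HydrationSeries, wet_reference: float,
                    dry_frac: float = 0.15, semi_frac: float = 0.6,
                    smooth_window: int = 5) -> StateLabels:
    """Label each frame wet / semihydrated / dry.

    The smoothed count n is dry if n <= dry_frac * wet_reference,
    semihydrated if n <= semi_frac * wet_reference, else wet.  The default
    fractions (0.15, 0.6) encode the observed levels of a fully wet pore,
    a semihydrated pore at about half that count, and a pore essentially
    free of liquid water, as scale-free fractions of the wet reference.
    """
    if not wet_reference > 0:
        raise ValueError("wet_reference must be positive")
    if not (0 < dry_frac < semi_frac < 1):
        raise ValueError("need 0 < dry_frac < semi_frac < 1")
    smoothed = _smooth(np.asarray(series.n_water, dtype=float), smooth_window)
    labels = np.full(len(smoothed), "wet", dtype=object)
    labels[smoothed <= semi_frac * wet_reference] = "semihydrated"
    labels[smoothed <= dry_frac * wet_reference] = "dry"
    return StateLabels(labels=labels, wet_reference=wet_reference,
                       dry_frac=dry_frac, semi_frac=semi_frac,
                       smooth_window=smooth_window)


def water_acf(series_list: Sequence[HydrationSeries], max_lag: float,
              lag_stride: int = 1, subtract_mean: bool = False) -> AcfResult:
    """Autocorrelation C(tau) of the pore-water number.

    The numerator <N(t)N(t+tau)> and denominator <N^2> are pooled over all
    series ("averaging over all trajectories"), so C(0) = 1 exactly.  With
    ``subtract_mean`` the conventional normalised autocovariance is returned
    instead; the unsubtracted form is the default because its plateau
    <N>^2/<N^2> distinguishes partial from complete dewetting.

    The across-series standard error of C is reported when more than one
    series is supplied.
    """
    if not series_list:
        raise ValueError("no series supplied")
    dt = series_list[0].dt
    for s in series_list[1:]:
        if abs(s.dt - dt) > 1e-9:
            raise ValueError("all series must share the same dt")
    shortest = min(len(s.n_water) for s in series_list)
    max_steps = int(np.floor(max_lag / dt + 1e-9))
    if max_steps >= shortest:
        raise ValueError("max_lag must be shorter than the shortest series")
    lags = np.arange(0, max_steps + 1, lag_stride)
    arrays = [np.asarray(s.n_water, dtype=float) for s in series_list]
    if subtract_mean:
        pooled_mean = np.concatenate(arrays).mean()
        arrays = [a - pooled_mean for a in arrays]
    denom_per = np.array([np.mean(a * a) for a in arrays])
    denom = np.concatenate(arrays)
    denom = np.mean(denom * denom)
    if denom == 0:
        raise ValueError("all-zero series: C(tau) undefined")
    C = np.empty(len(lags))
    per_series = np.empty((len(arrays), len(lags)))
    for j, lag in enumerate(lags):
        num_sum = 0.0
        num_n = 0
        for i, a in enumerate(arrays):
            prod = a[:len(a) - lag] * a[lag:] if lag else a * a
            num_sum += prod.sum()
            num_n += len(prod)
            per_series[i, j] = (prod.mean() / denom_per[i]
                                if denom_per[i] > 0 else np.nan)
        C[j] = (num_sum / num_n) / denom
    se = None
    if len(arrays) > 1:
        se = np.nanstd(per_series, axis=0, ddof=1) / np.sqrt(len(arrays))
    return AcfResult(lag=lags * dt, C=C, n_series=len(arrays), se=se)
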