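"""Free-energy profiles along the pore axis, three ways.

1. Boltzmann inversion of equilibrium axial densities,
   G(z) = -kT ln(rho(z)/rho_bulk), for species that sample the whole axis
   in unbiased runs (water, permeant ions in the open state).
2. WHAM over umbrella-sampling windows: harmonic restraints at a ladder of
   axial centres, combined by the self-consistent weighted-histogram
   equations into one unbiased PMF.
3. Stitching: an umbrella PMF valid only over the dewetted region and an
   equilibrium profile valid in the bulk-connected region are joined by a
   constant shift plus a linear crossfade over their overlap.

Energies are in kcal/mol; spring constants are accepted in kJ mol^-1 nm^-2
and converted.  Errors are split-half standard errors: the estimator is run
on the first and second halves of the data and the per-bin spread of the two
(after common-reference alignment) is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .core_io import AtomIndexSet, AxisFrame, Trajectory
from .units import DEFAULT_TEMPERATURE, kT as thermal_kT, spring_kj_nm2_to_kcal_A2

__all__ = ["DensityProfile", "FreeEnergyProfile", "UmbrellaWindow", "WhamResult",
           "axial_density", "boltzmann_invert", "wham", "split_half_error",
           "half_profile_error", "stitch_pmf"]


@dataclass
class DensityProfile:
    """Per-bin average occupancy of a species along the pore axis."""

    z_edges: np.ndarray
    counts: np.ndarray     # summed per-frame occupancy per bin
    n_frames: int
    species: str = "other"

    def __post_init__(self) -> None:
        self.z_edges = np.asarray(self.z_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if not (np.diff(self.z_edges) > 0).all():
            raise ValueError("z_edges must be strictly increasing")
        if len(self.counts) != len(self.z_edges) - 1:
            raise ValueError("counts must have len(z_edges) - 1 entries")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def density(self) -> np.ndarray:
        """Mean occupancy per frame per bin (bins share the same cylinder volume)."""
        return self.counts / max(self.n_frames, 1)


@dataclass
class FreeEnergyProfile:
    """Axial free energy on a bin grid, kcal/mol, with a declared zero."""

    z: np.ndarray
    G: np.ndarray
    err: Optional[np.ndarray] = None
    reference: str = "minimum"
    capped_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    provenance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        self.G = np.asarray(self.G, dtype=np.float64)
        self.capped_bins = np.asarray(self.capped_bins, dtype=int)
        if len(self.z) != len(self.G):
            raise ValueError("z and G must have equal length")

    @property
    def valid_mask(self) -> np.ndarray:
        m = np.ones(len(self.z), dtype=bool)
        m[self.capped_bins] = False
        return m

    def rereference(self, reference: str = "minimum") -> "FreeEnergyProfile":
        """Shift G so the minimum over non-capped bins is zero."""
        if reference != "minimum":
            raise ValueError("only the 'minimum' reference is supported here")
        shift = self.G[self.valid_mask].min()
        return FreeEnergyProfile(self.z.copy(), self.G - shift,
                                 None if self.err is None else self.err.copy(),
                                 "minimum", self.capped_bins.copy(),
                                 self.provenance)

    def to_tsv(self, path: str) -> None:
        err = self.err if self.err is not None else np.full_like(self.G, np.nan)
        with open(path, "w") as fh:
            fh.write("z\tG_kcal_mol\terr\tcapped\n")
            capped = set(self.capped_bins.tolist())
            for i in range(len(self.z)):
                fh.write(f"{self.z[i]:.4f}\t{self.G[i]:.6f}\t{err[i]:.6f}\t"
                         f"{int(i in capped)}\n")


@dataclass
class UmbrellaWindow:
    """One umbrella-sampling window on the axial reaction coordinate.

    ``spring`` is in kJ mol^-1 nm^-2 (the unit restraint forces are reported
    in); it is converted to kcal mol^-1 A^-2 internally.  ``samples`` are
    reaction-coordinate values in angstroms.
    """

    center: float
    spring: float
    samples: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not self.spring > 0:
            raise ValueError("spring constant must be positive")
        if self.samples.size == 0:
            raise ValueError("window has no samples")

    @property
    def spring_kcal_A2(self) -> float:
        return spring_kj_nm2_to_kcal_A2(self.spring)

    def bias(self, z: np.ndarray) -> np.ndarray:
        """Restraint energy at positions z, kcal/mol."""
        return 0.5 * self.spring_kcal_A2 * (np.asarray(z) - self.center) ** 2


@dataclass
class WhamResult:
    pmf: FreeEnergyProfile
    f: np.ndarray              # per-window free-energy constants, kcal/mol, f[0] = 0
    n_iter: int
    converged: bool
    tol_achieved: float
    diagnostics: Optional[str] = None


def axial_density(traj: Trajectory, species_sel: AtomIndexSet,
                  axisframe: Optional[AxisFrame] = None,
                  lateral_radius: float = 10.0,
                  z_edges: Optional[np.ndarray] = None,
                  species: str = "other",
                  frame_slice: slice = slice(None)) -> DensityProfile:
    """Histogram selected particles along z inside a lateral cylinder.

    Coordinates are assumed canonical (pore axis = z through the origin).
    ``frame_slice`` restricts the frames used, e.g. the tail of a run.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if lateral_radius <= 0:
        raise ValueError("lateral_radius must be positive")
    if z_edges is None:
        raise ValueError("z_edges are required")
    z_edges = np.asarray(z_edges, dtype=np.float64)
    species_sel.validate_against(traj.topology)
    frames = traj.frames[frame_slice]
    if len(frames) == 0:
        raise ValueError("frame_slice selects no frames")
    counts = np.zeros(len(z_edges) - 1)
    for coords in frames:
        pts = coords[species_sel.indices]
        r = np.hypot(pts[:, 0], pts[:, 1])
        zs = pts[r <= lateral_radius, 2]
        counts += np.histogram(zs, bins=z_edges)[0]
    return DensityProfile(z_edges=z_edges, counts=counts,
                          n_frames=len(frames), species=species)


def boltzmann_invert(density: DensityProfile,
                     temperature: float = DEFAULT_TEMPERATURE,
                     bulk_zrange: Tuple[float, float] = (0.0, 0.0),
                     cap: float = 10.0) -> FreeEnergyProfile:
    """Effective free energy G(z) = -kT ln(rho(z)/rho_bulk).

    ``rho_bulk`` is the mean density over the bins whose centres fall in
    ``bulk_zrange`` (a region connected to bulk solution); G is zero there
    by construction.  Zero-count bins are set to ``cap`` kcal/mol and listed
    in ``capped_bins``.
    """
    zc = density.z_centers
    rho = density.density
    bulk_mask = (zc >= bulk_zrange[0]) & (zc <= bulk_zrange[1])
    if not bulk_mask.any() or not (rho[bulk_mask] > 0).any():
        raise ValueError("bulk_zrange contains no bin with nonzero density")
    rho_bulk = rho[bulk_mask].mean()
    if rho_bulk <= 0:
        raise ValueError("zero bulk density")
    kT = thermal_kT(temperature)
    G = np.full(len(zc), float(cap))
    nonzero = rho > 0
    G[nonzero] = -kT * np.log(rho[nonzero] / rho_bulk)
    capped = np.flatnonzero(~nonzero)
    return FreeEnergyProfile(z=zc, G=G, reference=f"bulk mean over {bulk_zrange}",
                             capped_bins=capped)


def _check_window_overlap(windows: Sequence[UmbrellaWindow],
                          z_edges: np.ndarray) -> Optional[str]:
    """Return a coverage diagnostic if consecutive windows share no bin."""
    order = np.argsort([w.center for w in windows])
    prev_bins = None
    for i in order:
        h = np.histogram(windows[i].samples, bins=z_edges)[0]
        occ = set(np.flatnonzero(h).tolist())
        if prev_bins is not None and not (occ & prev_bins):
            return (f"no histogram overlap between windows centred at "
                    f"{windows[i].center:g} A and its neighbour; PMF pieces "
                    f"are only determined up to independent constants")
        prev_bins = occ if prev_bins is None else occ
    return None


def wham(windows: Sequence[UmbrellaWindow], z_edges: np.ndarray,
         tolerance: float = 1e-8, max_iter: int = 100_000,
         cap: Optional[float] = None) -> WhamResult:
    """Weighted-histogram analysis of umbrella windows.

    Iterates the self-consistent WHAM equations (in log space, via
    logsumexp) until the largest change in the per-window free-energy
    constants f_i is below ``tolerance`` (kcal/mol) or ``max_iter`` is hit.
    The PMF is referenced to its minimum; bins visited by no window are set
    to ``cap`` (default: max finite G + 5 kT) and flagged.
    """
    if not windows:
        raise ValueError("at least one window required")
    T = windows[0].temperature
    if any(abs(w.temperature - T) > 1e-9 for w in windows):
        raise ValueError("all windows must share one temperature")
    kT = thermal_kT(T)
    z_edges = np.asarray(z_edges, dtype=np.float64)
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    n_win, n_bin = len(windows), len(zc)
    h = np.stack([np.histogram(w.samples, bins=z_edges)[0] for w in windows]).astype(float)
    N = h.sum(axis=1)
    if (N == 0).any():
        raise ValueError("a window has no samples inside the z range")
    H = h.sum(axis=0)
    bias_kT = np.stack([w.bias(zc) for w in windows]) / kT
    lnN = np.log(N)
    f_kT = np.zeros(n_win)
    ln_H = np.where(H > 0, np.log(np.maximum(H, 1e-300)), -np.inf)
    n_iter = 0
    delta = np.inf
    for n_iter in range(1, max_iter + 1):
        # ln denom_b = logsumexp_i [ln N_i + f_i - beta c_ib]
        ln_denom = logsumexp(lnN[:, None] + f_kT[:, None] - bias_kT, axis=0)
        ln_p = ln_H - ln_denom
        f_new = -logsumexp(ln_p[None, :] - bias_kT, axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f_kT)))
        f_kT = f_new
        if delta * kT < tolerance:
            break
    converged = delta * kT < tolerance
    diagnostics = _check_window_overlap(windows, z_edges)
    if diagnostics is not None:
        converged = False
    G = np.full(n_bin, np.nan)
    visited = np.isfinite(ln_p)
    G[visited] = -kT * ln_p[visited]
    G[visited] -= G[visited].min()
    cap_value = cap if cap is not None else (np.nanmax(G[visited]) + 5 * kT)
    capped = np.flatnonzero(~visited)
    G[~visited] = cap_value
    pmf = FreeEnergyProfile(z=zc, G=G, reference="minimum", capped_bins=capped)
    return WhamResult(pmf=pmf, f=f_kT * kT, n_iter=n_iter, converged=converged,
                      tol_achieved=delta * kT, diagnostics=diagnostics)


def half_profile_error(first: FreeEnergyProfile,
                       second: FreeEnergyProfile) -> Tuple[np.ndarray, np.ndarray]:
    """Split-half standard error from two half-data profiles.

    The second profile is shifted by the constant that minimises the squared
    difference over bins valid in both halves (profiles are defined up to a
    constant), then err = |G1 - G2| / 2 per bin, the standard error of the
    two-estimate mean.  Bins capped in either half get err = nan and are
    returned in the flagged index array.
    """
    if len(first.z) != len(second.z) or not np.allclose(first.z, second.z):
        raise ValueError("half profiles are on different grids")
    both = first.valid_mask & second.valid_mask
    if not both.any():
        raise ValueError("no bin is valid in both halves")
    shift = np.mean(first.G[both] - second.G[both])
    diff = first.G - (second.G + shift)
    err = np.abs(diff) / 2.0
    err[~both] = np.nan
    return err, np.flatnonzero(~both)


def split_half_error(windows: Sequence[UmbrellaWindow], z_edges: np.ndarray,
                     tolerance: float = 1e-8,
                     max_iter: int = 100_000) -> Tuple[np.ndarray, np.ndarray]:
    """Per-bin split-half standard error of a WHAM PMF.

    Each window's samples are split into first and second halves, WHAM is run
    on each half independently, and the two PMFs are compared after
    common-reference alignment.
    """
    halves: List[List[UmbrellaWindow]] = [[], []]
    for w in windows:
        mid = len(w.samples) // 2
        if mid == 0 or len(w.samples) - mid == 0:
            raise ValueError("every window must be splittable into two non-empty halves")
        halves[0].append(UmbrellaWindow(w.center, w.spring, w.samples[:mid], w.temperature))
        halves[1].append(UmbrellaWindow(w.center, w.spring, w.samples[mid:], w.temperature))
    p1 = wham(halves[0], z_edges, tolerance, max_iter).pmf
    p2 = wham(halves[1], z_edges, tolerance, max_iter).pmf
    return half_profile_error(p1, p2)


def stitch_pmf(umbrella: FreeEnergyProfile, equilibrium: FreeEnergyProfile,
               overlap_zrange: Tuple[float, float]) -> FreeEnergyProfile:
    """Join an umbrella PMF and an equilibrium-derived profile into one PMF.

    The equilibrium profile is shifted by the constant minimising the squared
    difference over the overlap, then the output takes the umbrella value
    below the overlap, the shifted equilibrium value above it, and a linear
    crossfade (weight linear in z) across the overlap.  Per-bin provenance is
    recorded.  Requires >= 2 bins valid in both profiles inside the overlap.
    """
    lo, hi = overlap_zrange
    if not lo < hi:
        raise ValueError("overlap_zrange must be increasing")
    zu = np.union1d(np.round(umbrella.z, 9), np.round(equilibrium.z, 9))

    def _interp(profile: FreeEnergyProfile) -> np.ndarray:
        m = profile.valid_mask
        zv, gv = profile.z[m], profile.G[m]
        # endpoints clamp; only points truly outside the profile (beyond a
        # grid-rounding tolerance) are marked undefined
        out = np.interp(zu, zv, gv)
        out[(zu < zv.min() - 1e-9) | (zu > zv.max() + 1e-9)] = np.nan
        return out

    gu = _interp(umbrella)
    ge = _interp(equilibrium)
    overlap = (zu >= lo) & (zu <= hi) & np.isfinite(gu) & np.isfinite(ge)
    if overlap.sum() < 2:
        raise ValueError("need >= 2 bins valid in both profiles inside the overlap")
    shift = np.mean(gu[overlap] - ge[overlap])
    ge = ge + shift
    w = np.clip((hi - zu) / (hi - lo), 0.0, 1.0)   # 1 below overlap -> 0 above
    G = np.where(np.isfinite(gu) & np.isfinite(ge), w * gu + (1 - w) * ge,
                 np.where(np.isfinite(gu), gu, ge))
    provenance = np.where(np.isfinite(gu) & np.isfinite(ge),
                          np.where(w >= 1.0, "umbrella",
                                   np.where(w <= 0.0, "equilibrium", "blend")),
                          np.where(np.isfinite(gu), "umbrella", "equilibrium"))
    valid = np.isfinite(G)
    G = G - np.nanmin(G)
    G[~valid] = np.nanmax(G[valid]) if valid.any() else 0.0
    return FreeEnergyProfile(z=zu, G=G, reference="minimum",
                             capped_bins=np.flatnonzero(~valid),
                             provenance=provenance)
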