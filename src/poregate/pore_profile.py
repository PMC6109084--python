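"""HOLE-style pore-radius profiling.

At each axial position z the profiler finds the largest sphere centred in
the plane at z that touches no atom:

    r(z) = max_c  min_i ( |c - x_i| - R_i ),   c = (cx, cy, z)

where R_i are hard-sphere atomic radii.  Sphere-atom contact is fully
three-dimensional: atoms within ``r_max + R_i`` of the slice participate, not
just atoms cut by the plane.  The in-plane maximisation uses seeded simulated
annealing with restarts (the objective is non-convex in irregular slices)
followed by a deterministic Nelder-Mead polish.  Profiles are traced
sequentially along z, each slice starting from the previous slice's centre.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize

from .core_io import Structure

logger = logging.getLogger(__name__)

__all__ = ["RadiusSet", "SliceResult", "PoreProfile", "slice_max_radius",
           "compute_profile", "average_profiles"]

#: Flagged radius cap: slices reaching it are open to bulk.
DEFAULT_R_MAX = 15.0


@dataclass
class RadiusSet:
    """Hard-sphere element radii in angstroms.

    Defaults are Bondi-type values; elements absent from the table fall back
    to ``default`` (carbon-like 1.70 A).
    """

    radii: Dict[str, float] = field(default_factory=lambda: {
        "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80})
    default: float = 1.70

    def __post_init__(self) -> None:
        if self.default <= 0 or any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")

    def lookup(self, elements: Sequence[str]) -> np.ndarray:
        return np.array([self.radii.get(str(e).upper(), self.default)
                         for e in elements])

    @classmethod
    def from_file(cls, path: str) -> "RadiusSet":
        """Read 'ELEMENT radius' lines; a line 'DEFAULT r' sets the fallback."""
        radii: Dict[str, float] = {}
        default = 1.70
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if parts[0].upper() == "DEFAULT":
                    default = float(parts[1])
                else:
                    radii[parts[0].upper()] = float(parts[1])
        return cls(radii=radii, default=default)


@dataclass
class SliceResult:
    center: np.ndarray  # in-plane (x, y)
    radius: float
    unbounded: bool = False


@dataclass
class PoreProfile:
    """Pore radius versus axial position, with per-slice sphere centres."""

    z: np.ndarray
    radius: np.ndarray
    centers: np.ndarray            # (n, 2)
    unbounded: np.ndarray          # bool flags: slice open to bulk
    spread: Optional[np.ndarray] = None
    n_sources: int = 1

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        self.centers = np.asarray(self.centers, dtype=np.float64).reshape(-1, 2)
        self.unbounded = np.asarray(self.unbounded, dtype=bool)
        if not (np.diff(self.z) > 0).all():
            raise ValueError("z must be strictly increasing")
        if (self.radius < 0).any():
            raise ValueError("radii must be non-negative")
        if not (len(self.z) == len(self.radius) == len(self.centers)
                == len(self.unbounded)):
            raise ValueError("profile arrays must have equal length")

    def to_tsv(self, path: str) -> None:
        spread = self.spread if self.spread is not None else np.zeros_like(self.z)
        with open(path, "w") as fh:
            fh.write("z\tradius\tcx\tcy\tspread\tflag\n")
            for i in range(len(self.z)):
                flag = "open_to_bulk" if self.unbounded[i] else "ok"
                fh.write(f"{self.z[i]:.4f}\t{self.radius[i]:.4f}\t"
                         f"{self.centers[i, 0]:.4f}\t{self.centers[i, 1]:.4f}\t"
                         f"{spread[i]:.4f}\t{flag}\n")


def _clearance(centers_xy: np.ndarray, z: float, atoms: np.ndarray,
               radii: np.ndarray, r_max: float) -> np.ndarray:
    """min_i(|c - x_i| - R_i) for a batch of in-plane centres, clipped at r_max."""
    c = np.column_stack([centers_xy, np.full(len(centers_xy), z)])
    d = np.linalg.norm(c[:, None, :] - atoms[None, :, :], axis=2) - radii[None, :]
    return np.minimum(d.min(axis=1), r_max)


def slice_max_radius(coords: np.ndarray, radii: np.ndarray, z: float,
                     init_center: Sequence[float] = (0.0, 0.0),
                     seed: Union[int, np.random.Generator] = 0,
                     r_max: float = DEFAULT_R_MAX,
                     n_restarts: int = 5,
                     n_steps: int = 250,
                     max_displacement: float = 4.0) -> SliceResult:
    """Largest clearance sphere centred in the plane at ``z``.

    Simulated annealing (``n_restarts`` seeded restarts, geometric cooling)
    maximises the clearance, then a Nelder-Mead polish refines the best
    candidate.  Deterministic for a given seed.  If no atom lies within
    ``r_max + R_i`` of the slice the result is ``r_max`` with the
    ``unbounded`` flag set.

    The clearance objective is globally unbounded outside the structure
    (far from all atoms it saturates at r_max), so the search is local:
    candidates further than ``max_displacement`` from ``init_center`` are
    rejected, keeping the optimiser in the pore-local basin traced from
    slice to slice.
    """
    coords = np.asarray(coords, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    near = np.abs(coords[:, 2] - z) <= r_max + radii
    init = np.asarray(init_center, dtype=np.float64)
    if not near.any():
        return SliceResult(center=init.copy(), radius=r_max, unbounded=True)
    atoms = coords[near]
    arad = radii[near]

    def f(c: np.ndarray) -> float:
        return float(_clearance(c[None, :], z, atoms, arad, r_max)[0])

    starts = [init, init + np.clip(-init, -max_displacement / 2,
                                   max_displacement / 2)]
    starts += [init + rng.normal(scale=min(2.0, max_displacement / 2), size=2)
               for _ in range(max(0, n_restarts - 2))]
    best_c, best_f = init.copy(), f(init)
    # cooling schedules: step size 1.0 -> 0.02 A, temperature 0.3 -> 0.003
    steps = 1.0 * (0.02 / 1.0) ** (np.arange(n_steps) / max(1, n_steps - 1))
    temps = 0.3 * (0.01) ** (np.arange(n_steps) / max(1, n_steps - 1))
    for start in starts[:max(1, n_restarts)]:
        c = np.asarray(start, dtype=np.float64).copy()
        fc = f(c)
        if fc > best_f:
            best_c, best_f = c.copy(), fc
        for s, T in zip(steps, temps):
            cand = c + rng.normal(scale=s, size=2)
            if np.linalg.norm(cand - init) > max_displacement:
                continue
            fcand = f(cand)
            if fcand >= fc or rng.random() < np.exp((fcand - fc) / T):
                c, fc = cand, fcand
                if fc > best_f:
                    best_c, best_f = c.copy(), fc
    res = minimize(lambda c: -f(c), best_c, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 400})
    if -res.fun > best_f and np.linalg.norm(res.x - init) <= max_displacement:
        best_c, best_f = res.x, -res.fun
    radius = min(best_f, r_max)
    unbounded = radius >= r_max - 1e-9
    return SliceResult(center=best_c, radius=max(radius, 0.0), unbounded=unbounded)


def compute_profile(frame: Union[Structure, np.ndarray],
                    radius_set: Optional[RadiusSet] = None,
                    z_min: float = -10.0, z_max: float = 30.0, dz: float = 0.5,
                    seed: int = 0, r_max: float = DEFAULT_R_MAX,
                    elements: Optional[Sequence[str]] = None,
                    init_center: Sequence[float] = (0.0, 0.0)) -> PoreProfile:
    """Trace the pore-radius profile over [z_min, z_max] in steps of dz.

    ``frame`` is a Structure (elements give the radii) or a bare (n, 3)
    coordinate array with ``elements`` supplied alongside.  Coordinates are
    assumed to be in the canonical axis frame.  Each slice is initialised at
    the previous slice's centre; the first at ``init_center`` (the axis).
    """
    if not z_min < z_max:
        raise ValueError("z_min must be < z_max")
    if not dz > 0:
        raise ValueError("dz must be positive")
    radius_set = radius_set or RadiusSet()
    if isinstance(frame, Structure):
        coords = frame.coords
        radii = radius_set.lookup(frame.elements)
    else:
        coords = np.asarray(frame, dtype=np.float64)
        if elements is None:
            raise ValueError("elements required when frame is a bare array")
        radii = radius_set.lookup(elements)
    zgrid = z_min + dz * np.arange(int(np.floor((z_max - z_min) / dz + 1e-9)) + 1)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(zgrid))
    out_r = np.empty(len(zgrid))
    out_c = np.empty((len(zgrid), 2))
    out_u = np.zeros(len(zgrid), dtype=bool)
    center = np.asarray(init_center, dtype=np.float64)
    for i, z in enumerate(zgrid):
        res = slice_max_radius(coords, radii, z, init_center=center,
                               seed=np.random.default_rng(child_seeds[i]),
                               r_max=r_max)
        out_r[i], out_c[i], out_u[i] = res.radius, res.center, res.unbounded
        if not res.unbounded:
            center = res.center
    return PoreProfile(z=zgrid, radius=out_r, centers=out_c, unbounded=out_u)


def average_profiles(profiles: List[PoreProfile],
                     mode: str = "stddev") -> PoreProfile:
    """Average several profiles on a common z grid, as across replicate runs.

    ``mode`` selects the per-z spread: sample standard deviation among the
    sources (``stddev``) or the standard error of their mean (``stderr``).
    """
    if mode not in ("stddev", "stderr"):
        raise ValueError("mode must be 'stddev' or 'stderr'")
    if not profiles:
        raise ValueError("no profiles to average")
    z0 = profiles[0].z
    for p in profiles[1:]:
        if len(p.z) != len(z0) or not np.allclose(p.z, z0, atol=1e-9):
            raise ValueError("profiles are on different z grids; regrid them "
                             "to a common grid before averaging")
    n = len(profiles)
    R = np.stack([p.radius for p in profiles])
    C = np.stack([p.centers for p in profiles])
    U = np.stack([p.unbounded for p in profiles])
    mean_r = R.mean(axis=0)
    if n == 1:
        logger.warning("average_profiles called with a single profile; spread is 0")
        spread = np.zeros_like(mean_r)
    else:
        spread = R.std(axis=0, ddof=1)
        if mode == "stderr":
            spread = spread / np.sqrt(n)
    return PoreProfile(z=z0.copy(), radius=mean_r, centers=C.mean(axis=0),
                       unbounded=U.any(axis=0), spread=spread, n_sources=n)
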