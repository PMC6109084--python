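"""Synthetic-data generation: toy nanopore, exact umbrella samplers, fixtures.

Four generators make every analysis module testable without external data:

* an overdamped Langevin "toy nanopore": two solvent reservoirs joined by a
  cylindrical channel through a fixed-atom wall slab, in reduced units
  (sigma = bead diameter, k_BT = 1).  Solvent beads interact by a purely
  repulsive WCA core; the wall adds an attractive well of depth
  ``wall_epsilon`` (0 = purely repulsive, i.e. hydrophobic).  The channel's
  occupancy is sensitive to radius and wall attraction, reproducing
  qualitatively the radius/hydrophobicity wetting phase behaviour of model
  nanopores — no mapping to angstroms or real water is implied;
* exact samplers for umbrella windows over known 1-D potentials (closed-form
  Gaussians for flat/harmonic truths, rejection sampling otherwise), the
  ground truth for WHAM validation;
* two-state telegraph count series with known switching rates, whose
  autocovariance has a closed form, for ACF validation;
* atomistic cylinder/funnel geometries with known inscribed radii, for the
  pore profiler.

All stochastic operations are exactly reproducible from (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .core_io import Structure, Trajectory
from .free_energy import UmbrellaWindow
from .hydration import HydrationSeries
from .units import DEFAULT_TEMPERATURE, kT as thermal_kT, spring_kj_nm2_to_kcal_A2

__all__ = ["ToyPoreConfig", "ToyState", "PotentialSpec", "TelegraphConfig",
           "WettingResult", "PRESETS", "build_pore_system", "free_state",
           "run_langevin", "wetting_fraction", "sample_umbrella_windows",
           "telegraph_series", "make_cylinder_fixture", "make_funnel_fixture"]

#: Euler-Maruyama stability bound for the WCA core (reduced units).
DT_MAX = 2e-3
#: Minimum clearance of placed solvent from any wall atom (sigma).
WALL_CLEARANCE = 0.8
#: Lattice hole margin: wall atoms are carved out below radius R + this.
HOLE_MARGIN = 0.4


@dataclass
class ToyPoreConfig:
    """Parameters of the toy nanopore, reduced units (sigma, k_BT = 1)."""

    pore_radius: float = 1.2
    pore_length: float = 5.0
    wall_epsilon: float = 0.0
    n_solvent: int = 160
    temperature: float = 1.0
    friction: float = 1.0
    dt: float = 5e-4
    box: Tuple[float, float, float] = (8.0, 8.0, 13.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pore_radius", "pore_length", "dt", "friction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_solvent < 1:
            raise ValueError("n_solvent must be >= 1")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.pore_length + 2 >= self.box[2]:
            raise ValueError("box too short for reservoirs around the pore")


#: Named parameter sets spanning the wetting phase diagram.
PRESETS: Dict[str, ToyPoreConfig] = {
    "narrow-hydrophobic": ToyPoreConfig(pore_radius=1.2, wall_epsilon=0.0,
                                        n_solvent=160, box=(8.0, 8.0, 13.0)),
    "narrow-hydrophilic": ToyPoreConfig(pore_radius=1.2, wall_epsilon=2.0,
                                        n_solvent=160, box=(8.0, 8.0, 13.0)),
    "wide": ToyPoreConfig(pore_radius=4.0, wall_epsilon=2.0,
                          n_solvent=400, box=(12.0, 12.0, 13.0)),
}


@dataclass
class ToyState:
    """Topology + current coordinates of a built toy system."""

    structure: Structure
    wall_mask: np.ndarray
    config: ToyPoreConfig

    @property
    def solvent_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.wall_mask)


def _wall_lattice(config: ToyPoreConfig) -> np.ndarray:
    """Fixed wall atoms: a unit lattice slab with a cylindrical hole.

    The hole is lined by explicit rings of atoms at radius exactly
    R + HOLE_MARGIN (the coarse lattice alone would leave an irregular,
    wider channel), so the solvent-accessible radius is set by construction.
    Interior lattice atoms that no solvent bead can ever reach (further than
    the interaction cutoff from accessible space) are pruned for speed.
    """
    bx, by, _ = config.box
    half_l = config.pore_length / 2.0
    hole = config.pore_radius + HOLE_MARGIN
    xs = np.arange(-bx / 2 + 0.5, bx / 2, 1.0)
    ys = np.arange(-by / 2 + 0.5, by / 2, 1.0)
    zs = np.arange(-half_l, half_l + 1e-9, 1.0)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    r = np.hypot(pts[:, 0], pts[:, 1])
    keep = r >= hole
    reachable = (np.abs(pts[:, 2]) >= half_l - 0.6) | (r <= hole + 3.0)
    lattice = pts[keep & reachable]
    # channel lining: rings at the hole radius, spacing <= ~0.7 sigma both
    # axially and around the circumference (tight enough that no bead leaks)
    n_ring = max(8, int(np.ceil(2 * np.pi * hole / 0.7)))
    angles = 2 * np.pi * np.arange(n_ring) / n_ring
    ring_z = np.arange(-half_l, half_l + 1e-9, 0.5)
    rings = []
    for i, z in enumerate(ring_z):
        # stagger alternate rings by half an angular step
        a = angles + (np.pi / n_ring) * (i % 2)
        rings.append(np.column_stack([hole * np.cos(a), hole * np.sin(a),
                                      np.full(n_ring, z)]))
    lining = np.vstack(rings)
    # drop lattice atoms the lining already covers
    close = cKDTree(lining).query(lattice)[0] < 0.5
    return np.vstack([lattice[~close], lining])


def build_pore_system(config: ToyPoreConfig) -> ToyState:
    """Place wall atoms and overlap-free solvent beads; reproducible from seed.

    Every solvent bead is at least ``WALL_CLEARANCE`` sigma from every wall
    atom and 0.85 sigma from every other bead.  Raises if the density is too
    high to place after bounded retries.
    """
    rng = np.random.default_rng(config.seed)
    wall = _wall_lattice(config)
    tree = cKDTree(wall)
    bx, by, bz = config.box
    half_l = config.pore_length / 2.0
    placed: List[np.ndarray] = []
    max_tries = 800 * config.n_solvent
    tries = 0
    while len(placed) < config.n_solvent:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {config.n_solvent} solvent beads after "
                f"{max_tries} tries; lower the density")
        tries += 1
        cand = rng.uniform(-0.5, 0.5, size=3) * np.array([bx, by, bz])
        rad = float(np.hypot(cand[0], cand[1]))
        if abs(cand[2]) < half_l + 0.3 and rad > config.pore_radius - HOLE_MARGIN:
            continue  # inside the slab, outside the channel
        d, _ = tree.query(cand)
        if d < WALL_CLEARANCE:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - cand, axis=1)) < 0.85:
            continue
        placed.append(cand)
    coords = np.vstack([wall, np.array(placed)])
    n_w, n_s = len(wall), len(placed)
    elements = ["W"] * n_w + ["S"] * n_s
    names = ["W"] * n_w + ["S"] * n_s
    resnames = ["WAL"] * n_w + ["SOL"] * n_s
    structure = Structure(np.arange(1, n_w + n_s + 1), elements, names, resnames,
                          np.concatenate([np.ones(n_w, dtype=int),
                                          np.arange(1, n_s + 1)]),
                          [""] * (n_w + n_s), coords, np.ones(n_w + n_s))
    mask = np.zeros(n_w + n_s, dtype=bool)
    mask[:n_w] = True
    return ToyState(structure=structure, wall_mask=mask, config=config)


def free_state(config: ToyPoreConfig) -> ToyState:
    """A wall-free box of solvent beads (for validation runs)."""
    rng = np.random.default_rng(config.seed)
    bx, by, bz = config.box
    placed: List[np.ndarray] = []
    tries = 0
    while len(placed) < config.n_solvent:
        if tries > 800 * config.n_solvent:
            raise RuntimeError("could not place solvent beads; lower the density")
        tries += 1
        cand = rng.uniform(-0.5, 0.5, size=3) * np.array([bx, by, bz])
        if placed and np.min(np.linalg.norm(np.array(placed) - cand, axis=1)) < 0.85:
            continue
        placed.append(cand)
    n = len(placed)
    structure = Structure(np.arange(1, n + 1), ["S"] * n, ["S"] * n, ["SOL"] * n,
                          np.arange(1, n + 1), [""] * n, np.array(placed), np.ones(n))
    return ToyState(structure=structure, wall_mask=np.zeros(n, dtype=bool),
                    config=config)


@njit(cache=False, fastmath=True)
def _bd_kernel(pos, wall, box, n_steps, stride, dt, kT, gamma, wall_eps,
               trap_k, seed, frames):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    ns = pos.shape[0]
    nw = wall.shape[0]
    rc_wca2 = 2.0 ** (1.0 / 3.0)
    rc_att2 = 6.25
    # attractive branch truncation shift (energy only; forces unaffected)
    noise_amp = np.sqrt(2.0 * kT * dt / gamma)
    mob = dt / gamma
    cap = 0.25
    out = 0
    forces = np.empty((ns, 3))
    for step in range(n_steps):
        for i in range(ns):
            forces[i, 0] = -trap_k * pos[i, 0]
            forces[i, 1] = -trap_k * pos[i, 1]
            forces[i, 2] = -trap_k * pos[i, 2]
        for i in range(ns):
            for j in range(i + 1, ns):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= box[0] * np.rint(dx / box[0])
                dy -= box[1] * np.rint(dy / box[1])
                dz -= box[2] * np.rint(dz / box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc_wca2 and r2 > 1e-12:
                    inv2 = 1.0 / r2
                    inv6 = inv2 * inv2 * inv2
                    fr = 24.0 * (2.0 * inv6 * inv6 - inv6) * inv2
                    forces[i, 0] += fr * dx
                    forces[i, 1] += fr * dy
                    forces[i, 2] += fr * dz
                    forces[j, 0] -= fr * dx
                    forces[j, 1] -= fr * dy
                    forces[j, 2] -= fr * dz
            for j in range(nw):
                dx = pos[i, 0] - wall[j, 0]
                dy = pos[i, 1] - wall[j, 1]
                dz = pos[i, 2] - wall[j, 2]
                dx -= box[0] * np.rint(dx / box[0])
                dy -= box[1] * np.rint(dy / box[1])
                dz -= box[2] * np.rint(dz / box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > 1e-12:
                    if r2 < rc_wca2:
                        inv2 = 1.0 / r2
                        inv6 = inv2 * inv2 * inv2
                        fr = 24.0 * (2.0 * inv6 * inv6 - inv6) * inv2
                        forces[i, 0] += fr * dx
                        forces[i, 1] += fr * dy
                        forces[i, 2] += fr * dz
                    elif wall_eps > 0.0 and r2 < rc_att2:
                        inv2 = 1.0 / r2
                        inv6 = inv2 * inv2 * inv2
                        fr = 24.0 * wall_eps * (2.0 * inv6 * inv6 - inv6) * inv2
                        forces[i, 0] += fr * dx
                        forces[i, 1] += fr * dy
                        forces[i, 2] += fr * dz
        for i in range(ns):
            for d in range(3):
                disp = forces[i, d] * mob
                if disp > cap:
                    disp = cap
                elif disp < -cap:
                    disp = -cap
                if noise_amp > 0.0:
                    disp += noise_amp * np.random.standard_normal()
                x = pos[i, d] + disp
                x -= box[d] * np.rint(x / box[d])
                pos[i, d] = x
        if (step + 1) % stride == 0:
            for i in range(ns):
                for d in range(3):
                    frames[out, i, d] = pos[i, d]
                    if not np.isfinite(pos[i, d]):
                        return out, False
            out += 1
    return out, True


def run_langevin(state: ToyState, n_steps: int, sample_stride: int = 40,
                 seed: int = 0, trap_k: float = 0.0) -> Trajectory:
    """Overdamped (position) Langevin dynamics, Euler-Maruyama, periodic box.

    Solvent-solvent interactions are purely repulsive WCA; solvent-wall adds
    a truncated-shifted attractive well of depth ``wall_epsilon`` beyond the
    repulsive core.  ``trap_k`` applies a harmonic restraint toward the
    origin (validation runs).  Deterministic given seed.  The conservative
    per-step displacement is capped at 0.25 sigma; dt must satisfy the
    documented stability bound dt <= 2e-3.
    """
    cfg = state.config
    if cfg.dt > DT_MAX:
        raise ValueError(f"dt = {cfg.dt} exceeds the stability bound {DT_MAX}")
    if sample_stride < 1 or n_steps < sample_stride:
        raise ValueError("need n_steps >= sample_stride >= 1")
    wall = np.ascontiguousarray(state.structure.coords[state.wall_mask])
    pos = np.ascontiguousarray(state.structure.coords[~state.wall_mask].copy())
    n_frames = n_steps // sample_stride
    ns = pos.shape[0]
    frames_s = np.empty((n_frames, ns, 3))
    box = np.array(cfg.box)
    out, ok = _bd_kernel(pos, wall, box, n_steps, sample_stride, cfg.dt,
                         cfg.temperature, cfg.friction, cfg.wall_epsilon,
                         trap_k, seed & 0x7FFFFFFF, frames_s)
    if not ok:
        raise FloatingPointError(
            f"numeric blow-up in Langevin integration; reduce dt (= {cfg.dt})")
    n_all = state.structure.n_atoms
    frames = np.empty((out, n_all, 3))
    frames[:, state.wall_mask, :] = state.structure.coords[state.wall_mask]
    frames[:, ~state.wall_mask, :] = frames_s[:out]
    return Trajectory(state.structure, frames, dt=cfg.dt * sample_stride)


@dataclass
class WettingResult:
    fraction: float
    se: float            # binomial standard error over post-equilibration frames
    n_frames: int
    mean_count: float
    expected_count: float


def wetting_fraction(traj: Trajectory, config: ToyPoreConfig,
                     equil_frac: float = 0.25) -> WettingResult:
    """Fraction of frames whose pore occupancy exceeds half its bulk-expected value.

    The expected occupancy is the per-frame bulk bead density (measured in
    the reservoirs, beyond 1.5 sigma from the slab faces) times the nominal
    channel cylinder volume pi R^2 L.  Frames before ``equil_frac`` of the
    run are discarded as equilibration.
    """
    first = int(np.floor(traj.n_frames * equil_frac))
    if first >= traj.n_frames:
        raise ValueError("no frames left after the equilibration cut")
    resnames = np.array([str(r) for r in traj.topology.resnames])
    sol = np.flatnonzero(resnames == "SOL")
    half_l = config.pore_length / 2.0
    bx, by, bz = config.box
    bulk_halfwidth = bz / 2.0 - (half_l + 1.5)
    if bulk_halfwidth <= 0:
        raise ValueError("no reservoir region to measure bulk density in")
    v_bulk = bx * by * 2 * bulk_halfwidth
    v_pore = np.pi * config.pore_radius ** 2 * config.pore_length
    wet = 0
    counts = []
    expected = []
    for f in range(first, traj.n_frames):
        pts = traj.frames[f][sol]
        r = np.hypot(pts[:, 0], pts[:, 1])
        in_pore = (np.abs(pts[:, 2]) <= half_l) & (r <= config.pore_radius)
        n_bulk = int((np.abs(pts[:, 2]) >= half_l + 1.5).sum())
        n_expect = n_bulk / v_bulk * v_pore
        counts.append(int(in_pore.sum()))
        expected.append(n_expect)
        if counts[-1] > 0.5 * n_expect:
            wet += 1
    n = traj.n_frames - first
    frac = wet / n
    se = float(np.sqrt(max(frac * (1 - frac), 1.0 / n) / n))
    return WettingResult(fraction=frac, se=se, n_frames=n,
                         mean_count=float(np.mean(counts)),
                         expected_count=float(np.mean(expected)))


# ---------------------------------------------------------------------------
# exact samplers over known potentials


@dataclass
class PotentialSpec:
    """A known 1-D potential on a valid z range (energies kcal/mol, z in A)."""

    form: str                      # flat | harmonic | quartic_double_well | tabulated
    params: Dict[str, object] = field(default_factory=dict)
    z_range: Tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.form not in ("flat", "harmonic", "quartic_double_well", "tabulated"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if not self.z_range[0] < self.z_range[1]:
            raise ValueError("z_range must be increasing")
        if self.form == "tabulated":
            zt = np.asarray(self.params["z"], dtype=float)
            if not (np.diff(zt) > 0).all():
                raise ValueError("tabulated z grid must be strictly increasing")
        if not np.isfinite(self.energy(np.linspace(*self.z_range, 64))).all():
            raise ValueError("potential is not finite on its valid range")

    def energy(self, z: Union[float, np.ndarray]) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.form == "flat":
            return np.zeros_like(z)
        if self.form == "harmonic":
            k = float(self.params.get("k", 1.0))
            z0 = float(self.params.get("z0", 0.0))
            return 0.5 * k * (z - z0) ** 2
        if self.form == "quartic_double_well":
            a = float(self.params["a"])
            b = float(self.params["b"])
            z0 = float(self.params.get("z0", 0.0))
            return a * ((z - z0) ** 2 - b ** 2) ** 2
        zt = np.asarray(self.params["z"], dtype=float)
        ut = np.asarray(self.params["U"], dtype=float)
        return np.interp(z, zt, ut)

    def barrier_height(self) -> float:
        """max - min of the potential over its valid range (fine grid)."""
        z = np.linspace(self.z_range[0], self.z_range[1], 4001)
        u = self.energy(z)
        return float(u.max() - u.min())


def double_well_truth(barrier_kT: float = 5.0, z_center: float = 18.0,
                      half_width: float = 12.0,
                      z_range: Tuple[float, float] = (2.0, 34.0),
                      temperature: float = DEFAULT_TEMPERATURE) -> PotentialSpec:
    """Quartic double well U = a((z - z_center)^2 - half_width^2)^2.

    The wells sit at z_center +- half_width with a central barrier of
    ``barrier_kT`` thermal units.  With the wells placed at the ends of an
    umbrella-window ladder and the barrier in the middle, every window
    samples near its own centre — the shape of a free-energy barrier across
    a dewetted pore segment.
    """
    kT = thermal_kT(temperature)
    a = barrier_kT * kT / half_width ** 4
    return PotentialSpec("quartic_double_well",
                         {"a": a, "b": half_width, "z0": z_center},
                         z_range=z_range)


def sample_umbrella_windows(truth: PotentialSpec, centers: Sequence[float],
                            spring: Union[float, Sequence[float]],
                            n_per_window: int,
                            temperature: float = DEFAULT_TEMPERATURE,
                            seed: int = 0) -> List[UmbrellaWindow]:
    """Exact samples from the biased densities p_i(z) ~ exp(-[U + bias_i]/kT).

    Flat and harmonic truths sample closed-form Gaussians (the valid range is
    assumed wide enough that truncation is negligible); other forms use
    rejection sampling against a uniform proposal on the valid range.
    ``spring`` is in kJ mol^-1 nm^-2, scalar or per-window.
    """
    kT = thermal_kT(temperature)
    centers = np.asarray(centers, dtype=float)
    springs = np.broadcast_to(np.asarray(spring, dtype=float), centers.shape)
    rng = np.random.default_rng(seed)
    windows: List[UmbrellaWindow] = []
    lo, hi = truth.z_range
    for z0, k_kj in zip(centers, springs):
        kb = spring_kj_nm2_to_kcal_A2(float(k_kj))
        if truth.form == "flat":
            samples = rng.normal(z0, np.sqrt(kT / kb), size=n_per_window)
        elif truth.form == "harmonic":
            ku = float(truth.params.get("k", 1.0))
            zu = float(truth.params.get("z0", 0.0))
            mean = (ku * zu + kb * z0) / (ku + kb)
            samples = rng.normal(mean, np.sqrt(kT / (ku + kb)), size=n_per_window)
        else:
            # rejection sampling against a uniform proposal; the envelope is
            # the grid maximum of the biased density (slight safety margin
            # guards the between-grid-point maximum)
            grid = np.linspace(lo, hi, 4001)
            log_biased_max = (-(truth.energy(grid)
                                + 0.5 * kb * (grid - z0) ** 2) / kT).max()
            if not np.isfinite(log_biased_max):
                raise ValueError("biased density is not normalizable on the range")
            collected: List[np.ndarray] = []
            n_have = 0
            while n_have < n_per_window:
                batch = max(4 * (n_per_window - n_have), 1024)
                zc = rng.uniform(lo, hi, size=batch)
                logp_c = (-(truth.energy(zc) + 0.5 * kb * (zc - z0) ** 2) / kT
                          - log_biased_max)
                kept = zc[rng.random(batch) < np.exp(logp_c)]
                collected.append(kept)
                n_have += len(kept)
            samples = np.concatenate(collected)[:n_per_window]
        windows.append(UmbrellaWindow(center=float(z0), spring=float(k_kj),
                                      samples=samples, temperature=temperature))
    return windows


# ---------------------------------------------------------------------------
# telegraph process


@dataclass
class TelegraphConfig:
    """Two-state Markov count process: levels (N1, N2), switching rates per ps."""

    levels: Tuple[int, int] = (40, 0)
    rates: Tuple[float, float] = (0.005, 0.005)   # (k12, k21)
    dt: float = 1.0
    n_steps: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rates) <= 0:
            raise ValueError("rates must be positive")
        if self.dt * max(self.rates) >= 0.1:
            raise ValueError("dt * max(rate) must be < 0.1 for the "
                             "discrete-time approximation to hold")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def telegraph_series(config: TelegraphConfig) -> HydrationSeries:
    """Sample the discrete-time two-state chain at dt, stationary start.

    Sojourn times are geometric (memoryless), so drawing the initial state
    from the stationary distribution makes the whole series stationary.  The
    autocovariance is Var(N) * exp(-(k12 + k21) tau) in the small-dt limit,
    which is the closed-form test target for the water-count ACF.
    """
    rng = np.random.default_rng(config.seed)
    k12, k21 = config.rates
    p12, p21 = k12 * config.dt, k21 * config.dt
    n1, n2 = config.levels
    # state 0 <-> level n1; stationary P(state 1) = k12 / (k12 + k21)
    state = int(rng.random() < k12 / (k12 + k21))
    values = np.empty(config.n_steps, dtype=np.int64)
    filled = 0
    while filled < config.n_steps:
        p = p12 if state == 0 else p21
        dur = int(rng.geometric(p))
        take = min(dur, config.n_steps - filled)
        values[filled:filled + take] = n1 if state == 0 else n2
        filled += take
        state = 1 - state
    return HydrationSeries(t=config.dt * np.arange(config.n_steps), n_water=values)


# ---------------------------------------------------------------------------
# geometry fixtures


def make_cylinder_fixture(ring_radius: float, length: float,
                          ring_spacing: float = 1.0, atoms_per_ring: int = 36,
                          atom_element: str = "C") -> Structure:
    """Stacked rings of atoms forming an ideal cylindrical pore along z.

    The inscribed hard-sphere radius is ``ring_radius`` minus the element's
    hard-sphere radius, by construction.  Rings sit at z = 0, spacing, ...,
    length inclusive.
    """
    return make_funnel_fixture(ring_radius, ring_radius, length, ring_spacing,
                               atoms_per_ring, atom_element)


def make_funnel_fixture(radius_top: float, radius_bottom: float, length: float,
                        ring_spacing: float = 1.0, atoms_per_ring: int = 36,
                        atom_element: str = "C") -> Structure:
    """Rings with radius varying linearly in z from radius_top (z=0) to radius_bottom."""
    if min(radius_top, radius_bottom, length, ring_spacing) <= 0 or atoms_per_ring < 3:
        raise ValueError("all fixture dimensions must be positive")
    zs = np.arange(0.0, length + 1e-9, ring_spacing)
    angles = 2 * np.pi * np.arange(atoms_per_ring) / atoms_per_ring
    coords = []
    resids = []
    for ring_i, z in enumerate(zs):
        r = radius_top + (radius_bottom - radius_top) * (z / length)
        for a in angles:
            coords.append([r * np.cos(a), r * np.sin(a), z])
            resids.append(ring_i + 1)
    n = len(coords)
    from .core_io import mass_of_element
    mass = mass_of_element(atom_element) or 1.0
    return Structure(np.arange(1, n + 1), [atom_element] * n, [atom_element] * n,
                     ["RNG"] * n, np.array(resids), [""] * n,
                     np.array(coords), np.full(n, mass))
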