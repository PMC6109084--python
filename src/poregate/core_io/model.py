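"""Core data model: structures, trajectories, atom index sets, axis frames.

The model is array-based (one numpy array per per-atom attribute) in the
style of MDAnalysis/mdtraj, so geometric operations vectorise.  Coordinates
are in angstroms, masses in amu, times in picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "Structure",
    "Trajectory",
    "AtomIndexSet",
    "AxisFrame",
    "mass_of_element",
]

# Standard atomic weights for the elements that occur in protein/lipid/water
# systems plus common counter-ions.  Single-letter toy-bead "elements" used by
# the synthetic simulator carry explicit masses and bypass this table.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "ZN": 65.38, "BR": 79.904, "I": 126.904,
}


def mass_of_element(element: str) -> Optional[float]:
    """Atomic mass for an element symbol, or None if unknown."""
    return ATOMIC_MASSES.get(element.upper())


@dataclass
class Structure:
    """A molecular structure as parallel per-atom arrays.

    Parameters
    ----------
    ids : integer atom serials, unique.
    elements : element symbols (upper-case convention).
    names : atom names (e.g. ``CA``, ``OW``).
    resnames : 3-letter residue codes.
    resids : residue numbers, preserved as read.
    chains : chain identifiers (may be empty strings).
    coords : (n_atoms, 3) float array, angstroms.
    masses : per-atom masses, amu; must be positive.
    """

    ids: np.ndarray
    elements: np.ndarray
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.masses = np.asarray(self.masses, dtype=np.float64)
        for attr in ("elements", "names", "resnames", "chains"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=object))
        n = len(self.ids)
        for attr in ("elements", "names", "resnames", "chains", "masses"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"attribute {attr!r} length mismatch with ids")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        uniq, counts = np.unique(self.ids, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1][0]
            raise ValueError(f"duplicate atom serial {int(dup)}")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if (self.masses <= 0).any():
            bad = int(self.ids[np.argmax(self.masses <= 0)])
            raise ValueError(f"non-positive mass for atom serial {bad}")

    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return Structure(self.ids.copy(), self.elements.copy(), self.names.copy(),
                         self.resnames.copy(), self.resids.copy(), self.chains.copy(),
                         np.array(coords, dtype=np.float64), self.masses.copy())

    def subset(self, indices: np.ndarray) -> "Structure":
        """New Structure containing only the atoms at the given positions."""
        idx = np.asarray(indices, dtype=np.int64)
        return Structure(self.ids[idx], self.elements[idx], self.names[idx],
                         self.resnames[idx], self.resids[idx], self.chains[idx],
                         self.coords[idx], self.masses[idx])

    def iter_atoms(self) -> Iterator[tuple]:
        for i in range(self.n_atoms):
            yield (int(self.ids[i]), self.elements[i], self.names[i],
                   self.resnames[i], int(self.resids[i]), self.chains[i],
                   self.coords[i], float(self.masses[i]))


@dataclass
class AtomIndexSet:
    """An ordered set of atom positions produced by a selection.

    ``indices`` are 0-based positions into the parent structure's arrays
    (every index must exist in the parent); ``selection_text`` records the
    expression that produced the set.  An empty set is valid.
    """

    indices: np.ndarray
    selection_text: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    def validate_against(self, structure: Structure) -> None:
        if len(self.indices) and (self.indices.min() < 0
                                  or self.indices.max() >= structure.n_atoms):
            raise IndexError("selection indices outside parent structure")


@dataclass
class AxisFrame:
    """Canonical pore frame: origin on the reference plane, pore axis = +z.

    ``sign_convention`` documents that positive axial distance points from the
    reference plane (the selectivity-filter entrance in channel work) into the
    cavity, so "distance below the filter" is a positive z.
    """

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    sign_convention: str = "cavity-positive"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.axis = np.asarray(self.axis, dtype=np.float64)
        norm = np.linalg.norm(self.axis)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"axis must be a unit vector (|axis| = {norm})")


@dataclass
class Trajectory:
    """An ordered stack of frames over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3); ``dt`` is the time between
    consecutive frames in ps and ``time0`` the time stamp of the first frame.
    """

    topology: Structure
    frames: np.ndarray
    dt: float
    time0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.time0 + self.dt * np.arange(self.n_frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]
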