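"""Readers and writers: PDB structures, XYZ/DCD/XTC trajectories.

The PDB dialect honoured here is deliberately minimal and predictable: only
ATOM/HETATM/TER/END records are interpreted, altloc 'A' (or blank) is kept and
other altlocs are dropped with a logged warning.  Malformed lines raise
``PDBFormatError`` naming the offending line number.

The plain-text XYZ trajectory dialect used for fixtures is::

    <n_atoms>
    time=<ps>
    <element> <x> <y> <z>
    ...

with frames concatenated.  DCD and XTC are read through MDAnalysis.
"""

from __future__ import annotations

import logging
import os
from typing import List, Optional

import numpy as np

from .model import Structure, Trajectory, mass_of_element

logger = logging.getLogger(__name__)

__all__ = [
    "PDBFormatError",
    "load_structure",
    "write_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_trajectory",
]

# Residue names recognised as monoatomic ions, for two-letter element inference
_ION_RESNAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "BR", "I",
                 "SOD", "CLA", "POT", "CAL", "MG2"}


class PDBFormatError(ValueError):
    """Raised for unreadable or inconsistent PDB input."""


def _infer_element(name: str, resname: str) -> str:
    """Infer an element symbol from an atom name when column 77-78 is absent.

    Leading digits are stripped; a two-letter symbol is accepted only when the
    residue is a recognised monoatomic ion (so ``CA`` in GLY stays carbon but
    ``CA`` in an ion record becomes calcium).
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if resname.strip().upper() in _ION_RESNAMES:
        two = stripped[:2].upper()
        if mass_of_element(two) is not None:
            return two
    return stripped[0].upper()


def load_structure(path: str, format: str = "PDB") -> Structure:
    """Load a structure file.

    Only the PDB format is supported.  Elements are taken from columns 77-78
    when present, otherwise inferred from the atom name.  An atom whose
    element cannot be assigned a mass is rejected.
    """
    if format.upper() != "PDB":
        raise ValueError(f"unsupported structure format {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ids: List[int] = []
    elements: List[str] = []
    names: List[str] = []
    resnames: List[str] = []
    resids: List[int] = []
    chains: List[str] = []
    coords: List[List[float]] = []
    masses: List[float] = []
    seen = set()
    n_altloc_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("TER", "END", "ENDMDL", "MODEL") or not rec:
                continue
            if rec not in ("ATOM", "HETATM"):
                continue  # other records are ignored by this dialect
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"line {lineno}: truncated {rec} record")
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise PDBFormatError(f"line {lineno}: unparsable field ({exc})") from None
            altloc = line[16]
            if altloc not in (" ", "A"):
                n_altloc_dropped += 1
                continue
            if serial in seen:
                raise PDBFormatError(f"line {lineno}: duplicate atom serial {serial}")
            seen.add(serial)
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip()
            try:
                resid = int(line[22:26])
            except ValueError:
                raise PDBFormatError(f"line {lineno}: unparsable residue number") from None
            element = line[76:78].strip().upper() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name, resname)
            mass = mass_of_element(element)
            if mass is None or mass <= 0:
                raise PDBFormatError(
                    f"line {lineno}: unknown element {element!r} for atom "
                    f"serial {serial} (name {name!r})")
            ids.append(serial)
            elements.append(element)
            names.append(name)
            resnames.append(resname)
            resids.append(resid)
            chains.append(chain)
            coords.append([x, y, z])
            masses.append(mass)
    if n_altloc_dropped:
        logger.warning("%s: dropped %d non-'A' altloc atoms", path, n_altloc_dropped)
    if not ids:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records found")
    try:
        return Structure(np.array(ids), elements, names, resnames,
                         np.array(resids), chains, np.array(coords), np.array(masses))
    except ValueError as exc:
        raise PDBFormatError(str(exc)) from None


def write_pdb(structure: Structure, path: str) -> None:
    """Write a Structure as ATOM records (coordinates at PDB's 1e-3 A precision)."""
    with open(path, "w") as fh:
        for (serial, element, name, resname, resid, chain, xyz, _m) in structure.iter_atoms():
            # atom-name column convention: 1-letter elements start in column 14
            if len(name) < 4 and len(str(element)) == 1:
                name_f = f" {name:<3s}"
            else:
                name_f = f"{name:<4s}"
            fh.write(
                "ATOM  {serial:>5d} {name} {resname:<3s} {chain:1s}{resid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                    serial=serial, name=name_f, resname=str(resname)[:3],
                    chain=(str(chain) or " ")[:1], resid=resid,
                    x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
                    el=str(element)[:2]))
        fh.write("END\n")


def write_xyz_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory in the plain multi-frame XYZ dialect."""
    elements = traj.topology.elements
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            t = traj.time0 + f * traj.dt
            fh.write(f"{traj.topology.n_atoms}\n")
            fh.write(f"time={t:.6f}\n")
            for el, xyz in zip(elements, traj.frames[f]):
                fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def read_xyz_trajectory(path: str, topology: Optional[Structure] = None) -> Trajectory:
    """Read the XYZ fixture dialect.

    If ``topology`` is omitted a minimal one is synthesised from the element
    column (sequential serials, residue UNK, unit masses for unknown symbols).
    """
    frames = []
    times = []
    elements_first: List[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}: expected atom count at line {i + 1}") from None
        header = lines[i + 1].strip()
        if not header.startswith("time="):
            raise ValueError(f"{path}: expected 'time=<ps>' at line {i + 2}")
        times.append(float(header[5:]))
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame at line {i + 1}")
        frame = np.empty((n, 3))
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) != 4:
                raise ValueError(f"{path}: bad atom line {i + 3 + j}")
            if not frames:
                elements_first.append(parts[0])
            frame[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(frame)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty trajectory")
    frames_arr = np.array(frames)
    dt = times[1] - times[0] if len(times) > 1 else 1.0
    if topology is None:
        n = frames_arr.shape[1]
        masses = [mass_of_element(e) or 1.0 for e in elements_first]
        topology = Structure(np.arange(1, n + 1), elements_first,
                             elements_first, ["UNK"] * n, np.ones(n, dtype=int),
                             [""] * n, frames_arr[0], np.array(masses))
    return Trajectory(topology, frames_arr, dt=dt if dt > 0 else 1.0, time0=times[0])


def read_trajectory(path: str, topology: Optional[Structure] = None,
                    format: Optional[str] = None) -> Trajectory:
    """Read a trajectory in XYZ, DCD or XTC format (inferred from extension)."""
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt == "xyz":
        return read_xyz_trajectory(path, topology)
    if fmt in ("dcd", "xtc"):
        if topology is None:
            raise ValueError(f"{fmt.upper()} trajectories require a topology Structure")
        if fmt == "dcd":
            from MDAnalysis.coordinates.DCD import DCDReader as Reader
        else:
            from MDAnalysis.coordinates.XTC import XTCReader as Reader
        frames = []
        dt = None
        t0 = 0.0
        with Reader(path) as reader:
            for k, ts in enumerate(reader):
                if k == 0:
                    t0 = float(ts.time)
                    dt = float(getattr(ts, "dt", 1.0)) or 1.0
                frames.append(np.array(ts.positions, dtype=np.float64))
        return Trajectory(topology, np.array(frames), dt=dt or 1.0, time0=t0)
    raise ValueError(f"unsupported trajectory format {fmt!r}")
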