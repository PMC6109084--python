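"""Centre-of-mass and pore-axis alignment.

Downstream modules assume a canonical frame: the reference selection's COM at
the origin and the pore axis along +z, with the cavity on the positive side.
``align_to_pore_axis`` transforms every frame of a trajectory into that frame
by a rigid rotation + translation (pairwise distances are preserved).

Whether trajectories should be aligned per frame or analysed in a fixed lab
frame is a genuine modelling choice; alignment here is per frame, and the
choice is recorded on the returned :class:`AxisFrame` via ``sign_convention``
plus the ``per_frame`` flag of this function.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .model import AtomIndexSet, AxisFrame, Structure, Trajectory

__all__ = ["center_of_mass", "align_to_pore_axis", "principal_axis"]


def center_of_mass(structure: Structure, sel: AtomIndexSet,
                   mass_weighted: bool = True,
                   coords: np.ndarray | None = None) -> np.ndarray:
    """COM of a selection; geometric mean when ``mass_weighted`` is off.

    ``coords`` may override the structure's coordinates (e.g. one trajectory
    frame with the same atom ordering).
    """
    if len(sel) == 0:
        raise ValueError("center_of_mass of an empty selection")
    sel.validate_against(structure)
    pts = (structure.coords if coords is None else np.asarray(coords))[sel.indices]
    if mass_weighted:
        w = structure.masses[sel.indices]
        return (pts * w[:, None]).sum(axis=0) / w.sum()
    return pts.mean(axis=0)


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest-variance direction of a point cloud."""
    pts = np.asarray(points, dtype=np.float64)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1e-12:
        raise ValueError("degenerate axis: zero-length principal axis")
    return evecs[:, -1]


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector v onto +z (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # v antiparallel to z: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    k = np.cross(v, z)
    s = np.linalg.norm(k)
    k = k / s
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def align_to_pore_axis(traj: Trajectory, ref_sel: AtomIndexSet,
                       axis_sel: AtomIndexSet,
                       per_frame: bool = True) -> Tuple[Trajectory, AxisFrame]:
    """Rigidly transform each frame into the canonical pore frame.

    The reference selection's COM is moved to the origin and the principal
    axis of the axis selection (e.g. the four-helix pore bundle) is rotated
    onto +z.  The sign is chosen so the axis selection's COM — the cavity
    side — lands at positive z.  With ``per_frame`` off, the transform of the
    first frame is applied to all frames (fixed lab frame).
    """
    if len(ref_sel) == 0 or len(axis_sel) == 0:
        raise ValueError("alignment selections must be non-empty")
    ref_sel.validate_against(traj.topology)
    axis_sel.validate_against(traj.topology)
    top = traj.topology
    out = np.empty_like(traj.frames)
    R = np.eye(3)
    com_ref = np.zeros(3)
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        if per_frame or f == 0:
            com_ref = center_of_mass(top, ref_sel, coords=coords)
            axis_pts = coords[axis_sel.indices]
            v = principal_axis(axis_pts)
            direction = axis_pts.mean(axis=0) - com_ref
            proj = float(np.dot(v, direction))
            if abs(proj) > 1e-9:
                if proj < 0:
                    v = -v
            elif v[2] < 0:  # ambiguous cavity side: keep +z-ward orientation
                v = -v
            R = _rotation_to_z(v)
        out[f] = (coords - com_ref) @ R.T
    new_top = top.with_coords(out[0])
    frame = AxisFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
                      sign_convention="cavity-positive")
    return Trajectory(new_top, out, dt=traj.dt, time0=traj.time0), frame
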