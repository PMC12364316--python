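"""Rigid-body alignment of a model into a map by maximising global CC.

The pose is a rotation about the model centroid followed by a translation.
Optimisation is gradient ascent with a backtracking line search; the
rotation gradient comes from the rigid-body torque identity applied to the
per-atom CC gradients, so the same oracle-tested gradient engine drives
both rigid and flexible fitting.  Multiple seeded random-rotation restarts
guard against shallow local optima.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .densmap import MapSimParams, cc_with_gradient
from .structio import DensityGrid, Selection, Structure


@dataclass
class RigidTransform:
    """Rotation (unit quaternion, scalar-first) about a centre + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.rotation, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"quaternion norm {n} is not 1")
        self.rotation = q / n
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(3))

    @classmethod
    def from_rotation(cls, rot: Rotation,
                      translation: np.ndarray | None = None) -> "RigidTransform":
        x, y, z, w = rot.as_quat()
        return cls(np.array([w, x, y, z]),
                   np.zeros(3) if translation is None else translation)

    def as_rotation(self) -> Rotation:
        w, x, y, z = self.rotation
        return Rotation.from_quat([x, y, z, w])

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix (rotation about the origin + translation)."""
        m = np.eye(4)
        m[:3, :3] = self.as_rotation().as_matrix()
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform equivalent to applying ``other`` first, then self."""
        r = self.as_rotation() * other.as_rotation()
        t = self.as_rotation().apply(other.translation) + self.translation
        return RigidTransform.from_rotation(r, t)

    def inverse(self) -> "RigidTransform":
        rinv = self.as_rotation().inv()
        return RigidTransform.from_rotation(rinv, -rinv.apply(self.translation))

    def angle_deg(self) -> float:
        return float(np.degrees(self.as_rotation().magnitude()))

    def apply_about(self, coords: np.ndarray, center: np.ndarray) -> np.ndarray:
        return self.as_rotation().apply(coords - center) + center + self.translation


@dataclass
class RigidFitResult:
    transform: RigidTransform
    cc_before: float
    cc_after: float
    n_restarts_used: int
    converged: bool

    def __post_init__(self) -> None:
        if self.cc_after < self.cc_before - 1e-9:
            raise ValueError("rigid fit must not decrease cc")


def apply_transform(structure: Structure, transform: RigidTransform,
                    center: np.ndarray | None = None) -> Structure:
    """Rotate the whole structure about its centroid, then translate.

    Internal geometry is preserved exactly (an isometry).
    """
    coords = structure.coords()
    if center is None:
        center = coords.mean(axis=0)
    return structure.with_coords(transform.apply_about(coords, center))


def save_transform(transform: RigidTransform, path: str | Path) -> None:
    """Write the 4x4 homogeneous matrix, row-major, as text."""
    np.savetxt(path, transform.matrix(), fmt="%.12g")


def load_transform(path: str | Path) -> RigidTransform:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError("transform file must contain a 4x4 matrix")
    rot = Rotation.from_matrix(m[:3, :3])
    return RigidTransform.from_rotation(rot, m[:3, 3])


def _pose_coords(x0_centered: np.ndarray, R: Rotation, center: np.ndarray,
                 t: np.ndarray) -> np.ndarray:
    return R.apply(x0_centered) + center + t


def _ascend(structure: Structure, selection: Selection, x0c: np.ndarray,
            center: np.ndarray, R: Rotation, t: np.ndarray,
            target_map: DensityGrid, params: MapSimParams,
            max_iter: int, tol: float = 1e-6) -> tuple[Rotation, np.ndarray, float, bool]:
    """Gradient ascent on cc over (rotation, translation) from one start."""

    def evaluate(Rc, tc, need_grad=True):
        coords = _pose_coords(x0c, Rc, center, tc)
        posed = structure.with_coords(coords)
        cc, grad = cc_with_gradient(posed, selection, target_map, params)
        return coords, cc, grad

    coords, cc, grad = evaluate(R, t)
    # characteristic radius converts rotation step to displacement units
    L = max(float(np.sqrt((x0c ** 2).sum(axis=1).mean())), 1e-6)
    step_len = 0.5  # initial trial displacement, Angstrom
    flat = 0
    converged = False
    for _ in range(max_iter):
        gt = grad.sum(axis=0)
        arm = coords - (center + t)
        gw = np.cross(arm, grad).sum(axis=0)
        scale = np.linalg.norm(gt) + L * np.linalg.norm(gw)
        if scale < 1e-14:
            converged = True
            break
        accepted = False
        while step_len > 1e-7:
            s = step_len / scale
            R_new = Rotation.from_rotvec(s * gw) * R
            t_new = t + s * gt
            coords_new, cc_new, grad_new = evaluate(R_new, t_new)
            if cc_new > cc:
                gain = cc_new - cc
                R, t, coords, cc, grad = R_new, t_new, coords_new, cc_new, grad_new
                step_len = min(step_len * 1.5, 2.0)
                accepted = True
                flat = flat + 1 if gain < tol else 0
                break
            step_len *= 0.5
        if not accepted or flat >= 3:
            converged = accepted or flat >= 3 or step_len <= 1e-7
            converged = True
            break
    return R, t, cc, converged


def fit_rigid(structure: Structure, target_map: DensityGrid,
              params: MapSimParams, n_restarts: int = 12,
              seed: int = 0, selection: Optional[Selection] = None,
              max_iter: int = 100) -> RigidFitResult:
    """Local CC ascent from the input pose plus seeded random-rotation restarts.

    Deterministic given ``seed``; the best restart wins, ties broken by the
    earliest restart index.  ``cc_after`` never falls below ``cc_before``.
    """
    if selection is None:
        selection = Selection(np.arange(len(structure)), label="custom")
    coords0 = structure.coords()
    center = coords0[selection.indices].mean(axis=0)
    x0c = coords0 - center

    _, cc_before = None, None
    cc_before = cc_with_gradient(structure, selection, target_map, params)[0]

    rng = np.random.default_rng(seed)
    starts: list[Rotation] = [Rotation.identity()]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(Rotation.random(random_state=rng))

    best: tuple[float, int, Rotation, np.ndarray, bool] | None = None
    for idx, R0 in enumerate(starts):
        R, t, cc, conv = _ascend(structure, selection, x0c, center, R0,
                                 np.zeros(3), target_map, params, max_iter)
        if best is None or cc > best[0] + 1e-12:
            best = (cc, idx, R, t, conv)
    assert best is not None
    cc_best, idx, R, t, conv = best

    # polish the winning pose with a tighter budget
    R, t, cc_best, conv = _ascend(structure, selection, x0c, center, R, t,
                                  target_map, params, max_iter=3 * max_iter)

    if cc_best < cc_before:
        # ascent never accepts a worse pose than its own start, but a random
        # restart could in principle end below the input pose; keep the input
        return RigidFitResult(RigidTransform.identity(), cc_before, cc_before,
                              idx + 1, True)
    transform = RigidTransform.from_rotation(R, t)
    return RigidFitResult(transform, cc_before, cc_best, idx + 1, conv)
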