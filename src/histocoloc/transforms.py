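"""Planar similarity transforms with an optional axis flip.

One shared convention for the simulator (which plants a transform between
the H&E frame and the mIF frame) and the registration estimator (which
recovers it):

    y = s * R(theta) * F * x + t

where ``F`` mirrors the x axis when ``flip`` is set, ``R`` is a
counter-clockwise rotation by ``rotation_deg``, ``s`` a positive isotropic
scale, and ``t`` a translation in μm.  The flip is applied first so a
recovered transform's parameters are directly comparable with planted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PlanarTransform:
    flip: bool = False
    rotation_deg: float = 0.0
    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        """2x2 linear part (scale * rotation * flip)."""
        th = np.deg2rad(self.rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        fl = np.diag([-1.0 if self.flip else 1.0, 1.0])
        return self.scale * rot @ fl

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (x, y) coordinates."""
        pts = np.asarray(points, dtype=float)
        if pts.size == 0:
            return pts.reshape(0, 2)
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "PlanarTransform":
        """Exact inverse.  Note the inverse of a flip-first transform is
        again flip-first, with adjusted rotation and translation."""
        inv_mat = np.linalg.inv(self.matrix)
        # Decompose inv_mat = s' R' F' with the same convention.
        flip = bool(np.linalg.det(inv_mat) < 0)
        fl = np.diag([-1.0 if flip else 1.0, 1.0])
        sr = inv_mat @ fl  # s' R'
        scale = float(np.sqrt(np.abs(np.linalg.det(sr))))
        rot_deg = float(np.rad2deg(np.arctan2(sr[1, 0], sr[0, 0])))
        t = -inv_mat @ np.asarray(self.translation)
        return PlanarTransform(flip, rot_deg, scale, (float(t[0]), float(t[1])))


def similarity_from_matches(src: np.ndarray, dst: np.ndarray) -> PlanarTransform:
    """Least-squares similarity (rotation + scale + translation, no flip)
    mapping matched ``src`` points onto ``dst`` (Umeyama/Procrustes).

    Both arrays are (n, 2) with row i of ``src`` matched to row i of ``dst``.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[0] < 2:
        raise ValueError("need >= 2 matched point pairs of equal shape")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    cov = xd.T @ xs / len(src)
    u, d, vt = np.linalg.svd(cov)
    s_fix = np.eye(2)
    if np.linalg.det(u @ vt) < 0:  # keep orientation-preserving (no flip)
        s_fix[1, 1] = -1.0
    rot = u @ s_fix @ vt
    var_s = (xs**2).sum() / len(src)
    scale = float(np.trace(np.diag(d) @ s_fix) / var_s) if var_s > 0 else 1.0
    if scale <= 0:
        scale = 1e-9
    t = mu_d - scale * rot @ mu_s
    rot_deg = float(np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0])))
    return PlanarTransform(False, rot_deg, scale, (float(t[0]), float(t[1])))


def compose_flip_then(sim: PlanarTransform, flip: bool) -> PlanarTransform:
    """Transform equal to ``x -> sim(F x)``: prepend an x-axis flip to a
    no-flip similarity, re-expressed in the flip-first convention."""
    if not flip:
        return sim
    if sim.flip:
        raise ValueError("sim must be flip-free")
    # sim(Fx) = s R F x + t which is already the flip-first form, except the
    # rotation angle is unchanged: s R F == s R' F with R' = R.
    return PlanarTransform(True, sim.rotation_deg, sim.scale, sim.translation)
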