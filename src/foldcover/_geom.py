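"""Low-level vector geometry shared across modules.

All routines operate on plain float64 numpy arrays of shape (..., 3) and are
unit-agnostic (coordinates are Ångstroms throughout the package).
"""

from __future__ import annotations

import numpy as np


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = _unit(p0 - p1)
    v = _unit(p2 - p1)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D so that |CD| = bond, angle(B,C,D) = angle and the
    dihedral A-B-C-D equals ``dihedral_deg`` (natural-extension / NeRF step).
    """
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            -bond * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_transform(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing
    ||(mobile @ R.T + t) - target||; reflections are excluded by
    determinant correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ct - rot @ cm
    return rot, trans


def apply_transform(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def kabsch_rmsd(a: np.ndarray, b: np.ndarray, *, allow_degenerate: bool = True) -> float:
    """Minimal RMSD between two equal-size point sets over proper rigid
    transforms (Kabsch). Uses the singular-value identity rather than an
    explicit superposition, with the smallest singular value sign-flipped
    when the optimal orthogonal map would be a reflection.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must share shape (m, 3)")
    m = a.shape[0]
    if m < 3:
        raise ValueError("need at least 3 points for superposition")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(ac.T @ bc)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # explicit residual (no cancellation near zero, unlike the
    # singular-value identity)
    resid = ac @ rot.T - bc
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
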