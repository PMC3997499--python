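"""Small geometric primitives: superposition, internal-coordinate placement,
deterministic sphere point sets and rigid transforms."""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "place_internal", "sphere_points", "rotation_about_axis"]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping ``mobile`` onto ``reference``.

    Returns (R, t) such that ``mobile @ R.T + t`` minimises the RMSD to
    ``reference``.  Proper rotations only (no reflection).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def place_internal(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihedral: float
) -> np.ndarray:
    """Place an atom X from internal coordinates relative to placed atoms a, b, c.

    ``bond`` = |X-a| in A, ``angle`` = X-a-b in degrees, ``dihedral`` =
    X-a-b-c in degrees (standard NeRF construction).
    """
    a, b, c = (np.asarray(v, float) for v in (a, b, c))
    theta = np.deg2rad(angle)
    phi = np.deg2rad(dihedral)
    u = b - a
    u_norm = np.linalg.norm(u)
    w = c - b
    n = np.cross(u, w)
    n_norm = np.linalg.norm(n)
    if u_norm < 1e-10 or n_norm < 1e-10:
        raise ValueError("collinear reference atoms in internal-coordinate placement")
    u /= u_norm
    n /= n_norm
    m = np.cross(n, u)
    return a + bond * (
        np.cos(theta) * u + np.sin(theta) * (np.cos(phi) * m - np.sin(phi) * n)
    )


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, near-uniform unit-sphere point set (generalized spiral).

    Uses the golden-angle (Fibonacci) spiral; no randomness, so surface areas
    computed from it are exactly reproducible for a given ``n``.
    """
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis through the origin."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)
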