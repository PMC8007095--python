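"""Small geometric utilities shared across modules."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize the last axis of ``v`` to unit length."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize a zero vector")
    return v / n


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto unit vector ``b``.

    Rodrigues construction; the antiparallel case picks a deterministic
    perpendicular axis.
    """
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180° turn about any axis perpendicular to a
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, p)
        axis /= np.linalg.norm(axis)
        return rotation_about(axis, np.pi)
    v = np.cross(a, b)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about ``axis`` (unit vector) by ``angle`` radians."""
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (via QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> np.ndarray:
    """Optimally superpose ``mobile`` onto ``reference`` (least squares).

    Returns the transformed copy of ``mobile``; inputs are (n, 3) arrays.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if weights is None:
        weights = np.ones(len(mobile))
    w = np.asarray(weights, float)[:, None]
    mc = (mobile * w).sum(0) / w.sum()
    rc = (reference * w).sum(0) / w.sum()
    a = (mobile - mc) * w
    b = reference - rc
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return (mobile - mc) @ rot.T + rc


def spherical_angles(points: np.ndarray, center: np.ndarray | None = None):
    """Return (r, phi, cos_theta) of points about ``center``.

    phi is the azimuthal angle in [-pi, pi); theta the polar angle from +z.
    """
    p = np.asarray(points, float)
    if center is not None:
        p = p - np.asarray(center, float)
    r = np.linalg.norm(p, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(r > 0, p[..., 2] / np.where(r > 0, r, 1.0), 1.0)
    phi = np.arctan2(p[..., 1], p[..., 0])
    return r, phi, np.clip(cos_theta, -1.0, 1.0)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def sample_vmf(mu: np.ndarray, kappa: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` unit vectors from a von Mises-Fisher distribution on S².

    Wood (1994) rejection scheme for the polar component.  ``kappa = 0``
    gives the uniform distribution on the sphere.
    """
    mu = np.asarray(mu, float) / np.linalg.norm(mu)
    if kappa < 1e-12:
        v = rng.normal(size=(n, 3))
        return unit(v)
    if np.isinf(kappa):
        return np.tile(mu, (n, 1))
    # polar cosines w ~ vMF marginal (dimension 3 has a closed-form inverse CDF)
    u = rng.uniform(size=n)
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    # azimuthal part uniform in the tangent plane of mu
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # orthonormal frame about mu
    ref = np.array([1.0, 0.0, 0.0])
    if abs(mu[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(mu, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(mu, e1)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, 1.0))
    return (
        w[:, None] * mu
        + (s * np.cos(phi))[:, None] * e1
        + (s * np.sin(phi))[:, None] * e2
    )
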