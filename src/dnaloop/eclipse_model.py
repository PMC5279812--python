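"""Analytic/numeric eclipse approximation for the looping-plateau reduction.

In the entropic regime (chain length ``L`` far beyond the Kuhn length) the
terminating segments of a looped chain approach the looping volume
isotropically, so a hard sphere near the volume reduces the looping
probability by the fraction of directions it occludes.  With
``I_x = \\int_{dr} Omega_x(r) d^3r`` the occluded solid angle integrated
over the looping volume, the plateau ratio is::

    F_inf ~ 1 - I_object / (4 pi dr - I_chain) + I_chain^object / (4 pi dr - I_chain)

where the intersection term restores directions already blocked by the
chain itself.  All integrals are evaluated by Monte-Carlo ray casting
(exact per sample) over uniform points of the looping volume and uniform
directions.  A sphere of radius ``R_o`` at distance ``d`` occludes (for the
chain terminus, whose own sphere has radius ``w/2``)::

    Omega = 2 pi (1 - sqrt(1 - ((R_o + w/2)/d)^2))

The "terminating segments" correction replaces the straight line-of-sight
rays with short flexible chains of length ``T``, which overlap the object
more often and lower the estimate toward the simulated plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .polymer_core import bending_constant_from_kuhn
from .looping_analysis import LoopCriteria

__all__ = [
    "EclipseScene",
    "EclipseResult",
    "EclipseFit",
    "solid_angle_sphere",
    "sample_region_points",
    "f_inf_static",
    "f_inf_eclipse",
    "terminating_segments_correction",
    "fit_quadratic_eclipse",
]

FOUR_PI = 4.0 * math.pi


class GeometryError(ValueError):
    """The object intersects the looping volume (eclipse model undefined)."""


@dataclass
class EclipseScene:
    """Looping volume, occluding object, and optional frozen chain joints."""

    region: LoopCriteria
    object_position: np.ndarray
    object_radius: float
    w: float
    chain_joints: np.ndarray | None = None  # (n, 3); occlusion radius w each

    def __post_init__(self):
        self.object_position = np.asarray(self.object_position, float)
        if self.chain_joints is not None:
            self.chain_joints = np.asarray(self.chain_joints, float)

    @property
    def effective_radius(self) -> float:
        return self.object_radius + 0.5 * self.w


@dataclass
class EclipseResult:
    f_inf: float
    se: float
    i_object: float = 0.0  # as fractions of 4 pi dr
    i_chain: float = 0.0
    i_both: float = 0.0


@dataclass
class EclipseFit:
    """Quadratic eclipse fit ``F_inf ~ 1 - A (R_o + w/2)^2 + B``."""

    A_K: float
    B_K: float
    r_squared: float
    covariance: np.ndarray


def solid_angle_sphere(distance: float, effective_radius: float) -> float:
    """Solid angle subtended by a sphere of (effective) radius ``R_eff`` at a
    point a distance ``d >= R_eff`` from its centre:
    ``2 pi (1 - sqrt(1 - (R_eff/d)^2))``.  Tangent case (``d = R_eff``)
    gives exactly ``2 pi``; raises if the point is inside the sphere.
    """
    if distance < effective_radius:
        raise GeometryError(
            f"point at d={distance} inside sphere of effective radius {effective_radius}"
        )
    x = effective_radius / distance
    return 2.0 * math.pi * (1.0 - math.sqrt(max(0.0, 1.0 - x * x)))


def sample_region_points(region: LoopCriteria, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points of the looping volume (shell sector): radius from the
    shell by inverse-CDF on r^3, direction uniform on the acceptance cap."""
    r3_lo = region.d_min**3
    r3_hi = (region.d_min + region.epsilon) ** 3
    r = (r3_lo + (r3_hi - r3_lo) * rng.random(n)) ** (1.0 / 3.0)
    ado = min(abs(region.domega), FOUR_PI)
    cos_c = 1.0 - ado / (2.0 * math.pi)
    mu = cos_c + (1.0 - cos_c) * rng.random(n)  # cos(zenith) uniform on cap
    phi = 2.0 * math.pi * rng.random(n)
    s = np.sqrt(1.0 - mu**2)
    axis = np.asarray(region.axis, float)
    axis = axis / np.linalg.norm(axis)
    if region.domega < 0:
        axis = -axis
    # orthonormal basis about the axis
    helper = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    dirs = (
        mu[:, None] * axis[None, :]
        + (s * np.cos(phi))[:, None] * e1[None, :]
        + (s * np.sin(phi))[:, None] * e2[None, :]
    )
    return np.asarray(region.anchor, float)[None, :] + r[:, None] * dirs


def f_inf_static(
    object_position,
    R_o: float,
    region: LoopCriteria,
    w: float,
    n_points: int = 100_000,
    rng: np.random.Generator | None = None,
) -> EclipseResult:
    """Rod-model (static eclipse) plateau estimate
    ``1 - <Omega_object/4pi>_region``, by uniform Monte-Carlo over the
    looping volume.  Raises :class:`GeometryError` if the object intersects
    the region."""
    rng = rng or np.random.default_rng()
    pts = sample_region_points(region, n_points, rng)
    d = np.linalg.norm(pts - np.asarray(object_position, float)[None, :], axis=1)
    r_eff = R_o + 0.5 * w
    if np.any(d < r_eff):
        raise GeometryError("object intersects the looping volume")
    x = r_eff / d
    frac = 0.5 * (1.0 - np.sqrt(1.0 - x * x))  # Omega / 4 pi
    m = float(np.mean(frac))
    se = float(np.std(frac, ddof=1)) / math.sqrt(n_points)
    return EclipseResult(f_inf=1.0 - m, se=se, i_object=m)


def _ray_hits_sphere(points, dirs, center, radius) -> np.ndarray:
    """Vectorized ray/sphere test: does the ray p + t d (t > 0) pass within
    ``radius`` of ``center``?"""
    rel = center[None, :] - points
    b = np.einsum("ij,ij->i", rel, dirs)
    c = np.einsum("ij,ij->i", rel, rel) - radius * radius
    return (c < 0.0) | ((b > 0.0) & (b * b > c))


def f_inf_eclipse(
    scene: EclipseScene,
    n_points: int = 100_000,
    rng: np.random.Generator | None = None,
) -> EclipseResult:
    """Full eclipse combination with the chain-occlusion correction.

    Monte-Carlo over (point in region) x (uniform direction): a direction
    contributes to ``I_chain`` if its ray hits any frozen chain-joint
    sphere (occlusion radius ``w``), to ``I_object`` if it hits the object
    (radius ``R_o + w/2``), and to the intersection term if both.
    """
    rng = rng or np.random.default_rng()
    pts = sample_region_points(scene.region, n_points, rng)
    z = rng.normal(size=(n_points, 3))
    dirs = z / np.linalg.norm(z, axis=1, keepdims=True)

    d = np.linalg.norm(pts - scene.object_position[None, :], axis=1)
    if np.any(d < scene.effective_radius):
        raise GeometryError("object intersects the looping volume")

    hit_obj = _ray_hits_sphere(pts, dirs, scene.object_position, scene.effective_radius)
    hit_chain = np.zeros(n_points, dtype=bool)
    if scene.chain_joints is not None and len(scene.chain_joints):
        for joint in scene.chain_joints:
            hit_chain |= _ray_hits_sphere(pts, dirs, joint, scene.w)
    f_obj = float(np.mean(hit_obj))
    f_chain = float(np.mean(hit_chain))
    f_both = float(np.mean(hit_obj & hit_chain))
    denom = 1.0 - f_chain
    if denom <= 0:
        raise GeometryError("chain occludes the entire sky from the looping volume")
    f = 1.0 - f_obj / denom + f_both / denom
    # binomial-scale SE of the dominant (object) term
    se = math.sqrt(max(f_obj * (1 - f_obj), f_both * (1 - f_both)) / n_points) / denom
    return EclipseResult(f_inf=f, se=se, i_object=f_obj, i_chain=f_chain, i_both=f_both)


def terminating_segments_correction(
    T: float,
    scene: EclipseScene,
    link_length: float,
    kuhn_length: float,
    n_samples: int = 50_000,
    rng: np.random.Generator | None = None,
    rigid: bool = False,
) -> tuple[float, float]:
    """Survival of short flexible chains leaving the looping volume.

    Grows chains of contour length ``T`` (links of ``link_length``, bending
    constant from ``kuhn_length``) from uniform points of the looping
    volume with uniform initial directions, and returns ``(fraction of
    chains whose joints avoid the object, SE)``, normalized by the same
    fraction with the object removed (identically 1 when the scene holds no
    other obstacle).  With ``rigid=True`` the chain is a straight rod of
    length ``T`` — the rod-model limit.
    """
    rng = rng or np.random.default_rng()
    if rigid:
        n_links_eff, l, a = 1, T, 0.0
    else:
        n_links_eff = max(int(round(T / link_length)), 1)
        l = link_length
        a = bending_constant_from_kuhn(kuhn_length, link_length)
    pts = sample_region_points(scene.region, n_samples, rng)
    z = rng.normal(size=(n_samples, 3))
    t = z / np.linalg.norm(z, axis=1, keepdims=True)

    c = scene.object_position
    r_eff = scene.effective_radius
    alive = np.ones(n_samples, dtype=bool)
    pos = pts.copy()
    for _ in range(n_links_eff):
        # continuous segment-sphere test: the chain is a tube of radius w/2,
        # so each link sweeps a capsule against the object sphere
        rel = c[None, :] - pos
        proj = np.clip(np.einsum("ij,ij->i", rel, t), 0.0, l)
        closest = pos + proj[:, None] * t
        d2 = np.einsum("ij,ij->i", closest - c[None, :], closest - c[None, :])
        alive &= d2 >= r_eff * r_eff
        pos = pos + l * t
        if not rigid and n_links_eff > 1:
            # advance tangents by a Boltzmann bend (azimuth uniform)
            u1 = 1.0 - rng.random(n_samples)
            if a < 1e-12:
                ct = 2.0 * u1 - 1.0
            else:
                ct = 1.0 + np.log(u1 + (1.0 - u1) * math.exp(-2.0 * a)) / a
            ct = np.clip(ct, -1.0, 1.0)
            st = np.sqrt(1.0 - ct**2)
            phi = 2.0 * math.pi * rng.random(n_samples)
            helper = np.zeros_like(t)
            small = np.abs(t[:, 2]) < 0.9
            helper[small, 2] = 1.0
            helper[~small, 1] = 1.0
            e1 = np.cross(t, helper)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(t, e1)
            t = (
                ct[:, None] * t
                + (st * np.cos(phi))[:, None] * e1
                + (st * np.sin(phi))[:, None] * e2
            )
    p = float(np.mean(alive))
    se = math.sqrt(p * (1 - p) / n_samples)
    return p, se


def fit_quadratic_eclipse(radii, f_values, errors, w: float) -> EclipseFit:
    """Weighted least squares of ``F_inf`` against ``1 - A (R_o + w/2)^2 + B``.

    Returns coefficients, their covariance, and R^2 relative to the
    weighted mean.  Raises for fewer than 3 points or a singular design
    (all radii equal).
    """
    radii = np.asarray(radii, float)
    f_values = np.asarray(f_values, float)
    errors = np.asarray(errors, float)
    if len(radii) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(radii, radii[0]):
        raise np.linalg.LinAlgError("all radii equal: singular design")
    x = (radii + 0.5 * w) ** 2
    wts = np.where(errors > 0, 1.0 / errors**2, 1.0)
    # model: F - 1 = -A x + B
    X = np.column_stack([-x, np.ones_like(x)])
    y = f_values - 1.0
    WX = X * wts[:, None]
    cov = np.linalg.inv(X.T @ WX)
    beta = cov @ (WX.T @ y)
    resid = y - X @ beta
    ybar = float(np.sum(wts * y) / np.sum(wts))
    ss_res = float(np.sum(wts * resid**2))
    ss_tot = float(np.sum(wts * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return EclipseFit(A_K=float(beta[0]), B_K=float(beta[1]), r_squared=r2, covariance=cov)
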