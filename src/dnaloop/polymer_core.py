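"""Geometry and energy primitives of the discrete semi-flexible chain.

The polymer is a chain of ``N`` links of length ``l``; joint ``i`` is the end
point of link ``i`` and joint 0 the origin terminus.  Every joint carries a
hard-wall sphere of diameter ``w`` (the chain cross-section).  The bending
energy per joint is ``a (1 - cos theta)`` with ``a`` the dimensionless
bending constant, related to the Kuhn length ``b`` through the discrete
worm-like-chain identity ``b/l = (1+c)/(1-c)`` with ``c = <cos theta> =
coth a - 1/a``.  Twist carries no elastic energy; the local material frame
``(u, v, t)`` is parallel-transported along the chain, and bound proteins
are modelled as hard spheres hung off a joint at a phase angle ``gamma``
about the local tangent.

All lengths are in nanometres; base-pair positions convert at 0.34 nm/bp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

BP_NM = 0.34  # contour length of one base pair of dsDNA, nm

__all__ = [
    "BP_NM",
    "SimulationParams",
    "ChainConf",
    "Protrusion",
    "bending_energy",
    "mean_cos_theta",
    "bending_constant_from_kuhn",
    "sample_bend",
    "propagate_frame",
    "protrusion_center",
    "hard_wall_overlap",
    "phantom_chain_r2",
    "default_delta_i",
]


def default_delta_i(w: float, l: float) -> int:
    """Neighbour-exclusion window for link length ``l`` and chain width ``w``.

    For ``l >= w`` consecutive joint spheres cannot overlap and ``Delta_i = 1``.
    For ``l < w`` the window must satisfy ``Delta_i >= w/l``; the default is
    ``ceil((4/3) w / l)`` (19 for the base-pair stage of dsDNA).
    """
    if l >= w:
        return 1
    return int(math.ceil((4.0 / 3.0) * w / l))


@dataclass
class SimulationParams:
    """Physical and numerical constants of a simulation.

    Parameters
    ----------
    w : chain cross-section diameter, nm.
    b : Kuhn length, nm.
    l1, l2 : link lengths of the fine (stage-1) and coarse (stage-2)
        resolution segments, nm.  Stage 1 resolves single base pairs so
        that bound objects can sit at base-pair positions; stage 2 uses
        ``l2 = w`` links for speed.
    N1, N2 : number of links in each stage.
    delta_i_stage1 : exclusion window for stage-1 self-avoidance.
    n_chains : ensemble size.
    seed : root RNG seed; per-chain streams are derived from it.
    """

    w: float = 4.6
    b: float = 106.0
    l1: float = BP_NM
    l2: float = 4.6
    N1: int = 100
    N2: int = 100
    delta_i_stage1: int | None = None
    n_chains: int = 100_000
    seed: int = 0
    bp_nm: float = BP_NM

    def __post_init__(self) -> None:
        if min(self.w, self.b, self.l1, self.l2) <= 0:
            raise ValueError("w, b, l1 and l2 must be positive")
        if self.delta_i_stage1 is None:
            self.delta_i_stage1 = default_delta_i(self.w, self.l1)
        if self.l1 < self.w and self.delta_i_stage1 < self.w / self.l1:
            raise ValueError(
                f"delta_i_stage1={self.delta_i_stage1} violates Delta_i >= w/l1 "
                f"= {self.w / self.l1:.2f}"
            )
        if self.N1 * self.l1 + self.N2 * self.l2 <= 0:
            raise ValueError("total chain length must be positive")

    @property
    def a1(self) -> float:
        """Bending constant of stage-1 links."""
        return bending_constant_from_kuhn(self.b, self.l1)

    @property
    def a2(self) -> float:
        """Bending constant of stage-2 links."""
        return bending_constant_from_kuhn(self.b, self.l2)

    @property
    def total_length(self) -> float:
        return self.N1 * self.l1 + self.N2 * self.l2


@dataclass
class ChainConf:
    """A single chain configuration.

    ``joints`` holds ``r_0 .. r_N`` (shape ``(N+1, 3)``); ``frames`` holds the
    per-link orthonormal triads ``(u_i, v_i, t_i)`` (shape ``(N, 3, 3)``, rows
    u, v, t); ``link_lengths`` the per-link lengths.  A discarded chain has
    ``rosenbluth_weight == 0``.
    """

    joints: np.ndarray
    frames: np.ndarray
    link_lengths: np.ndarray
    rosenbluth_weight: float = 1.0
    discarded: bool = False

    @property
    def n_links(self) -> int:
        return len(self.link_lengths)

    def end_to_end(self) -> np.ndarray:
        return self.joints[-1] - self.joints[0]


@dataclass
class Protrusion:
    """A hard-sphere bound object.

    ``on_chain`` protrusions hang off chain link ``link_index`` (1-based along
    the looping segment; negative values address links of the outside
    segment grown in the ``-t_1`` direction from joint 0) at phase ``gamma``
    about the local tangent.  ``static`` protrusions sit at a fixed lab-frame
    ``position``.
    """

    kind: str = "on_chain"  # "on_chain" | "static"
    link_index: int = 0
    position: np.ndarray | None = None
    radius: float = 0.0
    phase: float = 0.0
    role: str = "object"  # "object" | "activator"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("protrusion radius must be positive")
        if self.kind == "on_chain":
            if self.link_index == 0:
                raise ValueError("on-chain protrusion needs a nonzero link index")
        elif self.kind == "static":
            if self.position is None:
                raise ValueError("static protrusion needs a position")
            self.position = np.asarray(self.position, dtype=float)
        else:
            raise ValueError(f"unknown protrusion kind {self.kind!r}")

    def contact_radius(self, w: float) -> float:
        """Joint-centre distance below which the protrusion overlaps the chain."""
        return self.radius + 0.5 * w

    def along_chain_nm(self, l1: float) -> float:
        """Signed along-chain distance K of the binding link, nm."""
        return self.link_index * l1


def bending_energy(theta: float, a: float) -> float:
    """Dimensionless bending energy ``beta E = a (1 - cos theta)``.

    The azimuthal angle does not enter (azimuthal symmetry).
    """
    return a * (1.0 - np.cos(theta))


def mean_cos_theta(a: float) -> float:
    """``<cos theta> = coth a - 1/a`` under the Boltzmann bend density.

    This is the Langevin function of ``a``; it is also the per-step tangent
    correlation of the discrete chain.  Accurate for all ``a >= 0``.
    """
    a = float(a)
    if a < 1e-4:
        return a / 3.0 - a**3 / 45.0
    return 1.0 / math.tanh(a) - 1.0 / a


def _kuhn_ratio(a: float) -> float:
    """Forward map of the stiffness relation: returns b/l for bending constant a."""
    c = mean_cos_theta(a)
    return (1.0 + c) / (1.0 - c)


def bending_constant_from_kuhn(b: float, l: float) -> float:
    """Invert ``b/l = (a - 1 + a coth a)/(a + 1 - a coth a)`` for ``a``.

    Equivalent to ``b/l = (1+c)/(1-c)`` with ``c = coth a - 1/a``.  The
    freely-jointed limit ``b = l`` gives ``a = 0``; for large ``b/l``,
    ``a -> (b/l + 1)/2``.  Raises for ``b/l < 1`` (no non-negative root).
    """
    ratio = b / l
    if ratio < 1.0:
        raise ValueError(f"b/l = {ratio:.4g} < 1 has no non-negative solution")
    if ratio == 1.0:
        return 0.0
    lo, hi = 1e-12, (ratio + 1.0) / 2.0 + 2.0
    a = brentq(lambda x: _kuhn_ratio(x) - ratio, lo, hi, xtol=1e-14, rtol=1e-15)
    return float(a)


def sample_bend(a: float, rng: np.random.Generator) -> tuple[float, float]:
    """Draw a bend ``(theta, phi)`` from the Boltzmann density of one joint.

    ``theta`` follows ``p(theta) ~ exp(-a(1-cos theta)) sin theta`` via the
    closed-form inverse CDF ``cos theta = 1 + ln(u + (1-u) e^{-2a})/a`` for
    ``u`` uniform on (0, 1]; ``phi`` is uniform on [0, 2 pi).  At ``a = 0``
    the direction is uniform on the sphere.
    """
    u = 1.0 - rng.random()  # (0, 1]
    if a < 1e-12:
        cos_t = 2.0 * u - 1.0
    else:
        cos_t = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * a)) / a
    cos_t = min(1.0, max(-1.0, cos_t))
    theta = math.acos(cos_t)
    phi = 2.0 * math.pi * rng.random()
    return theta, phi


def propagate_frame(frame: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Advance the material frame by one link.

    ``frame`` is a ``(3, 3)`` array with rows ``(u, v, t)``.  The new tangent
    has zenith ``theta`` and azimuth ``phi`` in the old local frame; ``u`` is
    parallel-transported (rotated by the minimal rotation taking ``t`` to the
    new tangent), which encodes the absence of intrinsic twist.
    """
    u, v, t = frame
    st, ct = math.sin(theta), math.cos(theta)
    t_new = st * math.cos(phi) * u + st * math.sin(phi) * v + ct * t
    n = np.cross(t, t_new)
    s = np.linalg.norm(n)
    if s < 1e-14:
        u_new = u.copy()
    else:
        n = n / s
        u_new = u * ct + np.cross(n, u) * st + n * np.dot(n, u) * (1.0 - ct)
    # re-orthogonalize against accumulated drift
    u_new = u_new - np.dot(u_new, t_new) * t_new
    u_new /= np.linalg.norm(u_new)
    v_new = np.cross(t_new, u_new)
    return np.array([u_new, v_new, t_new])


def initial_frame() -> np.ndarray:
    """Lab-frame convention: t_1 = +z, u = +x, v = t x u = +y, r_0 at origin.

    The looping-volume axis u^0 is the lab +x direction.
    """
    return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])


def protrusion_center(
    r_k: np.ndarray,
    u_hat: np.ndarray,
    t_hat: np.ndarray,
    gamma: float,
    w: float,
    R_o: float,
) -> np.ndarray:
    """Centre of a protrusion bound at joint ``r_k``.

    ``r_object = r_k + (w/2 + R_o) R(gamma, t) u`` with ``R`` a right-handed
    rotation about the tangent.  ``gamma = 0`` places the sphere along ``u``
    (in phase with the looping volume), ``gamma = pi`` opposite to it.
    """
    direction = u_hat * math.cos(gamma) + np.cross(t_hat, u_hat) * math.sin(gamma)
    return r_k + (0.5 * w + R_o) * direction


def hard_wall_overlap(
    joints: np.ndarray,
    i: int,
    delta_i: int,
    w: float,
    protrusions: Sequence[tuple[np.ndarray, float, int]] = (),
) -> bool:
    """Hard-wall test for newly placed joint ``i``.

    True iff joint ``i`` lies within ``w`` of any joint ``j <= i - delta_i``,
    or within the contact radius of a protrusion ``(center, R_o, anchor)``
    whose anchor link index is ``< i`` (pass ``anchor = -1`` for static
    objects).  Touching spheres (equality) are allowed.
    """
    r_i = joints[i]
    jmax = i - delta_i
    if jmax >= 0:
        d2 = np.sum((joints[: jmax + 1] - r_i) ** 2, axis=1)
        if np.any(d2 < w * w * (1.0 - 1e-9)):
            return True
    for center, R_o, anchor in protrusions:
        if anchor == i:
            continue  # tangent to its own anchor joint by construction
        if anchor >= 0 and anchor >= i:
            continue  # not yet placed during growth
        contact = R_o + 0.5 * w
        if np.sum((r_i - center) ** 2) < contact * contact * (1.0 - 1e-9):
            return True
    return False


def phantom_chain_r2(N: int, l: float, a: float) -> float:
    """Mean-square end-to-end distance of the phantom (non-interacting) chain.

    Closed form for the discrete worm-like chain with per-step tangent
    correlation ``c = coth a - 1/a``::

        <R^2> = N l^2 [ (1+c)/(1-c) - 2 c (1 - c^N) / (N (1-c)^2) ]

    At ``a = 0`` this reduces to the freely-jointed ``N l^2``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    c = mean_cos_theta(a)
    if c == 0.0:
        return N * l * l
    return N * l * l * ((1 + c) / (1 - c) - 2 * c * (1 - c**N) / (N * (1 - c) ** 2))
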