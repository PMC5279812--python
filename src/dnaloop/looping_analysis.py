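"""Looping criteria, probabilities, the ratio F(L) and its plateau.

A chain of length ``L`` is *looped* when its distal terminus falls inside
the looping volume: a radial shell ``d_min <= |dr| <= d_min + eps`` about
the anchor, intersected with a spherical cap of solid angle ``|domega|``
about the orientation axis (``domega < 0`` selects the cap about the
reversed axis; ``|domega| = 4 pi`` accepts every direction).

The looping-probability ratio ``F(L) = P_looped^object(L) /
P_looped^baseline(L)`` compares an ensemble with a bound protrusion to the
bare chain; its large-``L`` plateau ``F_infinity`` is reported as the mean
of a trailing window of ``F(L)`` points with a ±1.96 standard-error
halfwidth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .chain_sampler import Ensemble
    from .polymer_core import Protrusion, SimulationParams

__all__ = [
    "LoopCriteria",
    "EveCriteria",
    "PCurve",
    "FCurve",
    "default_criteria",
    "is_looped",
    "looping_probability",
    "f_ratio",
    "estimate_f_infinity",
    "eve_looping_probability",
]

FOUR_PI = 4.0 * math.pi


@dataclass(frozen=True)
class LoopCriteria:
    """Origin-anchored looping volume.

    ``domega`` is the signed angular acceptance in steradians, in
    ``(-4 pi, 4 pi]``; the cap half-angle satisfies
    ``|domega| = 2 pi (1 - cos theta_c)``.
    """

    d_min: float
    epsilon: float
    domega: float
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    anchor: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.d_min < 0:
            raise ValueError("d_min must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if abs(self.domega) > FOUR_PI:
            raise ValueError("|domega| must be <= 4 pi")


@dataclass(frozen=True)
class EveCriteria:
    """Activator-anchored looping: the distal terminus must reach the shell
    ``R_chain + R_activator <= |r_N - r_act| <= ... + eps`` about *any*
    activator sphere, within ``domega`` of the chain-to-activator axis.
    One accumulator column per entry of ``domegas``.
    """

    domegas: tuple[float, ...] = (2 * math.pi * 0.1, 2 * math.pi, -math.pi)
    epsilon: float = 3.0


def default_criteria(params: "SimulationParams") -> LoopCriteria:
    """The standard looping volume: d_min = w, eps = 2w, domega = 2 pi x 0.1,
    axis u^0 = +x."""
    return LoopCriteria(d_min=params.w, epsilon=2 * params.w, domega=2 * math.pi * 0.1)


def is_looped(chain_end, criteria: LoopCriteria) -> bool:
    """Pure predicate form of the looping volume test."""
    dr = np.asarray(chain_end, float) - np.asarray(criteria.anchor, float)
    d = float(np.linalg.norm(dr))
    if d < criteria.d_min or d > criteria.d_min + criteria.epsilon or d == 0.0:
        return False
    ado = abs(criteria.domega)
    if ado >= FOUR_PI:
        return True
    axis = np.asarray(criteria.axis, float)
    axis = axis / np.linalg.norm(axis)
    cos_c = 1.0 - ado / (2.0 * math.pi)
    ca = float(np.dot(dr, axis)) / d
    if criteria.domega < 0:
        ca = -ca
    return ca >= cos_c


@dataclass
class PCurve:
    """Per-length looping probability with standard errors."""

    lengths_nm: np.ndarray
    lengths_bp: np.ndarray
    p: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        self.lengths_nm = np.asarray(self.lengths_nm, float)
        self.lengths_bp = np.asarray(self.lengths_bp, float)
        self.p = np.asarray(self.p, float)
        self.se = np.asarray(self.se, float)


@dataclass
class FCurve:
    """The looping-probability ratio on a length grid, with plateau fields
    filled in by :func:`estimate_f_infinity`."""

    lengths_nm: np.ndarray
    lengths_bp: np.ndarray
    f_values: np.ndarray
    std_errors: np.ndarray
    plateau_mean: float | None = None
    plateau_halfwidth: float | None = None
    plateau_window: int | None = None
    flatness_ok: bool | None = None


def _weighted_binomial_se(loop_w: np.ndarray, z: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """SE of a weighted probability via the effective sample size
    ``n_eff = (sum w)^2 / sum w^2`` (equals the plain binomial SE for unit
    weights)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = loop_w / z
        n_eff = np.where(z2 > 0, z * z / np.where(z2 > 0, z2, 1.0), 0.0)
        se = np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / np.where(n_eff > 0, n_eff, np.nan))
    return se


def _criterion_column(ensemble: "Ensemble", criteria) -> int:
    if criteria is None:
        return 0
    if ensemble.crit_mode == 0:
        for ci, cr in enumerate(ensemble.criteria):
            if cr == criteria:
                return ci
        raise KeyError("criteria were not compiled into this ensemble")
    raise KeyError("activator-anchored ensemble: use eve_looping_probability")


def looping_probability(ensemble: "Ensemble", criteria: LoopCriteria | None = None) -> PCurve:
    """Weighted looped fraction per recorded length, with SE.

    ``criteria`` must be one of the criteria the ensemble was generated
    with (streaming accumulation); omit it for the first/only criterion.
    """
    if np.all(ensemble.z_rec == 0):
        raise ZeroDivisionError("Z = 0 at every recorded length")
    ci = _criterion_column(ensemble, criteria)
    z = ensemble.z_rec
    lw = ensemble.loop_w[:, ci]
    p = np.where(z > 0, lw / np.where(z > 0, z, 1.0), np.nan)
    se = _weighted_binomial_se(lw, z, ensemble.z_rec)  # unit weights: z2 = z
    return PCurve(ensemble.lengths_nm, ensemble.lengths_bp, p, se)


def f_ratio(p_object: PCurve, p_baseline: PCurve) -> FCurve:
    """Pointwise ratio ``F = P_obj / P_base`` with first-order independent
    error propagation.  Grids must match; zero baseline raises."""
    if not np.allclose(p_object.lengths_nm, p_baseline.lengths_nm):
        raise ValueError("length grids differ")
    if np.any(~np.isfinite(p_baseline.p)) or np.any(p_baseline.p <= 0):
        raise ZeroDivisionError("baseline looping probability is zero at some lengths")
    f = p_object.p / p_baseline.p
    rel2 = np.zeros_like(f)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_o = np.where(p_object.p > 0, p_object.se / p_object.p, 0.0)
        rel_b = p_baseline.se / p_baseline.p
        rel2 = rel_o**2 + rel_b**2
        # for zero numerators propagate the baseline + counting scale
        se = np.where(p_object.p > 0, f * np.sqrt(rel2), p_object.se / p_baseline.p)
    return FCurve(p_object.lengths_nm, p_object.lengths_bp, f, se)


def estimate_f_infinity(curve: FCurve, window: int | None = None,
                        kuhn_length: float | None = None) -> tuple[float, float]:
    """Plateau of F(L): mean over the trailing ``window`` points and a
    ±1.96-standard-error halfwidth.

    Default window: the last 480 points when the curve has that many, else
    the trailing half of the points with ``L > 5 b`` (``kuhn_length``
    required in that case; with neither available, the trailing half of the
    whole curve).  Also performs a flatness check (trailing linear-fit slope
    consistent with zero within 2 SE); failure sets ``flatness_ok=False``
    as a diagnostic, never an error.
    """
    n = len(curve.f_values)
    if window is None:
        if n >= 480:
            window = 480
        elif kuhn_length is not None:
            tail = np.flatnonzero(curve.lengths_nm > 5 * kuhn_length)
            window = max(len(tail) // 2, 2) if len(tail) >= 4 else max(n // 2, 1)
        else:
            window = max(n // 2, 1)
    if window > n:
        raise ValueError(f"window {window} larger than curve ({n} points)")
    tail_f = curve.f_values[-window:]
    mean = float(np.mean(tail_f))
    if window == 1:
        half = float("nan")
    else:
        half = 1.96 * float(np.std(tail_f, ddof=1)) / math.sqrt(window)
    # flatness diagnostic
    ok = True
    if window >= 3:
        x = curve.lengths_nm[-window:]
        x = x - x.mean()
        y = tail_f - mean
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        se_slope = math.sqrt(
            float(np.sum(resid**2)) / max(window - 2, 1) / float(np.sum(x * x))
        )
        ok = abs(slope) <= 2.0 * se_slope if se_slope > 0 else True
    curve.plateau_mean = mean
    curve.plateau_halfwidth = half
    curve.plateau_window = window
    curve.flatness_ok = bool(ok)
    return mean, half


def eve_looping_probability(ensemble: "Ensemble", domega: float | None = None) -> PCurve:
    """Total looping probability with respect to the enhancer activators.

    The total is the *sum* of the per-activator looping probabilities (no
    de-duplication of chains looped with respect to several activators at
    once); the double-counted weight fraction is available from
    :func:`eve_double_count_fraction` as a diagnostic.
    """
    if ensemble.crit_mode != 1:
        raise ValueError("ensemble was not generated with activator-anchored criteria")
    ci = _eve_column(ensemble, domega)
    z = ensemble.z_rec
    lw = ensemble.loop_w[:, ci]
    p = np.where(z > 0, lw / np.where(z > 0, z, 1.0), np.nan)
    # SE from the union count (conservative for the summed estimator)
    se = _weighted_binomial_se(ensemble.union_w[:, ci], z, z)
    return PCurve(ensemble.lengths_nm, ensemble.lengths_bp, p, se)


def _eve_column(ensemble: "Ensemble", domega: float | None) -> int:
    domegas = ensemble.criteria.domegas
    if domega is None:
        if len(domegas) != 1:
            raise ValueError(f"specify domega, one of {domegas}")
        return 0
    for ci, d in enumerate(domegas):
        if math.isclose(d, domega, rel_tol=1e-12, abs_tol=1e-12):
            return ci
    raise KeyError(f"domega {domega} not among compiled choices {domegas}")


def eve_double_count_fraction(ensemble: "Ensemble", domega: float | None = None) -> float:
    """Fraction of the summed looped weight that came from chains looped
    with respect to more than one activator simultaneously."""
    ci = _eve_column(ensemble, domega)
    total = float(ensemble.loop_w[:, ci].sum())
    union = float(ensemble.union_w[:, ci].sum())
    if total == 0:
        return 0.0
    return (total - union) / total
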