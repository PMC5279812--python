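"""Self-validation: closed-form and brute-force oracles for the sampler.

The central correctness check is sampler equivalence: because bend angles
are drawn from the exact elastic Boltzmann density and hard walls act by
discarding, the sequential kernel must reproduce a *naive* rejection
sampler — full chains drawn from the phantom ensemble, then rejected on
any overlap — which is implemented here independently (vectorized numpy,
its own RNG).  Phantom-chain moments against closed forms and the
solid-angle formula against direction sampling complete the suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .eclipse_model import solid_angle_sphere
from .looping_analysis import LoopCriteria, is_looped
from .polymer_core import (
    SimulationParams,
    mean_cos_theta,
    phantom_chain_r2,
    propagate_frame,
    initial_frame,
)

__all__ = ["naive_rejection_ensemble", "run_validate"]


def sample_bend_cos(a: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized inverse-CDF draw of cos(theta) from the Boltzmann bend
    density (independent implementation used by the oracle sampler)."""
    u = 1.0 - rng.random(n)
    if a < 1e-12:
        return 2.0 * u - 1.0
    return np.clip(1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * a)) / a, -1.0, 1.0)


def naive_rejection_ensemble(
    n_chains: int,
    n_links: int,
    link_length: float,
    a: float,
    w: float,
    rng: np.random.Generator,
    protrusion: tuple[int, float, float] | None = None,
    delta_i: int = 1,
    criteria: LoopCriteria | None = None,
) -> dict:
    """Brute-force oracle: draw whole phantom chains, then reject any chain
    with a hard-wall overlap (joint-joint under the ``delta_i`` window, or
    joint/protrusion).  ``protrusion`` is ``(link_index, radius, gamma)``.

    Returns acceptance fraction, end-to-end ``<R^2>`` over accepted chains
    and the looped fraction, each with standard errors.
    """
    M, N = n_chains, n_links
    cos_t = sample_bend_cos(a, M * N, rng).reshape(M, N)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = 2.0 * math.pi * rng.random((M, N))

    u = np.tile([1.0, 0.0, 0.0], (M, 1))
    t = np.tile([0.0, 0.0, 1.0], (M, 1))
    pos = np.zeros((M, N + 1, 3))
    frames_u = np.zeros((M, N, 3))
    frames_t = np.zeros((M, N, 3))
    for i in range(N):
        v = np.cross(t, u)
        ct = cos_t[:, i : i + 1]
        st = sin_t[:, i : i + 1]
        cp = np.cos(phi[:, i : i + 1])
        sp = np.sin(phi[:, i : i + 1])
        t_new = st * cp * u + st * sp * v + ct * t
        n_ax = np.cross(t, t_new)
        nn = np.linalg.norm(n_ax, axis=1, keepdims=True)
        safe = nn[:, 0] > 1e-14
        n_ax = np.where(safe[:, None], n_ax / np.where(nn > 0, nn, 1.0), n_ax)
        ndu = np.einsum("ij,ij->i", n_ax, u)[:, None]
        u_new = u * ct + np.cross(n_ax, u) * st + n_ax * ndu * (1.0 - ct)
        u_new = np.where(safe[:, None], u_new, u)
        u_new -= np.einsum("ij,ij->i", u_new, t_new)[:, None] * t_new
        u_new /= np.linalg.norm(u_new, axis=1, keepdims=True)
        u, t = u_new, t_new
        pos[:, i + 1] = pos[:, i] + link_length * t
        frames_u[:, i] = u
        frames_t[:, i] = t

    ok = np.ones(M, dtype=bool)
    w2 = w * w * (1.0 - 1e-9)
    for i in range(N + 1):
        for j in range(i + delta_i, N + 1):
            d2 = np.einsum("ij,ij->i", pos[:, j] - pos[:, i], pos[:, j] - pos[:, i])
            ok &= d2 >= w2
    center = None
    if protrusion is not None:
        k, R_o, gamma = protrusion
        u_k = frames_u[:, k - 1]
        t_k = frames_t[:, k - 1]
        direction = u_k * math.cos(gamma) + np.cross(t_k, u_k) * math.sin(gamma)
        center = pos[:, k] + (0.5 * w + R_o) * direction
        contact2 = (0.5 * w + R_o) ** 2 * (1.0 - 1e-9)
        for i in range(N + 1):
            if i == k:
                continue  # tangent to its own anchor joint
            d2 = np.einsum("ij,ij->i", pos[:, i] - center, pos[:, i] - center)
            ok &= d2 >= contact2

    acc = float(np.mean(ok))
    n_ok = int(ok.sum())
    out = {
        "acceptance": acc,
        "acceptance_se": math.sqrt(max(acc * (1 - acc), 1e-300) / M),
        "n_accepted": n_ok,
    }
    if n_ok:
        r2 = np.einsum("ij,ij->i", pos[ok, -1], pos[ok, -1])
        out["r2_mean"] = float(r2.mean())
        out["r2_se"] = float(r2.std(ddof=1)) / math.sqrt(n_ok)
        if criteria is not None:
            looped = np.array([is_looped(e, criteria) for e in pos[ok, -1]])
            p = float(looped.mean())
            out["p_loop"] = p
            out["p_loop_se"] = math.sqrt(max(p * (1 - p), 1e-300) / n_ok)
    return out


@dataclass
class Check:
    name: str
    passed: bool
    value: float
    expected: float
    tolerance: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def run_validate(seed: int = 0, quick: bool = True) -> dict:
    """Execute the oracle suite; returns a machine-readable report.

    Failures are reported, never raised.  ``quick=False`` increases the
    Monte-Carlo sample sizes roughly tenfold.
    """
    from .chain_sampler import (
        GrowthSchedule,
        Segment,
        generate_ensemble,
        two_stage_schedule,
    )
    from .polymer_core import Protrusion

    scale = 1 if quick else 10
    rng = np.random.default_rng(seed)
    checks: list[Check] = []

    # 1. sampled <cos theta> vs the Langevin function
    for a in (0.0, 5.0):
        n = 200_000 * scale
        c = sample_bend_cos(a, n, rng)
        expect = mean_cos_theta(a)
        se = float(c.std(ddof=1)) / math.sqrt(n)
        checks.append(Check(f"mean_cos_theta_a{a:g}", abs(c.mean() - expect) < 3 * se,
                            float(c.mean()), expect, 3 * se))

    # 2. phantom-chain <R^2> vs closed form (kernel path, hard walls off)
    params = SimulationParams(N1=0, N2=200, seed=seed)
    sched = GrowthSchedule(segments=[Segment(200, params.l2)])
    n = 20_000 * scale
    ens = generate_ensemble(sched, params, n, seed=seed, record="final",
                            phantom=True,
                            criteria=LoopCriteria(0.0, 1e9, 4 * math.pi))
    r2 = float(ens.mean_r2()[-1])
    expect = phantom_chain_r2(200, params.l2, params.a2)
    se = expect * math.sqrt(2.0 / n)  # scale estimate of var(R^2)
    checks.append(Check("phantom_r2", abs(r2 - expect) < 3 * se, r2, expect, 3 * se))

    # 3. kernel vs naive rejection sampler (the central unbiasedness oracle)
    n = 60_000 * scale
    crit = LoopCriteria(d_min=0.0, epsilon=3 * 4.6, domega=4 * math.pi)
    a_flex = 1.0
    oracle = naive_rejection_ensemble(
        n, 20, 4.6, a_flex, 4.6, np.random.default_rng(seed + 1),
        protrusion=(5, 4.6, 0.0), criteria=crit,
    )
    p_flex = SimulationParams(N1=0, N2=20, b=_b_of(a_flex, 4.6), seed=seed)
    sched = GrowthSchedule(
        segments=[Segment(20, 4.6)],
        protrusions=[Protrusion(kind="on_chain", link_index=5, radius=4.6)],
    )
    ens = generate_ensemble(sched, p_flex, n, seed=seed, record="final", criteria=crit)
    acc = ens.acceptance_fraction()
    acc_se = math.sqrt(acc * (1 - acc) / n)
    tol = 3 * math.hypot(acc_se, oracle["acceptance_se"])
    checks.append(Check("rejection_acceptance", abs(acc - oracle["acceptance"]) < tol,
                        acc, oracle["acceptance"], tol))
    r2 = float(ens.mean_r2()[-1])
    r2_se = oracle["r2_se"] * math.sqrt(oracle["n_accepted"] / max(ens.z_final, 1))
    tol = 3 * math.hypot(r2_se, oracle["r2_se"])
    checks.append(Check("rejection_r2", abs(r2 - oracle["r2_mean"]) < tol,
                        r2, oracle["r2_mean"], tol))
    p = float(ens.loop_w[-1, 0] / ens.z_rec[-1])
    p_se = math.sqrt(p * (1 - p) / ens.z_rec[-1])
    tol = 3 * math.hypot(p_se, oracle["p_loop_se"])
    checks.append(Check("rejection_p_loop", abs(p - oracle["p_loop"]) < tol,
                        p, oracle["p_loop"], tol))

    # 4. solid-angle formula vs brute-force direction sampling
    n = 200_000 * scale
    for ratio in (1.2, 3.0, 30.0):
        r_eff, d = 1.0, ratio
        z = rng.normal(size=(n, 3))
        dirs = z / np.linalg.norm(z, axis=1, keepdims=True)
        # sphere centred at d*z_hat: a ray from origin hits iff angle < asin(r/d)
        hits = dirs[:, 2] > math.sqrt(1.0 - (r_eff / d) ** 2)
        est = 4 * math.pi * float(hits.mean())
        se = 4 * math.pi * math.sqrt(hits.mean() * (1 - hits.mean()) / n)
        expect = solid_angle_sphere(d, r_eff)
        checks.append(Check(f"solid_angle_d{ratio:g}", abs(est - expect) < 3 * se,
                            est, expect, 3 * se))
    checks.append(Check("solid_angle_tangent",
                        abs(solid_angle_sphere(1.0, 1.0) - 2 * math.pi) < 1e-12,
                        solid_angle_sphere(1.0, 1.0), 2 * math.pi, 1e-12))

    # 5. frame orthonormality over a long transport chain
    frame = initial_frame()
    rng2 = np.random.default_rng(seed + 2)
    worst = 0.0
    for _ in range(10_000):
        frame = propagate_frame(frame, rng2.uniform(0, math.pi), rng2.uniform(0, 2 * math.pi))
        worst = max(worst, float(np.abs(frame @ frame.T - np.eye(3)).max()))
    checks.append(Check("frame_orthonormality", worst < 1e-10, worst, 0.0, 1e-10))

    return {
        "passed": all(c.passed for c in checks),
        "checks": [c.as_dict() for c in checks],
        "seed": seed,
        "quick": quick,
    }


def _b_of(a: float, l: float) -> float:
    """Kuhn length giving bending constant ``a`` at link length ``l``."""
    c = mean_cos_theta(a)
    return l * (1 + c) / (1 - c)
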