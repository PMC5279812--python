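"""Ensemble growth of self-avoiding chains with bound protrusions.

Chains are grown link by link (sequential importance sampling in the
Rosenbluth tradition): each bend angle is drawn from the exact elastic
Boltzmann density, so the elastic energy contributes no weight and the
hard-wall factor is handled by single-trial survival — a surviving chain has
Rosenbluth weight 1, the partition sum ``Z`` is the number of survivors, and
weighted ensemble averages are unbiased (the scheme is exact rejection
sampling, which the validation suite checks against an independent
vectorized sampler).

Looping observables are recorded at intermediate lengths while the chain
grows, so a single ensemble yields the whole ``P_looped(L)`` curve; a chain
contributes at length ``L`` iff it survived ``trailing_links`` joints past
the recorded joint (this implements trailing-flank bookkeeping: the weight
of the extended chain is assigned to the central segment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .polymer_core import (
    BP_NM,
    ChainConf,
    Protrusion,
    SimulationParams,
    bending_constant_from_kuhn,
    default_delta_i,
    initial_frame,
    propagate_frame,
    protrusion_center,
    sample_bend,
)

__all__ = [
    "Segment",
    "GrowthSchedule",
    "Ensemble",
    "two_stage_schedule",
    "grow_chain",
    "generate_ensemble",
    "merge_ensembles",
    "ensemble_average",
    "confinement_check",
    "save_ensemble",
    "load_ensemble",
    "write_xyz",
]


@dataclass
class Segment:
    """A run of ``n_links`` links of equal length; ``delta_i`` defaults to
    1 for ``l >= w`` and ``ceil((4/3) w/l)`` otherwise."""

    n_links: int
    link_length: float
    delta_i: int | None = None

    def resolved_delta_i(self, w: float) -> int:
        return self.delta_i if self.delta_i is not None else default_delta_i(w, self.link_length)


@dataclass
class GrowthSchedule:
    """Full description of what to grow.

    ``segments`` are the forward (looping-segment) pieces, fine resolution
    first.  ``outside_segments`` are grown backwards from joint 0 in the
    ``-t_1`` direction before the forward pieces — used both for leading
    flanks and for the outside ``Q`` segment that hosts negative-K
    protrusions.  ``trailing_links`` is the number of joints past each
    recorded length that must survive for the length to count (trailing
    flank).  ``confinement_radius`` adds a hard spherical wall centred on
    joint 0.
    """

    segments: list[Segment]
    protrusions: list[Protrusion] = field(default_factory=list)
    outside_segments: list[Segment] = field(default_factory=list)
    trailing_links: int = 0
    confinement_radius: float | None = None

    @property
    def n_forward(self) -> int:
        return sum(s.n_links for s in self.segments)

    @property
    def n_backward(self) -> int:
        return sum(s.n_links for s in self.outside_segments)

    def validate(self, params: SimulationParams) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one forward segment")
        for p in self.protrusions:
            if p.kind != "on_chain":
                continue
            if p.link_index > 0 and p.link_index > self.n_forward:
                raise ValueError(f"protrusion link {p.link_index} beyond forward region")
            if p.link_index < 0:
                if -p.link_index > self.n_backward:
                    raise ValueError(
                        f"protrusion link {p.link_index} beyond outside region"
                    )
                # outside placements require Q >> |K|
                q_len = sum(s.n_links * s.link_length for s in self.outside_segments)
                k_len = -p.link_index * self.outside_segments[0].link_length
                if q_len < 10.0 * abs(k_len):
                    raise ValueError(
                        f"outside segment Q={q_len:.0f} nm must be >= 10 |K| = "
                        f"{10 * abs(k_len):.0f} nm"
                    )
        if self.trailing_links < 0:
            raise ValueError("trailing_links must be >= 0")
        if self.confinement_radius is not None and self.confinement_radius <= params.w:
            raise ValueError("confinement radius must exceed the chain width")


def two_stage_schedule(
    params: SimulationParams,
    protrusions: Sequence[Protrusion] = (),
    **kwargs,
) -> GrowthSchedule:
    """The standard two-resolution schedule: ``N1`` base-pair links followed
    by ``N2`` links of length ``l2 = w``."""
    segs = []
    if params.N1 > 0:
        segs.append(Segment(params.N1, params.l1, params.delta_i_stage1))
    if params.N2 > 0:
        segs.append(Segment(params.N2, params.l2))
    return GrowthSchedule(segments=segs, protrusions=list(protrusions), **kwargs)


# ---------------------------------------------------------------------------
# schedule compilation


class _Compiled:
    """Flat arrays consumed by the numba kernel."""

    def __init__(self, schedule: GrowthSchedule, params: SimulationParams,
                 criteria, record):
        from .looping_analysis import EveCriteria, LoopCriteria, default_criteria

        schedule.validate(params)
        w = params.w
        nb = schedule.n_backward
        nf = schedule.n_forward
        n = 1 + nb + nf
        j_len = np.zeros(n)
        j_a = np.zeros(n)
        j_s = np.zeros(n)
        j_excl = np.zeros(n)

        def fill(segs, sign, start):
            i, s = start, 0.0
            for seg in segs:
                a = bending_constant_from_kuhn(params.b, seg.link_length)
                excl = seg.resolved_delta_i(w) * seg.link_length
                for _ in range(seg.n_links):
                    s += seg.link_length
                    j_len[i] = seg.link_length
                    j_a[i] = a
                    j_s[i] = sign * s
                    j_excl[i] = excl
                    i += 1
            return i

        fill(schedule.outside_segments, -1.0, 1)
        fill(schedule.segments, +1.0, 1 + nb)
        excl0 = j_excl[1 + nb]
        if nb:
            excl0 = max(excl0, j_excl[1])
        j_excl[0] = excl0

        prots = schedule.protrusions
        n_prot = len(prots)
        p_joint = np.full(n_prot, -1, dtype=np.int64)
        p_gamma = np.zeros(n_prot)
        p_radius = np.zeros(n_prot)
        p_static = np.zeros((n_prot, 3))
        for q, p in enumerate(prots):
            p_radius[q] = p.radius
            if p.kind == "static":
                p_static[q] = p.position
            else:
                p_gamma[q] = p.phase
                p_joint[q] = (nb + p.link_index) if p.link_index > 0 else -p.link_index

        # record grid
        trail = schedule.trailing_links
        max_anchor_fwd = max(
            (int(a) for a in p_joint if a > nb), default=nb
        )
        if record == "coarse":
            first_last_seg = 1 + nb + nf - schedule.segments[-1].n_links
            cand = np.arange(first_last_seg, 1 + nb + nf)
        elif record == "all":
            cand = np.arange(1 + nb, 1 + nb + nf)
        elif record == "final":
            cand = np.array([nb + nf])
        else:  # sequence of forward link numbers, 1-based
            cand = nb + np.asarray(list(record), dtype=np.int64)
        cand = cand[(cand > max_anchor_fwd) & (cand <= nb + nf - trail)]
        if len(cand) == 0:
            raise ValueError("record grid is empty (protrusion anchors or "
                             "trailing links leave no recordable joints)")
        rec_of = np.full(n, -1, dtype=np.int64)
        rec_of[cand] = np.arange(len(cand))

        # criteria
        if criteria is None:
            criteria = [default_criteria(params)]
        if isinstance(criteria, EveCriteria):
            mode = 1
            act_idx = np.array(
                [q for q, p in enumerate(prots) if p.role == "activator"],
                dtype=np.int64,
            )
            if len(act_idx) == 0:
                raise ValueError("activator-anchored criteria need activator protrusions")
            ncrit = len(criteria.domegas)
            c_axis = np.zeros((ncrit, 3))
            c_dmin = np.zeros(ncrit)
            c_eps = np.full(ncrit, criteria.epsilon)
            c_domega = np.asarray(criteria.domegas, dtype=float)
            crit_list = criteria
        else:
            if isinstance(criteria, LoopCriteria):
                criteria = [criteria]
            mode = 0
            act_idx = np.zeros(0, dtype=np.int64)
            ncrit = len(criteria)
            c_axis = np.zeros((ncrit, 3))
            c_dmin = np.zeros(ncrit)
            c_eps = np.zeros(ncrit)
            c_domega = np.zeros(ncrit)
            for ci, cr in enumerate(criteria):
                ax = np.asarray(cr.axis, dtype=float)
                c_axis[ci] = ax / np.linalg.norm(ax)
                c_dmin[ci] = cr.d_min
                c_eps[ci] = cr.epsilon
                c_domega[ci] = cr.domega
            crit_list = list(criteria)

        self.schedule = schedule
        self.params = params
        self.criteria = crit_list
        self.mode = mode
        self.nb = nb
        self.args = dict(
            j_len=j_len, j_a=j_a, j_s=j_s, j_excl=j_excl, nb=nb, w=w,
            conf_radius=float(schedule.confinement_radius or 0.0),
            p_joint=p_joint, p_gamma=p_gamma, p_radius=p_radius,
            p_static=p_static, rec_of=rec_of, n_rec=len(cand), trail=trail,
            crit_mode=mode, c_axis=c_axis, c_dmin=c_dmin, c_eps=c_eps,
            c_domega=c_domega, act_idx=act_idx,
        )
        self.lengths_nm = j_s[cand].copy()


@dataclass
class Ensemble:
    """Accumulated weighted observables of a chain ensemble.

    ``z_rec[m]`` is the summed weight of chains alive at recorded length
    ``lengths_nm[m]`` (plus trailing links); ``loop_w[m, c]`` the looped
    weight under criterion ``c`` (for activator-anchored criteria this is
    the *sum* over activators, ``union_w`` the de-duplicated union).  All
    accumulators are additive under merging of independently indexed
    sub-ensembles.
    """

    params: SimulationParams
    lengths_nm: np.ndarray
    z_rec: np.ndarray
    loop_w: np.ndarray
    loop_w2: np.ndarray
    union_w: np.ndarray
    r2_sum: np.ndarray
    n_generated: int
    n_discarded: int
    z_final: float
    seed: int
    chain_offset: int
    criteria: object
    crit_mode: int
    chains: list[ChainConf] | None = None

    @property
    def partition_sum(self) -> float:
        return self.z_final

    @property
    def lengths_bp(self) -> np.ndarray:
        return self.lengths_nm / self.params.bp_nm

    def acceptance_fraction(self) -> float:
        return 1.0 - self.n_discarded / self.n_generated

    def mean_r2(self) -> np.ndarray:
        """Weighted <R^2> (end-to-end from joint 0) per recorded length."""
        return self.r2_sum / self.z_rec


def grow_chain(
    schedule: GrowthSchedule,
    params: SimulationParams,
    rng: np.random.Generator,
) -> ChainConf:
    """Grow a single chain (pure-Python reference path).

    Returns the chain in chain order (outside region reversed, then joint 0,
    then the forward region).  Discarded chains come back with
    ``discarded=True`` and weight 0, never as exceptions.
    """
    schedule.validate(params)
    w = params.w
    conf = schedule.confinement_radius or 0.0

    def seg_joints(segs, sign):
        lens, avals, excls, svals = [], [], [], []
        s = 0.0
        for seg in segs:
            a = bending_constant_from_kuhn(params.b, seg.link_length)
            excl = seg.resolved_delta_i(w) * seg.link_length
            for _ in range(seg.n_links):
                s += seg.link_length
                lens.append(seg.link_length)
                avals.append(a)
                excls.append(excl)
                svals.append(sign * s)
        return lens, avals, excls, svals

    bl, ba, be, bs = seg_joints(schedule.outside_segments, -1.0)
    fl, fa, fe, fs = seg_joints(schedule.segments, +1.0)
    nb = len(bl)
    lens = [0.0] + bl + fl
    avals = [0.0] + ba + fa
    excls = [max(fe[0], be[0] if nb else 0.0)] + be + fe
    svals = [0.0] + bs + fs

    n = len(lens)
    pos = np.zeros((n, 3))
    frames = np.zeros((n, 3, 3))
    placed: dict[int, tuple[np.ndarray, float]] = {}
    anchors: dict[int, list[int]] = {}
    for q, p in enumerate(schedule.protrusions):
        if p.kind == "static":
            placed[q] = (np.asarray(p.position, float), p.radius)
        else:
            g = (nb + p.link_index) if p.link_index > 0 else -p.link_index
            anchors.setdefault(g, []).append(q)

    alive = True

    def dead() -> ChainConf:
        return ChainConf(
            joints=pos, frames=frames, link_lengths=np.array(lens[1:]),
            rosenbluth_weight=0.0, discarded=True,
        )

    for phase in range(2):
        if phase == 0:
            rng_idx = range(1, nb + 1)
            frame = initial_frame()
            frame[2] = -frame[2]  # t = -z
            frame[1] = np.cross(frame[2], frame[0])
        else:
            rng_idx = range(nb + 1, n)
            frame = initial_frame()
        p_cur = np.zeros(3)
        for i in rng_idx:
            theta, phi = sample_bend(avals[i], rng)
            frame = propagate_frame(frame, theta, phi)
            p_cur = p_cur + lens[i] * frame[2]
            pos[i] = p_cur
            frames[i] = frame
            if conf > 0.0 and np.linalg.norm(p_cur) + 0.5 * w > conf:
                return dead()
            # joint-joint hard walls
            for j in range(i):
                if abs(svals[i] - svals[j]) < max(excls[i], excls[j]):
                    continue
                if np.sum((p_cur - pos[j]) ** 2) < w * w * (1.0 - 1e-9):
                    return dead()
            # joint vs placed protrusions
            for q, (c, R) in placed.items():
                contact = R + 0.5 * w
                if np.sum((p_cur - c) ** 2) < contact * contact * (1.0 - 1e-9):
                    return dead()
            # place protrusions anchored here
            for q in anchors.get(i, ()):
                p = schedule.protrusions[q]
                c = protrusion_center(p_cur, frame[0], frame[2], p.phase, w, p.radius)
                if conf > 0.0 and np.linalg.norm(c) + p.radius > conf:
                    return dead()
                contact = p.radius + 0.5 * w
                for j in range(i):  # own anchor joint excluded (tangent)
                    if np.sum((c - pos[j]) ** 2) < contact * contact * (1.0 - 1e-9):
                        return dead()
                for qq, (c2, R2) in placed.items():
                    if np.sum((c - c2) ** 2) < (p.radius + R2) ** 2 * (1.0 - 1e-9):
                        return dead()
                placed[q] = (c, p.radius)

    # chain order: reversed outside region, origin, forward region
    order = list(range(nb, 0, -1)) + [0] + list(range(nb + 1, n))
    centers = (
        np.array([placed[q][0] for q in sorted(placed)]) if placed else None
    )
    link_frames, link_lens = [], []
    for m in range(1, nb + 1):
        gi = nb - m + 1  # chain link m traverses growth link gi in reverse
        f = frames[gi].copy()
        f[2] = -f[2]
        f[1] = np.cross(f[2], f[0])
        link_frames.append(f)
        link_lens.append(lens[gi])
    for i in range(nb + 1, n):
        link_frames.append(frames[i])
        link_lens.append(lens[i])
    conf_chain = ChainConf(
        joints=pos[order],
        frames=np.array(link_frames),
        link_lengths=np.array(link_lens),
        rosenbluth_weight=1.0,
        discarded=False,
    )
    conf_chain.origin_index = nb  # type: ignore[attr-defined]
    conf_chain.protrusion_centers = centers  # type: ignore[attr-defined]
    return conf_chain


def generate_ensemble(
    schedule: GrowthSchedule,
    params: SimulationParams,
    n_chains: int,
    seed: int | None = None,
    *,
    criteria=None,
    record="coarse",
    chain_offset: int = 0,
    keep_chains: bool = False,
    phantom: bool = False,
    check_protrusions: bool = True,
) -> Ensemble:
    """Grow ``n_chains`` chains and accumulate looping observables.

    Deterministic given ``(seed, chain_offset, schedule)``; sub-ensembles
    over disjoint chain-index ranges merge to identical totals.  With
    ``phantom=True`` joint-joint hard walls are disabled (protrusion and
    confinement walls remain unless ``check_protrusions=False``).

    ``keep_chains=True`` additionally retains a list of chains sampled by
    the reference Python path (its own stream seeded from ``seed``) for use
    with :func:`ensemble_average`; the streaming accumulators always come
    from the compiled kernel.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if seed is None:
        seed = params.seed
    comp = _Compiled(schedule, params, criteria, record)
    a = comp.args
    z_rec, loop_w, union_w, r2_sum, n_disc, z_final = _kernels.run_ensemble(
        np.int64(seed), np.int64(chain_offset), np.int64(n_chains),
        a["j_len"], a["j_a"], a["j_s"], a["j_excl"], np.int64(a["nb"]),
        float(a["w"]), np.uint8(0 if phantom else 1), float(a["conf_radius"]),
        a["p_joint"], a["p_gamma"], a["p_radius"], a["p_static"],
        np.uint8(1 if check_protrusions else 0),
        a["rec_of"], np.int64(a["n_rec"]), np.int64(a["trail"]),
        np.int64(a["crit_mode"]), a["c_axis"], a["c_dmin"], a["c_eps"],
        a["c_domega"], a["act_idx"],
    )
    if n_disc == n_chains:
        raise RuntimeError("every chain was discarded (Z = 0); loosen the "
                           "geometry or increase the ensemble")
    chains = None
    if keep_chains:
        rng = np.random.default_rng(seed)
        chains = [grow_chain(schedule, params, rng) for _ in range(n_chains)]
    return Ensemble(
        params=params,
        lengths_nm=comp.lengths_nm,
        z_rec=z_rec,
        loop_w=loop_w,
        loop_w2=loop_w.copy(),  # unit weights: sum w^2 = sum w
        union_w=union_w,
        r2_sum=r2_sum,
        n_generated=n_chains,
        n_discarded=int(n_disc),
        z_final=float(z_final),
        seed=seed,
        chain_offset=chain_offset,
        criteria=comp.criteria,
        crit_mode=comp.mode,
        chains=chains,
    )


def merge_ensembles(*ensembles: Ensemble) -> Ensemble:
    """Merge sub-ensembles (additive accumulators; exact for count-valued
    sums since all weights are unit)."""
    if len(ensembles) < 1:
        raise ValueError("nothing to merge")
    first = ensembles[0]
    for e in ensembles[1:]:
        if not np.array_equal(e.lengths_nm, first.lengths_nm):
            raise ValueError("length grids differ")
    out = replace(
        first,
        z_rec=sum(e.z_rec for e in ensembles),
        loop_w=sum(e.loop_w for e in ensembles),
        loop_w2=sum(e.loop_w2 for e in ensembles),
        union_w=sum(e.union_w for e in ensembles),
        r2_sum=sum(e.r2_sum for e in ensembles),
        n_generated=sum(e.n_generated for e in ensembles),
        n_discarded=sum(e.n_discarded for e in ensembles),
        z_final=sum(e.z_final for e in ensembles),
        chains=None,
    )
    return out


def ensemble_average(ensemble: Ensemble, observable) -> float:
    """Weighted ensemble average ``sum f(x_j) w_j / Z`` over retained chains.

    Requires the ensemble to have been generated with ``keep_chains=True``;
    the streaming accumulators cover the standard observables without
    retaining chains.
    """
    if ensemble.chains is None:
        raise ValueError("ensemble was generated without keep_chains=True")
    z = sum(c.rosenbluth_weight for c in ensemble.chains)
    if z <= 0:
        raise ZeroDivisionError("Z = 0: ensemble average undefined")
    return sum(
        observable(c) * c.rosenbluth_weight
        for c in ensemble.chains
        if c.rosenbluth_weight > 0
    ) / z


def confinement_check(joint, radius: float, center=(0.0, 0.0, 0.0), w: float = 0.0) -> bool:
    """True iff the whole joint sphere (radius ``w/2``) fits inside the
    confining sphere."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return float(np.linalg.norm(np.asarray(joint, float) - np.asarray(center, float))) + 0.5 * w <= radius


# ---------------------------------------------------------------------------
# checkpoints and trajectory export


def save_ensemble(ensemble: Ensemble, path) -> None:
    """Single-file binary checkpoint with named arrays (numpy .npz)."""
    meta = dict(
        n_generated=ensemble.n_generated,
        n_discarded=ensemble.n_discarded,
        z_final=ensemble.z_final,
        seed=ensemble.seed,
        chain_offset=ensemble.chain_offset,
        crit_mode=ensemble.crit_mode,
        params=ensemble.params.__dict__,
    )
    np.savez(
        path,
        lengths_nm=ensemble.lengths_nm,
        z_rec=ensemble.z_rec,
        loop_w=ensemble.loop_w,
        loop_w2=ensemble.loop_w2,
        union_w=ensemble.union_w,
        r2_sum=ensemble.r2_sum,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_ensemble(path) -> Ensemble:
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        return Ensemble(
            params=SimulationParams(**meta["params"]),
            lengths_nm=f["lengths_nm"],
            z_rec=f["z_rec"],
            loop_w=f["loop_w"],
            loop_w2=f["loop_w2"],
            union_w=f["union_w"],
            r2_sum=f["r2_sum"],
            n_generated=meta["n_generated"],
            n_discarded=meta["n_discarded"],
            z_final=meta["z_final"],
            seed=meta["seed"],
            chain_offset=meta["chain_offset"],
            criteria=None,
            crit_mode=meta["crit_mode"],
        )


def write_xyz(chains: Sequence[ChainConf], path) -> None:
    """One XYZ frame per chain; joints tagged ``C``, protrusion centres ``P``."""
    with open(path, "w") as fh:
        for c in chains:
            centers = getattr(c, "protrusion_centers", None)
            n = len(c.joints) + (0 if centers is None else len(centers))
            fh.write(f"{n}\nchain weight={c.rosenbluth_weight}\n")
            for r in c.joints:
                fh.write(f"C {r[0]:.4f} {r[1]:.4f} {r[2]:.4f}\n")
            if centers is not None:
                for r in centers:
                    fh.write(f"P {r[0]:.4f} {r[1]:.4f} {r[2]:.4f}\n")
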