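"""Numba kernel for sequential chain growth.

One flat kernel grows an ensemble of chains joint by joint: bend angles come
from the exact Boltzmann density (inverse CDF), so the only stochastic weight
is hard-wall survival — a surviving chain carries Rosenbluth weight 1 and the
scheme is exact rejection sampling of the self-avoiding Boltzmann ensemble.

Joints are laid out in growth order in a single array:

* index 0 — joint ``r_0`` at the origin (pre-placed),
* indices ``1 .. nb`` — joints of the backward-grown region (leading flank
  or the outside ``Q`` segment for negative-K scenes), grown first,
* indices ``nb+1 .. n_joints-1`` — forward (looping-segment) joints.

Growth order equals index order, so "previously generated" always means a
smaller index.  ``s[i]`` is the signed arc coordinate of joint ``i``
(negative backward).  Joints ``i, j`` hard-wall interact iff
``|s_i - s_j| >= max(excl_i, excl_j)`` where ``excl`` is the segment's
exclusion arc (``Delta_i * l``); overlap is a strict ``< w`` on centre
distance (touching allowed).

Per-chain random streams are counter-based (splitmix64 seeded from
``(seed, chain_index)``), so ensembles are deterministic and mergeable
regardless of how the chain-index range is partitioned.
"""

import numpy as np
from numba import njit

_U = np.uint64
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _mix(z):
    z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
    return z ^ (z >> _U(31))


@njit(cache=True, inline="always")
def _next(state):
    state[0] = state[0] + _U(0x9E3779B97F4A7C15)
    return _mix(state[0])


@njit(cache=True, inline="always")
def _unif(state):
    # uniform double in [0, 1)
    return float(_next(state) >> _U(11)) * _INV53


@njit(cache=True, inline="always")
def _accept(dx, dy, dz, d, ax, ay, az, dmin, eps, domega):
    """Looping acceptance: radial shell plus spherical cap about +/- axis."""
    if d < dmin or d > dmin + eps or d <= 0.0:
        return False
    ado = domega if domega >= 0.0 else -domega
    if ado >= 4.0 * np.pi:
        return True
    cos_c = 1.0 - ado / (2.0 * np.pi)
    ca = (dx * ax + dy * ay + dz * az) / d
    if domega < 0.0:
        ca = -ca
    return ca >= cos_c


@njit(cache=True)
def run_ensemble(
    seed,            # int64 root seed
    chain_offset,    # int64 first chain index
    n_chains,        # int64
    # per-joint static description, growth order, length n_joints
    j_len,           # f8[:] link length ending at joint i (j_len[0] unused)
    j_a,             # f8[:] bending constant of that link
    j_s,             # f8[:] signed arc coordinate
    j_excl,          # f8[:] exclusion arc threshold of the joint's segment
    nb,              # int64 number of backward joints
    w,               # f8 chain width
    chain_chain,     # u1 enable joint-joint hard walls
    conf_radius,     # f8 confinement sphere radius about origin; <=0 disables
    # protrusions (length n_prot)
    p_joint,         # i8[:] global joint index of anchor; -1 for static
    p_gamma,         # f8[:]
    p_radius,        # f8[:]
    p_static,        # f8[:, :] (n_prot, 3) static positions (ignored for on-chain)
    prot_chain,      # u1 enable protrusion overlap tests
    # recording
    rec_of,          # i8[:] length n_joints: joint -> record slot or -1
    n_rec,           # int64
    trail,           # int64 joints beyond a recorded joint required alive
    # looping criteria
    crit_mode,       # int64 0: origin-anchored; 1: activator-anchored
    c_axis,          # f8[:, :] (n_crit, 3) axes (mode 0)
    c_dmin,          # f8[:] (mode 0; mode 1 uses w/2 + R_activator)
    c_eps,           # f8[:]
    c_domega,        # f8[:]
    act_idx,         # i8[:] protrusion indices of activators (mode 1)
):
    n_joints = j_len.shape[0]
    n_prot = p_joint.shape[0]
    n_crit = c_domega.shape[0]
    n_act = act_idx.shape[0]

    pos = np.empty((n_joints, 3))
    centers = np.empty((n_prot, 3))
    axes = np.empty((n_prot, 3))  # unit vector joint -> centre, for activators

    z_rec = np.zeros(n_rec)
    loop_sum = np.zeros((n_rec, n_crit))
    union_sum = np.zeros((n_rec, n_crit))
    r2_sum = np.zeros(n_rec)
    n_discarded = 0
    z_final = 0.0

    two_pi = 2.0 * np.pi
    w2 = w * w * (1.0 - 1e-9)  # touching joints (exact tangency) never overlap
    state = np.empty(1, dtype=np.uint64)

    for chain in range(n_chains):
        state[0] = _mix(_U(seed) * _U(0x9E3779B97F4A7C15) ^ _U(chain_offset + chain + 1))
        alive = True

        # static protrusions are present from the start
        for p in range(n_prot):
            if p_joint[p] < 0:
                centers[p, 0] = p_static[p, 0]
                centers[p, 1] = p_static[p, 1]
                centers[p, 2] = p_static[p, 2]

        pos[0, 0] = 0.0
        pos[0, 1] = 0.0
        pos[0, 2] = 0.0

        # two growth phases: backward joints 1..nb, then forward joints
        for phase in range(2):
            if not alive:
                break
            if phase == 0:
                lo, hi = 1, nb + 1
                tx, ty, tz = 0.0, 0.0, -1.0
            else:
                lo, hi = nb + 1, n_joints
                tx, ty, tz = 0.0, 0.0, 1.0
            ux, uy, uz = 1.0, 0.0, 0.0
            vx = ty * uz - tz * uy
            vy = tz * ux - tx * uz
            vz = tx * uy - ty * ux
            px, py, pz = 0.0, 0.0, 0.0  # both phases start at the origin

            for i in range(lo, hi):
                a = j_a[i]
                l = j_len[i]
                # --- sample bend from the Boltzmann density
                u1 = 1.0 - _unif(state)  # (0, 1]
                if a < 1e-12:
                    ct = 2.0 * u1 - 1.0
                else:
                    ct = 1.0 + np.log(u1 + (1.0 - u1) * np.exp(-2.0 * a)) / a
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                st = np.sqrt(1.0 - ct * ct)
                phi = two_pi * _unif(state)
                cp = np.cos(phi)
                sp = np.sin(phi)
                # --- new tangent in the local frame
                ntx = st * cp * ux + st * sp * vx + ct * tx
                nty = st * cp * uy + st * sp * vy + ct * ty
                ntz = st * cp * uz + st * sp * vz + ct * tz
                # --- parallel transport u: rotate about n = t x t_new by theta
                nx = ty * ntz - tz * nty
                ny = tz * ntx - tx * ntz
                nz = tx * nty - ty * ntx
                nn = np.sqrt(nx * nx + ny * ny + nz * nz)
                if nn < 1e-14:
                    nux, nuy, nuz = ux, uy, uz
                else:
                    nx /= nn
                    ny /= nn
                    nz /= nn
                    ndu = nx * ux + ny * uy + nz * uz
                    cxx = ny * uz - nz * uy
                    cxy = nz * ux - nx * uz
                    cxz = nx * uy - ny * ux
                    nux = ux * ct + cxx * st + nx * ndu * (1.0 - ct)
                    nuy = uy * ct + cxy * st + ny * ndu * (1.0 - ct)
                    nuz = uz * ct + cxz * st + nz * ndu * (1.0 - ct)
                # re-orthogonalize u against drift
                dut = nux * ntx + nuy * nty + nuz * ntz
                nux -= dut * ntx
                nuy -= dut * nty
                nuz -= dut * ntz
                inv = 1.0 / np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux * inv
                uy = nuy * inv
                uz = nuz * inv
                tx, ty, tz = ntx, nty, ntz
                vx = ty * uz - tz * uy
                vy = tz * ux - tx * uz
                vz = tx * uy - ty * ux

                px += l * tx
                py += l * ty
                pz += l * tz
                pos[i, 0] = px
                pos[i, 1] = py
                pos[i, 2] = pz

                # --- confinement (whole joint sphere inside)
                if conf_radius > 0.0:
                    if np.sqrt(px * px + py * py + pz * pz) + 0.5 * w > conf_radius:
                        alive = False
                        break

                # --- hard wall vs previously placed joints (all j < i)
                if chain_chain:
                    si = j_s[i]
                    ei = j_excl[i]
                    ok = True
                    for j in range(i):
                        ds = si - j_s[j]
                        if ds < 0.0:
                            ds = -ds
                        ej = j_excl[j]
                        thr = ei if ei > ej else ej
                        if ds < thr:
                            continue
                        dx = px - pos[j, 0]
                        dy = py - pos[j, 1]
                        dz = pz - pos[j, 2]
                        if dx * dx + dy * dy + dz * dz < w2:
                            ok = False
                            break
                    if not ok:
                        alive = False
                        break

                # --- hard wall vs already-placed protrusions (anchor < i or static)
                if prot_chain and n_prot > 0:
                    ok = True
                    for p in range(n_prot):
                        if p_joint[p] >= i:
                            continue  # own anchor (==i) handled at placement; >i unplaced
                        contact = p_radius[p] + 0.5 * w
                        dx = px - centers[p, 0]
                        dy = py - centers[p, 1]
                        dz = pz - centers[p, 2]
                        if dx * dx + dy * dy + dz * dz < contact * contact * (1.0 - 1e-9):
                            ok = False
                            break
                    if not ok:
                        alive = False
                        break

                # --- place protrusions anchored at this joint
                for p in range(n_prot):
                    if p_joint[p] != i:
                        continue
                    g = p_gamma[p]
                    cg = np.cos(g)
                    sg = np.sin(g)
                    # R(gamma, t) u = u cos g + (t x u) sin g   (t.u = 0)
                    rx = ux * cg + (ty * uz - tz * uy) * sg
                    ry = uy * cg + (tz * ux - tx * uz) * sg
                    rz = uz * cg + (tx * uy - ty * ux) * sg
                    off = 0.5 * w + p_radius[p]
                    cx = px + off * rx
                    cy = py + off * ry
                    cz = pz + off * rz
                    centers[p, 0] = cx
                    centers[p, 1] = cy
                    centers[p, 2] = cz
                    axes[p, 0] = rx
                    axes[p, 1] = ry
                    axes[p, 2] = rz
                    # confinement: whole protrusion sphere inside
                    if conf_radius > 0.0:
                        if np.sqrt(cx * cx + cy * cy + cz * cz) + p_radius[p] > conf_radius:
                            alive = False
                            break
                    if prot_chain:
                        # vs all previously placed joints (own tangent anchor excluded)
                        contact = p_radius[p] + 0.5 * w
                        c2 = contact * contact * (1.0 - 1e-9)
                        ok = True
                        for j in range(i):
                            dx = cx - pos[j, 0]
                            dy = cy - pos[j, 1]
                            dz = cz - pos[j, 2]
                            if dx * dx + dy * dy + dz * dz < c2:
                                ok = False
                                break
                        if ok:
                            # vs other placed protrusions
                            for q in range(n_prot):
                                if q == p:
                                    continue
                                qj = p_joint[q]
                                if qj > i or (qj == i and q > p):
                                    continue  # not yet placed
                                rr = p_radius[p] + p_radius[q]
                                dx = cx - centers[q, 0]
                                dy = cy - centers[q, 1]
                                dz = cz - centers[q, 2]
                                if dx * dx + dy * dy + dz * dz < rr * rr * (1.0 - 1e-9):
                                    ok = False
                                    break
                        if not ok:
                            alive = False
                            break
                if not alive:
                    break

                # --- record prefix observables (forward phase only)
                if phase == 1:
                    g = i - trail
                    if g > nb and rec_of[g] >= 0:
                        slot = rec_of[g]
                        z_rec[slot] += 1.0
                        ex = pos[g, 0]
                        ey = pos[g, 1]
                        ez = pos[g, 2]
                        r2_sum[slot] += ex * ex + ey * ey + ez * ez
                        if crit_mode == 0:
                            d = np.sqrt(ex * ex + ey * ey + ez * ez)
                            for c in range(n_crit):
                                if _accept(ex, ey, ez, d, c_axis[c, 0], c_axis[c, 1],
                                           c_axis[c, 2], c_dmin[c], c_eps[c], c_domega[c]):
                                    loop_sum[slot, c] += 1.0
                                    union_sum[slot, c] += 1.0
                        else:
                            for c in range(n_crit):
                                nsat = 0.0
                                for ai in range(n_act):
                                    p = act_idx[ai]
                                    dx = ex - centers[p, 0]
                                    dy = ey - centers[p, 1]
                                    dz = ez - centers[p, 2]
                                    d = np.sqrt(dx * dx + dy * dy + dz * dz)
                                    dmin = 0.5 * w + p_radius[p]
                                    if _accept(dx, dy, dz, d, axes[p, 0], axes[p, 1],
                                               axes[p, 2], dmin, c_eps[c], c_domega[c]):
                                        nsat += 1.0
                                if nsat > 0.0:
                                    loop_sum[slot, c] += nsat
                                    union_sum[slot, c] += 1.0

        if alive:
            z_final += 1.0
        else:
            n_discarded += 1

    return z_rec, loop_sum, union_sum, r2_sum, n_discarded, z_final
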