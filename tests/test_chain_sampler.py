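"""Sequential growth: unbiasedness, determinism, merging, prefix recording."""

import math

import numpy as np
import pytest

from dnaloop import (
    GrowthSchedule,
    LoopCriteria,
    Protrusion,
    Segment,
    SimulationParams,
    confinement_check,
    ensemble_average,
    generate_ensemble,
    grow_chain,
    merge_ensembles,
    two_stage_schedule,
)
from dnaloop.chain_sampler import load_ensemble, save_ensemble, write_xyz
from dnaloop.polymer_core import phantom_chain_r2, bending_constant_from_kuhn

ALL_DIRS = LoopCriteria(0.0, 1e6, 4 * math.pi)


def stage2_params(n_links, **kw):
    return SimulationParams(N1=0, N2=n_links, **kw)


class TestGrowChain:
    def test_phantom_survives_with_unit_weight(self, rng):
        params = stage2_params(30)
        sched = GrowthSchedule(segments=[Segment(30, params.l2)])
        c = grow_chain(sched, params, rng)
        assert not c.discarded
        assert c.rosenbluth_weight == 1.0
        assert c.n_links == 30
        # joints consistent with frames: r_i - r_{i-1} = l * t_i
        steps = np.diff(c.joints, axis=0)
        assert np.allclose(steps, c.link_lengths[:, None] * c.frames[:, 2], atol=1e-9)

    def test_discard_is_returned_not_raised(self, rng):
        # a protrusion larger than the confining sphere can never fit
        params = stage2_params(10)
        sched = GrowthSchedule(
            segments=[Segment(10, params.l2)],
            protrusions=[Protrusion(kind="on_chain", link_index=2, radius=50.0)],
            confinement_radius=30.0,
        )
        for _ in range(20):
            c = grow_chain(sched, params, rng)
            assert c.discarded and c.rosenbluth_weight == 0.0

    def test_outside_segment_chain_order(self, rng):
        params = stage2_params(10)
        sched = GrowthSchedule(
            segments=[Segment(10, params.l2)],
            outside_segments=[Segment(5, params.l2)],
        )
        for _ in range(50):
            c = grow_chain(sched, params, rng)
            if c.discarded:
                continue
            assert c.joints.shape == (16, 3)
            assert np.allclose(c.joints[c.origin_index], 0.0)
            steps = np.diff(c.joints, axis=0)
            assert np.allclose(
                steps, c.link_lengths[:, None] * c.frames[:, 2], atol=1e-9
            )
            break
        else:
            pytest.fail("no surviving chain")


class TestEnsemble:
    def test_zero_chains_rejected(self):
        params = stage2_params(5)
        with pytest.raises(ValueError):
            generate_ensemble(
                GrowthSchedule(segments=[Segment(5, params.l2)]), params, 0
            )

    def test_phantom_partition_sum_is_n(self):
        params = stage2_params(20)
        sched = GrowthSchedule(segments=[Segment(20, params.l2)])
        e = generate_ensemble(sched, params, 500, seed=3, criteria=ALL_DIRS,
                              record="final", phantom=True)
        assert e.z_final == 500
        assert e.n_discarded == 0
        # every chain is "looped" under the all-accepting criteria
        assert e.loop_w[-1, 0] == 500

    def test_determinism_and_merge_additivity(self):
        params = stage2_params(25)
        sched = GrowthSchedule(segments=[Segment(25, params.l2)])
        kw = dict(criteria=ALL_DIRS, record="all")
        e1 = generate_ensemble(sched, params, 400, seed=9, **kw)
        e2 = generate_ensemble(sched, params, 400, seed=9, **kw)
        assert e1.z_final == e2.z_final
        assert np.array_equal(e1.loop_w, e2.loop_w)
        assert np.array_equal(e1.r2_sum, e2.r2_sum)
        # split into sub-ensembles over disjoint chain-index ranges
        a = generate_ensemble(sched, params, 250, seed=9, **kw)
        b = generate_ensemble(sched, params, 150, seed=9, chain_offset=250, **kw)
        m = merge_ensembles(a, b)
        assert m.z_final == e1.z_final
        assert np.array_equal(m.z_rec, e1.z_rec)
        assert np.array_equal(m.loop_w, e1.loop_w)
        assert np.allclose(m.r2_sum, e1.r2_sum, rtol=1e-12)

    def test_different_seeds_merge_sums_z(self):
        params = stage2_params(10)
        sched = GrowthSchedule(segments=[Segment(10, params.l2)])
        e1 = generate_ensemble(sched, params, 300, seed=1, criteria=ALL_DIRS, phantom=True)
        e2 = generate_ensemble(sched, params, 200, seed=2, criteria=ALL_DIRS, phantom=True)
        assert merge_ensembles(e1, e2).z_final == 500

    def test_phantom_r2_matches_closed_form(self):
        params = stage2_params(100)
        sched = GrowthSchedule(segments=[Segment(100, params.l2)])
        n = 30_000
        e = generate_ensemble(sched, params, n, seed=4, criteria=ALL_DIRS,
                              record="all", phantom=True)
        expect = phantom_chain_r2(100, params.l2, params.a2)
        got = e.mean_r2()[-1]
        se = expect * math.sqrt(2.0 / n)
        assert abs(got - expect) < 3 * se
        # and at an intermediate length
        mid = len(e.lengths_nm) // 2
        n_mid = mid + 1
        expect_mid = phantom_chain_r2(n_mid, params.l2, params.a2)
        assert abs(e.mean_r2()[mid] - expect_mid) < 3 * expect_mid * math.sqrt(2.0 / n)

    def test_prefix_consistency(self):
        """Observables recorded at length L from longer chains match an
        independent ensemble grown only to L."""
        params_long = stage2_params(60)
        params_short = stage2_params(30)
        crit = LoopCriteria(0.0, 50.0, 4 * math.pi)
        n = 40_000
        e_long = generate_ensemble(
            GrowthSchedule(segments=[Segment(60, 4.6)]), params_long, n,
            seed=5, criteria=crit, record="all")
        e_short = generate_ensemble(
            GrowthSchedule(segments=[Segment(30, 4.6)]), params_short, n,
            seed=6, criteria=crit, record="final")
        i = np.flatnonzero(np.isclose(e_long.lengths_nm, e_short.lengths_nm[-1]))[0]
        p_long = e_long.loop_w[i, 0] / e_long.z_rec[i]
        p_short = e_short.loop_w[-1, 0] / e_short.z_rec[-1]
        se = math.sqrt(
            p_long * (1 - p_long) / e_long.z_rec[i]
            + p_short * (1 - p_short) / e_short.z_rec[-1]
        )
        assert abs(p_long - p_short) < 3 * se

    def test_ensemble_average_normalization(self):
        params = stage2_params(8)
        sched = GrowthSchedule(segments=[Segment(8, params.l2)])
        e = generate_ensemble(sched, params, 50, seed=2, criteria=ALL_DIRS,
                              keep_chains=True)
        assert ensemble_average(e, lambda c: 1.0) == pytest.approx(1.0)
        r2 = ensemble_average(e, lambda c: c.end_to_end() @ c.end_to_end())
        assert r2 > 0

    def test_all_discarded_raises(self):
        params = stage2_params(10)
        sched = GrowthSchedule(
            segments=[Segment(10, params.l2)],
            protrusions=[Protrusion(kind="on_chain", link_index=2, radius=40.0)],
            confinement_radius=20.0,
        )
        with pytest.raises(RuntimeError):
            generate_ensemble(sched, params, 50, seed=1, criteria=ALL_DIRS)


class TestConfinement:
    def test_confinement_check_geometry(self):
        assert confinement_check([0, 0, 0], 10.0, w=4.6)
        assert not confinement_check([10.0, 0, 0], 10.0, w=4.6)
        assert confinement_check([7.7, 0, 0], 10.0, w=4.6)

    def test_confinement_increases_looping(self):
        """With the gyration radius comparable to the confining sphere, the
        looped fraction of survivors rises above the free-chain value."""
        params = stage2_params(80)
        crit = LoopCriteria(4.6, 9.2, 2 * math.pi)
        n = 60_000
        free = generate_ensemble(
            GrowthSchedule(segments=[Segment(80, 4.6)]), params, n,
            seed=8, criteria=crit)
        conf = generate_ensemble(
            GrowthSchedule(segments=[Segment(80, 4.6)], confinement_radius=80.0),
            params, n, seed=8, criteria=crit)
        win = 15
        p_free = free.loop_w[-win:, 0].sum() / free.z_rec[-win:].sum()
        p_conf = conf.loop_w[-win:, 0].sum() / conf.z_rec[-win:].sum()
        se = math.sqrt(
            p_free / max(free.loop_w[-win:, 0].sum(), 1)
            + p_conf / max(conf.loop_w[-win:, 0].sum(), 1)
        ) * max(p_free, p_conf)
        assert p_conf > p_free + 2 * se


class TestRejectionOracle:
    def test_sis_matches_naive_rejection(self):
        """Central unbiasedness oracle: the sequential sampler agrees with
        an independent whole-chain rejection sampler on acceptance, <R^2>
        and a permissive looped fraction (3 combined SE)."""
        from dnaloop.validate import naive_rejection_ensemble, _b_of

        n = 40_000
        a = 1.5
        crit = LoopCriteria(0.0, 13.8, 4 * math.pi)
        oracle = naive_rejection_ensemble(
            n, 18, 4.6, a, 4.6, np.random.default_rng(100),
            protrusion=(5, 4.6, 0.0), criteria=crit)
        params = SimulationParams(N1=0, N2=18, b=_b_of(a, 4.6))
        sched = GrowthSchedule(
            segments=[Segment(18, 4.6)],
            protrusions=[Protrusion(kind="on_chain", link_index=5, radius=4.6)],
        )
        e = generate_ensemble(sched, params, n, seed=101, record="final", criteria=crit)
        acc = e.acceptance_fraction()
        tol = 3 * math.hypot(
            math.sqrt(acc * (1 - acc) / n), oracle["acceptance_se"])
        assert abs(acc - oracle["acceptance"]) < tol
        r2 = e.mean_r2()[-1]
        tol = 3 * math.sqrt(2) * oracle["r2_se"]
        assert abs(r2 - oracle["r2_mean"]) < tol
        p = e.loop_w[-1, 0] / e.z_rec[-1]
        tol = 3 * math.hypot(
            math.sqrt(max(p * (1 - p), 1e-12) / e.z_rec[-1]), oracle["p_loop_se"])
        assert abs(p - oracle["p_loop"]) < tol


class TestIO:
    def test_checkpoint_roundtrip(self, tmp_path):
        params = stage2_params(12)
        sched = GrowthSchedule(segments=[Segment(12, params.l2)])
        e = generate_ensemble(sched, params, 200, seed=3, criteria=ALL_DIRS)
        path = tmp_path / "ens.npz"
        save_ensemble(e, path)
        e2 = load_ensemble(path)
        assert e2.z_final == e.z_final
        assert np.array_equal(e2.loop_w, e.loop_w)
        assert e2.params.w == params.w

    def test_xyz_export(self, tmp_path, rng):
        params = stage2_params(10)
        sched = GrowthSchedule(
            segments=[Segment(10, params.l2)],
            protrusions=[Protrusion(kind="on_chain", link_index=3, radius=5.0)],
        )
        chains = []
        while len(chains) < 3:
            c = grow_chain(sched, params, rng)
            if not c.discarded:
                chains.append(c)
        path = tmp_path / "traj.xyz"
        write_xyz(chains, path)
        text = path.read_text().splitlines()
        assert text[0].strip() == "12"  # 11 joints + 1 protrusion centre
        assert any(line.startswith("P ") for line in text)


def test_schedule_validation():
    params = SimulationParams(N1=10, N2=10)
    with pytest.raises(ValueError):
        GrowthSchedule(segments=[]).validate(params)
    s = GrowthSchedule(
        segments=[Segment(10, 0.34)],
        protrusions=[Protrusion(kind="on_chain", link_index=50, radius=1.0)],
    )
    with pytest.raises(ValueError):
        s.validate(params)
    # outside placement requires Q >= 10 |K|
    s = GrowthSchedule(
        segments=[Segment(10, 4.6)],
        outside_segments=[Segment(20, 0.34)],
        protrusions=[Protrusion(kind="on_chain", link_index=-10, radius=1.0)],
    )
    with pytest.raises(ValueError):
        s.validate(params)
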