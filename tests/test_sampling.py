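import numpy as np
import pytest

from graftropy import (
    DeadEnd,
    LatticeConfig,
    enumerate_exact,
    free_sites,
    grow_chain,
    sample_ensemble,
)
from graftropy.sampling import Environment
from graftropy.surfaces import HeightField
from helpers import small_anchored_env


class TestFreeSites:
    def test_first_step_from_open_space_has_24_options(self, free_env_small):
        start = free_env_small.lattice.origin
        assert len(free_sites(free_env_small, {start}, start)) == 24

    def test_anchored_first_step_has_16_options(self, flat_anchored_env):
        start = flat_anchored_env.start
        assert len(free_sites(flat_anchored_env, {start}, start)) == 16

    def test_occupied_neighbours_are_excluded(self, free_env_small, moves):
        start = free_env_small.lattice.origin
        nb = tuple(s + d for s, d in zip(start, moves.vectors[0]))
        options = free_sites(free_env_small, {start, nb}, start)
        assert len(options) == 23 and nb not in options


class TestGrowChain:
    def test_two_segment_chain_records_k24(self, free_env_small):
        rec = grow_chain(free_env_small, 2, np.random.default_rng(0))
        assert rec.k == [24]
        assert len(rec.sites) == 2

    def test_step_two_always_has_23_options(self, free_env_small):
        # No (023) two-step walk can revisit: only the exact reverse move
        # returns, and that site is occupied.
        rng = np.random.default_rng(1)
        for _ in range(50):
            rec = grow_chain(free_env_small, 3, rng)
            assert rec.k[1] == 23

    def test_dead_end_when_fully_enclosed(self):
        # Altitude 9 everywhere except a one-column well: every move from
        # the well bottom collides with the solid.
        z = np.full((41, 41), 9, dtype=np.int32)
        z[20, 20] = 0
        field = HeightField(z=z, L=41)
        from graftropy.surfaces import AnchorSpec
        from graftropy.sampling import anchored_environment

        env = anchored_environment(
            field,
            AnchorSpec(mode="min", region=((0, 40), (0, 40)), site=(20, 20, 1)),
            LatticeConfig(box_edge=41),
        )
        out = grow_chain(env, 3, np.random.default_rng(0))
        assert isinstance(out, DeadEnd) and out.step == 1

    def test_rejects_too_short_chain(self, free_env_small):
        with pytest.raises(ValueError):
            grow_chain(free_env_small, 1, np.random.default_rng(0))


class TestEnumeration:
    def test_free_counts_match_coordination_arithmetic(self, free_env_small):
        assert enumerate_exact(free_env_small, 3) == [24, 24 * 23]

    def test_flat_anchored_first_shell_is_16(self, flat_anchored_env):
        assert enumerate_exact(flat_anchored_env, 2) == [16]

    def test_guards_combinatorial_blowup(self, free_env_small):
        with pytest.raises(ValueError):
            enumerate_exact(free_env_small, 6)


class TestEnsembleSampling:
    def test_same_seed_gives_identical_streams(self, free_env_small):
        a = sample_ensemble(free_env_small, 8, 200, seed=42)
        b = sample_ensemble(free_env_small, 8, 200, seed=42)
        assert np.array_equal(a.k, b.k)

    def test_different_seeds_differ(self, free_env_small):
        a = sample_ensemble(free_env_small, 8, 200, seed=1)
        b = sample_ensemble(free_env_small, 8, 200, seed=2)
        assert not np.array_equal(a.k, b.k)

    def test_rejects_empty_request(self, free_env_small):
        with pytest.raises(ValueError):
            sample_ensemble(free_env_small, 8, 0, seed=0)

    def test_self_avoidance_and_bond_validity(self, free_env_small, moves):
        stats = sample_ensemble(free_env_small, 12, 300, seed=3, store_sites=True)
        move_set = set(moves.vectors)
        for rec in stats.records():
            assert len(set(rec.sites)) == len(rec.sites)
            for a, b in zip(rec.sites, rec.sites[1:]):
                assert tuple(np.subtract(b, a)) in move_set

    def test_anchored_chains_never_enter_solid(self, moves):
        env = small_anchored_env(field_z0=3)
        stats = sample_ensemble(env, 10, 300, seed=4, store_sites=True)
        floor = int(env.heights[0, 0])
        assert int(stats.sites[..., 2].min()) >= floor

    def test_both_growth_paths_match_exact_second_step_mean(self, flat_anchored_env):
        # Exact oracle: from one unit above a flat wall, 8 of the 16 first
        # moves stay near the wall (15 continuations) and 8 rise clear of
        # it (23 continuations), so E[k_2] = 19 exactly.  Both the compiled
        # kernel and the pure-Python grower must reproduce it.
        start = flat_anchored_env.start
        opts = free_sites(flat_anchored_env, {start}, start)
        exact = np.mean(
            [len(free_sites(flat_anchored_env, {start, s}, s)) for s in opts]
        )
        assert exact == 19.0
        n = 20000
        stats = sample_ensemble(flat_anchored_env, 3, n, seed=5)
        se = stats.k[:, 1].std() / np.sqrt(n)
        assert abs(stats.k[:, 1].mean() - exact) < 4 * se
        rng = np.random.default_rng(6)
        ks = [grow_chain(flat_anchored_env, 3, rng).k[1] for _ in range(8000)]
        assert abs(np.mean(ks) - exact) < 4 * np.std(ks) / np.sqrt(len(ks))

    def test_abort_on_pathological_dead_end_rate(self):
        # A deep one-column well dead-ends every chain.
        z = np.full((41, 41), 9, dtype=np.int32)
        z[20, 20] = 0
        field = HeightField(z=z, L=41)
        from graftropy.surfaces import AnchorSpec
        from graftropy.sampling import anchored_environment

        env = anchored_environment(
            field,
            AnchorSpec(mode="min", region=((0, 40), (0, 40)), site=(20, 20, 1)),
            LatticeConfig(box_edge=41),
        )
        with pytest.raises(RuntimeError, match="dead-end"):
            sample_ensemble(env, 5, 500, seed=0)

    def test_unbiased_weighted_counts_reproduce_enumeration(self, free_env_small):
        # Rosenbluth weights make mean(prod k) estimate the SAW count.
        n = 20000
        target = enumerate_exact(free_env_small, 4)[-1]
        stats = sample_ensemble(free_env_small, 4, n, seed=7)
        weights = stats.k.astype(float).prod(axis=1)
        est, se = weights.mean(), weights.std() / np.sqrt(n)
        assert abs(est - target) < 3 * se + 1e-9


class TestEnvironmentContracts:
    def test_blocked_start_rejected(self):
        z = np.full((41, 41), 5, dtype=np.int32)
        field = HeightField(z=z, L=41)
        cfg = LatticeConfig(box_edge=41)
        with pytest.raises(ValueError, match="solid"):
            Environment(lattice=cfg, heights=z, start=(20, 20, 2))

    def test_heights_must_match_box(self):
        cfg = LatticeConfig(box_edge=41)
        with pytest.raises(ValueError):
            Environment(lattice=cfg, heights=np.zeros((5, 5), dtype=np.int32), start=(2, 2, 1))
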