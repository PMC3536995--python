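import numpy as np
import pytest

from graftropy import (
    generate_rmd,
    generate_ugm,
    is_blocked,
    read_heightfield,
    reduce_surface,
    select_anchor,
    write_heightfield,
)
from graftropy.roughness import altitude_std, fractal_dimension
from graftropy.surfaces import HeightField, anchor_region


class TestUncorrelatedGaussian:
    def test_zero_sigma_gives_flat_plane(self):
        field = generate_ugm(16, z0=5, sigma=0.0, seed=0)
        assert np.all(field.z == 5)

    def test_same_seed_reproduces_grid(self):
        a = generate_ugm(32, 0, 1.0, seed=9)
        b = generate_ugm(32, 0, 1.0, seed=9)
        assert np.array_equal(a.z, b.z)

    def test_integer_truncation_shrinks_spread(self):
        # Truncation toward zero maps (-1, 1) to 0; for sigma = 1 the
        # altitude SD drops to ~0.684 (1-D Monte Carlo oracle, >=4e6 draws).
        field = generate_ugm(1024, z0=0, sigma=1.0, seed=3)
        assert 0.6 < altitude_std(field) < 1.0
        assert altitude_std(field) == pytest.approx(0.684, abs=0.02)

    def test_cells_are_uncorrelated_at_lag_one(self):
        field = generate_ugm(1024, z0=0, sigma=1.0, seed=4)
        z = field.z.astype(float) - field.z.mean()
        r = (z[:-1] * z[1:]).mean() / (z**2).mean()
        assert abs(r) < 0.01

    def test_literal_single_uniform_variant_is_deterministic_and_rough(self):
        a = generate_ugm(64, 0, 1.0, seed=5, literal_single_uniform=True)
        b = generate_ugm(64, 0, 1.0, seed=5, literal_single_uniform=True)
        assert np.array_equal(a.z, b.z)
        assert altitude_std(a) > 0

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_ugm(0, 0, 1.0, 0)
        with pytest.raises(ValueError):
            generate_ugm(8, 0, -1.0, 0)


class TestMidpointDisplacement:
    def test_deterministic_given_seed(self):
        a = generate_rmd(64, 0, 0.5, 1.0, seed=2)
        b = generate_rmd(64, 0, 0.5, 1.0, seed=2)
        assert np.array_equal(a.z, b.z)

    def test_vanishing_amplitude_gives_flat_integer_field(self):
        field = generate_rmd(64, 7, 0.5, 1e-9, seed=1)
        assert np.all(field.z == 7)
        assert fractal_dimension(field) == 2.0

    def test_rescale_option_controls_empirical_sd(self):
        field = generate_rmd(256, 300, 0.5, 1.0, seed=6, rescale_to=4.0)
        assert altitude_std(field) == pytest.approx(4.0, abs=0.25)

    def test_larger_hurst_is_smoother(self):
        d_rough = np.mean(
            [fractal_dimension(generate_rmd(256, 300, 0.2, 1.0, seed=s)) for s in range(3)]
        )
        d_smooth = np.mean(
            [fractal_dimension(generate_rmd(256, 300, 1.5, 1.0, seed=s)) for s in range(3)]
        )
        assert d_rough > d_smooth

    def test_sigma_increases_roughness_monotonically(self):
        # D_F grows with the displacement amplitude over {0.4, 1, 3, 10}.
        means = []
        for sigma in (0.4, 1.0, 3.0, 10.0):
            vals = [
                fractal_dimension(generate_rmd(256, 300, 0.5, sigma, seed=s))
                for s in range(5)
            ]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_rejects_non_power_of_two_and_bad_sigma(self):
        with pytest.raises(ValueError):
            generate_rmd(100, 0, 0.5, 1.0, 0)
        with pytest.raises(ValueError):
            generate_rmd(64, 0, 0.5, 0.0, 0)


class TestAnchorSelection:
    def test_flat_field_any_mode_sits_one_above_plane(self):
        field = HeightField(z=np.full((64, 64), 3, dtype=np.int32), L=64)
        for mode in ("min", "max", "mean", "random"):
            spec = select_anchor(field, mode, seed=1)
            x, y, z = spec.site
            assert z == 4
            (x0, x1), (y0, y1) = spec.region
            assert x0 <= x <= x1 and y0 <= y <= y1

    def test_max_mode_finds_unique_peak(self):
        field = HeightField(z=np.zeros((64, 64), dtype=np.int32), L=64)
        (x0, x1), _ = anchor_region(64)
        field.z[x0 + 2, x0 + 3] = 9
        spec = select_anchor(field, "max", seed=0)
        assert spec.site == (x0 + 2, x0 + 3, 10)

    def test_mean_mode_picks_altitude_nearest_global_mean(self):
        # One cell at 10 among zeros: the mean rounds near 0, so a
        # zero-altitude site must win.
        field = HeightField(z=np.zeros((64, 64), dtype=np.int32), L=64)
        (x0, x1), _ = anchor_region(64)
        field.z[x0 + 1, x0 + 1] = 10
        spec = select_anchor(field, "mean", seed=0)
        assert spec.site[2] == 1

    def test_region_scales_with_parent_size(self):
        assert anchor_region(1024) == ((301, 723), (301, 723))


class TestReduction:
    def test_window_centred_on_anchor(self):
        field = generate_ugm(128, 0, 1.0, seed=8)
        spec = select_anchor(field, "max", seed=0)
        window, local = reduce_surface(field, spec, 65)
        assert window.L == 65
        lx, ly, lz = local.site
        assert (lx, ly) == (32, 32)
        assert window.z[lx, ly] == lz - 1

    def test_identity_crop(self):
        field = generate_ugm(64, 0, 1.0, seed=8)
        spec = select_anchor(field, "mean", seed=0)
        window, local = reduce_surface(field, spec, 64)
        assert np.array_equal(window.z, field.z)

    def test_corner_anchor_window_clamped_inside_parent(self):
        field = HeightField(z=np.zeros((64, 64), dtype=np.int32), L=64)
        from graftropy.surfaces import AnchorSpec

        spec = AnchorSpec(mode="random", region=((0, 63), (0, 63)), site=(1, 1, 1))
        window, local = reduce_surface(field, spec, 33)
        assert window.L == 33
        assert local.site[:2] == (1, 1)  # clamped: window starts at parent corner

    def test_rejects_oversized_box(self):
        field = HeightField(z=np.zeros((16, 16), dtype=np.int32), L=16)
        from graftropy.surfaces import AnchorSpec

        spec = AnchorSpec(mode="mean", region=((0, 15), (0, 15)), site=(8, 8, 1))
        with pytest.raises(ValueError):
            reduce_surface(field, spec, 33)


class TestBlocking:
    def test_strict_inequality_at_surface_level(self):
        field = HeightField(z=np.zeros((8, 8), dtype=np.int32), L=8)
        assert not is_blocked(field, (3, 3, 0))
        assert is_blocked(field, (3, 3, -1))

    def test_blocked_count_per_column_equals_altitude(self):
        field = HeightField(
            z=np.arange(16, dtype=np.int32).reshape(4, 4), L=4
        )
        for x in range(4):
            for y in range(4):
                blocked = sum(is_blocked(field, (x, y, z)) for z in range(20))
                assert blocked == int(field.z[x, y])

    def test_exactly_16_of_24_moves_free_above_plane(self, moves):
        # Enumerate the (023) vectors against the half-space z < 0 from a
        # start site one unit above the plane: the 8 moves with dz in
        # {-2, -3} land inside the solid.
        field = HeightField(z=np.zeros((64, 64), dtype=np.int32), L=64)
        start = (32, 32, 1)
        free = [
            v
            for v in moves.vectors
            if not is_blocked(field, (start[0] + v[0], start[1] + v[1], start[2] + v[2]))
        ]
        assert len(free) == 16


class TestGridFileFormat:
    def test_round_trip_exact(self, tmp_path):
        field = generate_rmd(32, 5, 0.7, 2.0, seed=13)
        path = tmp_path / "grid.txt"
        write_heightfield(field, path)
        back = read_heightfield(path)
        assert np.array_equal(back.z, field.z)
        assert back.meta["type"] == field.meta["type"]
        assert back.meta["H"] == pytest.approx(0.7)
        assert back.meta["seed"] == 13
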