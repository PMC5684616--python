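"""Coupled simulation: seeding geometry, growth dynamics, area metrics."""

import numpy as np
import pytest

from gbspheroid.lattice import Phenotype
from gbspheroid.simulate import (
    SimulationConfig,
    equivalent_radius,
    measure_area,
    run,
    seed_spheroid,
)


class TestConfig:
    def test_grid_side_is_floor_of_length_over_cell_size(self):
        assert SimulationConfig(cell_size_um=18.0).n == 277
        assert SimulationConfig(cell_size_um=14.0).n == 357
        assert SimulationConfig(cell_size_um=20.0).n == 250

    def test_step_count(self):
        assert SimulationConfig(duration_days=10.0, tau_h=8.0).n_steps == 30

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(tau_h=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(L_mm=0.1, cell_size_um=20.0, initial_cells=625)
        with pytest.raises(ValueError):
            SimulationConfig(
                phenotypes=(Phenotype(0, 24.0), Phenotype(1, 30.0)),
                frequencies=(0.7, 0.7),
            )


class TestSeeding:
    def test_625_cells_form_compact_centered_disc(self):
        cfg = SimulationConfig()
        grid = seed_spheroid(cfg, np.random.default_rng(0))
        assert grid.n_cells == 625
        live = grid.live_indices()
        center = (cfg.n - 1) / 2
        d = np.hypot(grid.row[live] - center, grid.col[live] - center)
        # rasterized disc of 625 sites has radius ~ sqrt(625/pi) ~ 14.1
        assert d.max() == pytest.approx(np.sqrt(625 / np.pi), abs=1.0)

    def test_single_cell_lands_at_center(self):
        cfg = SimulationConfig(L_mm=0.126, cell_size_um=18.0, initial_cells=1)
        grid = seed_spheroid(cfg, np.random.default_rng(0))  # n = 7
        assert grid.site_of(grid.live_indices()[0]) == (3, 3)

    def test_monoclonal_seeding_uses_the_single_phenotype(self):
        cfg = SimulationConfig(phenotypes=(Phenotype(5, 24.0, 2),))
        grid = seed_spheroid(cfg, np.random.default_rng(0))
        assert set(grid.phen[grid.live_indices()]) == {5}

    def test_initial_ages_below_doubling_time(self):
        cfg = SimulationConfig()
        grid = seed_spheroid(cfg, np.random.default_rng(0))
        ages = grid.age_h[grid.live_indices()]
        assert (ages >= 0).all() and (ages < 25.5).all()

    def test_zero_age_mode(self):
        cfg = SimulationConfig(initial_age_mode="zero")
        grid = seed_spheroid(cfg, np.random.default_rng(0))
        assert (grid.age_h[grid.live_indices()] == 0).all()


class TestAreaMetrics:
    def test_site_count_area_arithmetic(self):
        cfg = SimulationConfig(cell_size_um=18.0)
        grid = seed_spheroid(cfg, np.random.default_rng(0))
        assert measure_area(grid) == pytest.approx(625 * 0.018**2)  # 0.2025 mm^2

    def test_empty_grid_has_zero_area(self):
        cfg = SimulationConfig(initial_cells=0)
        grid = seed_spheroid(cfg, np.random.default_rng(0))
        assert measure_area(grid) == 0.0
        assert measure_area(grid, "convex_hull") == 0.0

    def test_hull_area_bounds_site_count_area(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            cfg = SimulationConfig(
                L_mm=0.9, cell_size_um=18.0, initial_cells=int(rng.integers(1, 400))
            )
            grid = seed_spheroid(cfg, rng)
            assert measure_area(grid, "convex_hull") >= measure_area(grid) - 1e-12

    @pytest.mark.parametrize(
        "area,expected",
        [(0.0, 0.0), (np.pi, 1000.0), (0.2025, 253.885)],
    )
    def test_equivalent_radius(self, area, expected):
        assert equivalent_radius(area) == pytest.approx(expected, abs=1e-2)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            equivalent_radius(-1.0)


class TestRun:
    def test_unconstrained_growth_doubles_every_step(self):
        # single cell, dt = tau: 1 -> 2 -> 4 -> 8 before any contact inhibition
        cfg = SimulationConfig(
            L_mm=0.45, cell_size_um=18.0, tau_h=8.0,
            duration_days=1.0, initial_cells=1,
            phenotypes=(Phenotype(0, 8.0, 3),),
        )
        rec = run(cfg)
        assert rec.total_cells[:4].tolist() == [1, 2, 4, 8]

    def test_empty_start_stays_flat_zero(self):
        cfg = SimulationConfig(L_mm=0.45, initial_cells=0, duration_days=1.0)
        rec = run(cfg)
        assert (rec.total_cells == 0).all() and (rec.area_mm2 == 0).all()
        assert len(rec.time_days) == cfg.n_steps + 1

    def test_identical_seed_gives_bit_identical_record(self, small_config):
        a, b = run(small_config), run(small_config)
        np.testing.assert_array_equal(a.area_mm2, b.area_mm2)
        np.testing.assert_array_equal(a.total_cells, b.total_cells)
        np.testing.assert_array_equal(a.quiescent_cells, b.quiescent_cells)
        for pid in a.phenotype_counts:
            np.testing.assert_array_equal(
                a.phenotype_counts[pid], b.phenotype_counts[pid]
            )

    def test_different_seed_gives_different_trajectory(self, small_config):
        a = run(small_config)
        b = run(small_config.with_(seed=small_config.seed + 1))
        assert not np.array_equal(a.total_cells, b.total_cells)

    def test_growth_monotone_without_death(self, small_config):
        rec = run(small_config)
        assert (np.diff(rec.total_cells) >= 0).all()
        assert (np.diff(rec.area_mm2) >= -1e-15).all()

    def test_births_bounded_by_cycling_population(self, small_config):
        rec = run(small_config)
        births = np.diff(rec.total_cells)
        cycling = (rec.total_cells - rec.quiescent_cells)[:-1]
        assert (births <= cycling).all()

    def test_sealed_box_freezes_population(self):
        # full grid: nobody can divide, everyone ends up quiescent
        cfg = SimulationConfig(
            L_mm=0.126, cell_size_um=18.0, initial_cells=49,
            duration_days=2.0, phenotypes=(Phenotype(0, 8.0, 2),),
        )
        rec = run(cfg)
        assert (rec.total_cells == 49).all()
        assert rec.quiescent_cells[-1] == 49

    def test_per_phenotype_counts_sum_to_total(self):
        cfg = SimulationConfig(
            L_mm=1.0, cell_size_um=18.0, initial_cells=60, duration_days=3.0,
            phenotypes=(Phenotype(0, 20.0, 2), Phenotype(1, 30.0, 2)),
            seed=3,
        )
        rec = run(cfg)
        total = sum(rec.phenotype_counts.values())
        np.testing.assert_array_equal(total, rec.total_cells)

    def test_hypoxic_death_removes_cells(self):
        # brutal consumption with a lethal threshold: the interior dies
        from gbspheroid.oxygen import OxygenParams

        cfg = SimulationConfig(
            L_mm=1.0, cell_size_um=18.0, initial_cells=300, duration_days=2.0,
            oxygen=OxygenParams(o_deadly=0.5, kappa_star_override=50.0),
            seed=1,
        )
        rec = run(cfg)
        assert rec.total_cells[-1] < 300

    def test_record_frame_shape(self, small_config):
        df = run(small_config).to_frame()
        assert len(df) == (small_config.n_steps + 1)
        assert {"time_days", "area_mm2", "total_cells", "quiescent_cells",
                "phenotype_id", "phenotype_count"} <= set(df.columns)
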