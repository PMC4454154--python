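import numpy as np
import pytest

from evapkmc import (
    CellKind,
    HeightMap,
    HoleHistogram,
    detect_dual_scale,
    hole_histogram,
    label_components,
    label_grains,
    log_bins,
    make_fixture,
    project_height,
)

from conftest import flood_fill_label, make_film, partition_signature


class TestProjectHeight:
    def test_empty_state_all_zero(self):
        hmap = project_height(make_film(fill=CellKind.VAPOR))
        assert np.all(hmap.grid == 0)

    def test_single_particle(self):
        state = make_film(D=8, H=4, fill=CellKind.VAPOR)
        state.grid[3, 5, 2] = CellKind.PARTICLE
        hmap = project_height(state)
        assert hmap.grid[3, 5] == 1
        assert hmap.grid.sum() == 1

    def test_stacked_column(self):
        state = make_film(D=8, H=4, fill=CellKind.VAPOR)
        state.grid[2, 2, 1:4] = CellKind.PARTICLE
        assert project_height(state).grid[2, 2] == 3

    def test_sum_equals_particle_count(self):
        from evapkmc import build_initial_state

        state = build_initial_state(16, 0.25, 0.1, seed=0)
        hmap = project_height(state)
        assert hmap.grid.sum() == state.particle_count


class TestLabelGrains:
    def test_diagonal_touching_depends_on_connectivity(self):
        g = np.zeros((8, 8), dtype=int)
        g[2, 2] = g[3, 3] = 1
        hmap = HeightMap(g)
        assert label_grains(hmap, connectivity=8).count == 1
        assert label_grains(hmap, connectivity=4).count == 2

    def test_two_blobs_statistics(self):
        table = label_grains(make_fixture("two_blobs", 8))
        assert table.count == 2
        s = table.summary
        assert s["mean_area"] == pytest.approx(4.0)
        assert s["std_area"] == pytest.approx(0.0)
        assert s["min_area"] == s["max_area"] == 4

    def test_seam_grain_periodic_vs_image_mode(self):
        hmap = make_fixture("seam_grain", 8)
        assert label_grains(hmap, periodic=True).count == 1
        assert label_grains(hmap, periodic=False).count == 2

    def test_checkerboard_grain_count(self):
        hmap = make_fixture("checkerboard", 8)
        assert label_grains(hmap, connectivity=4, periodic=False).count == 32

    def test_min_area_filter(self):
        hmap = make_fixture("two_blobs", 8)
        assert label_grains(hmap, min_area_cells=5).count == 0
        assert label_grains(hmap, min_area_cells=4).count == 2

    def test_filter_monotone_in_min_area(self):
        rng = np.random.default_rng(0)
        hmap = HeightMap((rng.random((32, 32)) < 0.45).astype(int))
        counts = [
            label_grains(hmap, min_area_cells=m).count for m in range(0, 12)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_pattern_gives_empty_table(self):
        table = label_grains(HeightMap(np.zeros((8, 8), dtype=int)))
        assert table.count == 0
        assert table.summary["count"] == 0

    def test_max_height_column(self):
        g = np.zeros((8, 8), dtype=int)
        g[1:3, 1:3] = [[1, 2], [3, 1]]
        table = label_grains(HeightMap(g))
        assert table.table["max_height"].tolist() == [3]

    def test_physical_area_scales_with_cell_size_squared(self):
        g = make_fixture("two_blobs", 8).grid
        for cs in (9.765625, 19.53125):  # 2.5um/256px and twice that
            s = label_grains(HeightMap(g, cell_size=cs)).summary
            assert s["mean_area_nm2"] == pytest.approx(4 * cs**2)


class TestLabelingOracle:
    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("periodic", [False, True])
    def test_matches_brute_force_flood_fill(self, connectivity, periodic):
        rng = np.random.default_rng(connectivity * 10 + periodic)
        for density in (0.2, 0.5, 0.8):
            for _ in range(40):
                mask = rng.random((16, 16)) < density
                labels, n = label_components(mask, connectivity, periodic)
                ref_labels, ref_n = flood_fill_label(mask, connectivity, periodic)
                assert n == ref_n
                assert partition_signature(labels) == partition_signature(
                    ref_labels
                )


class TestHoleHistogram:
    def test_known_hole_areas(self):
        hmap = make_fixture("holes_mix", 16)
        hist = hole_histogram(hmap, bin_edges=[1, 10, 30, 100])
        assert hist.hole_areas.tolist() == [2, 2, 3, 40]
        assert hist.total_area.tolist() == [7.0, 0.0, 40.0]
        assert hist.gap_ranges == [(10.0, 30.0)]

    def test_fully_covered_map(self):
        hmap = HeightMap(np.ones((8, 8), dtype=int))
        hist = hole_histogram(hmap, bin_edges=[1, 10, 100])
        assert np.all(hist.total_area == 0)
        assert hist.gap_ranges == []

    def test_mass_accounting(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            hmap = HeightMap((rng.random((16, 16)) < 0.5).astype(int))
            grains = label_grains(hmap, min_area_cells=0)
            holes = hole_histogram(hmap, bin_edges=[1, 16 * 16 + 1])
            grain_area = grains.table["area_cells"].sum()
            assert grain_area + holes.hole_areas.sum() == 16 * 16

    def test_complementary_connectivity(self):
        # single diagonal line of occupied cells: with 8-connected grains the
        # two background triangles are separate 4-connected holes
        g = np.eye(8, dtype=int)
        hmap = HeightMap(g)
        h8 = hole_histogram(hmap, bin_edges=[1, 100], connectivity=8,
                            periodic=False)
        h4 = hole_histogram(hmap, bin_edges=[1, 100], connectivity=4,
                            periodic=False)
        assert len(h8.hole_areas) == 2
        assert len(h4.hole_areas) == 1

    def test_bad_bin_edges_rejected(self):
        hmap = make_fixture("holes_mix", 16)
        with pytest.raises(ValueError):
            hole_histogram(hmap, bin_edges=[10, 10, 30])

    def test_log_bins_shape(self):
        edges = log_bins(1e4, 12)
        assert len(edges) == 13
        assert np.all(np.diff(edges) > 0)


class TestDetectDualScale:
    def test_gap_with_balanced_sides(self):
        hist = HoleHistogram(np.array([1, 10, 30, 100.0]),
                             np.array([7.0, 0.0, 40.0]))
        assert detect_dual_scale(hist)

    def test_single_occupied_bin(self):
        hist = HoleHistogram(np.array([1, 10.0]), np.array([5.0]))
        assert not detect_dual_scale(hist)

    def test_minor_side_below_threshold(self):
        hist = HoleHistogram(np.array([1, 10, 30, 100.0]),
                             np.array([100.0, 0.0, 1.0]))
        assert not detect_dual_scale(hist, min_fraction=0.05)
        assert detect_dual_scale(hist, min_fraction=0.005)

    def test_empty_histogram(self):
        hist = HoleHistogram(np.array([1, 10.0]), np.array([0.0]))
        assert not detect_dual_scale(hist)


class TestHeightMapIO:
    def test_text_round_trip(self, tmp_path):
        hmap = make_fixture("holes_mix", 16)
        path = tmp_path / "map.txt"
        hmap.to_text(path)
        back = HeightMap.from_text(path)
        assert np.array_equal(back.grid, hmap.grid)

    def test_pgm_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        hmap = HeightMap(rng.integers(0, 256, size=(16, 16)))
        path = tmp_path / "map.pgm"
        hmap.to_pgm(path)
        back = HeightMap.from_pgm(path)
        assert np.array_equal(back.grid, hmap.grid)

    def test_pgm_rejects_tall_columns(self, tmp_path):
        hmap = HeightMap(np.full((8, 8), 300))
        with pytest.raises(ValueError):
            hmap.to_pgm(tmp_path / "map.pgm")

    def test_snapshot_projection(self, tmp_path):
        from evapkmc import build_initial_state, save_snapshot

        state = build_initial_state(8, 0.5, 0.2, seed=3)
        path = tmp_path / "snap.h5"
        save_snapshot(state, path)
        hmap = HeightMap.from_snapshot(path)
        assert np.array_equal(hmap.grid, project_height(state).grid)

    def test_negative_heights_rejected(self):
        with pytest.raises(ValueError):
            HeightMap(np.array([[-1, 0], [0, 0]]))
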