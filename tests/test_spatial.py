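import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from tp53tme.spatial import (
    SpatialError,
    assign_regions,
    find_neighbors,
    grid_partition,
    neighborhood_composition,
    neighbors_brute_force,
    region_abundance,
)


def _cells(xy, phenotypes=None, radius=0.0, roi="r1", group="low"):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame(
        {
            "roi_id": roi,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "phenotype": phenotypes or ["other"] * len(xy),
            "radius": radius,
            "patient_group": group,
        }
    )


class TestGridPartition:
    def test_default_is_400_blocks_of_50um(self):
        grid = grid_partition(1000.0, 400)
        assert grid.n_blocks == 400
        assert grid.block_side == pytest.approx(50.0)

    def test_corner_mapping(self):
        grid = grid_partition(1000.0, 400)
        assert grid.block_of(0.0, 0.0) == 1
        assert grid.block_of(999.9, 999.9) == 400
        assert grid.block_of(1000.0, 1000.0) == 400  # outer edge closed

    def test_partition_property_random_points(self):
        grid = grid_partition(1000.0, 400)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, size=(10_000, 2))
        blocks = grid.block_of(pts[:, 0], pts[:, 1])
        assert blocks.min() >= 1 and blocks.max() <= 400
        # block membership agrees with the block rectangles
        for idx in np.unique(blocks)[:20]:
            x0, y0, x1, y1 = grid.block_rect(int(idx))
            sub = pts[blocks == idx]
            assert (sub[:, 0] >= x0).all() and (sub[:, 0] < x1 + 1e-9).all()
            assert (sub[:, 1] >= y0).all() and (sub[:, 1] < y1 + 1e-9).all()

    def test_block_areas_tile_roi(self):
        grid = grid_partition(1000.0, 400)
        total = sum(
            (r[2] - r[0]) * (r[3] - r[1])
            for r in (grid.block_rect(i) for i in range(1, 401))
        )
        assert total == pytest.approx(1000.0 ** 2)

    def test_non_square_block_count_raises(self):
        with pytest.raises(SpatialError, match="perfect square"):
            grid_partition(1000.0, 300)


class TestAssignRegions:
    def _mask(self, overrides=None):
        mask = pd.DataFrame(
            {"roi_id": "r1", "block_index": np.arange(1, 401), "region": "stroma"}
        )
        for idx, region in (overrides or {}).items():
            mask.loc[mask["block_index"] == idx, "region"] = region
        return mask

    def test_region_lookup_and_locality(self):
        cells = _cells([[25.0, 25.0], [26.0, 24.0], [975.0, 975.0]])
        mask = self._mask({1: "boundary"})
        out = assign_regions(cells, mask)
        assert out["region"].tolist() == ["boundary", "boundary", "stroma"]
        # relabeling block 400 flips exactly the cell inside it
        out2 = assign_regions(cells, self._mask({1: "boundary", 400: "tumor"}))
        assert out2["region"].tolist() == ["boundary", "boundary", "tumor"]

    def test_out_of_bounds_cell_raises(self):
        cells = _cells([[1500.0, 10.0]])
        with pytest.raises(SpatialError, match="outside ROI"):
            assign_regions(cells, self._mask())

    def test_incomplete_mask_raises(self):
        cells = _cells([[10.0, 10.0]])
        mask = self._mask().iloc[:100]
        with pytest.raises(SpatialError, match="expected 400"):
            assign_regions(cells, mask)


class TestFindNeighbors:
    def test_zero_radius_threshold(self):
        near = _cells([[0.0, 0.0], [3.9, 0.0]])
        far = _cells([[0.0, 0.0], [4.1, 0.0]])
        assert find_neighbors(near)[0] == [1]
        assert find_neighbors(far)[0] == []

    def test_membrane_gap_uses_radii(self):
        cells = _cells([[0.0, 0.0], [13.0, 0.0]], radius=5.0)
        assert find_neighbors(cells)[0] == [1]  # gap = 13 - 10 = 3 <= 4
        cells_far = _cells([[0.0, 0.0], [14.5, 0.0]], radius=5.0)
        assert find_neighbors(cells_far)[0] == []

    def test_symmetry_and_irreflexivity(self):
        rng = np.random.default_rng(1)
        cells = _cells(rng.uniform(0, 200, size=(150, 2)), radius=3.0)
        adj = find_neighbors(cells)
        for i, nbrs in adj.items():
            assert i not in nbrs
            for j in nbrs:
                assert i in adj[j]

    def test_matches_bruteforce_with_mixed_radii(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n = int(rng.integers(20, 200))
            cells = _cells(rng.uniform(0, 300, size=(n, 2)))
            cells["radius"] = rng.uniform(0, 8, size=n)
            assert find_neighbors(cells) == neighbors_brute_force(cells)

    def test_negative_margin_raises(self):
        with pytest.raises(SpatialError, match="margin"):
            find_neighbors(_cells([[0.0, 0.0]]), margin=-1.0)


class TestRegionAbundance:
    def _annotated(self, treg_low=3, treg_high=3):
        rows = []
        for group, k in (("low", treg_low), ("high", treg_high)):
            for r in range(4):
                phenos = ["Treg"] * k + ["cancer_1"] * (10 - k)
                for i, ph in enumerate(phenos):
                    rows.append(
                        {"roi_id": f"{group}{r}", "x": 1.0 * i, "y": 1.0,
                         "phenotype": ph, "patient_group": group, "region": "boundary"}
                    )
        return pd.DataFrame(rows)

    def test_proportion_computation(self):
        table, _, _ = region_abundance(self._annotated(treg_low=3), "Treg", "boundary")
        assert np.allclose(table["proportion"], 0.3)

    def test_identical_groups_p_one(self):
        _, stat, p = region_abundance(self._annotated(3, 3), "Treg", "boundary")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_unknown_phenotype_raises(self):
        with pytest.raises(SpatialError, match="palette"):
            region_abundance(self._annotated(), "NKT", "boundary")


class TestNeighborhoodComposition:
    def test_single_center_tally(self):
        cells = _cells(
            [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [50.0, 50.0]],
            phenotypes=["Treg", "cancer_1", "cancer_1", "granulocyte", "cancer_1"],
        )
        prof = neighborhood_composition(cells, "Treg")
        counts = dict(zip(prof["neighbor_phenotype"], prof["count"]))
        assert counts == {"cancer_1": 2, "granulocyte": 1}
        assert (prof["n_centers"] == 1).all()

    def test_isolated_center(self):
        cells = _cells([[0.0, 0.0], [500.0, 500.0]], phenotypes=["Treg", "cancer_1"])
        prof = neighborhood_composition(cells, "Treg")
        assert prof["count"].sum() == 0
        assert prof["n_centers"].iloc[0] == 1

    def test_composition_conserves_center_degree(self):
        rng = np.random.default_rng(5)
        cells = _cells(
            rng.uniform(0, 100, size=(200, 2)),
            phenotypes=list(rng.choice(["Treg", "cancer_1", "granulocyte"], size=200)),
            radius=2.0,
        )
        adj = find_neighbors(cells)
        centers = cells.index[cells["phenotype"] == "Treg"]
        total_degree = sum(len(adj[c]) for c in centers)
        prof = neighborhood_composition(cells, "Treg")
        assert prof["count"].sum() == total_degree

    def test_group_without_centers_is_flagged(self):
        cells = pd.concat(
            [
                _cells([[0.0, 0.0], [1.0, 1.0]], phenotypes=["Treg", "cancer_1"], group="low"),
                _cells([[0.0, 0.0], [1.0, 1.0]], phenotypes=["cancer_1", "cancer_1"],
                       roi="r2", group="high"),
            ],
            ignore_index=True,
        )
        prof = neighborhood_composition(cells, "Treg")
        high = prof[prof["patient_group"] == "high"]
        assert (high["n_centers"] == 0).all()
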