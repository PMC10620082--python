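"""Surface fitting, cortical depth, regional statistics and proximity."""

import numpy as np
import pandas as pd
import pytest

from cortexmap import spatial as sp


class TestSurface:
    def test_horizontal_line_exact(self):
        xy = np.column_stack([np.linspace(0, 100, 20), np.zeros(20)])
        line = sp.fit_surface_line(xy)
        assert np.allclose(line.vertices[:, 1], 0.0)

    def test_jittered_line_within_jitter(self, rng):
        x = np.linspace(0, 500, 80)
        y = rng.uniform(0, 2, 80)
        line = sp.fit_surface_line(np.column_stack([x, y]))
        assert np.all(np.abs(line.vertices[:, 1]) <= 2.0)

    def test_order_invariance(self, rng):
        xy = np.column_stack([np.linspace(0, 100, 30), rng.uniform(0, 2, 30)])
        a = sp.fit_surface_line(xy)
        b = sp.fit_surface_line(xy[rng.permutation(30)])
        assert np.allclose(a.vertices, b.vertices)

    def test_too_few_cells_raise(self):
        with pytest.raises(ValueError):
            sp.fit_surface_line(np.array([[0.0, 0.0]]))


class TestDepth:
    def test_on_surface_zero(self):
        line = sp.SurfaceLine(np.array([[0.0, 0.0], [10.0, 0.0]]))
        d = sp.cortical_depth(np.array([[5.0, 0.0]]), [0], {0: line})
        assert d.depth_um[0] == 0.0

    def test_hand_computed_point_segment_distance(self):
        # point (5, 3) vs segment (0,0)-(10,0): perpendicular distance 3
        line = sp.SurfaceLine(np.array([[0.0, 0.0], [10.0, 0.0]]))
        d = sp.cortical_depth(np.array([[5.0, 3.0]]), [0], {0: line})
        assert abs(d.depth_um[0] - 3.0) < 1e-9

    def test_beyond_segment_end_uses_vertex(self):
        line = sp.SurfaceLine(np.array([[0.0, 0.0], [10.0, 0.0]]))
        d = sp.cortical_depth(np.array([[13.0, 4.0]]), [0], {0: line})
        assert abs(d.depth_um[0] - 5.0) < 1e-9  # 3-4-5 triangle to (10, 0)

    def test_max_normalized_depth_is_one(self, rng):
        line = sp.SurfaceLine(np.array([[0.0, 0.0], [100.0, 0.0]]))
        pts = np.column_stack([rng.uniform(0, 100, 200),
                               rng.uniform(0, 500, 200)])
        d = sp.cortical_depth(pts, np.zeros(200, int), {0: line})
        assert np.isclose(d.normalized_depth.max(), 1.0)
        assert (d.normalized_depth >= 0).all()

    def test_unfitted_slice_raises(self):
        line = sp.SurfaceLine(np.array([[0.0, 0.0], [10.0, 0.0]]))
        with pytest.raises(ValueError):
            sp.cortical_depth(np.array([[0.0, 0.0]]), [1], {0: line})


class TestRegionEnrichment:
    def test_equal_proportions_zero(self):
        subtype = ["a"] * 40 + ["b"] * 40
        region = (["in"] * 20 + ["out"] * 20) * 2
        enr = sp.region_enrichment(subtype, region, [0] * 80)
        assert np.allclose(enr["log2_ratio"], 0.0)

    def test_eightfold_ratio_gives_three(self):
        # subtype a: 8/10 of in-region cells, 1/10 of out-region cells
        subtype = ["a"] * 8 + ["b"] * 2 + ["a"] * 1 + ["b"] * 9
        region = ["in"] * 10 + ["out"] * 10
        enr = sp.region_enrichment(subtype, region, [0] * 20)
        assert np.isclose(enr.loc["a", "log2_ratio"], 3.0)

    def test_in_only_subtype_flagged_infinite(self):
        subtype = ["a"] * 5 + ["b"] * 5 + ["b"] * 10
        region = ["in"] * 10 + ["out"] * 10
        enr = sp.region_enrichment(subtype, region, [0] * 20)
        assert np.isposinf(enr.loc["a", "log2_ratio"])
        assert enr.loc["a", "infinite"]

    def test_single_region_raises(self):
        with pytest.raises(ValueError):
            sp.region_enrichment(["a"], ["in"], [0])


class TestRegionDEG:
    def test_exchangeable_null_no_significance(self, rng):
        X = rng.poisson(5, size=(400, 50)).astype(float)
        region = np.array(["in", "out"])[rng.integers(0, 2, 400)]
        deg = sp.region_deg(X, [f"g{i}" for i in range(50)], region)
        assert deg.significant.sum() == 0

    def test_planted_twofold_gene_detected(self, rng):
        X = rng.poisson(5, size=(1000, 30)).astype(float)
        region = np.array(["in"] * 500 + ["out"] * 500)
        X[:500, 0] = rng.poisson(10, 500)
        deg = sp.region_deg(X, [f"g{i}" for i in range(30)], region)
        assert bool(deg.loc[deg.gene == "g0", "significant"].iloc[0])
        assert deg.loc[deg.gene == "g0", "fold_change"].iloc[0] > 1.2

    def test_constant_gene_p_one(self, rng):
        X = rng.poisson(5, size=(100, 3)).astype(float)
        X[:, 1] = 7.0
        region = np.array(["in"] * 50 + ["out"] * 50)
        deg = sp.region_deg(X, list("abc"), region)
        assert deg.loc[deg.gene == "b", "p"].iloc[0] == 1.0


class TestSignature:
    def test_sets_disjoint_and_in_region_scores_higher(self, rng):
        n, g = 600, 40
        X = rng.poisson(5, size=(n, g)).astype(float)
        region = np.array(["in"] * 300 + ["out"] * 300)
        X[:300, :12] *= 3.0   # enriched in-region
        X[300:, 12:24] *= 3.0  # depleted in-region
        genes = [f"g{i}" for i in range(g)]
        deg = sp.region_deg(X, genes, region)
        score, sets = sp.signature_score(X, genes, deg)
        assert not set(sets["enriched"]) & set(sets["depleted"])
        assert len(sets["enriched"]) == 10
        assert score[:300].mean() > score[300:].mean()

    def test_few_genes_warns_and_uses_available(self, rng):
        X = rng.poisson(5, size=(400, 6)).astype(float)
        region = np.array(["in"] * 200 + ["out"] * 200)
        X[:200, 0] *= 4
        X[200:, 1] *= 4
        genes = list("abcdef")
        deg = sp.region_deg(X, genes, region)
        with pytest.warns(UserWarning, match="fewer than"):
            _, sets = sp.signature_score(X, genes, deg)
        assert sets["enriched"] == ["a"]


class TestProximity:
    def test_single_subtype_enrichment_exactly_zero(self, rng):
        xy = rng.uniform(0, 100, size=(300, 2))
        res = sp.proximity_enrichment(xy, ["a"] * 300, [0] * 300, k=10,
                                      n_shuffles=5, seed=0)
        assert np.allclose(res.enrichment.values, 0.0)  # O == E exactly

    def test_planted_blobs_within_positive_cross_negative(self, rng):
        from tests_support import blob_coordinates
        pts_list, labels_list, slices = [], [], []
        for s in range(4):
            pts, lab = blob_coordinates(rng, [(0, 0), (60, 0)], 150, scale=5)
            pts_list.append(pts)
            labels_list.append(np.where(lab == 0, "a", "b"))
            slices.append(np.full(300, s))
        res = sp.proximity_enrichment(np.vstack(pts_list),
                                      np.concatenate(labels_list),
                                      np.concatenate(slices),
                                      k=15, n_shuffles=30, seed=1)
        assert res.enrichment.loc["a", "a"] > 0
        assert res.enrichment.loc["b", "b"] > 0
        assert res.enrichment.loc["a", "b"] < 0
        assert res.qvals.loc["a", "a"] < 0.05

    def test_random_labels_small_enrichment(self, rng):
        xy = np.vstack([rng.uniform(0, 300, size=(1200, 2)) for _ in range(3)])
        slices = np.repeat(np.arange(3), 1200)
        labels = rng.choice(["a", "b", "c"], size=3600)
        res = sp.proximity_enrichment(xy, labels, slices, k=30,
                                      n_shuffles=50, seed=2)
        assert np.nanmax(np.abs(res.enrichment.values)) < 0.15

    def test_q_at_least_p(self, rng):
        xy = rng.uniform(0, 100, size=(400, 2))
        labels = rng.choice(["a", "b"], size=400)
        res = sp.proximity_enrichment(xy, labels, [0] * 400, k=10,
                                      n_shuffles=20, seed=3)
        mask = ~np.isnan(res.pvals.values)
        assert np.all(res.qvals.values[mask] >= res.pvals.values[mask] - 1e-12)

    def test_expected_invariant_to_arrangement(self, rng):
        """E depends on label counts, not on where the cells actually are."""
        labels = np.array(["a"] * 200 + ["b"] * 200)
        uniform = rng.uniform(0, 100, size=(400, 2))
        from tests_support import blob_coordinates
        blobs, _ = blob_coordinates(rng, [(0, 0), (50, 50)], 200, scale=3)
        e = []
        for xy in (uniform, blobs):
            res = sp.proximity_enrichment(xy, labels, [0] * 400, k=20,
                                          n_shuffles=100, seed=4)
            e.append(res.expected.values)
        assert np.max(np.abs(e[0] - e[1]) / np.maximum(e[0], 1)) < 0.05

    def test_parameter_validation(self, rng):
        with pytest.raises(ValueError):
            sp.proximity_enrichment(np.zeros((5, 2)), ["a"] * 5, [0] * 5, k=0)
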