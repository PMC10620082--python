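"""Generator contracts: determinism, planted structure, NB marginals."""

import numpy as np
import pytest

from cortexmap.codebook import BLANK
from cortexmap.synthetic import (ARG_PANEL_FOSB, PROJECTION_CLASSES,
                                 PainConfig, SubtypeSpec, TissueConfig,
                                 default_projection_map,
                                 default_reference_config,
                                 default_tissue_config, generate_pain_pair,
                                 generate_reference, generate_tissue,
                                 generate_traces)


def single_subtype_config(seed=0, **over):
    base = default_tissue_config(seed=seed)
    st = SubtypeSpec(name="only", major_class="excitatory",
                     layer_weights=(1.0,) * 4, markers=("Cux2",),
                     marker_fc=5.0, dispersion=8.0)
    over.setdefault("n_surface_cells_per_slice", 0)
    over.setdefault("region_effects", {})
    over.setdefault("batch_effects", {"m": 1.0})
    return TissueConfig(genes=base.genes, gene_baseline=base.gene_baseline,
                        subtypes=(st,), seed=seed, **over)


class TestTissue:
    def test_identical_seed_identical_output(self, tissue_config):
        a = generate_tissue(tissue_config)
        b = generate_tissue(tissue_config)
        assert np.array_equal(a.X, b.X)
        assert a.obs.equals(b.obs)

    def test_layer_confined_subtype_stays_in_layer(self):
        base = default_tissue_config()
        confined = SubtypeSpec(name="L1only", major_class="excitatory",
                               layer_weights=(1.0, 0.0, 0.0, 0.0),
                               markers=("Cux2",))
        other = SubtypeSpec(name="deep", major_class="excitatory",
                            layer_weights=(0.0, 1.0, 1.0, 1.0),
                            markers=("Foxp2",))
        cfg = TissueConfig(genes=base.genes, gene_baseline=base.gene_baseline,
                           subtypes=(confined, other), n_slices=2,
                           n_cells_per_slice=400, seed=5)
        a = generate_tissue(cfg)
        depths = a.obs.loc[a.obs.truth_subtype == "L1only", "y_um"]
        assert (depths < base.layer_boundaries[0]).all()

    def test_single_subtype_regions_exchangeable(self):
        cfg = single_subtype_config(seed=3, n_slices=2, n_cells_per_slice=1500)
        a = generate_tissue(cfg)
        X = np.asarray(a.X, dtype=float)
        mask = (a.obs.region == "in").to_numpy()
        diff = X[mask].mean(0) - X[~mask].mean(0)
        se = np.sqrt(X[mask].var(0) / mask.sum() + X[~mask].var(0) / (~mask).sum())
        assert np.mean(np.abs(diff) < 4 * se) > 0.95

    def test_nb_marginal_moments(self):
        """Sample mean and variance match the configured NB moments."""
        cfg = single_subtype_config(seed=4, n_slices=1, n_cells_per_slice=5000)
        a = generate_tissue(cfg)
        X = np.asarray(a.X, dtype=float)
        gi = {g: i for i, g in enumerate(cfg.genes)}
        mu = np.asarray(cfg.gene_baseline, dtype=float).copy()
        mu[gi["Cux2"]] *= 5.0
        disp = 8.0
        var = mu + mu ** 2 / disp
        n = X.shape[0]
        se_mean = np.sqrt(var / n)
        within = np.abs(X.mean(0) - mu) < 3 * se_mean
        assert within.mean() > 0.95
        assert np.all(np.abs(X.mean(0) - mu) < 6 * se_mean)
        # variance: NB 4th-moment SE is wide; check a 25% relative band
        assert np.median(np.abs(X.var(0) / var - 1)) < 0.25

    def test_surface_cells_on_pia(self, tissue):
        surf = tissue.obs[tissue.obs.truth_subtype == "VLMC"]
        assert len(surf) > 0
        assert (surf.y_um <= 2.0 + 1e-9).all()

    def test_bad_layer_boundaries_raise(self):
        base = default_tissue_config()
        with pytest.raises(ValueError):
            TissueConfig(genes=base.genes, gene_baseline=base.gene_baseline,
                         subtypes=base.subtypes,
                         layer_boundaries=(300.0, 100.0, 500.0, 800.0))

    def test_nonpositive_fold_change_raises(self):
        base = default_tissue_config()
        bad = SubtypeSpec(name="bad", major_class="excitatory",
                          layer_weights=(1, 1, 1, 1), markers=("Cux2",),
                          marker_fc=0.0)
        with pytest.raises(ValueError):
            TissueConfig(genes=base.genes, gene_baseline=base.gene_baseline,
                         subtypes=(bad,))


class TestPainPair:
    def test_null_configuration_exchangeable(self):
        tc = default_tissue_config(seed=6, n_slices=1, n_cells_per_slice=800)
        pc = PainConfig(arg_suppression=1.0, n_pairs=1, seed=6)
        sham, sni = generate_pain_pair(tc, pc)
        Xa, Xb = np.asarray(sham.X, float), np.asarray(sni.X, float)
        diff = Xa.mean(0) - Xb.mean(0)
        se = np.sqrt(Xa.var(0) / len(Xa) + Xb.var(0) / len(Xb))
        assert np.mean(np.abs(diff) < 4 * se) > 0.95

    def test_arg_suppression_halves_panel_means(self):
        tc = default_tissue_config(seed=7, n_slices=1, n_cells_per_slice=1200)
        pc = PainConfig(arg_suppression=0.5, affected_subtypes=("L5_ET_1",),
                        n_pairs=2, seed=7)
        sham, sni = generate_pain_pair(tc, pc)
        gi = {g: i for i, g in enumerate(tc.genes)}
        cols = [gi[g] for g in pc.arg_genes]
        m_sham = np.asarray(sham.X, float)[
            (sham.obs.truth_subtype == "L5_ET_1").to_numpy()][:, cols].mean()
        m_sni = np.asarray(sni.X, float)[
            (sni.obs.truth_subtype == "L5_ET_1").to_numpy()][:, cols].mean()
        assert m_sni < m_sham
        assert abs(m_sni / m_sham - 0.5) < 0.15

    def test_three_pairs_three_pair_ids(self):
        tc = default_tissue_config(seed=8, n_slices=1, n_cells_per_slice=100)
        sham, sni = generate_pain_pair(tc, PainConfig(n_pairs=3, seed=8))
        assert sham.obs.pair_id.nunique() == 3
        assert sni.obs.pair_id.nunique() == 3

    def test_unknown_subtype_raises(self):
        tc = default_tissue_config(seed=9)
        with pytest.raises(ValueError):
            generate_pain_pair(tc, PainConfig(affected_subtypes=("nope",)))

    def test_suppression_bounds(self):
        with pytest.raises(ValueError):
            PainConfig(arg_suppression=0.0)


class TestReference:
    def test_deterministic_map(self):
        cfg = default_tissue_config(seed=10)
        ref = generate_reference(cfg, seed=1, n_cells_per_subtype=20,
                                 projection_map={"L5_ET_1": "PAG"})
        sub = ref.obs[ref.obs.cluster == "L5_ET_1"]
        assert (sub.projection == "PAG").all()
        assert (ref.obs.loc[ref.obs.cluster != "L5_ET_1",
                            "projection"] == "w/o").all()

    def test_default_classes_mirror_six_targets_plus_wo(self):
        rc = default_reference_config(seed=2)
        ref = generate_reference(rc, seed=2, n_cells_per_subtype=10)
        assert set(ref.obs.projection) == set(PROJECTION_CLASSES)
        assert "w/o" in set(ref.obs.projection)

    def test_seed_reproducibility(self):
        rc = default_reference_config(seed=3)
        a = generate_reference(rc, seed=3, n_cells_per_subtype=15)
        b = generate_reference(rc, seed=3, n_cells_per_subtype=15)
        assert np.array_equal(a.X, b.X)
        assert a.obs.equals(b.obs)

    def test_empty_classes_raise(self):
        rc = default_reference_config(seed=3)
        with pytest.raises(ValueError):
            generate_reference(rc, projection_classes=(), seed=0)


class TestTraces:
    def test_noiseless_traces_equal_barcodes(self, small_codebook):
        ids = list(range(10))
        traces, truth = generate_traces(small_codebook, ids, seed=0)
        assert np.array_equal(traces, small_codebook.codewords[ids].astype(float))
        assert truth == [small_codebook.assignment[i] for i in ids]

    def test_flip_count_matches_binomial_expectation(self, small_codebook):
        n = 3000
        ids = [0] * n
        p = 1 / 24
        traces, _ = generate_traces(small_codebook, ids, flip_prob_10=p,
                                    flip_prob_01=p, seed=1)
        flips = np.abs(traces - small_codebook.codewords[0]).sum(axis=1)
        # 24 bits at rate 1/24 -> about one flipped bit per trace
        assert abs(flips.mean() - 1.0) < 4 * np.sqrt(1.0 / n)

    def test_rate_bounds(self, small_codebook):
        with pytest.raises(ValueError):
            generate_traces(small_codebook, [0], flip_prob_10=1.0)
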