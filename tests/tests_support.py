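"""Shared helpers for building small purpose-built synthetic tables."""

import numpy as np

from cortexmap.synthetic import (SubtypeSpec, TissueConfig,
                                 default_tissue_config, generate_tissue)


def single_subtype_tissue(seed=0, n_cells=400):
    """A tissue with one excitatory subtype (expressing the excitatory
    class markers) and no surface monolayer."""
    base = default_tissue_config()
    st = SubtypeSpec(name="only", major_class="excitatory",
                     layer_weights=(1.0,) * 4,
                     markers=tuple(base.class_markers["excitatory"]),
                     marker_fc=8.0)
    cfg = TissueConfig(genes=base.genes, gene_baseline=base.gene_baseline,
                       subtypes=(st,), n_slices=1, n_cells_per_slice=n_cells,
                       n_surface_cells_per_slice=0, region_effects={},
                       batch_effects={"m": 1.0}, class_markers=base.class_markers,
                       seed=seed)
    return generate_tissue(cfg)


def blob_coordinates(rng, centers, n_per, scale=1.0):
    """2D Gaussian blobs with integer labels."""
    pts = np.vstack([rng.normal(c, scale, size=(n_per, 2)) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels
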