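"""Synthetic tissue, reference and trace generators.

These generators emulate the statistical structure of a MERFISH study of
mouse prefrontal cortex (PFC): laminar tissue with a pial surface at
depth 0, layer-biased neuronal subtype densities, negative-binomial
probe counts with subtype marker structure, an in/out-PFC regional split
with planted expression differences, per-mouse library-size batch
effects, paired sham/SNI (spared nerve injury) conditions with
activity-regulated-gene (ARG) suppression, projection-labeled reference
cells, and noisy 24-bit intensity traces for decoding tests.

Every generator is bit-deterministic given its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

from .codebook import Codebook

EXC, INH, NON = "excitatory", "inhibitory", "non_neuronal"

#: the six subcortical projection targets plus the unlabeled class
PROJECTION_CLASSES = ("cPFC", "DS", "hypothalamus", "NAc", "PAG", "amygdala", "w/o")

#: ARG panels: the two published five-gene variants (with Fosb or with Fos)
ARG_PANEL_FOSB = ("Arc", "Junb", "Fosb", "Npas4", "Nr4a1")
ARG_PANEL_FOS = ("Arc", "Junb", "Fos", "Npas4", "Nr4a1")


@dataclass(frozen=True)
class SubtypeSpec:
    """One cell subtype: identity, laminar density and expression model."""

    name: str
    major_class: str
    layer_weights: tuple[float, ...]  # density weight per lamina, >= 0
    markers: tuple[str, ...]          # genes upregulated in this subtype
    marker_fc: float = 10.0           # multiplicative marker fold-change
    dispersion: float = 10.0          # NB size parameter (var = m + m^2/disp)


@dataclass(frozen=True)
class TissueConfig:
    """Parameters of one synthetic tissue run.

    Geometry is 2D per slice: x lateral (um), y depth (um) with y = 0 at
    the pial surface increasing inward; slices are indexed
    anterior-to-posterior and spaced ``slice_spacing`` um apart.  The
    "in-PFC" region is the contiguous x-interval
    ``[0, pfc_fraction * width_um)`` of each slice.
    """

    genes: tuple[str, ...]
    gene_baseline: tuple[float, ...]          # NB mean per gene, panel-wide
    subtypes: tuple[SubtypeSpec, ...]
    layer_boundaries: tuple[float, ...] = (100.0, 300.0, 500.0, 800.0)
    n_slices: int = 6
    slice_spacing: float = 150.0
    n_cells_per_slice: int = 800
    n_surface_cells_per_slice: int = 60
    width_um: float = 1500.0
    pfc_fraction: float = 0.4
    region_effects: dict = field(default_factory=dict)   # gene -> in-PFC factor
    batch_effects: dict = field(default_factory=lambda: {"mouse1": 1.0})
    class_markers: dict = field(default_factory=dict)    # major class -> genes
    surface_subtype: str = "VLMC"
    volume_median_um3: float = 1000.0
    volume_sigma_log: float = 0.5
    seed: int = 0

    def __post_init__(self):
        lb = np.asarray(self.layer_boundaries, dtype=float)
        if len(lb) < 1 or np.any(np.diff(lb) <= 0) or lb[0] <= 0:
            raise ValueError("layer_boundaries must be positive and strictly increasing")
        if len(self.genes) != len(self.gene_baseline):
            raise ValueError("gene_baseline must align with genes")
        n_layers = len(lb)
        for st in self.subtypes:
            if len(st.layer_weights) != n_layers:
                raise ValueError(
                    f"subtype {st.name}: {len(st.layer_weights)} layer weights "
                    f"for {n_layers} laminae")
            if min(st.layer_weights) < 0:
                raise ValueError(f"subtype {st.name}: negative density weight")
            if st.marker_fc <= 0:
                raise ValueError(f"subtype {st.name}: fold-change must be > 0")
            unknown = set(st.markers) - set(self.genes)
            if unknown:
                raise ValueError(f"subtype {st.name}: markers not in panel: {unknown}")
        for g, f in self.region_effects.items():
            if g not in self.genes:
                raise ValueError(f"region effect for unknown gene {g}")
            if f <= 0:
                raise ValueError("region-effect factors must be > 0")

    @property
    def subtype_names(self) -> list[str]:
        return [st.name for st in self.subtypes]

    @property
    def depth_max(self) -> float:
        return float(self.layer_boundaries[-1])


@dataclass(frozen=True)
class PainConfig:
    """Paired sham/SNI design with ARG suppression and planted DEGs."""

    arg_genes: tuple[str, ...] = ARG_PANEL_FOSB
    arg_suppression: float = 0.5      # multiplicative factor in (0, 1]
    affected_subtypes: tuple[str, ...] = ("L5_ET_1",)
    planted_degs: dict = field(default_factory=dict)  # subtype -> {gene: fc}
    n_pairs: int = 3                  # sham/SNI mouse pairs
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.arg_suppression <= 1):
            raise ValueError("arg_suppression must be in (0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


# ---------------------------------------------------------------------------
# default study conditions


def _default_panel():
    """The default desk-scale gene panel (name, baseline mean)."""
    class_markers = {
        EXC: ("Slc17a7", "Satb2", "Neurod6"),
        INH: ("Gad1", "Gad2", "Slc32a1"),
        NON: ("Sox9", "Hepacam", "Cldn11"),
    }
    subtype_markers = {
        "L23_IT_1": ("Cux2", "Otof", "Calb1", "Rasgrf2", "Lamp5"),
        "L5_ET_1": ("Pou3f1", "Fam84b", "Fezf2", "Bcl6", "Chrna6"),
        "L6_CT_1": ("Foxp2", "Syt6", "Tle4", "Ctgf", "Nxph4"),
        "Pvalb_1": ("Pvalb", "Tac1", "Myo5b", "Pthlh", "Moxd1"),
        "Sst_1": ("Sst", "Chodl", "Nos1", "Crh", "Pdyn"),
        "Astro_1": ("Aqp4", "Gja1", "Slc1a3", "Mlc1", "Fgfr3"),
        "Oligo_1": ("Mbp", "Mog", "Sox10", "Plp1", "Opalin"),
        "VLMC": ("Ptgds", "Slc6a13", "Dcn", "Col1a1", "Lum"),
    }
    arg_genes = sorted(set(ARG_PANEL_FOSB) | set(ARG_PANEL_FOS))
    # planted in/out-PFC expression differences, 12 genes each way
    enriched = ["Nnat", "Gria1", "Cacng8", "Kcnn3", "Kcng1", "Kcnf1",
                "Cxcl12", "Kcnmb4", "Cacna1e", "Cacna1h", "Scn3b", "Cdh13"]
    depleted = ["Scn4b", "Kcna2", "Kcnb2", "Kcnc2", "Kcnc3", "Kcnq3",
                "Kcnq5", "Kcnh7", "Kcnh5", "Abcd2", "Rorb", "Syt17"]
    filler = [f"Filler{i:02d}" for i in range(1, 25)]
    genes: list[str] = []
    for group in class_markers.values():
        genes += list(group)
    for group in subtype_markers.values():
        genes += list(group)
    genes += arg_genes + enriched + depleted + filler
    rng = np.random.default_rng(20230416)  # frozen panel baselines
    baseline = rng.uniform(0.5, 2.0, size=len(genes))
    # ARGs get a healthy baseline so suppression is measurable
    for g in arg_genes:
        baseline[genes.index(g)] = 2.0
    region_effects = {g: 2.0 for g in enriched}
    region_effects.update({g: 0.5 for g in depleted})
    return genes, baseline, class_markers, subtype_markers, region_effects


def default_tissue_config(seed: int = 0, **overrides) -> TissueConfig:
    """Default study conditions: 3 major classes x {3, 2, 2} subtypes
    plus a VLMC surface monolayer, 6 slices from 3 mice (2 each), planted
    in/out-PFC expression differences and mild library-size batch effects.
    """
    genes, baseline, class_markers, sub_markers, region_effects = _default_panel()

    def mk(name, major, weights, fc=10.0, disp=10.0):
        markers = sub_markers[name] + class_markers[major]
        return SubtypeSpec(name=name, major_class=major,
                           layer_weights=weights, markers=markers,
                           marker_fc=fc, dispersion=disp)

    subtypes = (
        mk("L23_IT_1", EXC, (1.0, 1.0, 0.05, 0.0)),
        mk("L5_ET_1", EXC, (0.0, 0.1, 1.0, 0.1)),
        mk("L6_CT_1", EXC, (0.0, 0.0, 0.1, 1.0)),
        mk("Pvalb_1", INH, (0.2, 0.8, 0.8, 0.4)),
        mk("Sst_1", INH, (0.4, 0.6, 0.6, 0.8)),
        mk("Astro_1", NON, (0.6, 0.5, 0.5, 0.5)),
        mk("Oligo_1", NON, (0.05, 0.1, 0.3, 1.0)),
    )
    cfg = dict(
        genes=tuple(genes),
        gene_baseline=tuple(float(b) for b in baseline),
        subtypes=subtypes,
        region_effects=region_effects,
        batch_effects={"mouse1": 1.0, "mouse2": 1.15, "mouse3": 0.9},
        class_markers=class_markers,
        seed=seed,
    )
    cfg.update(overrides)
    return TissueConfig(**cfg)


def surface_subtype_spec(config: TissueConfig) -> SubtypeSpec:
    """Expression model for the pial-surface monolayer cells."""
    _, _, _, sub_markers, _ = _default_panel()
    markers = tuple(m for m in sub_markers["VLMC"] if m in config.genes)
    markers = markers + tuple(m for m in config.class_markers.get(NON, ())
                              if m in config.genes)
    return SubtypeSpec(name=config.surface_subtype, major_class=NON,
                       layer_weights=(0.0,) * len(config.layer_boundaries),
                       markers=markers, marker_fc=10.0, dispersion=10.0)


# ---------------------------------------------------------------------------
# tissue generation


def _mean_matrix(config: TissueConfig, subtypes: list[SubtypeSpec]) -> np.ndarray:
    """NB mean per (subtype, gene) before region/batch factors."""
    base = np.asarray(config.gene_baseline, dtype=float)
    gi = {g: i for i, g in enumerate(config.genes)}
    mu = np.tile(base, (len(subtypes), 1))
    for s, st in enumerate(subtypes):
        for m in st.markers:
            mu[s, gi[m]] *= st.marker_fc
    return mu


def _region_factor(config: TissueConfig) -> np.ndarray:
    f = np.ones(len(config.genes))
    gi = {g: i for i, g in enumerate(config.genes)}
    for g, v in config.region_effects.items():
        f[gi[g]] = v
    return f


def _nb_sample(rng, mean, dispersion):
    mean = np.maximum(mean, 1e-12)
    return rng.negative_binomial(dispersion, dispersion / (dispersion + mean))


def generate_tissue(config: TissueConfig, *,
                    mean_adjust: dict | None = None,
                    batch_override: str | None = None,
                    condition: str = "none",
                    rng: np.random.Generator | None = None) -> ad.AnnData:
    """Simulate one tissue run.

    Cells are placed uniformly in x and depth; each cell's subtype is
    drawn with probability proportional to the subtype density weights of
    its lamina.  Counts are negative binomial with per-subtype marker
    structure, multiplied by in-PFC region factors and per-batch
    library-size factors.  A monolayer of surface-marker cells lies on
    the pial boundary (y in [0, 2] um).  Ground-truth subtype labels are
    stored in ``obs["truth_subtype"]``.

    ``mean_adjust`` maps subtype name -> per-gene multiplicative factors
    (used by :func:`generate_pain_pair` to plant condition effects).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    subtypes = list(config.subtypes) + [surface_subtype_spec(config)]
    mu0 = _mean_matrix(config, subtypes)
    if mean_adjust:
        name_to_row = {st.name: i for i, st in enumerate(subtypes)}
        for name, factors in mean_adjust.items():
            if name not in name_to_row:
                raise ValueError(f"unknown subtype in adjustment: {name}")
            mu0[name_to_row[name]] = mu0[name_to_row[name]] * np.asarray(factors)
    region_f = _region_factor(config)
    boundaries = np.asarray(config.layer_boundaries)
    weights = np.array([st.layer_weights for st in subtypes[:-1]], dtype=float)
    batches = list(config.batch_effects)
    disp = np.array([st.dispersion for st in subtypes])

    frames, counts_blocks = [], []
    for s in range(config.n_slices):
        batch = batch_override or batches[s % len(batches)]
        lib = config.batch_effects.get(batch, 1.0) if batch_override is None else 1.0
        n = config.n_cells_per_slice
        x = rng.uniform(0, config.width_um, n)
        y = rng.uniform(0, config.depth_max, n)
        layer = np.searchsorted(boundaries, y, side="right")
        layer = np.minimum(layer, len(boundaries) - 1)
        w = weights[:, layer].T  # (n, n_subtypes)
        w_sum = w.sum(axis=1, keepdims=True)
        w = np.where(w_sum > 0, w / np.maximum(w_sum, 1e-300), 1.0 / w.shape[1])
        cum = np.cumsum(w, axis=1)
        u = rng.uniform(size=n)
        st_idx = (u[:, None] < cum).argmax(axis=1)

        ns = config.n_surface_cells_per_slice
        if ns:
            xs = (np.arange(ns) + 0.5) / ns * config.width_um
            xs = xs + rng.uniform(-2, 2, ns)
            ys = rng.uniform(0, 2, ns)  # on the pia, jitter <= 2 um
            x = np.concatenate([x, xs])
            y = np.concatenate([y, ys])
            st_idx = np.concatenate([st_idx, np.full(ns, len(subtypes) - 1)])
            n += ns

        in_pfc = x < config.pfc_fraction * config.width_um
        region = np.where(in_pfc, "in", "out")
        subregion = np.where(in_pfc,
                             np.where(y < config.depth_max / 2, "PL", "ILA"),
                             "MOs")
        mu = mu0[st_idx] * np.where(in_pfc[:, None], region_f, 1.0) * lib
        counts = _nb_sample(rng, mu, disp[st_idx][:, None])
        volume = rng.lognormal(np.log(config.volume_median_um3),
                               config.volume_sigma_log, n)
        frames.append(pd.DataFrame({
            "x_um": x, "y_um": y, "volume_um3": volume,
            "slice": s, "batch": batch, "region": region,
            "subregion": subregion, "condition": condition,
            "truth_subtype": [subtypes[i].name for i in st_idx],
            "truth_major": [subtypes[i].major_class for i in st_idx],
        }))
        counts_blocks.append(counts)

    obs = pd.concat(frames, ignore_index=True)
    obs.index = pd.Index([f"cell{i:06d}" for i in range(len(obs))], name="cell_id")
    X = np.vstack(counts_blocks).astype(np.int32)
    adata = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=pd.Index(config.genes, name="gene")))
    adata.layers["counts"] = X.copy()
    adata.uns["tissue"] = {"seed": config.seed, "n_slices": config.n_slices,
                           "pfc_fraction": config.pfc_fraction}
    return adata


def generate_pain_pair(tissue_config: TissueConfig, pain_config: PainConfig,
                       ) -> tuple[ad.AnnData, ad.AnnData]:
    """Paired sham/SNI tissues differing only by the planted pain effects.

    Each of the ``n_pairs`` sham/SNI mouse pairs shares one batch label
    (the paired slices are imaged together), so condition contrasts are
    within-batch.  Under "SNI", ARG-panel means in affected subtypes are
    multiplied by ``arg_suppression`` and the per-subtype planted DEG
    fold-changes are applied.
    """
    genes = tissue_config.genes
    known = set(tissue_config.subtype_names) | {tissue_config.surface_subtype}
    missing = set(pain_config.arg_genes) - set(genes)
    if missing:
        raise ValueError(f"ARG genes not in panel: {missing}")
    for st, degs in pain_config.planted_degs.items():
        if st not in known:
            raise ValueError(f"unknown subtype in planted_degs: {st}")
        bad = set(degs) - set(genes)
        if bad:
            raise ValueError(f"planted DEGs not in panel: {bad}")
    for st in pain_config.affected_subtypes:
        if st not in known:
            raise ValueError(f"unknown affected subtype: {st}")

    gi = {g: i for i, g in enumerate(genes)}
    sni_adjust: dict[str, np.ndarray] = {}
    for st in pain_config.affected_subtypes:
        f = np.ones(len(genes))
        for g in pain_config.arg_genes:
            f[gi[g]] *= pain_config.arg_suppression
        sni_adjust[st] = f
    for st, degs in pain_config.planted_degs.items():
        f = sni_adjust.get(st, np.ones(len(genes)))
        for g, fc in degs.items():
            f[gi[g]] *= fc
        sni_adjust[st] = f

    shams, snis = [], []
    for p in range(pain_config.n_pairs):
        for cond, out in (("sham", shams), ("SNI", snis)):
            rng = np.random.default_rng(
                [tissue_config.seed, pain_config.seed, p, cond == "SNI"])
            a = generate_tissue(tissue_config, rng=rng,
                                mean_adjust=sni_adjust if cond == "SNI" else None,
                                batch_override=f"pair{p + 1}", condition=cond)
            a.obs["pair_id"] = f"pair{p + 1}"
            out.append(a)
    sham = ad.concat(shams, index_unique="-")
    sni = ad.concat(snis, index_unique="-")
    for a in (sham, sni):
        a.obs["pair_id"] = a.obs["pair_id"].astype(str)
    return sham, sni


# ---------------------------------------------------------------------------
# reference (scRNA-seq-like) cells


def default_reference_config(seed: int = 0, n_exc_subtypes: int = 7) -> TissueConfig:
    """A reference-style panel with ``n_exc_subtypes`` excitatory subtypes
    (for projection-transfer tests); geometry fields are unused there."""
    base = default_tissue_config(seed=seed)
    rng = np.random.default_rng(seed + 101)
    filler = [g for g in base.genes if g.startswith("Filler")]
    named = ["L23_IT_1", "L5_ET_1", "L6_CT_1"]
    subtypes = [st for st in base.subtypes if st.name in named]
    per = 5
    for j in range(n_exc_subtypes - len(named)):
        markers = tuple(filler[j * per:(j + 1) * per])
        if len(markers) < per:
            raise ValueError("panel too small for requested subtype count")
        subtypes.append(SubtypeSpec(
            name=f"Exc_extra_{j + 1}", major_class=EXC,
            layer_weights=tuple(rng.uniform(0.1, 1.0, len(base.layer_boundaries))),
            markers=markers + base.class_markers[EXC], marker_fc=10.0))
    return replace(base, subtypes=tuple(subtypes))


def default_projection_map(config: TissueConfig) -> dict:
    """Deterministic subtype -> projection-target map over the paper's six
    targets; subtypes beyond the sixth are left unlabeled ("w/o")."""
    exc = [st.name for st in config.subtypes if st.major_class == EXC]
    targets = [c for c in PROJECTION_CLASSES if c != "w/o"]
    return {name: targets[i] for i, name in enumerate(exc) if i < len(targets)}


def generate_reference(config: TissueConfig, projection_classes=PROJECTION_CLASSES,
                       seed: int = 0, n_cells_per_subtype: int = 150,
                       projection_map: dict | None = None) -> ad.AnnData:
    """Reference cells sharing the gene panel, with cluster labels and a
    projection label drawn from a subtype -> target map ("w/o" for
    unmapped subtypes)."""
    if not projection_classes:
        raise ValueError("projection classes must be non-empty")
    if projection_map is None:
        projection_map = default_projection_map(config)
    unknown_targets = set(projection_map.values()) - set(projection_classes)
    if unknown_targets:
        raise ValueError(f"projection targets not in classes: {unknown_targets}")
    rng = np.random.default_rng(seed)
    subtypes = list(config.subtypes)
    mu = _mean_matrix(config, subtypes)
    blocks, clusters, projections = [], [], []
    for i, st in enumerate(subtypes):
        blocks.append(_nb_sample(
            rng, np.tile(mu[i], (n_cells_per_subtype, 1)), st.dispersion))
        clusters += [st.name] * n_cells_per_subtype
        projections += [projection_map.get(st.name, "w/o")] * n_cells_per_subtype
    X = np.vstack(blocks).astype(np.int32)
    obs = pd.DataFrame({"cluster": clusters, "projection": projections})
    obs.index = pd.Index([f"ref{i:06d}" for i in range(len(obs))], name="cell_id")
    adata = ad.AnnData(X=X, obs=obs,
                       var=pd.DataFrame(index=pd.Index(config.genes, name="gene")))
    adata.layers["counts"] = X.copy()
    return adata


# ---------------------------------------------------------------------------
# bit-intensity traces


def generate_traces(codebook: Codebook, true_ids, flip_prob_10: float = 0.0,
                    flip_prob_01: float = 0.0, intensity_noise: float = 0.0,
                    seed: int = 0) -> tuple[np.ndarray, list[str]]:
    """Noisy 24-value intensity traces with known ground truth.

    Each trace starts from the true codeword, flips 1->0 bits with
    probability ``flip_prob_10`` and 0->1 bits with ``flip_prob_01``
    independently per bit, then adds Gaussian intensity noise.  Returns
    ``(traces, truth_labels)``.
    """
    for r in (flip_prob_10, flip_prob_01):
        if not (0 <= r < 1):
            raise ValueError("flip rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ids = np.asarray(true_ids, dtype=int)
    words = codebook.codewords[ids].astype(float)
    u = rng.uniform(size=words.shape)
    flipped = np.where(words == 1,
                       np.where(u < flip_prob_10, 0.0, 1.0),
                       np.where(u < flip_prob_01, 1.0, 0.0))
    traces = flipped + rng.normal(0.0, intensity_noise, size=words.shape) \
        if intensity_noise > 0 else flipped
    truth = [codebook.assignment[i] for i in ids]
    return traces, truth
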