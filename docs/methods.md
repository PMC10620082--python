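# Methods

This note documents the models, parameter choices and numerical conventions
behind `cortexmap`, and what the synthetic-data experiments do and do not
demonstrate.

## Synthetic tissue model

The generator emulates the statistical structure of a coronal MERFISH run
over laminar cortex; it is the substrate for every test in the package.

**Geometry.** Each slice is a 2D rectangle: x lateral (default width
1,500 µm), y depth with y = 0 at the pial surface increasing inward. Laminae
are depth intervals bounded at 100, 300, 500 and 800 µm. Slices are indexed
anterior→posterior and nominally 150 µm apart; all neighborhood statistics
are computed within slice, since that spacing is beyond cell-interaction
range. The "in-PFC" region is the contiguous interval x < 0.4·width of every
slice — the simplest mask that supports in/out contrasts. A monolayer of
VLMC-like surface cells is placed on y ∈ [0, 2] µm at regular x positions, so
surface-line fitting is well-posed.

**Cell sampling.** Cell positions are uniform in (x, y); the subtype of a
cell is drawn with probability proportional to the subtype's density weight
in the cell's lamina. The default panel has 3 major classes × {3, 2, 2}
subtypes (plus VLMC), each with five subtype markers at 10× fold change and
three shared class markers, over a 103-gene panel whose baselines are frozen
draws from U(0.5, 2).

**Counts.** Gene counts are negative binomial, parameterized by mean m and
dispersion θ (variance m + m²/θ, θ = 10 by default) — the standard
overdispersed model for probe counts. The mean is the panel baseline times
the subtype's marker fold change, times an in-PFC region factor (24 genes
planted at 2× or 0.5×), times a per-mouse library-size factor (1.0, 1.15,
0.9 across the three default mice). Cell volumes are lognormal with median
1,000 µm³ and σ_log = 0.5, so the [100, 4,000] µm³ filter removes a small
tail and is exercised nontrivially.

**Pain design.** Sham/SNI pairs share a batch label (paired slices imaged
together), so condition contrasts are within-batch by construction. Under
SNI, the ARG-panel means of affected subtypes are multiplied by the
suppression factor (default 0.5 in L5_ET_1) and per-subtype planted DEG fold
changes are applied; nothing else differs between the paired draws.

**What the generator does not emulate.** Optics, point-spread functions and
image stacks (traces are abstract 24-vectors); segmentation errors other
than a fixed planted doublet mechanism; continuous within-subtype expression
gradients (subtypes are exchangeable draws, so clusters are true blobs);
spatial autocorrelation of expression within a subtype; ambient RNA.
Passing tests therefore demonstrate correctness and calibration of the
statistics under a well-specified planted model — not performance on real
tissue, where cluster boundaries are gradual and the consolidation and
marker-assignment steps would need curation.

## Codebook

Barcodes are weight-4 binary words over 24 bits with minimum pairwise
Hamming distance 4; two equal-weight words satisfy the distance bound
exactly when their supports share ≤ 2 positions, which is the check used
throughout. Construction is greedy accumulation over the C(24,4) = 10,626
candidate words (lexicographic plus 19 shuffled restart orders, keeping the
largest code), followed by ruin-and-recreate refinement: drop a random ~6%
of codewords, re-greedy in a fresh order, keep the result if not smaller.
The search is deterministic given its seed.

Measured capacity: plain greedy attains ~380–390 codewords; with the default
100 refinement rounds ~430–440; long runs plateau near 470. The 476-word
goal (416 genes + 60 blanks) is therefore treated as a search target: the
attained capacity is reported and the synthetic gene panel scaled to fit
(attained − 60 genes), as the analysis scripts do.

Decoding L2-normalizes both trace and codeword and takes the nearest
codeword by Euclidean distance, scale-invariant by construction. The default
rejection threshold 0.52 accepts single-bit flips of a weight-4 word
(distance ≈ 0.518 for a 1→0 flip, ≈ 0.460 for 0→1) and rejects two-bit
errors (≥ ≈ 0.7). A trace whose binarized form differs from the matched
codeword in more than one bit is also rejected, which makes the
"corrected bits ≤ 1" contract structural rather than model-dependent.
Blanks are codewords assigned to no gene; the ratio of mean decoded events
per blank to mean events per gene is the misidentification metric, and it
decreases monotonically as the threshold tightens.

## QC and normalization

Filters: volume ∈ [100, 4,000] µm³; total counts ≥ 10 and ≤ the 98% sample
quantile of the run; ≥ 10 detected genes. The quantile is the
linear-interpolation sample quantile computed once over all cells of the run
and frozen (refiltering with the frozen value is idempotent); below 50 cells
the quantile rule is disabled as unstable. Surviving cells are scaled to a
500-count total (exactly, to float precision) and log(1+x)-transformed.
Normalization applies to passing cells only; failing cells keep raw counts
and are excluded downstream.

The doublet flag is a stand-in occupying the pipeline slot of a dedicated
doublet detector: cells are provisionally k-means clustered and scored by
the margin between the best single-centroid fit and the best two-centroid
average fit; the top 2% by score are flagged, and all-tied degenerate inputs
flag nothing. It recovers > 80% of planted centroid-average doublets but is
not a substitute for purpose-built methods on real data.

## PC selection, batch centering, clustering

Scaling uses the population (divide-by-n) standard deviation; constant genes
map to zero columns. PCA eigenvalues are those of the covariance (divide by
n). The shuffle rule permutes every gene column independently — breaking
gene–gene covariance while preserving marginals, the parallel-analysis
reading of "randomly shuffled" — ten times; PCs of the real data with
eigenvalue above the mean first shuffled eigenvalue are kept. On pure noise
this keeps ≤ 1 component ≥ 95% of the time; planted rank-3 structure keeps
≥ 3. At least 2 PCs are always carried forward so downstream geometry is
defined.

Batch correction is per-batch mean centering in PC space (grand mean
re-added): exact for additive batch shifts, identity for one batch, and a
deliberate simplification of mixture-aware methods — adequate here because
the planted batch effect is a global library-size factor.

The KNN graph connects i and j if either is among the other's k nearest
Euclidean neighbors (self excluded); distance ties break toward the lower
cell index, making the graph deterministic under duplicated points. Leiden
uses the modularity-style (RB configuration) objective at the stated
resolution with a fixed seed.

**Two rounds and consolidation.** Round 1 (k = 10, resolution 0.3) clusters
all usable cells; each cluster is assigned the major class whose marker set
has the highest mean z-score, and clusters scoring > 0.5 for two or more
marker sets are removed as doublet-like. Round 2 re-embeds each class and
subclusters at resolution 2 with k = 50/20/15 (excitatory / inhibitory /
non-neuronal). At these resolutions Leiden fragments large homogeneous
populations: a KNN graph over a blob of hundreds of cells is a locally dense
chain, and resolution 2 prefers communities smaller than the blob. Published
workflows resolve this by manual curation; here the analogue is automated:
communities are merged when the number of KNN edges between them exceeds 1%
of k times the smaller community's size, and merged groups are the connected
components of that cluster-level adjacency. On separated populations the
signal is near-binary — distinct subtypes share essentially no KNN edges
while fragments of one population share hundreds — so the 1% threshold is
uncritical. A DE-based merge rule was evaluated and rejected: splits along a
blob's noise axis create genuine conditional mean differences between the
halves (selection effect), so fragments of one population can show
"significant" DEGs with fold changes up to ~2.5. The same consolidation runs
after round 1, which also resolves the degenerate one-subtype tissue (all
marker scores ≈ 0, fragment argmax would be noise).

**Choosing k.** The bootstrap rule clusters 10 resamples of 80% of cells at
each candidate k, computes mean pairwise ARI between resample labelings on
shared cells, and returns the smallest candidate within one standard error
of the maximum stability — a conventional stability criterion adopted here
because only the use of bootstrapping, not the algorithm, is prescribed.

## Spatial statistics

The surface line is the x-sorted polyline through surface-marker centroids
(cells sharing an x are averaged; y is smoothed by a centered moving average
of window 5). Depth is the minimum point-to-segment distance over the
polyline; normalized depth divides by the maximum over the analyzed set, so
the deepest cell is exactly 1.

Regional subtype enrichment normalizes subtype counts by total cells per
region within each slice, averages the per-slice proportions across slices,
and reports log₂(in/out); subtypes absent from one region carry an infinite
sentinel with a flag, never silently dropped. Regional DEGs use the
two-sided Wilcoxon rank-sum on normalized (non-log) expression with
Bonferroni correction; fold change is the ratio of group means on the linear
scale, as "fold change > 1.2" reads. The signature score takes the top ten
enriched and top ten depleted significant genes by fold change (ties by
smaller p; the sets are disjoint by construction) and scores each cell as
the mean expression difference.

Proximity enrichment counts, per slice, how often subtype b appears among
the 30 spatial nearest neighbors of subtype-a cells, summed over slices. The
null permutes labels within slice — preserving subtype composition, the
conservative reading of "randomly assigning a subtype" — 100 times (the
default; a single-shuffle mode reproduces the literal one-shuffle
construction), and enrichment is log₂(O/E). Per-pair p-values compare the
per-slice observed counts against the pooled per-slice shuffled counts by
two-sided Wilcoxon rank-sum (the slice is the replicate unit), BH-adjusted
over pairs. With one subtype, shuffling is a no-op and enrichment is exactly
zero. E depends only on label counts, not the spatial arrangement, and under
a shuffled tissue the BH-significant fraction stays at or below nominal.

## Transfer and projection

Co-embedding restricts both tables to shared genes, z-scales the union
jointly, takes 30 PCs, and centers by dataset of origin. The correspondence
matrix pools, for each cluster of one dataset, the 30 nearest cross-dataset
neighbors of its members and tabulates cluster fractions; rows sum to 1, and
the two directional matrices are averaged. The projection classifier is an
RBF-kernel SVM with γ = 0.01 and cost 10 over the 30 PCs, trained on a 70/30
stratified split of reference cells (classes under 5 cells excluded with a
warning); performance is the macro-averaged one-vs-rest AUC, a convention
made explicit because a single published AUC does not determine the
averaging rule. Imputation is a one-round distance-weighted (1/(d+1e-9))
kNN average of reference expression — a simplified single-integration
variant of two-round schemes, labeled as such.

## Pain analysis

ARG scores z-score each panel gene over all cells pooled across conditions
(population sd; zero-variance genes contribute 0 with a warning) and average
over the panel. Two five-gene panels are supported — the default with Fosb
and a variant with Fos — because both orderings circulate; tests use the
default. Paired comparisons average scores per mouse pair and condition and
apply the two-tailed paired t-test across pairs (p = 1 by convention when
all differences are zero; effect-only reporting below 2 pairs).

The perturbation score is a simplified per-subtype separability AUC standing
in for ensemble-based perturbation rankings: 100 cells per condition are
subsampled (class-balanced), an L2-regularized logistic classifier is
3-fold cross-validated, and the held-out AUC is averaged over 10 repeats.
It is symmetric to condition relabeling and ranks the planted-effect subtype
first under the default conditions.

The LRT DEG test fits, per gene, logistic models C ~ E + S and C ~ 1 + S
(S: categorical batch indicators; E: the single gene's expression) and
refers Λ = 2(ℓ_full − ℓ_null) to chi-square with 1 df, Bonferroni-corrected
over genes tested. The null model is fit once per dataset. Perfect
separation falls back to a Newton solve with ridge 1e-4 on non-intercept
terms (the unpenalized MLE diverges there), and the gene is flagged.
Measured operating characteristics at n = 400: null type-I 0.049 at
α = 0.05 with uniform p-values, > 90% Bonferroni power for a unit log-odds
effect, and no type-I inflation from batch-only effects (the batch term
absorbs them).

## Problem sizes and numerical conventions

Default experiment sizes — ~5,200-cell tissues, 120–150 reference cells per
subtype, 50×200 null replicates for the LRT, 100 proximity shuffles — were
chosen so every statistical property is measurable with comfortable margins
on a single CPU; they are the package's study conditions, not tuning knobs.
Other conventions: all randomness flows from explicit seeds through
`numpy.random.default_rng`; eigenvalues and z-scores use divide-by-n;
Bonferroni multiplies by the number of genes tested and caps at 1; BH uses
the standard step-up procedure; infinite log-ratios are flagged sentinels;
KNN distance ties break by cell index; Leiden determinism is delegated to
its seed.

## Known limitations

- The codebook search is heuristic; it verifiably never violates the
  weight/distance invariants but does not certify maximal capacity.
- Batch centering, the doublet flag, the perturbation AUC and one-round
  imputation are deliberate simplifications of richer published tools; each
  preserves the corresponding pipeline contract, not the tool's internals.
- Connectivity consolidation assumes separated populations; on continuous
  real-tissue gradients it would under-split, and curation or a DE-aware
  criterion with selection-effect control would be needed.
- The proximity p-values treat slices as replicates; with very few slices
  the Wilcoxon granularity limits attainable significance.
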