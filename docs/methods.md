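# Methods

`emtscape` reimplements, at desk scale and against synthetic data with
planted ground truth, a single-cell analysis of epithelial-mesenchymal
plasticity (EMP) during a bifurcating epithelial-to-mesenchymal
transition (EMT): a progenitor epithelium (here, early endocardium)
passes through a hybrid state co-expressing epithelial and mesenchymal
programs before resolving into mesenchymal or endothelial termini. The
package covers simulation, QC and normalization, graph clustering,
signature scoring with dual-threshold EMP classification, trajectory
inference with branch probabilities and differentiation potential,
filtered marker calling, and correlation-based ligand-activity ranking.

## The synthetic world

Each cell carries a latent time `s ∈ [0, 1]` and a branch label: trunk
for `s < 0.5`, then mesenchymal or endocardial with configurable
fractions (default 50/50). Timepoint labels (defaults E8.25 / E9.25 /
E10.5) are overlapping windows on `s`, so consecutive embryonic stages
share latent states. The hybrid (EMP) window defaults to
`s ∈ (0.40, 0.60)` — the plasticity phase occupies roughly a fifth of
the sampled developmental axis, mirroring a transition that spans about
one embryonic day of a five-day series.

Gene programs are logistic curves in `(s, branch)`:

- **endothelial panel** — high on trunk and endocardial branch, decaying
  along the mesenchymal branch as the window resolves;
- **mesenchymal panel** — switches on entering the window (half-maximal
  at `s = 0.5`), stays high on the mesenchymal branch, resolves on the
  endocardial branch;
- **shear-response panel** — a bump confined to the window, standing in
  for the mechanosensitive transcriptional response of cells under flow;
- **epicardial panel** — basal throughout (a negative-control score axis
  for this endothelial-derived lineage);
- hidden structure genes (not in any scored panel): a progenitor program
  that decays over the early trunk, branch-specific terminal programs
  that activate at window exit, and shared smooth programs. Without the
  terminal programs a resolving branch would retrace the progenitor
  expression profile and the manifold would fold back on itself; real
  differentiated states activate their own identity genes, and so does
  the simulator.

Counts are negative binomial via gamma–Poisson: per-cell relative
intensities are scaled to a lognormal library size (mean 2000, CV 0.3,
mean-1 true size factors retained) and overdispersed with shared size
parameter `r = 10` (variance `μ + μ²/r`), a moderate droplet-data
regime. Zeros arise from the NB itself; no extra zero inflation.
Doublets are sums of two singlet count vectors, labelled, replacing the
configured tail fraction of cells. Mitochondrial content is an
independent truncated-normal covariate with an optional high-mito
low-quality subpopulation, so QC can be exercised without modelling
mitochondrial genes.

The **stalled** genotype multiplies the hybrid-window occupancy mass by
an enrichment factor `F` (the window mass becomes exactly `F·m`; the
mass outside, including the mesenchymal terminus, is scaled down to
keep a distribution — so the planted window-occupancy ratio equals `F`
exactly, and an `F·m ≥ 1` request is rejected). This emulates a
transition arrested in the hybrid state with correspondingly fewer
mesenchymal cells.

What a green test on this world does *not* establish: realistic
transcriptome-wide covariance, ambient RNA, batch chemistry, cell-cycle
structure, or the scale (50k cells, 20k genes) of real data.

## QC and normalization

Cells pass QC when detected genes strictly exceed `min_genes` and
mitochondrial fraction is strictly below `max_mito_fraction` (module
defaults 2000 and 0.20, the real-data convention; the pipeline's
synthetic default is `min_genes=50` since the simulation has 200
genes). Size factors are library sizes rescaled to mean 1 — a
documented simplification of pooled deconvolution factors that keeps
the contract (positive, mean 1, corrects depth). Normalization is
`log2(count / size_factor + 1)`. HVGs are ranked by variance of the
normalized values after removing ribosomal/mitochondrial prefixes,
Y-linked genes and Xist.

The doublet score simulates artificial doublets by summing random cell
pairs' counts, renormalizes, embeds originals and doublets in a common
PCA space, and reports (density of simulated doublets) / (density of
originals)² per cell, with density the inverse mean distance to the k
(default 20) nearest members of each set, normalized by set size. Zero
original density yields an `inf` sentinel with a warning. Scores are
reported, never used to drop cells.

## Graph, clustering, diffusion

The kNN graph is built in PCA space (Euclidean); when timepoints are
given, mutual-nearest-neighbour pairs (k_mnn = 20 per side) between
*consecutive* timepoints are added as edges — the augmentation stands in
for full augmented-affinity batch integration while keeping its stated
mechanism. Edge weights are the Jaccard index of the endpoints'
self-inclusive neighbour sets. Clustering is seeded Louvain on the
weighted graph, with community ids renumbered by their lowest member for
stable labels.

Diffusion components come from the adaptive-kernel operator: per-cell
bandwidth = distance to the ⌈k/3⌉-th neighbour,
`w_ij = exp(−d²/(σ_i σ_j))`, symmetrized, with a unit self-loop added
(keeps the chain aperiodic), row-normalized to `P`. Eigenpairs are
computed through the symmetric conjugate `D^{1/2} P D^{-1/2}`; the
trivial pair is (1, constant); nontrivial components are scaled by
`λ/(1−λ)` (the multiscale convention). `diffuse_expression` applies
`Pᵗ X` — visualization-grade smoothing only.

## Trajectory

Pseudotime is the exact single-source shortest-path distance from the
start cell over the kNN graph with edge lengths measured in
diffusion-component space. Waypoint subsampling from the reference
method is a scalability device and is replaced by exact per-cell paths.

Branch probabilities solve the absorbing Markov chain on the
pseudotime-directed graph (transition weights ∝ Jaccard edge weights;
termini absorbing; `(I − Q)B = R` solved sparsely). Two numerical
choices matter on noisy data and are off by default in the low-level
function but on in `run_trajectory`:

- `backward_scale` (default 1.0 end-to-end, 0 = strict in
  `branch_probabilities`): edges up to `backward_scale · σ_i` backward
  in pseudotime are kept, `σ_i` the standard deviation of cell i's
  neighbour pseudotime offsets. Strict forward-only edges funnel walks
  down whichever corridor happens to sit marginally ahead in estimated
  pseudotime and can make genuinely reachable termini unreachable.
- one step of diffusion smoothing of the solved probabilities (the
  per-cell interpolation step of waypoint-based methods), with terminus
  rows reset to one-hot.

Differentiation potential is the Shannon entropy (natural log) of each
cell's branch-probability row: 0 at termini, at most `ln(#termini)`.
A known property of this construction, visible in the tests: with two
termini, absorption probabilities are harmonic on the trunk, so the
trunk forms an entropy plateau whose level reflects the realized global
fate asymmetry; entropy is reliably *elevated* in the hybrid window
relative to early trunk and branches (the aggregate test), but the
identity of the individual top-entropy cells near the window boundary
is seed-dependent within the kNN resolution.

Termini are auto-detected as each cluster's pseudotime-argmax cell,
kept when it is a pseudotime local maximum over its two-hop graph
neighbourhood (one-hop maxima are too easily created by pseudotime
noise mid-branch), with explicit override always available. Gene trends
are branch-probability-weighted local-linear (degree 1) regressions of
expression on pseudotime with a Gaussian kernel (bandwidth as a
fraction of the pseudotime range, default 0.1), evaluated on a fixed
100-point grid, with pointwise standard errors. The robustness check
reruns the trajectory across a list of k values (termini fixed after
the first connected k) and reports pairwise Pearson correlations of
pseudotime, differentiation potential and flattened branch
probabilities, excluding and flagging any k whose graph leaves cells
unreachable.

## Signature scores and EMP

A profile score is the arithmetic mean of log-normalized expression over
the signature genes present in the matrix (absent genes are logged and
dropped, not zero-imputed). Thresholds per role come from one of three
strategies: nearest-rank percentile (default 75 at module level), Otsu's
between-class-variance threshold, or fixed values. On the synthetic
world the score distributions are strongly bimodal and the pipeline
defaults to Otsu; percentile-75 intersects the two top quartiles, which
is empty when the co-elevated compartment is smaller than either
single-positive compartment. A cell is flagged EMP when it meets both
the epithelial-side (endothelial or epicardial, per lineage) and the
mesenchymal thresholds; both raw scores are kept because plasticity is
a continuum and the flag is a visualization-grade binary. For condition
contrasts, thresholds are fit once on the pooled score distribution and
applied to both conditions; the EMP-fraction fold change carries a
percentile bootstrap CI over cells (default 1000 resamples).
`mean_scale` centres each role's scores for comparison displays.

## Markers and batch genes

Marker calling is one-vs-rest two-sided Wilcoxon rank-sum per gene
(exact null when `n ≤ 12` without ties, else the tie-corrected normal
approximation with continuity correction), Benjamini–Hochberg FDR per
contrast, and the filters: log2 fold change (difference of group means
of log-normalized values) above 0.25, detection (count > 0) in more
than 25% of the group, q ≤ 0.05, positive enrichment only. Batch-gene
detection is the same machinery at 0.5 / 75%. In pairwise mode the
detection filter applies to the higher-expressing side. Note the
continuity-corrected normal approximation can differ from the exact p
by up to ~0.016 at n = 6+6; it converges quickly with n.

## Ligand activity

From a receiver differential-expression table, the response set is the
FDR-ranked genes passing the 0.25 / 25% / q ≤ 0.05 filters and the
background is every other gene detected above a floor (default 10%).
Candidate ligands must be detected in more than 10% of at least one
sender population and, when a receptor mapping is available, have a
receptor detected in the receiver. Activity is the Pearson correlation
between a ligand's regulatory-potential vector over the gene universe
(response ∪ background, restricted to prior targets) and the binary
response indicator; constant vectors are reported missing with a
warning. The top-quartile filter flags the top ⌈n/4⌉ scores (ties at
the threshold keep more; all-equal keeps everything) while the full
ranking is always reported. The synthetic prior plants one driver
ligand (potential = indicator + clipped Gaussian noise) among
half-normal decoys.

## Pipeline

`run_pipeline` executes simulate → qc → cluster → score → trajectory →
markers → ligands from one validated YAML config (unknown keys and
out-of-range values rejected, defaults filled), logs per-stage counts
and timings, and writes a manifest with a config hash and SHA-256
digests of every output file; identical config and seed reproduce
identical digests. The pipeline's default synthetic world plants the
four-fold stalled-condition enrichment the analysis is designed to
detect. All randomness descends from the single config seed through
named `numpy` seed sequences.

## Known limitations

- Library-size (not deconvolution) size factors; no expression-level
  batch correction (MNN edges only).
- The absorbing-chain entropy plateau discussed above: differentiation
  potential separates hybrid window from committed branches cleanly,
  but ranks within the trunk-side plateau are noise-dominated.
- The ligand prior is synthetic; no curated ligand–receptor database is
  bundled, and the human-to-mouse symbol conversion of real priors is a
  pass-through hook.
- Exact Wilcoxon only for `n ≤ 12` without ties; beyond that the normal
  approximation is used rather than permutation.
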