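# Methods

This note documents the models and procedures implemented in `enskit`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions used throughout. Counts are
stored genes-as-rows (Matrix Market convention); exported tables are
cells-as-rows; coordinates are in micrometres and times in seconds. All
stochastic steps take explicit integer seeds.

## Synthetic count matrices (`synthetic_data.gen_counts`)

Counts follow a gamma–Poisson (negative binomial) model with
`var = mu + mu^2/theta` (default dispersion `theta = 2`, a typical droplet
scRNA-seq value). Per-cell library sizes are lognormal (default
`mu = 9.2, sigma = 0.3`, i.e. a median of ~10,000 UMIs, matching 10x-scale
depth). Each of the planted classes shares a lognormal baseline expression
profile; a class's marker genes are elevated `2**marker_log2fc`-fold and the
profile renormalised to unit mass, so the realised marker fold change is
marginally below nominal (with default gene counts the bias is under 3%, and
a Monte-Carlo test confirms the realised ratio within 10% of nominal).

* **Doublets** sum the counts of two random singlets and are binomially
  thinned to 0.8× the summed depth — elevated but not doubled UMIs, as in
  real doublets.
* **Contaminants** (non-neural cells caught by sorting: epithelium, glia,
  myocytes) use an independently permuted baseline profile plus their own
  strongly elevated markers (default 16-fold), named after canonical
  exclusion markers (*Muc13*, *Sox10*, *Myh11*).
* **Mitochondrial content** is imposed per cell: a target fraction is drawn
  (default Normal(0.05, 0.02), clipped) and matching `mt-` counts are added
  multinomially, so the realised fraction equals the draw up to rounding.
* **Sex genes**: female cells receive Poisson *Xist* counts and zero Y-gene
  counts; males the converse — consistent with the evidence rule used by
  sex inference.

Not emulated: transcriptome-wide gene–gene covariance, ambient-RNA soup,
batch chemistry effects, or realistic dropout curves. Recovery tests on
these simulations therefore demonstrate algorithmic correctness at the
stated effect sizes, not performance on arbitrary real data.

## QC filtering (`qc_filtering`)

Global thresholds follow the study's two profiles: juvenile (mito ≤ 0.2)
and postnatal (mito ≤ 0.1), detected genes within [500, 6,500] (inclusive —
"within the range" is read as closed), UMIs ≤ 40,000, after optional
pre-filters (≥ 200 UMIs per cell, genes expressed in ≥ 3 cells). The filter
is idempotent and every criterion's removals are reason-coded in the report.

Per-cluster trimming removes cells strictly below the 1st or strictly above
the 99th percentile of their cluster's UMI distribution. The percentile
convention — linear interpolation between order statistics — is the common
statistical default; the original workflow does not state its convention, so
this one is fixed here and verified against a brute-force oracle. Clusters
with fewer than 3 cells are not trimmed (percentiles are meaningless there).

Doublet scoring is a pANN re-implementation: artificial doublets (default
0.25× the real-cell count) are sums of two random real cells; real and
artificial cells are log-normalised and embedded jointly by PCA, and a
cell's score is the fraction of its k nearest neighbours that are
artificial. The pK-sweep of the original tool is omitted — pANN is the
algorithmic core, and no parameter values were reported to reproduce; the
"auto" threshold takes the (1 − expected doublet rate) score quantile.

Iterative refinement alternates clustering with signature-driven exclusion.
A cluster's contaminant score z-scores each signature gene across cells,
averages per cell, and standardises the cluster mean against the score
distribution of cells *outside* the cluster; clusters scoring above 2 (two
background SDs) are dropped, survivors are percentile-trimmed, and the next
round re-clusters. A score z-scored across *clusters* was considered and
rejected: with C clusters it is bounded by (C−1)/√C, so no threshold near 2
can ever fire when few clusters exist, and noise genes reach the same bound
as real markers — the enrichment form is unbounded and magnitude-sensitive.

## Normalisation, clustering, annotation (`cluster_annotate`)

Two normalisations: `log_cpm` = log1p(count/libsize × 10⁴), and analytic
Pearson residuals `(x − mu)/sqrt(mu + mu²/theta)` with `mu` proportional to
library size and gene total, fixed `theta = 100`, clipped at ±√n_cells.
The residual form serves as the variance-stabilising stand-in for
regularised negative-binomial regression; it captures the variance
stabilisation without learned per-gene regularisation. Variable genes are
ranked by Pearson-residual variance under either method; excluded genes
(sex genes *Xist*, *Tsix*, *Ddx3y*, *Uty*, *Kdm5d*, *Eif2s3y*, *Gm13305*,
*Gm8730*; optionally the immediate-early genes *Fos*, *Jun*, *Junb*, *Egr1*)
are removed from the variable set but kept in the matrix.

Cells are embedded by exact PCA of the centred HVG submatrix. The SNN graph
takes each cell's k nearest neighbours (default k = 15, self included),
weights kNN-adjacent pairs by the Jaccard overlap of their neighbour sets,
and prunes weights below 1/15 (the common default; the original workflow
does not state its weights). Louvain (igraph multilevel, seeded traversal)
partitions the graph at the configured resolution; labels are canonicalised
0..C−1 by decreasing size. Note two structural facts verified by tests:
raising the resolution cannot reduce the community count on the same graph,
and as resolution → 0⁺ a *connected* graph collapses to one community
(disconnected components can never merge, since merging them gains no edge
weight).

Markers are ranked per cluster by one-vs-rest two-sided Wilcoxon rank-sum
tests with BH correction across genes within the cluster, ordered by
adjusted p then |logFC| (logFC compares expm1-backtransformed means for log
data). Cluster annotation z-scores each gene across cells and scores a
signature as the cluster-mean z over its genes; the argmax signature is
assigned only if it beats the runner-up by a margin (default 0.1),
otherwise "unassigned". Scoring across cells rather than across cluster
means keeps the score magnitude-sensitive (see the QC discussion above).

## Reference mapping (`reference_mapping`)

Sex calls use count evidence only: *Xist* > 0 with zero Y-gene sum is
female, the converse male, both zero N/A, both positive ambiguous. This is
the one fully specified rule in the original workflow; no trained
classifier is reproduced.

Joint embedding computes per-dataset variable genes, merges them,
intersects with the shared gene namespace (error below 50 shared genes),
and fits one PCA on the concatenated log-normalised cells. Batch alignment
is deliberately minimal — iterative centroid matching (each dataset's mean
translated onto the pooled mean, ≤ 10 iterations) — the smallest defined
computation realising "integration" without re-implementing external
machinery. It removes translation-like batch effects (e.g. gene-wise
multiplicative efficiency differences, which are shifts on the log scale)
and is not claimed to remove nonlinear batch distortion.

Label transfer classifies each query cell by its k (default 30) nearest
unmasked reference cells, Gaussian-weighted with bandwidth equal to the
cell's median neighbour distance; scores form a probability vector and the
argmax is predicted. Masking removes reference classes before the search,
preserving the original rationale (avoiding competition between
transcriptionally similar classes, e.g. myENC5/6/11 vs smENC1–3) as a
first-class parameter: a masked label scores exactly 0 and can never be
predicted.

## Ligand–receptor scoring (`lr_signaling`)

For a record with ligand genes L₁..Lₚ (sender s) and receptor subunits
R₁..Rq (receiver r):

    L = geomean_i trimmed_mean(expr(L_i) in s),
    R = geomean_j trimmed_mean(expr(R_j) in r),
    prob = L·R / (kh + L·R),        kh = 0.5 by default.

The Hill form with geometric-mean subunit aggregation mirrors the published
cell–cell communication model this stage re-implements; the trim is applied
per tail (trimmed-mean convention), dropping ⌊n·trim⌋ values from each end
— 20% for neuron–neuron runs and 10% for neuron–epithelium runs, where
small heterogeneous epithelial clusters would otherwise lose real signal.
Cofactor modulation is carried in the database schema but not scored.
Significance uses label permutation with the add-one estimator
p = (1 + #{null ≥ obs})/(1 + N), which cannot return zero, and BH
correction within each sender→receiver pair. Calibration is verified under
an exchangeable null: the rejection rate at 0.05 is estimated over three
batches of 200 single-gene interactions at 199 permutations (one batch has
binomial SD ≈ 0.015 around 0.05, so averaging keeps estimator noise inside
the checked band).

## Calcium epochs (`calcium_epochs`)

The default protocol encodes the poking experiment: 24 epochs at 50
samples/s; each epoch lowers the electrode 25 µm at t = 0, a further 25 µm
at 10 s, raises it at 25 s, and scores a 20 s poststimulus window; the next
epoch's 20 s baseline coincides with that post window. Onsets default to a
45 s inter-onset interval with a 20 s lead-in, giving a 19-min recording.

ΔF/F uses a running low-percentile baseline (10th percentile, 30 s window).
Spike detection — unspecified in the original "custom notebook" and
therefore defined here — finds local maxima of the 0.2-s-smoothed ΔF/F
trace exceeding `z_threshold` (default 3.5) times the *raw-trace* robust
noise SD (1.4826 × MAD), merges events within 0.5 s, and reports the
upward threshold crossing before each peak. Requiring the short-window mean
to clear a threshold set on raw noise demands a sustained elevation: a
calcium transient (decay ≈ 0.7 s) loses almost nothing to the averaging
while single-sample noise excursions are suppressed by ~√(window·fps). A
plain per-sample z = 3.5 peak rule at 50 Hz produces ≈ 0.2 false spikes per
minute on pure noise and cannot meet the < 0.02/min target this detector is
held to; the smoothed-versus-raw construction achieves it with ≥ 95% recall
of 5σ transients and latency accuracy of one or two samples.

Latency classes use half-open windows taken literally from their
definitions: first spike in [0, 0.5) s after stimulus start → immediate;
[0.5, 25) → delayed; [25, 45) → poststimulus; a spike at exactly 0.5 s is
delayed. Cell categories: a spike in a baseline window marks a cell
spontaneous *only when the spike lies outside every epoch's stim+post
window* — under this protocol every baseline coincides exactly with the
preceding post window, so without that qualification any poststimulus
responder would be mislabelled spontaneous; "ongoing activity" is activity
not attributable to stimulation. Spontaneous cells are categorised but
excluded from epoch-level summaries by default, matching the original
analysis. Group comparisons report both the two-tailed Student's t test and
the Mann–Whitney U, with a flag naming the primary test.

## 3D proximity (`proximity3d`)

Varicosities are represented by their centre points; cell surfaces by
ellipsoids (centre, semi-axes, optional rotation) or triangle meshes. The
point-to-ellipsoid distance solves the Lagrange condition
`y_i = a_i² x_i/(a_i² + t)` for the unique positive multiplier via
bracketed Brent root-finding (machine-precision tolerance) — the objective
is strictly monotone in `t`, so bracketing is as fast as and more robust
than a Newton iteration. Interior points return 0. Mesh distances take the
minimum over exact point-to-triangle distances (vectorised closest-point
region tests). Distances are invariant under rigid motion of the whole
scene to 1e-9 µm and match an independent constrained-minimisation oracle
to 1e-4 µm. Whether the original measurements were varicosity-centre-to-
surface or surface-to-surface is not stated; centre-to-surface is
implemented, consistent with "varicosity to cell" phrasing. Distance
distributions are summarised per cell-type × fiber-class by median, IQR and
a Gaussian KDE with Silverman bandwidth; two-sample comparisons use the
two-sided Mann–Whitney U (minimum three observations per group).

## Scene and trace generators

`gen_traces` adds instantaneous-rise, exponential-decay transients
(amplitude in units of the noise SD, default 5σ; decay 0.7 s, a GCaMP6f
scale) to Gaussian noise on a constant baseline; quiescent-responding cells
receive one event per epoch at the planted latency, spontaneous cells an
additional homogeneous Poisson train. Not emulated: photobleaching, motion
artefacts, indicator saturation, bursting statistics.

`gen_scene` places well-separated ellipsoidal cells and, per cell, one
varicosity exactly at the planted distance along the outward normal at a
random surface point (for a convex surface the offset along the normal *is*
the shortest distance); background varicosities are rejection-sampled to
lie strictly farther from every cell than its planted distance. Planted
distances are recovered to < 0.01 µm by construction plus solver accuracy.

## Problem sizes and determinism

Validation workloads use 1,500-cell × 800-gene count matrices (five seeds
for recovery claims), three batches of 200 interactions × 199 permutations
for calibration, 19-minute 3-to-6-ROI trace sets, and 20-cell scenes —
sizes at which every claim is measured in seconds to a few minutes while
keeping estimator noise well below the tested margins. Every generator and
every stochastic stage is reproducible from its integer seed; the pipeline
runner derives per-stage sub-seeds from one global seed so a whole run is
reproducible from its config file.

## Known limitations

* The synthetic generators are deliberately simple (independent genes,
  Gaussian trace noise, ellipsoidal cells); passing recovery tests bounds
  algorithmic correctness, not robustness to real-data pathologies.
* Batch alignment is translation-only; strongly nonlinear batch effects
  require external integration tools.
* The LR stage scores single records; pathway-level aggregation, network
  centrality and cofactor modulation are out of scope.
* Percentile and boundary conventions (interpolated percentiles, inclusive
  gene range, half-open latency windows) are fixed choices where the
  original workflow is silent; all are exposed in configuration.
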