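# enskit

`enskit` is an analysis toolkit for single-cell and imaging studies of the
enteric nervous system, built around the workflows used to characterise the
neuron classes of the mouse small-intestine submucosal plexus (smENC1–smENC3:
a putative intrinsic primary afferent class marked by *Nmu*/*Adgrg6*, and two
secretomotor classes marked by *Sst* and *Vip*/*Npy*). It provides, as one
coherent package:

* **QC and iterative refinement of scRNA-seq counts** — global thresholds
  (mitochondrial fraction, detected-gene range 500–6,500, UMI ceiling
  40,000), per-cluster 1st/99th-percentile UMI trimming, artificial-doublet
  (pANN) scoring, and marker-signature-driven exclusion of contaminating
  non-neural populations.
* **Clustering and annotation** — log-CP10K or analytic Pearson-residual
  normalisation, variable-gene selection with sex-gene/IEG exclusion lists,
  PCA, shared-nearest-neighbour graph construction with Jaccard weights, and
  Louvain community detection at configurable resolution, plus one-vs-rest
  Wilcoxon marker tables and signature-based cluster annotation.
* **Reference mapping** — rule-based sex inference from *Xist*/Y-gene counts,
  joint PCA embedding of reference and query datasets, and distance-weighted
  kNN label transfer with class *masking* (masked reference classes are
  removed from competition and can never be predicted).
* **Ligand–receptor signalling** — communication probabilities
  `p = LR/(kh + LR)` from per-tail truncated means (20% within neurons, 10%
  for neuron–epithelium), permutation-null p-values and Benjamini–Hochberg
  correction, with a bundled toy database (Calcb–Calcrl, Sst–Sstr1,
  Vip–Vipr1/2, Nrtn–Gfra2, Fgf1–Fgfr2/3, …).
* **Calcium-epoch analysis** — ΔF/F, spike detection, and classification of
  responses to a 24-epoch mucosal-poking protocol into immediate (< 0.5 s),
  delayed (0.5–25 s) and poststimulus (release + 20 s) latency classes, with
  nonresponding / quiescent-responding / spontaneous cell categories.
* **3D proximity** — exact point-to-ellipsoid (and point-to-mesh) shortest
  distances between nerve-fiber varicosities and cell surfaces, with
  per-class distance distributions and Mann–Whitney comparisons.
* **Synthetic data with ground truth** — negative-binomial count matrices
  with planted classes, markers, doublets, contaminants, mitochondrial
  fractions and sex genes; calcium traces with planted transients locked to
  the poking protocol; 3D scenes with planted shortest distances. Every
  analysis stage is validated by recovering what the generators planted.

## Worked example

```python
from enskit.synthetic_data import SimCountsConfig, gen_counts
from enskit.qc_filtering import iterative_refine, RefineRound, doublet_scores
from enskit.cluster_annotate import cluster_counts, normalize_hvg, annotate_classes
from sklearn.metrics import roc_auc_score

cfg = SimCountsConfig(
    n_cells=1500, n_genes=2000, n_classes=3,
    class_names=("smENC1", "smENC2", "smENC3"),
    marker_names={0: ["Nmu", "Adgrg6"], 1: ["Sst"], 2: ["Vip", "Npy"]},
    seed=0,
)
counts, truth = gen_counts(cfg)

scores = doublet_scores(counts, seed=0)
print(f"doublet AUROC vs truth: "
      f"{roc_auc_score((truth.class_of_cell == 'doublet').to_numpy(), scores):.3f}")

refined, report = iterative_refine(
    counts, [RefineRound(resolution=1.0)],
    {"contaminant": truth.marker_genes["contaminant"]}, seed=0,
)
print(f"iterative refinement kept {refined.n_cells}/{counts.n_cells} cells")

clusters = cluster_counts(refined, resolution=0.04, n_pcs=30, seed=0)
print(f"{clusters.n_clusters} cardinal clusters at resolution 0.04")

nm, _ = normalize_hvg(refined)
for _, row in annotate_classes(nm, clusters).iterrows():
    print(f"cluster {row['cluster']} -> {row['class']} (score {row['score']:.2f})")
```

Output:

```
doublet AUROC vs truth: 0.999
iterative refinement kept 1245/1500 cells
3 cardinal clusters at resolution 0.04
cluster 0 -> smENC3 (score 0.81)
cluster 1 -> smENC2 (score 0.77)
cluster 2 -> smENC1 (score 0.82)
```

The simulation plants 10% doublets and 15% contaminating cells among three
neuron classes. Doublet scoring separates planted doublets almost perfectly
(AUROC 0.999); signature-driven refinement removes the contaminant cluster
and percentile-trims each community (1,245 of 1,500 cells kept ≈ the 1,275
non-contaminant cells minus the ~2% trimmed); low-resolution Louvain then
recovers exactly the three cardinal classes, which the bundled marker
signatures label correctly.

A command-line layer mirrors the library
(`enskit simulate|qc|cluster|transfer|lr|calcium|proximity|run`); see
`enskit --help`.

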