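"""Normalisation, variable-gene selection, graph clustering and marker
analysis for single-cell count matrices.

Two normalisations are provided: log counts-per-10k (``log_cpm``) and
analytic Pearson residuals of a negative-binomial model with fixed
dispersion (``pearson_residual``), the latter standing in for regularised
NB regression as a variance-stabilising transform. Cells are embedded by
PCA on highly variable genes, connected in a shared-nearest-neighbour
(SNN) graph with Jaccard edge weights, and partitioned with the Louvain
algorithm at a configurable resolution. Marker genes are ranked by
one-vs-rest Wilcoxon rank-sum tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .containers import SEX_GENES, CountMatrix, NormalizedMatrix

#: marker signatures of the submucosal neuron classes and the generic
#: differentiation states used for cluster annotation
DEFAULT_SIGNATURES: dict[str, tuple[str, ...]] = {
    "smENC1": ("Nmu", "Adgrg6"),
    "smENC2": ("Sst",),
    "smENC3": ("Vip", "Npy"),
    "glia": ("Sox10", "Plp1"),
    "SCP": ("Dhh", "Col14a1", "Gfra3"),
    "neuroblast": ("Ascl1",),
    "neuron": ("Elavl4",),
}


@dataclass
class NormalizeConfig:
    method: str = "log_cpm"
    n_hvg: int = 3000
    exclude_genes: Sequence[str] = SEX_GENES
    pearson_theta: float = 100.0

    def __post_init__(self) -> None:
        if self.method not in ("log_cpm", "pearson_residual"):
            raise ValueError(f"unknown normalisation method {self.method!r}")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be positive")


@dataclass
class GraphClusterConfig:
    n_pcs: int = 30
    k_neighbors: int = 15
    resolution: float = 1.0
    snn_prune: float = 1.0 / 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def normalize_hvg(
    counts: CountMatrix, cfg: NormalizeConfig | None = None
) -> tuple[NormalizedMatrix, list]:
    """Normalise counts and select highly variable genes.

    log_cpm: log1p(count / libsize * 1e4). pearson_residual:
    (x - mu)/sqrt(mu + mu^2/theta) with mu proportional to library size and
    gene total, theta fixed, residuals clipped at +/- sqrt(n_cells).

    HVGs are the ``n_hvg`` genes with the largest Pearson-residual variance
    after removing ``exclude_genes``; excluded genes stay in the matrix for
    downstream use. Returns the normalised matrix (all genes) and HVG list.
    """
    cfg = cfg or NormalizeConfig()
    X = np.asarray(counts.X.todense(), dtype=float)
    libsize = X.sum(axis=0)
    if np.any(libsize <= 0):
        raise ValueError("cells with zero library size must be filtered first")

    # Pearson residuals drive HVG ranking under either method
    gene_tot = X.sum(axis=1)
    mu = np.outer(gene_tot, libsize) / libsize.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (X - mu) / np.sqrt(mu + mu**2 / cfg.pearson_theta)
    resid[~np.isfinite(resid)] = 0.0
    clip = np.sqrt(counts.n_cells)
    resid = np.clip(resid, -clip, clip)
    resid_var = resid.var(axis=1)

    if cfg.method == "log_cpm":
        values = np.log1p(X / libsize * 1e4)
    else:
        values = resid

    excluded = set(cfg.exclude_genes)
    order = np.argsort(-resid_var, kind="stable")
    hvgs = [counts.genes[i] for i in order if counts.genes[i] not in excluded]
    hvgs = hvgs[: cfg.n_hvg]
    nm = NormalizedMatrix(values, counts.genes, counts.cells, cfg.method, hvgs)
    return nm, hvgs


@dataclass
class Embedding:
    """PCA cell embedding (cells x components) with loadings."""

    coords: np.ndarray
    cells: pd.Index
    loadings: np.ndarray  # components x genes
    explained_variance: np.ndarray
    genes: pd.Index


def pca_embed(normalized: NormalizedMatrix, n_pcs: int = 30, seed: int = 0) -> Embedding:
    """Centered-gene PCA of the HVG submatrix, components by variance."""
    sub = normalized.hvg_submatrix() if normalized.hvgs else normalized
    M = sub.values.T  # cells x genes
    n_pcs = min(n_pcs, min(M.shape) - 1) if min(M.shape) > 1 else 1
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(M)
    return Embedding(
        coords=coords,
        cells=sub.cells,
        loadings=pca.components_,
        explained_variance=pca.explained_variance_,
        genes=sub.genes,
    )


@dataclass
class ClusterAssignment:
    """Per-cell community labels with provenance."""

    labels: pd.Series  # int labels 0..C-1, index = cells
    resolution: float
    round: int = 0

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def cells_in(self, label: int) -> pd.Index:
        return self.labels.index[self.labels == label]


def snn_graph(coords: np.ndarray, k_neighbors: int, prune: float) -> igraph.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    k-NN sets (self included) are compared pairwise over all kNN-adjacent
    pairs; Jaccard overlaps below ``prune`` are dropped.
    """
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)  # includes self
    k = idx.shape[1]
    import scipy.sparse as sp

    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, idx.ravel())), shape=(n, n))
    shared = (A @ A.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * k - s)
    keep = jac >= prune
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jac[keep].tolist()
    return g


def snn_louvain(
    embedding: Embedding, cfg: GraphClusterConfig | None = None
) -> ClusterAssignment:
    """Louvain communities on the SNN graph at the configured resolution.

    Labels are canonicalised 0..C-1 by decreasing community size; the seed
    fixes the Louvain node-traversal order.
    """
    cfg = cfg or GraphClusterConfig()
    coords = embedding.coords[:, : cfg.n_pcs]
    g = snn_graph(coords, cfg.k_neighbors, cfg.snn_prune)
    import random as _random

    igraph.set_random_number_generator(_random.Random(cfg.seed))
    part = g.community_multilevel(weights="weight", resolution=cfg.resolution)
    raw = np.asarray(part.membership)
    # canonical labels by decreasing cluster size (ties by first occurrence)
    sizes = pd.Series(raw).value_counts()
    order = sizes.sort_values(ascending=False, kind="stable").index
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[x] for x in raw], index=embedding.cells, name="cluster")
    return ClusterAssignment(labels=labels, resolution=cfg.resolution)


def cluster_counts(
    counts: CountMatrix,
    resolution: float,
    n_pcs: int = 30,
    k_neighbors: int = 15,
    seed: int = 0,
    normalize_cfg: NormalizeConfig | None = None,
) -> ClusterAssignment:
    """Convenience pipeline: normalise -> PCA -> SNN-Louvain."""
    nm, _ = normalize_hvg(counts, normalize_cfg)
    emb = pca_embed(nm, n_pcs=n_pcs, seed=seed)
    return snn_louvain(
        emb,
        GraphClusterConfig(
            n_pcs=min(n_pcs, emb.coords.shape[1]),
            k_neighbors=min(k_neighbors, counts.n_cells - 1),
            resolution=resolution,
            seed=seed,
        ),
    )


def de_markers(
    normalized: NormalizedMatrix, clusters: ClusterAssignment, min_cells: int = 2
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table.

    Per cluster, every gene is tested against all other cells (two-sided
    rank-sum), p-values are BH-adjusted across genes within the cluster and
    genes ranked by adjusted p then decreasing |logFC|. logFC compares
    expm1-backtransformed means for log data, plain means otherwise.
    Clusters smaller than ``min_cells`` are skipped with a warning.
    """
    V = normalized.values
    expr = np.expm1(V) if normalized.method == "log_cpm" else V
    rows = []
    for cl in range(clusters.n_clusters):
        in_mask = (clusters.labels == cl).to_numpy()
        if in_mask.sum() < min_cells:
            warnings.warn(f"cluster {cl} has <{min_cells} cells; skipped in DE")
            continue
        A = V[:, in_mask]
        B = V[:, ~in_mask]
        stat, p = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided")
        mean_in = expr[:, in_mask].mean(axis=1)
        mean_out = expr[:, ~in_mask].mean(axis=1)
        logfc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        padj = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": normalized.genes,
                "logFC": logfc,
                "pct.in": (A > 0).mean(axis=1),
                "pct.out": (B > 0).mean(axis=1),
                "p": p,
                "p_adj": padj,
            }
        )
        # rank by adjusted p then |logFC| descending
        df["__absfc"] = -df["logFC"].abs()
        df = df.sort_values(["p_adj", "__absfc"], kind="stable").drop(columns="__absfc")
        df["rank"] = np.arange(1, len(df) + 1)
        rows.append(df)
    if not rows:
        return pd.DataFrame(
            columns=["cluster", "gene", "logFC", "pct.in", "pct.out", "p", "p_adj", "rank"]
        )
    return pd.concat(rows, ignore_index=True)


def annotate_classes(
    normalized: NormalizedMatrix,
    clusters: ClusterAssignment,
    signatures: Mapping[str, Sequence[str]] | None = None,
    margin: float = 0.1,
) -> pd.DataFrame:
    """Map clusters to named classes by signature scores.

    Each gene's expression is z-scored across cells (so a score reflects
    effect magnitude, not just rank among clusters); a cluster's score for
    a signature is the mean z over the signature's genes and the cluster's
    cells. A cluster is assigned the argmax signature if its score exceeds
    the runner-up by ``margin``; ties within the margin (and empty gene
    overlap) give "unassigned".
    """
    signatures = signatures or DEFAULT_SIGNATURES
    n_cl = clusters.n_clusters
    V = normalized.values
    sd_cells = V.std(axis=1, keepdims=True)
    sd_cells[sd_cells == 0] = 1.0
    zcells = (V - V.mean(axis=1, keepdims=True)) / sd_cells
    z = np.zeros((len(normalized.genes), n_cl))
    for cl in range(n_cl):
        z[:, cl] = zcells[:, (clusters.labels == cl).to_numpy()].mean(axis=1)

    rows = []
    for cl in range(n_cl):
        scores = {}
        for name, genes in signatures.items():
            idx = normalized.genes.get_indexer([g for g in genes if g in normalized.genes])
            if len(idx) == 0:
                continue
            scores[name] = float(z[idx, cl].mean())
        if not scores:
            warnings.warn(f"cluster {cl}: no signature gene present in the matrix")
            rows.append({"cluster": cl, "class": "unassigned", "score": np.nan,
                         "runner_up": None, "margin": np.nan})
            continue
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        best, runner = ranked[0], (ranked[1] if len(ranked) > 1 else (None, -np.inf))
        gap = best[1] - runner[1]
        assigned = best[0] if gap > margin else "unassigned"
        rows.append({"cluster": cl, "class": assigned, "score": best[1],
                     "runner_up": runner[0], "margin": float(gap)})
    return pd.DataFrame(rows)
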