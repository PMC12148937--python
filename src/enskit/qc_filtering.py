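"""Cell-quality pipeline: global thresholds, per-cluster percentile
trimming, artificial-doublet scoring and iterative marker-driven exclusion.

The global stage removes cells by mitochondrial fraction (> 0.2 for the
juvenile dataset, > 0.1 for the postnatal one), detected-gene range
(500-6,500 retained, boundaries inclusive) and UMI ceiling (40,000), after
optional pre-filters dropping cells with < 200 UMIs and genes expressed in
fewer than three cells. Clustered cells are then trimmed per cluster at
the 1st/99th UMI percentiles (linear-interpolation convention, strict
inequalities at the cutoffs), doublets are scored by the fraction of
artificial-doublet nearest neighbours in PCA space (pANN), and contaminant
cell populations are removed by iterative clustering against marker
signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .cluster_annotate import (
    ClusterAssignment,
    NormalizeConfig,
    cluster_counts,
    normalize_hvg,
)
from .containers import CountMatrix


@dataclass
class QCThresholds:
    """Global per-cell quality thresholds."""

    max_mito_fraction: float = 0.2  # 0.1 for the postnatal dataset
    min_genes: int = 500
    max_genes: int = 6500
    max_umis: int = 40_000
    min_umis_prefilter: int = 200
    min_cells_per_gene: int = 3
    trim_percentiles: tuple = (1.0, 99.0)

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")
        low, high = self.trim_percentiles
        if not (0 < low < high < 100):
            raise ValueError("trim percentiles must satisfy 0 < low < high < 100")

    @classmethod
    def juvenile(cls) -> "QCThresholds":
        return cls(max_mito_fraction=0.2)

    @classmethod
    def postnatal(cls) -> "QCThresholds":
        return cls(max_mito_fraction=0.1)


@dataclass
class QCReport:
    """Ordered log of filtering steps with per-reason removal counts."""

    steps: list = field(default_factory=list)

    def add(self, step: str, n_in: int, n_removed: int, detail: dict | None = None) -> None:
        self.steps.append(
            {
                "step": step,
                "n_in": int(n_in),
                "n_removed": int(n_removed),
                "n_retained": int(n_in - n_removed),
                **(detail or {}),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def total_removed(self) -> int:
        return int(sum(s["n_removed"] for s in self.steps if s.get("unit", "cell") == "cell"))


@dataclass
class DoubletParams:
    """Artificial-doublet (pANN) scoring settings."""

    artificial_fraction: float = 0.25
    k_neighbors: int = 30
    n_pcs: int = 10
    score_threshold: object = "auto"
    expected_doublet_rate: float = 0.075

    def __post_init__(self) -> None:
        if self.artificial_fraction <= 0:
            raise ValueError("artificial_fraction must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def global_filter(
    counts: CountMatrix,
    th: QCThresholds | None = None,
    prefilter: bool = True,
) -> tuple[CountMatrix, QCReport]:
    """Apply global QC thresholds; report removals per criterion.

    With ``prefilter`` enabled, cells with fewer than
    ``min_umis_prefilter`` UMIs and genes expressed in fewer than
    ``min_cells_per_gene`` cells are dropped first. A cell is then retained
    iff mito fraction <= max, min_genes <= genes <= max_genes (inclusive)
    and UMIs <= max. If no mitochondrial gene is present, the mito
    criterion is skipped with a warning.
    """
    th = th or QCThresholds()
    report = QCReport()
    cm = counts

    if prefilter:
        umis = cm.umis_per_cell()
        keep = umis >= th.min_umis_prefilter
        report.add("prefilter_min_umis", cm.n_cells, int((~keep).sum()),
                   {"threshold": th.min_umis_prefilter})
        cm = cm.subset_cells(keep)
        expressed_in = np.asarray((cm.X > 0).sum(axis=1)).ravel()
        gkeep = expressed_in >= th.min_cells_per_gene
        report.add("prefilter_min_cells_per_gene", cm.n_genes, int((~gkeep).sum()),
                   {"threshold": th.min_cells_per_gene, "unit": "gene"})
        cm = cm.subset_genes(gkeep)

    n0 = cm.n_cells
    mito_present = len(cm.mito_genes()) > 0
    if mito_present:
        mito_ok = cm.mito_fraction() <= th.max_mito_fraction
    else:
        warnings.warn("no mitochondrial genes found; mito criterion skipped")
        mito_ok = np.ones(n0, dtype=bool)
    genes_pc = cm.genes_per_cell()
    genes_ok = (genes_pc >= th.min_genes) & (genes_pc <= th.max_genes)
    umis = cm.umis_per_cell()
    umi_ok = umis <= th.max_umis
    keep = mito_ok & genes_ok & umi_ok

    report.add("mito_fraction", n0, int((~mito_ok).sum()),
               {"threshold": th.max_mito_fraction, "skipped": not mito_present})
    report.add("gene_range", n0, int((~genes_ok).sum()),
               {"range": [th.min_genes, th.max_genes]})
    report.add("max_umis", n0, int((~umi_ok).sum()), {"threshold": th.max_umis})
    report.add("global_filter_combined", n0, int((~keep).sum()))
    return cm.subset_cells(keep), report


def cluster_percentile_trim(
    umis_per_cell: np.ndarray,
    labels: ClusterAssignment | pd.Series | np.ndarray,
    trim: tuple = (1.0, 99.0),
    min_cluster_size: int = 3,
) -> np.ndarray:
    """Boolean retain mask after per-cluster UMI percentile trimming.

    Within each cluster independently, cells strictly below the low or
    strictly above the high percentile of the cluster's UMI distribution
    (linear-interpolation percentiles) are removed. Clusters smaller than
    ``min_cluster_size`` are left untrimmed.
    """
    umis = np.asarray(umis_per_cell, dtype=float)
    if isinstance(labels, ClusterAssignment):
        lab = labels.labels.to_numpy()
    else:
        lab = np.asarray(labels)
    if lab.shape[0] != umis.shape[0]:
        raise ValueError("labels must cover all cells")
    low, high = trim
    keep = np.ones(umis.shape[0], dtype=bool)
    for cl in np.unique(lab):
        idx = np.flatnonzero(lab == cl)
        if idx.size < min_cluster_size:
            continue
        lo_val, hi_val = np.percentile(umis[idx], [low, high], method="linear")
        keep[idx] = (umis[idx] >= lo_val) & (umis[idx] <= hi_val)
    return keep


def doublet_scores(
    counts: CountMatrix, params: DoubletParams | None = None, seed: int = 0
) -> np.ndarray:
    """pANN doublet score per cell.

    Artificial doublets are sums of two random real cells' counts; real and
    artificial cells are log-normalised and embedded together by PCA, and
    each real cell's score is the fraction of its k nearest neighbours
    (self excluded) that are artificial. Scores lie in [0, 1].
    """
    params = params or DoubletParams()
    rng = np.random.default_rng(seed)
    n = counts.n_cells
    if params.k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the number of cells")
    n_art = max(int(round(params.artificial_fraction * n)), 1)
    X = np.asarray(counts.X.todense(), dtype=float)
    pa = rng.integers(0, n, size=n_art)
    pb = rng.integers(0, n, size=n_art)
    art = X[:, pa] + X[:, pb]
    both = np.concatenate([X, art], axis=1)
    lib = both.sum(axis=0)
    lib[lib == 0] = 1.0
    logn = np.log1p(both / lib * 1e4)
    logn -= logn.mean(axis=1, keepdims=True)
    n_pcs = min(params.n_pcs, min(logn.shape) - 1)
    coords = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(logn.T)
    nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords[:n])
    neigh = idx[:, 1:]  # drop self
    return (neigh >= n).mean(axis=1)


def doublet_threshold(scores: np.ndarray, params: DoubletParams) -> float:
    """Score cutoff: the (1 - expected doublet rate) quantile ("auto")."""
    if params.score_threshold != "auto":
        return float(params.score_threshold)
    return float(np.quantile(scores, 1.0 - params.expected_doublet_rate))


def score_signature(
    counts: CountMatrix,
    clusters: ClusterAssignment,
    signature: Sequence[str],
    normalized_values: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cluster contaminant-signature enrichment z-score.

    Signature genes are log-normalised, z-scored across cells and averaged
    per cell; a cluster's score is its mean per-cell signature score
    standardised against the score distribution of all cells OUTSIDE the
    cluster. A score above ~2 therefore means the cluster sits more than
    two background standard deviations above the remaining cells.
    """
    genes = [g for g in signature if g in counts.genes]
    if not genes:
        return np.full(clusters.n_clusters, -np.inf)
    if normalized_values is None:
        X = np.asarray(counts.X.todense(), dtype=float)
        lib = X.sum(axis=0)
        lib[lib == 0] = 1.0
        normalized_values = np.log1p(X / lib * 1e4)
    idx = counts.genes.get_indexer(genes)
    V = normalized_values[idx, :]
    sd = V.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (V - V.mean(axis=1, keepdims=True)) / sd
    cell_score = z.mean(axis=0)
    lab = clusters.labels.to_numpy()
    out = np.empty(clusters.n_clusters)
    for cl in range(clusters.n_clusters):
        in_mask = lab == cl
        rest = cell_score[~in_mask]
        sd_rest = rest.std() if rest.size > 1 else 0.0
        if sd_rest == 0:
            sd_rest = 1.0
        out[cl] = (cell_score[in_mask].mean() - rest.mean()) / sd_rest
    return out


@dataclass
class RefineRound:
    """One round of iterative contaminant exclusion."""

    resolution: float = 1.0
    n_pcs: int = 20
    k_neighbors: int = 15
    signature_z_threshold: float = 2.0
    trim: tuple | None = (1.0, 99.0)


def iterative_refine(
    counts: CountMatrix,
    rounds_config: Sequence[RefineRound] | None = None,
    exclusion_signatures: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, QCReport]:
    """Iteratively cluster and exclude contaminant cell populations.

    Each round normalises and clusters the current cells, scores every
    cluster against each exclusion signature (see ``score_signature``),
    drops clusters whose score exceeds the round's threshold, then trims
    per-cluster UMI percentiles among the survivors. Raises if every cell
    would be excluded.
    """
    rounds_config = list(rounds_config) if rounds_config is not None else [RefineRound()]
    exclusion_signatures = dict(exclusion_signatures or {})
    report = QCReport()
    cm = counts

    for rnd, rcfg in enumerate(rounds_config):
        n0 = cm.n_cells
        if not exclusion_signatures and rcfg.trim is None:
            report.add(f"round{rnd}_noop", n0, 0, {"round": rnd})
            continue
        clusters = cluster_counts(
            cm,
            resolution=rcfg.resolution,
            n_pcs=rcfg.n_pcs,
            k_neighbors=min(rcfg.k_neighbors, cm.n_cells - 1),
            seed=seed + rnd,
        )
        lib = None
        X = np.asarray(cm.X.todense(), dtype=float)
        lib = X.sum(axis=0)
        lib[lib == 0] = 1.0
        logn = np.log1p(X / lib * 1e4)

        drop_clusters: set[int] = set()
        scores_log = {}
        for name, sig in exclusion_signatures.items():
            sc = score_signature(cm, clusters, sig, normalized_values=logn)
            scores_log[name] = np.round(sc, 3).tolist()
            drop_clusters |= set(np.flatnonzero(sc > rcfg.signature_z_threshold).tolist())
        keep = ~clusters.labels.isin(drop_clusters).to_numpy()
        report.add(
            f"round{rnd}_signature_exclusion",
            n0,
            int((~keep).sum()),
            {"round": rnd, "dropped_clusters": sorted(drop_clusters),
             "cluster_scores": scores_log, "resolution": rcfg.resolution},
        )
        if not keep.any():
            raise RuntimeError(f"round {rnd}: all cells excluded by signatures")
        cm = cm.subset_cells(keep)

        if rcfg.trim is not None:
            sub_labels = clusters.labels[keep].to_numpy()
            tkeep = cluster_percentile_trim(cm.umis_per_cell(), sub_labels, rcfg.trim)
            report.add(
                f"round{rnd}_percentile_trim", cm.n_cells, int((~tkeep).sum()),
                {"round": rnd, "trim": list(rcfg.trim)},
            )
            if not tkeep.any():
                raise RuntimeError(f"round {rnd}: all cells trimmed")
            cm = cm.subset_cells(tkeep)
    return cm, report
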