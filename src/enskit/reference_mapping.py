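"""Sex inference, joint embedding of reference and query datasets, and
masked label transfer.

Sex calls follow the count-evidence rule: Xist without Y-gene expression is
female, the converse male, both absent N/A, both present ambiguous. Label
transfer embeds reference and query cells in a shared PCA space built on
the union of per-dataset variable genes (with a simple centroid-matching
batch alignment) and classifies each query cell by its distance-weighted
k reference neighbours. Reference classes can be masked — removed from the
neighbour search entirely — to avoid competition between transcriptionally
similar classes; masked labels can never be predicted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .cluster_annotate import NormalizeConfig, normalize_hvg
from .containers import CountMatrix

Y_GENES_DEFAULT = ("Ddx3y", "Uty", "Kdm5d", "Eif2s3y")


def infer_sex(
    counts: CountMatrix,
    xist_gene: str = "Xist",
    y_genes: Sequence[str] = Y_GENES_DEFAULT,
) -> pd.DataFrame:
    """Rule-based per-cell sex call with evidence counts.

    Xist > 0 and Y-sum = 0 -> F; Xist = 0 and Y-sum > 0 -> M; both zero ->
    NA; both positive -> ambiguous.
    """
    xist = counts.gene_counts(xist_gene)
    ysum = np.zeros(counts.n_cells)
    for g in y_genes:
        ysum += counts.gene_counts(g)
    call = np.where(
        (xist > 0) & (ysum == 0), "F",
        np.where((xist == 0) & (ysum > 0), "M",
                 np.where((xist == 0) & (ysum == 0), "NA", "ambiguous")),
    )
    return pd.DataFrame(
        {"sex": call, "xist_count": xist.astype(int), "y_sum": ysum.astype(int)},
        index=counts.cells,
    )


@dataclass
class JointEmbedding:
    """Shared PCA space over concatenated reference + query cells."""

    coords: np.ndarray  # (n_ref + n_query) x n_pcs
    n_ref: int
    ref_cells: pd.Index
    query_cells: pd.Index
    shared_hvgs: list

    @property
    def ref_coords(self) -> np.ndarray:
        return self.coords[: self.n_ref]

    @property
    def query_coords(self) -> np.ndarray:
        return self.coords[self.n_ref:]


def joint_embed(
    ref_counts: CountMatrix,
    query_counts: CountMatrix,
    n_pcs: int = 50,
    n_hvg: int = 3000,
    align_batches: bool = True,
    max_align_iter: int = 10,
    min_shared_genes: int = 50,
) -> JointEmbedding:
    """Embed two datasets in one PCA space on merged variable genes.

    Each dataset's HVGs are computed separately, merged, and intersected
    with the genes shared by both datasets; PCA is fit on the concatenated
    log-normalised cells. Optional batch alignment iteratively translates
    each dataset's centroid onto the pooled centroid in PC space.
    """
    shared = ref_counts.genes.intersection(query_counts.genes)
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} shared genes; need at least {min_shared_genes}"
        )
    cfg = NormalizeConfig(method="log_cpm", n_hvg=n_hvg)
    ref_nm, ref_hvg = normalize_hvg(ref_counts, cfg)
    qry_nm, qry_hvg = normalize_hvg(query_counts, cfg)
    hvgs = [g for g in dict.fromkeys(list(ref_hvg) + list(qry_hvg)) if g in shared]
    if len(hvgs) < 2:
        raise ValueError("fewer than 2 shared variable genes")

    R = ref_nm.values[ref_nm.genes.get_indexer(hvgs), :].T
    Q = qry_nm.values[qry_nm.genes.get_indexer(hvgs), :].T
    M = np.vstack([R, Q])
    n_pcs_eff = min(n_pcs, min(M.shape) - 1)
    coords = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=0).fit_transform(M)
    if n_pcs_eff < n_pcs:  # pad so the contract "n_pcs columns" holds
        coords = np.pad(coords, ((0, 0), (0, n_pcs - n_pcs_eff)))

    n_ref = ref_counts.n_cells
    if align_batches:
        for _ in range(max_align_iter):
            global_mean = coords.mean(axis=0)
            shift_r = global_mean - coords[:n_ref].mean(axis=0)
            shift_q = global_mean - coords[n_ref:].mean(axis=0)
            coords[:n_ref] += shift_r
            coords[n_ref:] += shift_q
            if max(np.linalg.norm(shift_r), np.linalg.norm(shift_q)) < 1e-10:
                break
    return JointEmbedding(
        coords=coords,
        n_ref=n_ref,
        ref_cells=ref_counts.cells,
        query_cells=query_counts.cells,
        shared_hvgs=hvgs,
    )


@dataclass
class TransferResult:
    """Predicted labels plus the full per-cell score matrix."""

    predicted: pd.Series  # query cell -> label
    scores: pd.DataFrame  # query cells x labels, rows sum to 1
    mask: list

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.insert(0, "predicted.id", self.predicted)
        out.to_csv(path, sep="\t", index_label="cell")


def transfer_labels(
    embedding: JointEmbedding,
    ref_labels: pd.Series | Sequence[str],
    mask: Sequence[str] = (),
    k: int = 30,
) -> TransferResult:
    """Distance-weighted kNN label transfer with class masking.

    Masked reference cells are removed before the neighbour search. Each
    query cell's score for a label is the Gaussian-distance-weighted
    fraction of its k reference neighbours carrying that label (bandwidth =
    the cell's median neighbour distance); the prediction is the argmax.
    Scores form a probability vector; masked labels always score 0.
    """
    labels = pd.Series(np.asarray(ref_labels), index=embedding.ref_cells)
    mask = list(mask)
    unknown = set(mask) - set(labels.unique())
    if unknown:
        raise ValueError(f"mask labels not in reference: {sorted(unknown)}")
    keep = ~labels.isin(mask).to_numpy()
    if not keep.any():
        raise ValueError("mask removes every reference cell")
    ref_xy = embedding.ref_coords[keep]
    ref_lab = labels.to_numpy()[keep]
    k_eff = min(k, ref_xy.shape[0])

    nn = NearestNeighbors(n_neighbors=k_eff).fit(ref_xy)
    dist, idx = nn.kneighbors(embedding.query_coords)

    label_order = [l for l in pd.unique(labels) if l not in mask]
    scores = np.zeros((len(embedding.query_cells), len(label_order)))
    pos = {l: j for j, l in enumerate(label_order)}
    for i in range(dist.shape[0]):
        bw = np.median(dist[i])
        w = np.exp(-((dist[i] / bw) ** 2) / 2.0) if bw > 0 else np.ones(k_eff)
        w = w / w.sum()
        for d_w, j in zip(w, idx[i]):
            scores[i, pos[ref_lab[j]]] += d_w
    score_df = pd.DataFrame(scores, index=embedding.query_cells, columns=label_order)
    predicted = score_df.idxmax(axis=1)
    # masked labels carry explicit zero columns for the contract
    for m in mask:
        score_df[m] = 0.0
    return TransferResult(predicted=predicted, scores=score_df, mask=mask)
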