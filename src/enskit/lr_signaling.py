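"""Ligand-receptor communication scoring between cell groups.

For each (sender group, receiver group, ligand-receptor record) the
communication probability is a Hill-saturated product of averaged
expression: L and R are geometric means over the ligand genes (sender) and
receptor subunit genes (receiver) of their per-tail truncated means, and

    prob = L * R / (kh + L * R).

Truncated means drop ``floor(n * trim)`` values from each tail (20% per
tail for neuron-neuron comparisons, 10% for neuron-epithelium, where small
heterogeneous epithelial clusters would otherwise lose real signal).
Significance comes from a permutation null — group labels are reshuffled
and the probability recomputed — with the add-one estimator
p = (1 + #{null >= obs}) / (1 + n_permutations) and Benjamini-Hochberg
correction within each sender-receiver pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix


@dataclass(frozen=True)
class LRRecord:
    pathway: str
    ligand: tuple
    receptor: tuple
    cofactor: tuple = ()

    @property
    def name(self) -> str:
        return f"{'+'.join(self.ligand)}->{'+'.join(self.receptor)}"


@dataclass
class LRDatabase:
    """Ligand-receptor(-subunit) interaction records."""

    records: list

    def __post_init__(self) -> None:
        for r in self.records:
            if not r.ligand or not r.receptor:
                raise ValueError(f"record {r.pathway} lacks ligand or receptor genes")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_tsv(cls, path) -> "LRDatabase":
        df = pd.read_csv(path, sep="\t").fillna("")
        recs = [
            LRRecord(
                pathway=row["pathway"],
                ligand=tuple(str(row["ligand"]).split(";")),
                receptor=tuple(str(row["receptor"]).split(";")),
                cofactor=tuple(c for c in str(row.get("cofactor", "")).split(";") if c),
            )
            for _, row in df.iterrows()
        ]
        return cls(recs)

    @classmethod
    def bundled(cls) -> "LRDatabase":
        """The packaged toy database of pairs relevant to submucosal neurons."""
        with resources.as_file(
            resources.files("enskit.data").joinpath("lr_pairs.tsv")
        ) as p:
            return cls.from_tsv(p)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "pathway": [r.pathway for r in self.records],
                "ligand": [";".join(r.ligand) for r in self.records],
                "receptor": [";".join(r.receptor) for r in self.records],
                "cofactor": [";".join(r.cofactor) for r in self.records],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class LRParams:
    trim: float = 0.20  # per-tail; 0.10 for neuron-epithelium runs
    min_frac_expressing: float = 0.0
    n_permutations: int = 99
    kh: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim < 0.5:
            raise ValueError("trim must lie in [0, 0.5)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.kh <= 0:
            raise ValueError("kh must be positive")


def truncated_mean(x: Sequence[float], trim: float) -> float:
    """Mean after dropping floor(n * trim) values from each sorted tail."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty vector")
    k = math.floor(n * trim)
    if 2 * k >= n:
        raise ValueError("trim removes every value")
    return float(x[k: n - k].mean())


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def overexpressed_genes(
    normalized: NormalizedMatrix,
    groups: pd.Series | Sequence[str],
    alpha: float = 0.05,
) -> dict:
    """Genes over-expressed per group (one-sided Wilcoxon, BH within group).

    A gene belongs to a group's set when its BH-adjusted one-sided
    rank-sum p (group > rest) is below ``alpha`` and the group mean exceeds
    the rest mean.
    """
    groups = pd.Series(np.asarray(groups), index=normalized.cells)
    out: dict[str, list] = {}
    for g in pd.unique(groups):
        in_mask = (groups == g).to_numpy()
        if in_mask.sum() == 0 or (~in_mask).sum() == 0:
            raise ValueError(f"group {g!r} or its complement is empty")
        A = normalized.values[:, in_mask]
        B = normalized.values[:, ~in_mask]
        _, p = stats.mannwhitneyu(A, B, axis=1, alternative="greater")
        padj = bh_adjust(p)
        up = A.mean(axis=1) > B.mean(axis=1)
        out[g] = [
            normalized.genes[i]
            for i in np.flatnonzero((padj < alpha) & up)
        ]
    return out


def eligible_records(db: LRDatabase, over: Mapping[str, Sequence[str]]) -> list:
    """Records whose ligand or receptor is over-expressed in some group."""
    over_all = set().union(*[set(v) for v in over.values()]) if over else set()
    return [
        r
        for r in db
        if (set(r.ligand) | set(r.receptor)) & over_all
    ]


def _group_trimmed_means(
    values: np.ndarray, group_indices: Mapping[str, np.ndarray], trim: float
) -> dict:
    """Per-group truncated mean of every gene row."""
    out = {}
    for g, idx in group_indices.items():
        sub = np.sort(values[:, idx], axis=1)
        n = idx.size
        k = math.floor(n * trim)
        out[g] = sub[:, k: n - k].mean(axis=1)
    return out


def _probabilities(
    tm: Mapping[str, np.ndarray],
    frac: Mapping[str, np.ndarray],
    gene_index: pd.Index,
    records: Sequence[LRRecord],
    group_names: Sequence[str],
    params: LRParams,
) -> dict:
    """Hill probability for every (sender, receiver, record)."""

    def _gmean(vals: np.ndarray) -> float:
        if np.any(vals <= 0):
            return 0.0
        return float(np.exp(np.log(vals).mean()))

    probs = {}
    for rec in records:
        lig_idx = gene_index.get_indexer(rec.ligand)
        rec_idx = gene_index.get_indexer(rec.receptor)
        if (lig_idx < 0).any() or (rec_idx < 0).any():
            continue
        for s in group_names:
            L = _gmean(tm[s][lig_idx])
            if L > 0 and params.min_frac_expressing > 0 and np.any(
                frac[s][lig_idx] < params.min_frac_expressing
            ):
                L = 0.0
            for r in group_names:
                R = _gmean(tm[r][rec_idx])
                if R > 0 and params.min_frac_expressing > 0 and np.any(
                    frac[r][rec_idx] < params.min_frac_expressing
                ):
                    R = 0.0
                lr = L * R
                probs[(s, r, rec.name)] = lr / (params.kh + lr)
    return probs


def comm_probability(
    normalized: NormalizedMatrix,
    groups: pd.Series | Sequence[str],
    db: LRDatabase,
    params: LRParams | None = None,
) -> pd.DataFrame:
    """Communication probabilities for every sender-receiver-record triple.

    Records referencing genes absent from the matrix are skipped (logged
    as a warning). The probability is 0 whenever a ligand or receptor
    truncated mean is 0.
    """
    params = params or LRParams()
    groups = pd.Series(np.asarray(groups), index=normalized.cells)
    names = list(pd.unique(groups))
    gidx = {g: np.flatnonzero((groups == g).to_numpy()) for g in names}
    skipped = [
        r.name
        for r in db
        if (normalized.genes.get_indexer(r.ligand) < 0).any()
        or (normalized.genes.get_indexer(r.receptor) < 0).any()
    ]
    if skipped:
        warnings.warn(f"skipping records with absent genes: {skipped}")
    tm = _group_trimmed_means(normalized.values, gidx, params.trim)
    frac = {g: (normalized.values[:, idx] > 0).mean(axis=1) for g, idx in gidx.items()}
    probs = _probabilities(tm, frac, normalized.genes, list(db), names, params)
    rows = [
        {"sender": s, "receiver": r, "interaction": nm, "probability": p}
        for (s, r, nm), p in probs.items()
    ]
    return pd.DataFrame(rows)


def permutation_test(
    normalized: NormalizedMatrix,
    groups: pd.Series | Sequence[str],
    db: LRDatabase,
    params: LRParams | None = None,
) -> pd.DataFrame:
    """Probabilities with permutation p-values and BH adjustment.

    The null redraws the group labels ``n_permutations`` times and
    recomputes each triple's probability; p = (1 + #{null >= obs}) /
    (1 + n_permutations). BH runs within each sender-receiver pair across
    its interaction records.
    """
    params = params or LRParams()
    groups = pd.Series(np.asarray(groups), index=normalized.cells)
    names = list(pd.unique(groups))
    lab = groups.to_numpy()
    obs = comm_probability(normalized, groups, db, params)
    records = [
        r
        for r in db
        if not (normalized.genes.get_indexer(r.ligand) < 0).any()
        and not (normalized.genes.get_indexer(r.receptor) < 0).any()
    ]
    rng = np.random.default_rng(params.seed)
    obs_map = {
        (t.sender, t.receiver, t.interaction): t.probability for t in obs.itertuples()
    }
    exceed = {k: 0 for k in obs_map}
    for _ in range(params.n_permutations):
        perm = lab[rng.permutation(lab.size)]
        pidx = {g: np.flatnonzero(perm == g) for g in names}
        tm = _group_trimmed_means(normalized.values, pidx, params.trim)
        if params.min_frac_expressing > 0:
            frac = {
                g: (normalized.values[:, idx] > 0).mean(axis=1)
                for g, idx in pidx.items()
            }
        else:
            frac = {g: None for g in names}
        null = _probabilities(tm, frac, normalized.genes, records, names, params)
        for k, v in null.items():
            if v >= obs_map[k]:
                exceed[k] += 1
    obs = obs.copy()
    obs["p"] = [
        (1 + exceed[(t.sender, t.receiver, t.interaction)]) / (1 + params.n_permutations)
        for t in obs.itertuples()
    ]
    obs["p_adj"] = np.nan
    for (s, r), grp in obs.groupby(["sender", "receiver"]):
        obs.loc[grp.index, "p_adj"] = bh_adjust(grp["p"].to_numpy())
    return obs
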