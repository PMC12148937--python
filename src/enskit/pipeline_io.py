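"""Readers/writers, run configuration and the stage-chaining pipeline.

Counts are exchanged as the 10x Genomics Matrix Market triple
(matrix.mtx[.gz], barcodes.tsv[.gz], features.tsv[.gz]), genes as rows.
A run is driven by a YAML config with one block per stage; all randomness
derives from the single global seed, so a run is reproducible from its
config file alone.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import __version__
from .containers import CountMatrix

logger = logging.getLogger("enskit")

_STAGES = ("simulate", "qc", "cluster", "transfer", "lr", "calcium", "proximity")


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def make_unique(names) -> pd.Index:
    """Deduplicate names deterministically by appending -1, -2, ..."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}-{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return pd.Index(out)


def read_counts_10x(directory) -> CountMatrix:
    """Read a 10x-style MTX triple into a genes x cells CountMatrix.

    Accepts plain or gzipped files; the matrix orientation is normalised
    to genes-as-rows using the barcode/feature counts, and duplicate gene
    names are made unique deterministically.
    """
    directory = Path(directory)
    with _open_maybe_gz(_find(directory, "matrix.mtx"), "rb") as fh:
        X = sp.csr_matrix(scipy.io.mmread(fh))
    barcodes = pd.read_csv(
        _find(directory, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    features = pd.read_csv(_find(directory, "features.tsv"), sep="\t", header=None)
    gene_names = features[1] if features.shape[1] > 1 else features[0]
    gene_names = gene_names.astype(str)
    n_genes, n_cells = len(gene_names), len(barcodes)
    if X.shape == (n_cells, n_genes) and n_genes != n_cells:
        X = X.T.tocsr()
    if X.shape != (n_genes, n_cells):
        raise ValueError(
            f"MTX dims {X.shape} do not match {n_genes} features x {n_cells} barcodes"
        )
    return CountMatrix(X, make_unique(gene_names), make_unique(barcodes))


def write_counts_10x(counts: CountMatrix, directory, gz: bool = False) -> None:
    """Write a CountMatrix as a matrix.mtx / barcodes.tsv / features.tsv triple."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gz else ""
    with _open_maybe_gz(directory / f"matrix.mtx{suffix}", "wb") as fh:
        scipy.io.mmwrite(fh, sp.coo_matrix(counts.X))
    with _open_maybe_gz(directory / f"barcodes.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(counts.cells) + "\n")
    with _open_maybe_gz(directory / f"features.tsv{suffix}", "wt") as fh:
        fh.write("\n".join(f"{g}\t{g}\tGene Expression" for g in counts.genes) + "\n")


# ----------------------------------------------------------------- config
_KNOWN_KEYS = {
    "seed", "out_dir", "log_level", "stages",
    "simulate", "qc", "cluster", "transfer", "lr", "calcium", "proximity",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    out_dir: str = "enskit_run"
    log_level: str = "INFO"
    stages: list = field(default_factory=lambda: ["simulate", "qc", "cluster"])
    stage_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        unknown = set(obj) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = obj.get("stages", ["simulate", "qc", "cluster"])
        for s in stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}")
        return cls(
            seed=int(obj.get("seed", 0)),
            out_dir=str(obj.get("out_dir", "enskit_run")),
            log_level=str(obj.get("log_level", "INFO")),
            stages=list(stages),
            stage_params={s: dict(obj.get(s, {})) for s in _STAGES},
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sub_seed(self, stage: str) -> int:
        """Stage-specific seed derived from the global seed."""
        return (self.seed * 1_000_003 + _STAGES.index(stage) + 1) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; return the run manifest.

    Each stage writes its outputs under ``out_dir`` and records input and
    output cell counts in the manifest. Stages that need an upstream
    output raise a clear error naming the missing stage.
    """
    from .cluster_annotate import cluster_counts
    from .qc_filtering import QCThresholds, global_filter
    from .synthetic_data import SimCountsConfig, gen_counts

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": []}
    counts = None

    for stage in config.stages:
        params = dict(config.stage_params.get(stage, {}))
        entry = {"stage": stage, "seed": config.sub_seed(stage), "params": params}
        if stage == "simulate":
            cfg = SimCountsConfig(**params, seed=config.sub_seed(stage))
            counts, truth = gen_counts(cfg)
            write_counts_10x(counts, out / "simulated")
            truth.to_tsv(out / "simulated" / "truth.tsv")
            entry["n_cells_out"] = counts.n_cells
        elif stage == "qc":
            if counts is None:
                indir = params.pop("input", None)
                if indir is None:
                    raise RuntimeError("qc stage needs the simulate stage or an 'input' dir")
                counts = read_counts_10x(indir)
            entry["n_cells_in"] = counts.n_cells
            th = QCThresholds(**params.pop("thresholds", {}))
            counts, report = global_filter(counts, th, **params)
            report.to_frame().to_json(out / "qc_report.json", orient="records", indent=1)
            write_counts_10x(counts, out / "qc_filtered")
            entry["n_cells_out"] = counts.n_cells
        elif stage == "cluster":
            if counts is None:
                raise RuntimeError("cluster stage needs an upstream qc or simulate stage")
            entry["n_cells_in"] = counts.n_cells
            clusters = cluster_counts(
                counts,
                resolution=float(params.get("resolution", 1.0)),
                n_pcs=int(params.get("n_pcs", 30)),
                k_neighbors=int(params.get("k_neighbors", 15)),
                seed=config.sub_seed(stage),
            )
            clusters.labels.to_csv(out / "clusters.tsv", sep="\t", header=True)
            entry["n_clusters"] = clusters.n_clusters
        else:
            raise RuntimeError(
                f"stage {stage!r} has no chained implementation; run it via its "
                "module API or dedicated CLI subcommand"
            )
        manifest["stages"].append(entry)
        logger.info("stage %s done", stage)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
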