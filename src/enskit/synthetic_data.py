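"""Ground-truth simulators for every pipeline stage.

Three generators emulate the statistical structure the downstream stages
assume:

* ``gen_counts`` — negative-binomial scRNA-seq counts with planted neuron
  classes and markers, doublets (summed parent profiles, depth-thinned),
  contaminating non-neural cells with their own markers, imposed per-cell
  mitochondrial fractions, and sex-consistent Xist / Y-gene counts.
* ``gen_traces`` — GCaMP-like fluorescence traces: Gaussian noise plus
  instantaneous-rise exponential-decay transients locked to a 24-epoch
  mucosal-poking protocol, with optional spontaneous Poisson events.
* ``gen_scene`` — 3D ellipsoidal cell bodies and varicosity point clouds
  with per-cell planted shortest distances.

Every generator is fully determined by its integer seed and returns the
ground truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .calcium_epochs import StimulusProtocol, TraceSet
from .containers import CountMatrix
from .proximity3d import Cell, Ellipsoid, Scene

Y_GENES = ("Ddx3y", "Uty", "Kdm5d", "Eif2s3y")
DEFAULT_CONTAMINANT_MARKERS = ("Muc13", "Sox10", "Myh11")


def _check_fraction(name: str, value: float) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a finite fraction in [0, 1], got {value}")


# ======================================================================
# counts
# ======================================================================
@dataclass
class SimCountsConfig:
    """Settings of the planted-class count simulator."""

    n_cells: int = 1500
    n_genes: int = 2000
    n_classes: int = 3
    markers_per_class: int = 20
    marker_log2fc: float = 2.0
    doublet_fraction: float = 0.10
    contaminant_fraction: float = 0.15
    contaminant_log2fc: float = 4.0
    mito_fraction_dist: tuple = (0.05, 0.02)
    libsize_lognormal: tuple = (9.2, 0.3)  # median library ~1e4 UMIs
    nb_dispersion: float = 2.0
    sex_ratio: float = 0.5
    n_mito_genes: int = 10
    class_names: Sequence[str] | None = None
    marker_names: Mapping[int, Sequence[str]] | None = None
    contaminant_marker_names: Sequence[str] = DEFAULT_CONTAMINANT_MARKERS
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("doublet_fraction", "contaminant_fraction", "sex_ratio"):
            _check_fraction(nm, getattr(self, nm))
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if not np.isfinite(self.marker_log2fc):
            raise ValueError("marker_log2fc must be finite")
        if self.nb_dispersion <= 0 or not np.isfinite(self.nb_dispersion):
            raise ValueError("nb_dispersion must be a positive real")
        reserved = self.n_mito_genes + 1 + len(Y_GENES)
        need = reserved + self.n_classes * self.markers_per_class + self.markers_per_class
        if self.n_genes < need:
            raise ValueError(f"n_genes={self.n_genes} too small for config (need >= {need})")
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")

    @property
    def names(self) -> list:
        if self.class_names is not None:
            return list(self.class_names)
        return [f"class{i + 1}" for i in range(self.n_classes)]


@dataclass
class SimTruth:
    """Ground-truth labels attached to a simulated count matrix."""

    class_of_cell: pd.Series  # class name, "doublet" or "contaminant"
    sex_of_cell: pd.Series  # "F" / "M"
    marker_genes: dict  # class name -> list of marker genes

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"cell": self.class_of_cell.index, "class": self.class_of_cell.values,
             "sex": self.sex_of_cell.values}
        ).to_csv(path, sep="\t", index=False)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mean, 1e-12) / theta)
    return rng.poisson(lam)


def gen_counts(config: SimCountsConfig) -> tuple[CountMatrix, SimTruth]:
    """Simulate a genes x cells count matrix with known structure.

    Markers of class c are elevated ``2**marker_log2fc``-fold in c's
    expression profile (profiles renormalised to unit mass, so the realised
    mean ratio is marginally below the nominal fold change). Doublets sum
    two random singlet cells' counts and are thinned to 0.8x the summed
    depth. Contaminants use an independently shuffled baseline profile with
    their own strongly elevated markers. Mitochondrial counts are imposed
    per cell by drawing a target fraction and adding matching "mt-" counts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # ---------------------------------------------------------- gene names
    mito_genes = [f"mt-Sim{i + 1}" for i in range(cfg.n_mito_genes)]
    sex_genes = ["Xist", *Y_GENES]
    marker_genes: dict[str, list[str]] = {}
    used: set[str] = set(mito_genes) | set(sex_genes)
    for ci, cname in enumerate(cfg.names):
        names = list(cfg.marker_names.get(ci, [])) if cfg.marker_names else []
        while len(names) < cfg.markers_per_class:
            names.append(f"Mk{ci + 1}_{len(names) + 1}")
        marker_genes[cname] = names[: cfg.markers_per_class]
        used |= set(marker_genes[cname])
    cont_markers = list(cfg.contaminant_marker_names)
    while len(cont_markers) < cfg.markers_per_class:
        cont_markers.append(f"MkCont_{len(cont_markers) + 1}")
    marker_genes["contaminant"] = cont_markers
    used |= set(cont_markers)
    filler = [f"Gene{i + 1:05d}" for i in range(cfg.n_genes)]
    filler = [g for g in filler if g not in used]
    genes = mito_genes + sex_genes + [g for ms in marker_genes.values() for g in ms]
    genes += filler[: cfg.n_genes - len(genes)]
    genes_idx = pd.Index(genes)
    special = np.isin(genes, mito_genes + sex_genes)

    # ------------------------------------------------------- cell identity
    n_doub = int(round(cfg.doublet_fraction * cfg.n_cells))
    n_cont = int(round(cfg.contaminant_fraction * cfg.n_cells))
    n_sing = cfg.n_cells - n_doub - n_cont
    if n_sing < 2 * cfg.n_classes:
        raise ValueError("too few singlet cells for the requested class count")
    sing_class = rng.integers(0, cfg.n_classes, size=n_sing)

    # ---------------------------------------------------------- profiles
    base = rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    base[special] = 0.0
    base /= base.sum()
    profiles = []
    for ci, cname in enumerate(cfg.names):
        p = base.copy()
        p[genes_idx.get_indexer(marker_genes[cname])] *= 2.0**cfg.marker_log2fc
        profiles.append(p / p.sum())
    cont_base = base[~special][rng.permutation(int((~special).sum()))]
    cont_profile = np.zeros(cfg.n_genes)
    cont_profile[~special] = cont_base
    cont_profile[genes_idx.get_indexer(marker_genes["contaminant"])] *= (
        2.0**cfg.contaminant_log2fc
    )
    cont_profile /= cont_profile.sum()

    # --------------------------------------------------------- draw counts
    libsizes = rng.lognormal(cfg.libsize_lognormal[0], cfg.libsize_lognormal[1], cfg.n_cells)
    X = np.zeros((cfg.n_genes, cfg.n_cells), dtype=np.int64)
    labels = []
    for i in range(n_sing):
        X[:, i] = _nb_sample(rng, profiles[sing_class[i]] * libsizes[i], cfg.nb_dispersion)
        labels.append(cfg.names[sing_class[i]])
    for j in range(n_cont):
        i = n_sing + j
        X[:, i] = _nb_sample(rng, cont_profile * libsizes[i], cfg.nb_dispersion)
        labels.append("contaminant")
    for j in range(n_doub):
        i = n_sing + n_cont + j
        a, b = rng.choice(n_sing, size=2, replace=False)
        # summed parents thinned to 0.8x depth: elevated but not doubled UMIs
        X[:, i] = rng.binomial(X[:, a] + X[:, b], 0.8)
        labels.append("doublet")

    # --------------------------------------------------------------- sex
    sexes = np.where(rng.random(cfg.n_cells) < cfg.sex_ratio, "F", "M")
    xi = genes_idx.get_loc("Xist")
    yidx = genes_idx.get_indexer(Y_GENES)
    scale = libsizes / 1e4
    for i in range(cfg.n_cells):
        if sexes[i] == "F":
            X[xi, i] = rng.poisson(5.0 * scale[i])
        else:
            X[yidx, i] = rng.poisson(1.5 * scale[i], size=len(yidx))

    # ------------------------------------------------------ mito fraction
    mito_idx = genes_idx.get_indexer(mito_genes)
    mmean, msd = cfg.mito_fraction_dist
    frac = np.clip(rng.normal(mmean, msd, cfg.n_cells), 0.0, 0.8)
    other_total = X.sum(axis=0)
    mito_total = np.round(frac / (1.0 - frac) * other_total).astype(np.int64)
    mito_w = rng.dirichlet(np.full(len(mito_genes), 5.0))
    for i in range(cfg.n_cells):
        if mito_total[i] > 0:
            X[mito_idx, i] = rng.multinomial(mito_total[i], mito_w)

    cells = pd.Index([f"cell{i + 1:05d}" for i in range(cfg.n_cells)])
    cm = CountMatrix(sp.csr_matrix(X), genes_idx, cells)
    truth = SimTruth(
        class_of_cell=pd.Series(labels, index=cells, name="class"),
        sex_of_cell=pd.Series(sexes, index=cells, name="sex"),
        marker_genes=marker_genes,
    )
    return cm, truth


def write_counts_truth(truth: SimTruth, path) -> None:
    truth.to_tsv(path)


# ======================================================================
# traces
# ======================================================================
@dataclass
class SimTraceConfig:
    """Settings of the calcium-trace simulator."""

    n_cells: int = 10
    category_of_cell: Mapping[str, str] | None = None  # default: all quiescent
    planted_latency_s: object = (0.2, 20.0)  # float, (low, high) or per-cell map
    transient: tuple = (5.0, 0.7)  # amplitude (x noise sd), decay tau (s)
    noise_sd: float = 1.0
    baseline_f: float = 100.0
    spontaneous_rate_hz: float = 0.1
    duration_s: float = 1140.0  # 19-min recording
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0 or self.baseline_f <= 0:
            raise ValueError("noise_sd and baseline_f must be positive")
        if self.spontaneous_rate_hz < 0:
            raise ValueError("spontaneous_rate_hz must be non-negative")
        if self.category_of_cell is None:
            self.category_of_cell = {
                f"roi{i + 1:03d}": "quiescent_responding" for i in range(self.n_cells)
            }
        self.category_of_cell = dict(self.category_of_cell)
        if len(self.category_of_cell) != self.n_cells:
            raise ValueError("category_of_cell must cover exactly n_cells cells")
        bad = set(self.category_of_cell.values()) - {
            "nonresponding", "quiescent_responding", "spontaneous"
        }
        if bad:
            raise ValueError(f"unknown cell categories: {sorted(bad)}")
        win = self.protocol.response_window_s
        for cell, cat in self.category_of_cell.items():
            if cat == "quiescent_responding":
                for lat in np.atleast_1d(self._latency_spec(cell)):
                    if not 0.0 <= float(lat) < win:
                        raise ValueError(
                            f"planted latency {lat} s for quiescent cell {cell} lies "
                            f"outside the [0, {win}) s response window"
                        )

    def _latency_spec(self, cell: str):
        spec = self.planted_latency_s
        if isinstance(spec, Mapping):
            spec = spec[cell]
        return spec

    def draw_latency(self, cell: str, rng: np.random.Generator) -> float:
        spec = self._latency_spec(cell)
        if np.isscalar(spec):
            return float(spec)
        low, high = spec
        return float(rng.uniform(low, high))


def gen_traces(config: SimTraceConfig) -> tuple[TraceSet, pd.DataFrame]:
    """Simulate fluorescence traces with planted transients.

    Each planted event adds an instantaneous-rise, exponential-decay
    transient of amplitude ``transient[0]`` noise SDs to Gaussian noise on
    a constant baseline. Quiescent-responding cells receive one event per
    epoch at the planted latency; spontaneous cells additionally receive a
    homogeneous Poisson train across the whole recording.

    Returns the trace set and a truth table (cell, time_s, epoch, kind)
    where epoch is -1 for spontaneous events.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fps = cfg.protocol.fps
    n = int(round(cfg.duration_s * fps))
    times = np.arange(n) / fps
    amp = cfg.transient[0] * cfg.noise_sd
    tau = cfg.transient[1]

    traces = {}
    truth_rows = []
    for cell in cfg.category_of_cell:
        cat = cfg.category_of_cell[cell]
        f = cfg.baseline_f + rng.normal(0.0, cfg.noise_sd, size=n)
        events: list[tuple[float, int, str]] = []
        if cat in ("quiescent_responding", "spontaneous"):
            for e in range(cfg.protocol.n_epochs):
                t0 = cfg.protocol.epoch_starts_s[e]
                lat = cfg.draw_latency(cell, rng)
                if t0 + lat < cfg.duration_s:
                    events.append((t0 + lat, e, "evoked"))
        if cat == "spontaneous" and cfg.spontaneous_rate_hz > 0:
            n_ev = rng.poisson(cfg.spontaneous_rate_hz * cfg.duration_s)
            for t in np.sort(rng.uniform(0.0, cfg.duration_s, size=n_ev)):
                events.append((float(t), -1, "spontaneous"))
        for t_ev, epoch, kind in events:
            i0 = int(np.ceil(t_ev * fps - 1e-9))
            t_rel = times[i0:] - t_ev
            f[i0:] += amp * np.exp(-t_rel / tau)
            truth_rows.append({"cell": cell, "time_s": t_ev, "epoch": epoch, "kind": kind})
        traces[cell] = f

    truth = pd.DataFrame(truth_rows, columns=["cell", "time_s", "epoch", "kind"])
    return TraceSet(times, pd.DataFrame(traces)), truth


# ======================================================================
# scenes
# ======================================================================
@dataclass
class SimSceneConfig:
    """Settings of the 3D cell / varicosity scene simulator."""

    n_cells: int = 20
    cell_shape: tuple = (6.0, 5.0, 4.0)  # ellipsoid semi-axes, um
    n_varicosities: int = 200
    planted_min_distance_um: object = (0.5, 15.0)  # float, (low, high) or array
    volume_um: tuple = (400.0, 400.0, 60.0)
    cell_type: str = "EC"
    fiber_class: str = "fiber"
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.cell_shape) <= 0):
            raise ValueError("semi-axes must be positive")
        if self.n_varicosities < self.n_cells:
            raise ValueError("need at least one varicosity per cell")
        d = np.asarray(self.planted_min_distance_um, dtype=float).ravel()
        if np.any(d < 0):
            raise ValueError("planted distances must be non-negative")
        if np.max(d) + 2 * max(self.cell_shape) > min(self.volume_um):
            raise ValueError("planted distance exceeds the bounding box")

    def draw_distances(self, rng: np.random.Generator) -> np.ndarray:
        spec = np.asarray(self.planted_min_distance_um, dtype=float).ravel()
        if spec.size == 1:
            return np.full(self.n_cells, float(spec[0]))
        if spec.size == 2 and np.isscalar(self.planted_min_distance_um[0]):
            return rng.uniform(spec[0], spec[1], size=self.n_cells)
        if spec.size != self.n_cells:
            raise ValueError("per-cell distance vector length mismatch")
        return spec


def gen_scene(config: SimSceneConfig) -> tuple[Scene, pd.DataFrame]:
    """Simulate a 3D scene with planted per-cell shortest distances.

    For each cell one varicosity is placed exactly at the planted distance
    along the outward surface normal at a random surface point (the foot
    point of a convex surface lies at that normal, so the offset equals the
    true shortest distance). All other varicosities are rejected until they
    lie strictly farther than every cell's planted distance.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    a = np.asarray(cfg.cell_shape, dtype=float)
    box = np.asarray(cfg.volume_um, dtype=float)
    dists = cfg.draw_distances(rng)
    margin = np.max(a) + np.max(dists) + 1.0
    min_sep = 2.0 * margin

    # spread cell centres with rejection sampling
    centers: list[np.ndarray] = []
    for _ in range(20000):
        if len(centers) == cfg.n_cells:
            break
        c = rng.uniform(margin, box - margin)
        if all(np.linalg.norm(c - o) >= min_sep for o in centers):
            centers.append(c)
    if len(centers) < cfg.n_cells:
        raise ValueError("bounding box too small to separate the requested cells")

    cells = []
    vari_rows = []
    truth_rows = []
    vid = 0
    for i, (c, d) in enumerate(zip(centers, dists)):
        cell_id = f"cell{i + 1:03d}"
        cells.append(Cell(id=cell_id, cell_type=cfg.cell_type, surface=Ellipsoid(c, a)))
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        p = v / np.sqrt(np.sum((v / a) ** 2))  # surface point along v (body frame)
        nrm = p / a**2
        nrm /= np.linalg.norm(nrm)
        x = c + p + d * nrm
        vari_rows.append(
            {"id": f"v{vid:04d}", "fiber_class": cfg.fiber_class,
             "x": x[0], "y": x[1], "z": x[2]}
        )
        truth_rows.append(
            {"cell": cell_id, "planted_distance_um": float(d), "varicosity": f"v{vid:04d}"}
        )
        vid += 1

    # background varicosities, strictly farther than every planted minimum
    from .proximity3d import point_ellipsoid_distance

    n_extra = cfg.n_varicosities - cfg.n_cells
    placed = 0
    for _ in range(200000):
        if placed == n_extra:
            break
        x = rng.uniform(0.0, box)
        ok = all(
            point_ellipsoid_distance(x, cell.surface) > dists[j] + 0.5
            for j, cell in enumerate(cells)
        )
        if ok:
            vari_rows.append(
                {"id": f"v{vid:04d}", "fiber_class": cfg.fiber_class,
                 "x": x[0], "y": x[1], "z": x[2]}
            )
            vid += 1
            placed += 1
    if placed < n_extra:
        raise ValueError("could not place background varicosities; box too crowded")

    scene = Scene(cells=cells, varicosities=pd.DataFrame(vari_rows))
    return scene, pd.DataFrame(truth_rows)
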