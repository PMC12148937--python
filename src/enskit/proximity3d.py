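"""Shortest-distance quantification between nerve-fiber varicosities and
cell surfaces in 3D.

Reimplements the confocal-reconstruction workflow in which 3D surfaces are
built for epithelial cells (enterochromaffin, tuft) and labelled nerve
processes, and the shortest distance from each cell surface to any fiber
varicosity is measured. Varicosities are treated as points (their centres);
cell surfaces as ellipsoids (centre, semi-axes, optional rotation) or
triangulated meshes. All coordinates in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid optionally rotated by an orthonormal matrix."""

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray | None = None  # world = rotation @ body + center

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        if self.center.shape != (3,) or self.semi_axes.shape != (3,):
            raise ValueError("center and semi_axes must be 3-vectors")
        if np.any(~np.isfinite(self.center)) or np.any(self.semi_axes <= 0):
            raise ValueError("coordinates must be finite and semi-axes positive")
        if self.rotation is not None:
            self.rotation = np.asarray(self.rotation, dtype=float)
            if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
                raise ValueError("rotation must be orthonormal")

    def to_body(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        if self.rotation is not None:
            d = d @ self.rotation
        return d


@dataclass
class Cell:
    id: str
    cell_type: str
    surface: Ellipsoid | None = None
    mesh_vertices: np.ndarray | None = None
    mesh_faces: np.ndarray | None = None


@dataclass
class Scene:
    """3D cell bodies plus varicosity point clouds tagged by fiber class."""

    cells: list
    varicosities: pd.DataFrame  # columns: id, fiber_class, x, y, z
    voxel_size_um: float = 1.0

    def points(self, fiber_class: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        df = self.varicosities
        if fiber_class is not None:
            df = df[df["fiber_class"] == fiber_class]
        return df[["x", "y", "z"]].to_numpy(dtype=float), df["id"].to_numpy()

    @property
    def fiber_classes(self) -> list:
        return sorted(self.varicosities["fiber_class"].unique())

    # ------------------------------------------------------------------ I/O
    def to_json(self, path) -> None:
        obj = {
            "voxel_size_um": self.voxel_size_um,
            "cells": [
                {
                    "id": c.id,
                    "cell_type": c.cell_type,
                    "center": c.surface.center.tolist(),
                    "semi_axes": c.surface.semi_axes.tolist(),
                    "rotation": None
                    if c.surface.rotation is None
                    else c.surface.rotation.tolist(),
                }
                for c in self.cells
                if c.surface is not None
            ],
            "varicosities": self.varicosities.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Scene":
        with open(path) as fh:
            obj = json.load(fh)
        cells = [
            Cell(
                id=c["id"],
                cell_type=c["cell_type"],
                surface=Ellipsoid(
                    c["center"],
                    c["semi_axes"],
                    None if c.get("rotation") is None else np.array(c["rotation"]),
                ),
            )
            for c in obj["cells"]
        ]
        return cls(
            cells=cells,
            varicosities=pd.DataFrame(obj["varicosities"]),
            voxel_size_um=obj.get("voxel_size_um", 1.0),
        )


# ---------------------------------------------------------------- distances
def point_ellipsoid_distance(point: np.ndarray, ell: Ellipsoid) -> float:
    """Euclidean distance from a point to an ellipsoid surface.

    Points inside the ellipsoid have distance 0. The exterior foot point
    solves the Lagrange condition y_i = a_i^2 x_i / (a_i^2 + t) with the
    multiplier t the unique positive root of sum(a_i^2 x_i^2/(a_i^2+t)^2)=1,
    found by bracketed root-finding to 1e-12 relative tolerance.
    """
    x = ell.to_body(point)[0]
    a = ell.semi_axes
    q = float(np.sum((x / a) ** 2))
    if q <= 1.0:
        return 0.0

    def f(t: float) -> float:
        return float(np.sum((a * x) ** 2 / (a**2 + t) ** 2) - 1.0)

    hi = float(np.linalg.norm(x) * np.max(a) + np.max(a) ** 2)
    while f(hi) > 0:
        hi *= 2.0
    t = optimize.brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    y = a**2 * x / (a**2 + t)
    return float(np.linalg.norm(x - y))


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distances from many points to one triangle (Ericson's region test)."""
    a, b, c = tri
    ab, ac = b - a, c - a
    ap = points - a
    d1 = ap @ ab
    d2 = ap @ ac
    bp = points - b
    d3 = bp @ ab
    d4 = bp @ ac
    cp = points - c
    d5 = cp @ ab
    d6 = cp @ ac
    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
    closest[m] = a + v[m, None] * ab
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0.0)
    closest[m] = a + w[m, None] * ac
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom != 0, denom, 1.0), 0.0)
    closest[m] = b + w[m, None] * (c - b)
    done |= m
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = vb / denom
    w = vc / denom
    closest[m] = a + v[m, None] * ab + w[m, None] * ac
    return np.linalg.norm(points - closest, axis=1)


def point_mesh_distance(point: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> float:
    """Distance from a point to a triangulated surface (min over triangles)."""
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    best = np.inf
    for face in faces:
        d = _point_triangle_distance(pts, vertices[face])
        best = min(best, float(d[0]))
    return best


def shortest_distance(cell: Cell, points: np.ndarray, point_ids=None) -> tuple[float, object]:
    """Shortest distance (um) from a cell surface to any varicosity point.

    Returns the distance and the id (or index) of the nearest point.
    Points inside the surface give distance 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("varicosity point set is empty")
    if cell.surface is not None:
        dists = np.array([point_ellipsoid_distance(p, cell.surface) for p in points])
    elif cell.mesh_vertices is not None:
        dists = np.array(
            [point_mesh_distance(p, cell.mesh_vertices, cell.mesh_faces) for p in points]
        )
    else:
        raise ValueError(f"cell {cell.id} has no surface representation")
    i = int(np.argmin(dists))
    pid = point_ids[i] if point_ids is not None else i
    return float(dists[i]), pid


def distance_distribution(scene: Scene) -> pd.DataFrame:
    """Per (cell, fiber-class) shortest distances.

    Returns a long table with one row per cell x fiber class: the shortest
    distance, the nearest varicosity id, and the cell type. Minima are
    taken independently within each fiber class.
    """
    rows = []
    for cls in scene.fiber_classes:
        pts, ids = scene.points(cls)
        for cell in scene.cells:
            d, pid = shortest_distance(cell, pts, ids)
            rows.append(
                {
                    "cell": cell.id,
                    "cell_type": cell.cell_type,
                    "fiber_class": cls,
                    "shortest_distance_um": d,
                    "nearest_varicosity": pid,
                }
            )
    return pd.DataFrame(rows)


def summarize_distances(table: pd.DataFrame) -> pd.DataFrame:
    """Median/IQR and Gaussian-KDE summary per cell type x fiber class.

    KDE bandwidth follows Silverman's rule; degenerate groups (fewer than
    two distinct values) report NaN bandwidth.
    """
    out = []
    for (ctype, cls), grp in table.groupby(["cell_type", "fiber_class"]):
        d = grp["shortest_distance_um"].to_numpy()
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        try:
            kde = stats.gaussian_kde(d, bw_method="silverman")
            bw = float(kde.factor * d.std(ddof=1))
        except (np.linalg.LinAlgError, ValueError):
            bw = float("nan")
        out.append(
            {
                "cell_type": ctype,
                "fiber_class": cls,
                "n": len(d),
                "median_um": float(med),
                "iqr_um": float(q3 - q1),
                "kde_bandwidth_um": bw,
            }
        )
    return pd.DataFrame(out)


def compare_distances(dist_a: Sequence[float], dist_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U between two shortest-distance samples."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per group")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"mwu_stat": float(stat), "p": float(p), "n_a": int(a.size), "n_b": int(b.size)}
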