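"""Atlas registration and mapping.

Thin-plate-spline (TPS) registration from correspondence points, assignment
of mapped cell coordinates to 2D atlas-plate regions, shoelace (Gauss's
formula) region areas, and region volumes from aggregated areas times
section thickness.

Coordinate conventions: image pixels are 0-based with x right / y down;
atlas coordinates are in µm with x right / y up and the midline at x = 0
(x < 0 is the left hemisphere). The fitted transform absorbs the flip.
Registration along the rostro-caudal axis is plate snapping only: a slice
is matched to a single plate by its anterior-posterior coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from shapely.geometry import Point, Polygon


# --------------------------------------------------------------------------
# Thin-plate spline


class SingularTPSError(ValueError):
    """Control points are collinear or duplicated: TPS system is singular."""


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r, with U(0) = 0; computed as 0.5 * r^2 log r^2.
    out = np.zeros_like(r2, dtype=float)
    pos = r2 > 0
    out[pos] = 0.5 * r2[pos] * np.log(r2[pos])
    return out


@dataclass
class TPSTransform:
    """2D thin-plate-spline mapping fitted from point correspondences.

    With ``lam = 0`` the transform interpolates every control point exactly;
    ``lam > 0`` trades exactness for smoothness (useful for noisy clicked
    correspondences). With exactly three non-collinear points the kernel
    weights vanish and the map is the unique affine map.
    """

    source: np.ndarray          # (N, 2)
    target: np.ndarray          # (N, 2)
    lam: float
    weights: np.ndarray = field(repr=False)   # (N + 3, 2): kernel + affine

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_tps(self, points)


def fit_tps(source_points, target_points, lam: float = 0.0) -> TPSTransform:
    """Fit a 2D TPS from N >= 3 non-collinear correspondence points."""
    src = np.asarray(source_points, dtype=float)
    dst = np.asarray(target_points, dtype=float)
    if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
        raise ValueError("source and target must both be (N, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("at least 3 correspondence points are required")
    if lam < 0:
        raise ValueError("regularization lam must be >= 0")
    # Duplicate source points make K singular regardless of lam.
    d2 = np.sum((src[:, None, :] - src[None, :, :]) ** 2, axis=-1)
    if np.any(d2[~np.eye(n, dtype=bool)] == 0):
        raise SingularTPSError("duplicated source control points")
    P = np.hstack([np.ones((n, 1)), src])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise SingularTPSError("collinear source control points")
    K = _tps_kernel(d2) + lam * np.eye(n)
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 3, 2))
    b[:n] = dst
    try:
        w = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise SingularTPSError(str(exc)) from exc
    return TPSTransform(source=src, target=dst, lam=float(lam), weights=w)


def apply_tps(transform: TPSTransform, points) -> np.ndarray:
    """Map (M, 2) points through a fitted TPS."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (M, 2)")
    n = transform.source.shape[0]
    d2 = np.sum((pts[:, None, :] - transform.source[None, :, :]) ** 2, axis=-1)
    U = _tps_kernel(d2)                      # (M, N)
    P = np.hstack([np.ones((pts.shape[0], 1)), pts])
    return U @ transform.weights[:n] + P @ transform.weights[n:]


# --------------------------------------------------------------------------
# Atlas plates and region geometry


@dataclass
class RegionPolygon:
    acronym: str
    vertices: np.ndarray       # (V, 2) closed ring in atlas µm (first != last ok)
    hemisphere: str = "both"   # "left" | "right" | "both"


@dataclass
class AtlasPlate:
    """One coronal plate: labeled simple polygons at a given AP coordinate."""

    ap_coordinate: float                 # mm from bregma
    regions: list[RegionPolygon]

    def polygon(self, acronym: str) -> RegionPolygon:
        for reg in self.regions:
            if reg.acronym == acronym:
                return reg
        raise KeyError(acronym)

    # JSON: {"ap": .., "regions": [{"acronym": .., "hemisphere": ..,
    #                               "vertices": [[x, y], ...]}, ...]}
    @classmethod
    def from_json(cls, path: str | Path) -> "AtlasPlate":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            ap_coordinate=float(data["ap"]),
            regions=[
                RegionPolygon(
                    acronym=r["acronym"],
                    vertices=np.asarray(r["vertices"], dtype=float),
                    hemisphere=r.get("hemisphere", "both"),
                )
                for r in data["regions"]
            ],
        )

    def to_json(self, path: str | Path) -> None:
        data = {
            "ap": self.ap_coordinate,
            "regions": [
                {
                    "acronym": r.acronym,
                    "hemisphere": r.hemisphere,
                    "vertices": np.asarray(r.vertices, dtype=float).tolist(),
                }
                for r in self.regions
            ],
        }
        with open(path, "w") as fh:
            json.dump(data, fh)


def polygon_area(vertices) -> float:
    """Polygon area by the shoelace (Gauss's) formula; orientation-free."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
        raise ValueError("a simple polygon needs at least 3 (x, y) vertices")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def region_volume(areas_mm2, z_thickness_mm: float) -> float:
    """Region volume in mm³: summed per-slice areas × section thickness."""
    if z_thickness_mm <= 0:
        raise ValueError("z thickness must be positive")
    return float(np.sum(np.asarray(list(areas_mm2), dtype=float)) * z_thickness_mm)


def assign_region(points, plate: AtlasPlate) -> list[str | None]:
    """Label each (x, y) atlas-µm point with the acronym of the region
    containing it, or None when it falls in no polygon.

    Containment is the even-odd rule; points on a shared boundary are
    assigned to the first-listed polygon that covers them.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    polys = [(reg.acronym, Polygon(reg.vertices)) for reg in plate.regions]
    labels: list[str | None] = []
    for x, y in pts:
        pt = Point(float(x), float(y))
        label = None
        for acr, poly in polys:
            if poly.covers(pt):
                label = acr
                break
        labels.append(label)
    return labels


def hemisphere_of(x_um: float, midline_x: float = 0.0) -> str:
    """Hemisphere by sign of atlas x relative to the midline (left = x < 0)."""
    return "left" if x_um < midline_x else "right"
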