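"""Dual-channel 3D phantoms with ground truth.

Two morphologies are emulated: punctate filled-spherical staining (nuclear
IEG label) and somatic staining with dim dendritic/axonal processes
(cytoplasmic reporter). Cells are Gaussian-profile spheres on a noisy
background modulated by a low-frequency illumination gradient; the defaults
mirror a 1.08 × 1.08 µm lateral / 3 µm axial confocal geometry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from ..segment3d import SegmentedObject, VoxelStack


class PlacementError(RuntimeError):
    """Requested cell count cannot be placed at the required separation."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} cells at the "
            f"required minimum separation; reduce n_cells or the separation"
        )


@dataclass
class PhantomSpec:
    """Conditions for one phantom stack.

    ``snr`` is the cell peak amplitude divided by the background noise SD.
    Process parameters are used only by the soma+process generator.
    """

    n_cells: int = 20
    shape: tuple[int, int, int] = (16, 128, 128)          # (z, y, x)
    voxel_size: tuple[float, float, float] = (1.08, 1.08, 3.0)  # (x, y, z) µm
    radius_um: float = 6.0
    snr: float = 10.0
    amplitude: float = 200.0
    background: float = 100.0
    illumination_amplitude: float = 0.2   # fraction of the signal, low frequency
    min_separation_factor: float = 2.0    # centers >= factor * radius apart
    seed: int = 0
    # soma + process morphology
    n_processes: int = 3
    process_length_um: float = 40.0
    process_intensity_factor: float = 0.4
    process_sigma_um: float = 1.2


@dataclass
class TruthCell:
    x_vox: float
    y_vox: float
    z_vox: float
    radius_um: float
    channel: str

    def center_um(self, voxel_size) -> tuple[float, float, float]:
        vx, vy, vz = voxel_size
        return (self.x_vox * vx, self.y_vox * vy, self.z_vox * vz)


@dataclass
class PhantomTruth:
    """Ground truth: every planted cell and every designed channel pair."""

    cells: list[TruthCell]
    coloc_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (1.08, 1.08, 3.0)

    def channel_cells(self, channel: str) -> list[TruthCell]:
        return [c for c in self.cells if c.channel == channel]

    def centers_um(self, channel: str | None = None) -> np.ndarray:
        cells = self.cells if channel is None else self.channel_cells(channel)
        return np.array([c.center_um(self.voxel_size) for c in cells]).reshape(-1, 3)


# --------------------------------------------------------------------------
# placement and rendering helpers


def _place_centers(
    spec: PhantomSpec,
    rng: np.random.Generator,
    existing_um: np.ndarray | None = None,
    n: int | None = None,
) -> np.ndarray:
    """Rejection-sample cell centers (µm, xyz) with a minimum separation."""
    n = spec.n_cells if n is None else n
    vx, vy, vz = spec.voxel_size
    nz, ny, nx = spec.shape
    extent = np.array([nx * vx, ny * vy, nz * vz])
    margin = spec.radius_um
    if np.any(extent < 2 * margin) and n > 0:
        raise PlacementError(n, 0)
    min_sep = spec.min_separation_factor * spec.radius_um
    placed: list[np.ndarray] = []
    anchors = existing_um if existing_um is not None else np.empty((0, 3))
    tries_per_cell = 500
    for _ in range(n):
        ok = False
        for _ in range(tries_per_cell):
            cand = margin + rng.random(3) * (extent - 2 * margin)
            pool = placed + ([*anchors] if len(anchors) else [])
            if all(np.linalg.norm(cand - p) >= min_sep for p in pool):
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise PlacementError(n, len(placed))
    return np.array(placed).reshape(-1, 3)


def _stamp_sphere(canvas: np.ndarray, center_um, spec: PhantomSpec,
                  amplitude: float) -> None:
    """Add a Gaussian-profile sphere (sigma = radius / 2) onto the canvas."""
    vx, vy, vz = spec.voxel_size
    cx, cy, cz = center_um
    sig = spec.radius_um / 2.0
    reach = 1.5 * spec.radius_um
    nz, ny, nx = canvas.shape
    z0, z1 = max(0, int((cz - reach) / vz)), min(nz, int((cz + reach) / vz) + 2)
    y0, y1 = max(0, int((cy - reach) / vy)), min(ny, int((cy + reach) / vy) + 2)
    x0, x1 = max(0, int((cx - reach) / vx)), min(nx, int((cx + reach) / vx) + 2)
    zz = (np.arange(z0, z1) * vz - cz)[:, None, None]
    yy = (np.arange(y0, y1) * vy - cy)[None, :, None]
    xx = (np.arange(x0, x1) * vx - cx)[None, None, :]
    d2 = zz**2 + yy**2 + xx**2
    canvas[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-d2 / (2 * sig**2))


def _stamp_blob_max(canvas: np.ndarray, center_um, spec: PhantomSpec,
                    amplitude: float, sigma_um: float) -> None:
    """Max-combine a small Gaussian blob (filament cross-section)."""
    vx, vy, vz = spec.voxel_size
    cx, cy, cz = center_um
    reach = 2.5 * sigma_um
    nz, ny, nx = canvas.shape
    z0, z1 = max(0, int((cz - reach) / vz)), min(nz, int((cz + reach) / vz) + 2)
    y0, y1 = max(0, int((cy - reach) / vy)), min(ny, int((cy + reach) / vy) + 2)
    x0, x1 = max(0, int((cx - reach) / vx)), min(nx, int((cx + reach) / vx) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz = (np.arange(z0, z1) * vz - cz)[:, None, None]
    yy = (np.arange(y0, y1) * vy - cy)[None, :, None]
    xx = (np.arange(x0, x1) * vx - cx)[None, None, :]
    d2 = zz**2 + yy**2 + xx**2
    blob = amplitude * np.exp(-d2 / (2 * sigma_um**2))
    np.maximum(canvas[z0:z1, y0:y1, x0:x1], blob, out=canvas[z0:z1, y0:y1, x0:x1])


def _illumination_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative low-frequency gradient, one lateral period, random phase."""
    nz, ny, nx = spec.shape
    theta = rng.uniform(0, 2 * np.pi)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:ny, 0:nx]
    wave = np.sin(
        2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / max(ny, nx) + phase
    )
    return (1.0 + spec.illumination_amplitude * wave)[None, :, :]


def _assemble(spec: PhantomSpec, signal: np.ndarray,
              rng: np.random.Generator) -> VoxelStack:
    field2d = _illumination_field(spec, rng)
    noise_sd = spec.amplitude / spec.snr
    data = (spec.background + signal) * field2d + rng.normal(
        0.0, noise_sd, size=spec.shape
    )
    return VoxelStack(
        data=np.clip(data, 0, None).astype(np.float32),
        voxel_size=spec.voxel_size,
    )


def _truth_cells(centers_um: np.ndarray, spec: PhantomSpec, channel: str) -> list[TruthCell]:
    vx, vy, vz = spec.voxel_size
    return [
        TruthCell(x / vx, y / vy, z / vz, spec.radius_um, channel)
        for x, y, z in centers_um
    ]


# --------------------------------------------------------------------------
# generators


def make_punctate_stack(spec: PhantomSpec) -> tuple[VoxelStack, PhantomTruth]:
    """Punctate phantom: filled-spherical cells on a noisy background."""
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    signal = np.zeros(spec.shape, dtype=np.float64)
    for c in centers:
        _stamp_sphere(signal, c, spec, spec.amplitude)
    stack = _assemble(spec, signal, rng)
    stack.channel_name = "punctate"
    truth = PhantomTruth(
        cells=_truth_cells(centers, spec, "punctate"), voxel_size=spec.voxel_size
    )
    return stack, truth


def make_soma_process_stack(spec: PhantomSpec) -> tuple[VoxelStack, PhantomTruth]:
    """Soma phantom: bright somata plus dimmer random-walk filaments.

    Filaments start at the soma surface and wander with persistent random
    steps; their peak intensity is ``process_intensity_factor`` of the soma
    amplitude. Truth lists soma centers only.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    somata = np.zeros(spec.shape, dtype=np.float64)
    filaments = np.zeros(spec.shape, dtype=np.float64)
    step = 2.0  # µm per random-walk step
    for c in centers:
        _stamp_sphere(somata, c, spec, spec.amplitude)
        for _ in range(spec.n_processes):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = c + direction * spec.radius_um
            for _ in range(int(spec.process_length_um / step)):
                _stamp_blob_max(
                    filaments, pos, spec,
                    spec.process_intensity_factor * spec.amplitude,
                    spec.process_sigma_um,
                )
                direction = direction + 0.5 * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = pos + direction * step
    stack = _assemble(spec, np.maximum(somata, filaments), rng)
    stack.channel_name = "soma"
    truth = PhantomTruth(
        cells=_truth_cells(centers, spec, "soma"), voxel_size=spec.voxel_size
    )
    return stack, truth


def _equal_sphere_overlap_fraction(radius: float, distance: float) -> float:
    """Intersection volume of two equal spheres as a fraction of one sphere."""
    if distance >= 2 * radius:
        return 0.0
    lens = np.pi * (4 * radius + distance) * (2 * radius - distance) ** 2 / 12.0
    return float(np.clip(lens / (4.0 / 3.0 * np.pi * radius**3), 0.0, 1.0))


def make_dual_channel(
    spec: PhantomSpec,
    overlap_fraction: float,
    jitter_um: float = 0.0,
) -> tuple[VoxelStack, VoxelStack, PhantomTruth]:
    """Two punctate channels where a designed fraction of channel-2 cells
    share centers (within ``jitter_um``) with channel-1 cells.

    The truth records each designed pair with its designed fractional
    overlap (1.0 at zero jitter, the analytic equal-sphere intersection
    fraction otherwise).
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    centers1 = _place_centers(spec, rng)
    n = spec.n_cells
    n_pair = int(round(overlap_fraction * n))
    paired_idx = rng.choice(n, size=n_pair, replace=False) if n_pair else np.array([], int)

    centers2 = np.empty((0, 3))
    pairs: list[tuple[int, int, float]] = []
    jitters = []
    for j, i1 in enumerate(sorted(paired_idx.tolist())):
        offset = np.zeros(3)
        if jitter_um > 0:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = direction * jitter_um
        centers2 = np.vstack([centers2, centers1[i1] + offset])
        pairs.append(
            (i1, j, _equal_sphere_overlap_fraction(spec.radius_um, float(np.linalg.norm(offset))))
        )
        jitters.append(offset)
    if n - n_pair > 0:
        extra = _place_centers(
            spec, rng,
            existing_um=np.vstack([centers1, centers2]) if len(centers2) else centers1,
            n=n - n_pair,
        )
        centers2 = np.vstack([centers2, extra]) if len(centers2) else extra

    sig1 = np.zeros(spec.shape, dtype=np.float64)
    for c in centers1:
        _stamp_sphere(sig1, c, spec, spec.amplitude)
    sig2 = np.zeros(spec.shape, dtype=np.float64)
    for c in centers2:
        _stamp_sphere(sig2, c, spec, spec.amplitude)
    stack1 = _assemble(spec, sig1, rng)
    stack2 = _assemble(spec, sig2, rng)
    stack1.channel_name = "ch1"
    stack2.channel_name = "ch2"
    truth = PhantomTruth(
        cells=_truth_cells(centers1, spec, "ch1") + _truth_cells(centers2, spec, "ch2"),
        coloc_pairs=pairs,
        voxel_size=spec.voxel_size,
    )
    return stack1, stack2, truth


# --------------------------------------------------------------------------
# evaluation against truth


def evaluate_detection(
    objects: list[SegmentedObject],
    truth: PhantomTruth,
    channel: str | None = None,
    max_dist_um: float | None = None,
) -> dict[str, float]:
    """Match detected centroids to planted centers (Hungarian assignment,
    gated by ``max_dist_um``, default one cell radius) and report TP/FP/FN
    with precision and recall."""
    cells = truth.cells if channel is None else truth.channel_cells(channel)
    if max_dist_um is None:
        max_dist_um = cells[0].radius_um if cells else 1.0
    det = np.array([o.centroid_um for o in objects]).reshape(-1, 3)
    ref = (
        np.array([c.center_um(truth.voxel_size) for c in cells]).reshape(-1, 3)
    )
    tp = 0
    if len(det) and len(ref):
        dist = cdist(det, ref)
        cost = np.where(dist <= max_dist_um, dist, 1e9)
        rows, cols = linear_sum_assignment(cost)
        tp = int(np.sum(dist[rows, cols] <= max_dist_um))
    fp = len(det) - tp
    fn = len(ref) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}


def write_truth_table(truth: PhantomTruth, path: str | Path) -> None:
    """CSV: id, x, y, z (voxels), radius_um, channel."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "z", "radius_um", "channel"])
        for i, c in enumerate(truth.cells):
            writer.writerow([i, c.x_vox, c.y_vox, c.z_vox, c.radius_um, c.channel])
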