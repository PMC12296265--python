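"""3D cell segmentation for two staining morphologies, object-based
colocalization, and validation arithmetic.

Two algorithms mirror the two label morphologies of a dual-ensemble tagging
experiment:

* punctate, filled-spherical nuclear staining (c-Fos-like) — Fourier
  bandpass, per-plane rolling-ball background subtraction, 3D local-maxima
  seeding and spot growth;
* somatic staining with dendritic/axonal processes (eYFP-like) — background
  subtraction, 3D Gaussian blur, top-percentile thresholding, and watershed
  splitting of the mask. Processes are suppressed because their blurred
  intensity falls below the brightest-pixel cutoff.

Candidate co-labeled cells are enumerated from the two channels' label
volumes and filtered by percent volume overlap relative to the channel-2
object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import difference_of_gaussians
from skimage.morphology import disk, opening
from skimage.segmentation import watershed


# --------------------------------------------------------------------------
# Core containers


@dataclass
class VoxelStack:
    """One channel's 3D intensity grid with its physical voxel size.

    ``data`` is ordered (z, y, x); ``voxel_size`` is (x, y, z) in µm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.08, 1.08, 3.0)
    channel_name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("stack must be a 3D (z, y, x) array")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    def to_tiff(self, path: str | Path) -> None:
        vx, vy, vz = self.voxel_size
        tifffile.imwrite(
            str(path),
            self.data.astype(np.float32),
            imagej=True,
            resolution=(1.0 / vx, 1.0 / vy),
            metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
        )

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        voxel_size: tuple[float, float, float] | None = None,
        channel_name: str = "",
    ) -> "VoxelStack":
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            if voxel_size is None:
                page = tif.pages[0]
                xres = page.tags.get("XResolution")
                yres = page.tags.get("YResolution")
                meta = tif.imagej_metadata or {}
                if xres is None or "spacing" not in meta:
                    raise ValueError(
                        "TIFF carries no voxel size; pass voxel_size explicitly"
                    )
                vx = xres.value[1] / xres.value[0]
                vy = yres.value[1] / yres.value[0] if yres else vx
                voxel_size = (vx, vy, float(meta["spacing"]))
        if data.ndim == 2:
            data = data[None]
        return cls(data=data, voxel_size=voxel_size, channel_name=channel_name)


@dataclass
class SegmentedObject:
    object_id: int
    channel: str
    centroid_um: tuple[float, float, float]   # (x, y, z)
    voxel_count: int
    volume_um3: float
    peak_intensity: float


@dataclass
class SegmentationResult:
    """Objects plus the label volume they were cut from (ids match labels)."""

    objects: list[SegmentedObject]
    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.objects)

    def __iter__(self):
        return iter(self.objects)


@dataclass
class ColocRecord:
    id_ch1: int
    id_ch2: int
    overlap_voxels: int
    percent_overlap: float    # overlap volume as % of the channel-2 object


@dataclass
class ValidationCounts:
    tp: float
    fp: float
    fn: float
    precision: float
    recall: float
    f1: float
    tp_estimate_a: float
    tp_estimate_b: float


# --------------------------------------------------------------------------
# Parameters

# Stage names mirror the upstream batch macros; values are the adjustable
# defaults for the 1.08 × 1.08 × 3 µm imaging geometry.


@dataclass
class PunctateParams:
    bandpass_small: float = 2.0       # lateral pass band, voxels
    bandpass_large: float = 20.0
    rolling_ball_radius: int = 15     # voxels, per z-plane
    maxima_radius: float = 4.0        # lateral min seed separation, voxels
    seed_snr: float = 5.0             # seeds exceed median + snr * robust sigma
    seed_floor_fraction: float = 0.2  # ... and this fraction of the global max
    growth_fraction: float = 0.5      # grow down to this fraction of the seed
    min_volume_voxels: int = 30
    max_volume_voxels: int | None = None
    edge_margin: int = 0              # lateral voxels excluded at the border


@dataclass
class SomaParams:
    rolling_ball_radius: int = 15
    gaussian_sigma: float = 2.0       # lateral voxels; z scaled by anisotropy
    top_percent: float = 0.5          # brightest-pixel percentage
    maxima_radius: float = 5.0
    # the global percentile budget leaves dim cells only a small core, so the
    # soma minimum sits below the punctate default
    min_volume_voxels: int = 15
    max_volume_voxels: int | None = None
    edge_margin: int = 0


# --------------------------------------------------------------------------
# Stage primitives


def rolling_ball_subtract(data: np.ndarray, radius: int) -> np.ndarray:
    """Background subtraction: per-z-plane grayscale opening with a disk
    structuring element, subtracted from the original."""
    selem = disk(radius)
    out = np.empty_like(data, dtype=np.float32)
    for z in range(data.shape[0]):
        out[z] = data[z] - opening(data[z], selem)
    return out


def fourier_bandpass(data: np.ndarray, small: float, large: float) -> np.ndarray:
    """Lateral band-pass as a per-plane difference of Gaussians (the Fourier
    band-pass of the upstream macro is equivalent up to window shape)."""
    out = np.empty_like(data, dtype=np.float32)
    for z in range(data.shape[0]):
        out[z] = difference_of_gaussians(data[z], small / 2.0, large / 2.0)
    return out


def top_percentile_threshold(stack: VoxelStack | np.ndarray, percent: float) -> np.ndarray:
    """Binary mask of the brightest ``percent`` % voxels.

    The cutoff is the order statistic leaving at most floor(n × percent/100)
    voxels strictly above it, and the comparison is strict: a constant image
    yields an empty mask and the selected fraction never exceeds
    percent / 100 (ties shrink the selection further).
    """
    if not 0 < percent < 100:
        raise ValueError("percent must lie strictly between 0 and 100")
    data = stack.data if isinstance(stack, VoxelStack) else np.asarray(stack)
    m = int(np.floor(data.size * percent / 100.0))
    if m == 0:
        return np.zeros(data.shape, dtype=bool)
    flat = data.reshape(-1)
    idx = data.size - m - 1
    cutoff = np.partition(flat, idx)[idx]
    return data > cutoff


def _anisotropic_footprint(lateral_radius: float, voxel_size) -> np.ndarray:
    """Ellipsoidal neighborhood matching a lateral radius in voxels."""
    vx, _, vz = voxel_size
    rz = max(1, int(round(lateral_radius * vx / vz)))
    rl = max(1, int(round(lateral_radius)))
    zz, yy, xx = np.mgrid[-rz : rz + 1, -rl : rl + 1, -rl : rl + 1]
    return (xx / rl) ** 2 + (yy / rl) ** 2 + (zz / rz) ** 2 <= 1.0


_CONN26 = np.ones((3, 3, 3), dtype=bool)   # 26-neighborhood labeling


def _objects_from_labels(
    labels: np.ndarray,
    reference: np.ndarray,
    voxel_size,
    channel: str,
    min_volume: int,
    max_volume: int | None,
    edge_margin: int,
) -> SegmentationResult:
    """Measure labeled regions, apply volume and edge filters, relabel 1..K."""
    vx, vy, vz = voxel_size
    out_labels = np.zeros_like(labels, dtype=np.int32)
    objects: list[SegmentedObject] = []
    ny, nx = labels.shape[1], labels.shape[2]
    next_id = 1
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size:
        centroids = ndi.center_of_mass(np.ones_like(labels), labels, ids)
        counts = ndi.sum_labels(np.ones_like(labels), labels, ids)
        peaks = ndi.maximum(reference, labels, ids)
        for lid, (cz, cy, cx), cnt, pk in zip(ids, np.atleast_2d(centroids), counts, peaks):
            cnt = int(cnt)
            if cnt < min_volume:
                continue
            if max_volume is not None and cnt > max_volume:
                continue
            if edge_margin > 0 and (
                cx < edge_margin
                or cy < edge_margin
                or cx > nx - 1 - edge_margin
                or cy > ny - 1 - edge_margin
            ):
                continue
            out_labels[labels == lid] = next_id
            objects.append(
                SegmentedObject(
                    object_id=next_id,
                    channel=channel,
                    centroid_um=(cx * vx, cy * vy, cz * vz),
                    voxel_count=cnt,
                    volume_um3=cnt * vx * vy * vz,
                    peak_intensity=float(pk),
                )
            )
            next_id += 1
    return SegmentationResult(objects=objects, labels=out_labels, voxel_size=tuple(voxel_size))


# --------------------------------------------------------------------------
# The two morphology-specific algorithms


def segment_punctate(
    stack: VoxelStack, params: PunctateParams | None = None
) -> SegmentationResult:
    """Detect punctate filled-spherical cells.

    Stages, in order: (1) lateral Fourier band-pass, (2) per-plane
    rolling-ball background subtraction, (3) 3D local-maxima seeding,
    (4) spot growth around each seed down to a fractional-intensity cutoff
    (touching cells stay split along watershed lines), (5) volume filtering.
    An empty stack or one with no maxima yields an empty result.
    """
    params = params or PunctateParams()
    if min(stack.data.shape[1:]) <= params.bandpass_large:
        raise ValueError(
            f"stack lateral extent {stack.data.shape[1:]} is below the "
            f"band-pass support ({params.bandpass_large} voxels)"
        )
    filtered = fourier_bandpass(stack.data, params.bandpass_small, params.bandpass_large)
    filtered = rolling_ball_subtract(filtered, params.rolling_ball_radius)

    # Seeds must clear both the robust noise level and a fraction of the
    # brightest response (suppresses filter-ringing maxima on clean images).
    med = float(np.median(filtered))
    sigma = 1.4826 * float(np.median(np.abs(filtered - med))) + 1e-12
    thr = max(
        med + params.seed_snr * sigma,
        params.seed_floor_fraction * float(filtered.max()),
    )
    footprint = _anisotropic_footprint(params.maxima_radius, stack.voxel_size)
    seeds = peak_local_max(
        filtered, footprint=footprint, threshold_abs=thr, exclude_border=False
    )
    if seeds.shape[0] == 0:
        return SegmentationResult([], np.zeros_like(stack.data, dtype=np.int32),
                                  stack.voxel_size)

    markers = np.zeros_like(stack.data, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, seeds.shape[0] + 1)
    basins = watershed(-filtered, markers, mask=filtered > 0, connectivity=_CONN26)

    # Spot growth: inside each basin keep voxels above growth_fraction of the
    # seed intensity, retaining only the connected piece holding the seed.
    grown = np.zeros_like(basins, dtype=np.int32)
    for i, seed in enumerate(seeds, start=1):
        cut = params.growth_fraction * filtered[tuple(seed)]
        candidate = (basins == i) & (filtered >= cut)
        comp, _ = ndi.label(candidate, structure=_CONN26)
        keep = comp == comp[tuple(seed)]
        grown[keep] = i

    return _objects_from_labels(
        grown, stack.data, stack.voxel_size, stack.channel_name,
        params.min_volume_voxels, params.max_volume_voxels, params.edge_margin,
    )


def segment_soma(stack: VoxelStack, params: SomaParams | None = None) -> SegmentationResult:
    """Detect soma-staining cells while suppressing dendritic processes.

    Stages, in order: rolling-ball background subtraction, 3D Gaussian blur,
    top-percentile binary mask (brightest ``top_percent`` % voxels), watershed
    split of the mask seeded at blurred-intensity maxima, volume filtering.
    """
    params = params or SomaParams()
    if not 0 < params.top_percent < 100:
        raise ValueError("top_percent must lie strictly between 0 and 100")
    vx, _, vz = stack.voxel_size
    sub = rolling_ball_subtract(stack.data, params.rolling_ball_radius)
    sigma = (params.gaussian_sigma * vx / vz, params.gaussian_sigma, params.gaussian_sigma)
    blurred = ndi.gaussian_filter(sub, sigma=sigma)
    mask = top_percentile_threshold(blurred, params.top_percent)
    if not mask.any():
        return SegmentationResult([], np.zeros_like(stack.data, dtype=np.int32),
                                  stack.voxel_size)
    footprint = _anisotropic_footprint(params.maxima_radius, stack.voxel_size)
    seeds = peak_local_max(
        np.where(mask, blurred, 0.0), footprint=footprint, exclude_border=False
    )
    markers = np.zeros_like(stack.data, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, seeds.shape[0] + 1)
    labels = watershed(-blurred, markers, mask=mask, connectivity=_CONN26)
    return _objects_from_labels(
        labels, stack.data, stack.voxel_size, stack.channel_name,
        params.min_volume_voxels, params.max_volume_voxels, params.edge_margin,
    )


# --------------------------------------------------------------------------
# Object-based colocalization


def compute_pairwise_overlaps(
    labels_ch1: np.ndarray, labels_ch2: np.ndarray
) -> list[ColocRecord]:
    """Enumerate every pair of channel-1/channel-2 objects sharing >= 1 voxel.

    ``percent_overlap`` is the shared voxel count as a percentage of the
    channel-2 object's volume; a channel-2 object may appear in several
    records (one per overlapping channel-1 object).
    """
    l1 = np.asarray(labels_ch1)
    l2 = np.asarray(labels_ch2)
    if l1.shape != l2.shape:
        raise ValueError(f"label volumes differ in shape: {l1.shape} vs {l2.shape}")
    both = (l1 > 0) & (l2 > 0)
    if not both.any():
        return []
    a = l1[both].astype(np.int64)
    b = l2[both].astype(np.int64)
    key = a * (l2.max() + 1) + b
    uniq, counts = np.unique(key, return_counts=True)
    ch2_ids, ch2_sizes = np.unique(l2[l2 > 0], return_counts=True)
    size2 = dict(zip(ch2_ids.tolist(), ch2_sizes.tolist()))
    records = []
    for k, cnt in zip(uniq.tolist(), counts.tolist()):
        i1, i2 = divmod(k, int(l2.max()) + 1)
        records.append(
            ColocRecord(
                id_ch1=int(i1),
                id_ch2=int(i2),
                overlap_voxels=int(cnt),
                percent_overlap=100.0 * cnt / size2[i2],
            )
        )
    records.sort(key=lambda r: (r.id_ch1, r.id_ch2))
    return records


def threshold_coloc(records: list[ColocRecord], min_percent: float) -> list[ColocRecord]:
    """Keep candidate overlaps at or above ``min_percent`` percent volume.

    A channel-2 object surviving in several records counts as a single
    co-labeled cell: only its largest-overlap record is kept (ties broken
    toward the lower channel-1 id). The returned length is the co-labeled
    cell count.
    """
    if not 0 <= min_percent <= 100:
        raise ValueError("min_percent must lie in [0, 100]")
    surviving = [r for r in records if r.percent_overlap >= min_percent]
    best: dict[int, ColocRecord] = {}
    for rec in surviving:
        cur = best.get(rec.id_ch2)
        if cur is None or (rec.percent_overlap, -rec.id_ch1) > (
            cur.percent_overlap, -cur.id_ch1
        ):
            best[rec.id_ch2] = rec
    return sorted(best.values(), key=lambda r: r.id_ch2)


# --------------------------------------------------------------------------
# Validation against manual counts


class UndefinedMetricError(ZeroDivisionError):
    """Precision, recall, or F1 is undefined for these counts."""


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall: 1/F1 = (1/P + 1/R) / 2."""
    if precision <= 0 or recall <= 0:
        raise UndefinedMetricError("precision and recall must be positive for F1")
    return 2.0 * precision * recall / (precision + recall)


def validate_against_manual(
    auto_total: float, manual_total: float, fp: float, fn: float
) -> ValidationCounts:
    """Precision/recall/F1 from total automated and manual counts.

    The true-positive count is estimated as the mean of two derivations:
    (manual − FN) and (auto − FP).
    """
    if min(auto_total, manual_total, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    if fn > manual_total or fp > auto_total:
        raise ValueError("FN cannot exceed manual total nor FP the auto total")
    tp_a = manual_total - fn
    tp_b = auto_total - fp
    tp = 0.5 * (tp_a + tp_b)
    if tp + fp == 0 or tp + fn == 0:
        raise UndefinedMetricError("precision/recall undefined: no positives")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return ValidationCounts(
        tp=tp, fp=fp, fn=fn,
        precision=precision, recall=recall, f1=f1_score(precision, recall),
        tp_estimate_a=tp_a, tp_estimate_b=tp_b,
    )


# --------------------------------------------------------------------------
# Tab-separated object tables (the import dialect of the data model)

OBJECT_TABLE_COLUMNS = ["id", "x_um", "y_um", "z_um", "voxels", "volume_um3", "peak"]


def write_object_table(result: SegmentationResult, path: str | Path) -> None:
    rows = [
        {
            "id": o.object_id,
            "x_um": o.centroid_um[0],
            "y_um": o.centroid_um[1],
            "z_um": o.centroid_um[2],
            "voxels": o.voxel_count,
            "volume_um3": o.volume_um3,
            "peak": o.peak_intensity,
        }
        for o in result.objects
    ]
    pd.DataFrame(rows, columns=OBJECT_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_coloc_table(records: list[ColocRecord], path: str | Path) -> None:
    rows = [
        {
            "id_ch1": r.id_ch1,
            "id_ch2": r.id_ch2,
            "overlap_voxels": r.overlap_voxels,
            "percent_overlap": r.percent_overlap,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["id_ch1", "id_ch2", "overlap_voxels", "percent_overlap"]
    ).to_csv(path, sep="\t", index=False)
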