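"""Hierarchical experiment data model.

Slice records hold imaging metadata, imported segmentation objects, the
registration transform, and per-hemisphere exclusion annotations; mouse
records hold slices; the experiment record holds mice from exactly two
groups. Downstream of mapping, regional counts are aggregated across a
mouse's slices, normalized by mapped region volume to cells per mm³,
cleaned with a ±k-SD group outlier rule, and restricted to regions
represented in both groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from .ontology import Ontology
from .segment3d import ColocRecord, SegmentedObject

logger = logging.getLogger(__name__)

#: regions never expected to contain labeled cells (plus their descendants)
ALWAYS_EXCLUDED = ("fiber tracts", "VS")

COLUMNS = ["mouse_id", "group", "region", "channel", "count", "volume_mm3", "density"]


class IntegrityError(RuntimeError):
    pass


@dataclass
class RegionCountTable:
    """Long-form table: one row per (mouse, region, channel) with the raw
    count, the mapped region volume in mm³, and the density in cells/mm³."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"RegionCountTable missing columns {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        if (self.df["volume_mm3"] <= 0).any():
            raise IntegrityError("retained rows must have positive region volume")

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "RegionCountTable":
        df = pd.DataFrame(rows)
        if "density" not in df.columns:
            df["density"] = df["count"] / df["volume_mm3"]
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionCountTable":
        return cls(pd.read_csv(path))

    @property
    def mice(self) -> list[str]:
        return sorted(self.df["mouse_id"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.df["region"].unique())

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SliceRecord:
    slice_id: str
    ap_coordinate: float                    # mm from bregma
    z_thickness_um: float
    channel_names: list[str]
    image_path: str = ""
    objects: dict[str, list[SegmentedObject]] = field(default_factory=dict)
    coloc: list[ColocRecord] = field(default_factory=list)
    registration: atlas_mod.TPSTransform | None = None
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (acronym, hemi)
    # populated by map_slice:
    region_counts: pd.DataFrame | None = None   # region, hemisphere, channel, count
    region_areas: pd.DataFrame | None = None    # region, hemisphere, area_mm2

    def __post_init__(self):
        if self.z_thickness_um <= 0:
            raise ValueError("z thickness must be positive")


@dataclass
class MouseRecord:
    mouse_id: str
    group: str
    slices: list[SliceRecord] = field(default_factory=list)
    sex: str = ""

    def __post_init__(self):
        ids = [s.slice_id for s in self.slices]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate slice ids within mouse {self.mouse_id}")


@dataclass
class ExperimentRecord:
    mice: list[MouseRecord]
    channels: list[str]
    ontology: Ontology

    def __post_init__(self):
        groups = {m.group for m in self.mice}
        if len(groups) > 2:
            raise ValueError(
                f"group-wise analyses require at most two groups, got {sorted(groups)}"
            )

    @property
    def groups(self) -> list[str]:
        return sorted({m.group for m in self.mice})

    def group_mice(self, group: str) -> list[MouseRecord]:
        return [m for m in self.mice if m.group == group]


# --------------------------------------------------------------------------
# segmentation import


def import_object_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    channel: str = "",
) -> list[SegmentedObject]:
    """Read a tab-separated segmented-object table.

    The native dialect has columns id, x_um, y_um, z_um, voxels, volume_um3,
    peak; ``column_map`` remaps external exports (e.g. an ImageJ 3D-suite
    results table) onto those names. Zero-volume rows are dropped with a
    logged warning rather than treated as errors.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = ["id", "x_um", "y_um", "z_um", "voxels", "volume_um3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"object table {path} is missing column(s) {missing}")
    zero = df["voxels"] <= 0
    if zero.any():
        logger.warning(
            "dropping %d zero-volume object(s) from %s", int(zero.sum()), path
        )
        df = df[~zero]
    return [
        SegmentedObject(
            object_id=int(r.id),
            channel=channel,
            centroid_um=(float(r.x_um), float(r.y_um), float(r.z_um)),
            voxel_count=int(r.voxels),
            volume_um3=float(r.volume_um3),
            peak_intensity=float(getattr(r, "peak", 0.0)),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------
# exclusion handling


def exclude_regions(
    slice_rec: SliceRecord,
    acronyms: list[str],
    hemisphere: str,
    ontology: Ontology,
) -> SliceRecord:
    """Annotate misaligned or damaged regions for omission.

    Acronyms are validated against the ontology (misspellings raise with
    nearest matches); the exclusion later propagates to all descendants of
    each acronym. ``hemisphere`` is "left", "right", or "both".
    """
    if hemisphere not in ("left", "right", "both"):
        raise ValueError("hemisphere must be 'left', 'right' or 'both'")
    for acr in acronyms:
        ontology.validate(acr)
    new = list(slice_rec.excluded) + [(a, hemisphere) for a in acronyms]
    return replace(slice_rec, excluded=new)


def _expand_exclusions(
    excluded: list[tuple[str, str]], ontology: Ontology
) -> set[tuple[str, str]]:
    out: set[tuple[str, str]] = set()
    for acr, hemi in excluded:
        hemis = ("left", "right") if hemi == "both" else (hemi,)
        for sub in ontology.descendants(acr):
            for h in hemis:
                out.add((sub, h))
    return out


# --------------------------------------------------------------------------
# mapping a slice onto an atlas plate


def map_slice(
    slice_rec: SliceRecord,
    plate: atlas_mod.AtlasPlate,
    coloc_channel: str = "colabel",
) -> SliceRecord:
    """Warp the slice's objects into atlas space and tally per-region counts.

    Requires a fitted registration. Objects land in the region (and
    hemisphere, by sign of atlas x) whose polygon contains their warped
    centroid; unassigned objects are dropped from the tallies. Region areas
    come from Gauss's (shoelace) formula on the plate polygons.
    """
    if slice_rec.registration is None:
        raise ValueError(f"slice {slice_rec.slice_id} is not registered")
    rows = []
    per_channel: dict[str, list[SegmentedObject]] = dict(slice_rec.objects)
    if slice_rec.coloc:
        ch2 = slice_rec.channel_names[1] if len(slice_rec.channel_names) > 1 else None
        by_id = {o.object_id: o for o in per_channel.get(ch2, [])} if ch2 else {}
        per_channel[coloc_channel] = [
            by_id[r.id_ch2] for r in slice_rec.coloc if r.id_ch2 in by_id
        ]
    for channel, objs in per_channel.items():
        if not objs:
            continue
        xy = np.array([[o.centroid_um[0], o.centroid_um[1]] for o in objs])
        warped = atlas_mod.apply_tps(slice_rec.registration, xy)
        labels = atlas_mod.assign_region(warped, plate)
        for (x, _y), label in zip(warped, labels):
            if label is None:
                continue
            rows.append(
                {
                    "region": label,
                    "hemisphere": atlas_mod.hemisphere_of(x),
                    "channel": channel,
                    "count": 1,
                }
            )
    counts = (
        pd.DataFrame(rows)
        .groupby(["region", "hemisphere", "channel"], as_index=False)["count"]
        .sum()
        if rows
        else pd.DataFrame(columns=["region", "hemisphere", "channel", "count"])
    )
    areas = pd.DataFrame(
        [
            {
                "region": reg.acronym,
                "hemisphere": (
                    reg.hemisphere
                    if reg.hemisphere in ("left", "right")
                    else atlas_mod.hemisphere_of(float(np.mean(np.asarray(reg.vertices)[:, 0])))
                ),
                "area_mm2": atlas_mod.polygon_area(reg.vertices) / 1e6,
            }
            for reg in plate.regions
        ]
    )
    return replace(slice_rec, region_counts=counts, region_areas=areas)


# --------------------------------------------------------------------------
# aggregation and normalization


def aggregate_normalize(
    mouse: MouseRecord,
    ontology: Ontology,
    always_exclude: tuple[str, ...] = ALWAYS_EXCLUDED,
) -> RegionCountTable:
    """Aggregate mapped counts across a mouse's slices and normalize.

    Per region and channel: count = Σ over slices, volume = Σ over slices of
    area × section thickness, density = count / volume. Annotated exclusions
    (propagated down the ontology tree, per hemisphere) and the
    always-excluded structures are removed before summing. A region with
    counts but zero mapped volume is an integrity error.
    """
    drop: set[tuple[str, str]] = set()
    always = [a for a in always_exclude if a in ontology]
    count_frames = []
    volume_frames = []
    for sl in mouse.slices:
        if sl.region_counts is None or sl.region_areas is None:
            raise ValueError(
                f"slice {sl.slice_id} of mouse {mouse.mouse_id} is not mapped"
            )
        drop = _expand_exclusions(
            sl.excluded + [(a, "both") for a in always], ontology
        )
        counts = sl.region_counts
        if len(counts):
            keep = ~counts.apply(
                lambda r: (r["region"], r["hemisphere"]) in drop, axis=1
            )
            count_frames.append(counts[keep])
        areas = sl.region_areas
        keep_a = ~areas.apply(lambda r: (r["region"], r["hemisphere"]) in drop, axis=1)
        areas = areas[keep_a].copy()
        areas["volume_mm3"] = areas["area_mm2"] * sl.z_thickness_um / 1000.0
        volume_frames.append(areas)

    counts = (
        pd.concat(count_frames).groupby(["region", "channel"], as_index=False)["count"].sum()
        if count_frames
        else pd.DataFrame(columns=["region", "channel", "count"])
    )
    volumes = (
        pd.concat(volume_frames).groupby("region", as_index=False)["volume_mm3"].sum()
        if volume_frames
        else pd.DataFrame(columns=["region", "volume_mm3"])
    )
    merged = counts.merge(volumes, on="region", how="left")
    bad = merged["volume_mm3"].isna() | (merged["volume_mm3"] <= 0)
    if bad.any():
        raise IntegrityError(
            f"regions with counts but no mapped volume: "
            f"{sorted(merged.loc[bad, 'region'].unique())}"
        )
    merged["mouse_id"] = mouse.mouse_id
    merged["group"] = mouse.group
    merged["density"] = merged["count"] / merged["volume_mm3"]
    return RegionCountTable(merged[COLUMNS])


def concat_tables(tables: list[RegionCountTable]) -> RegionCountTable:
    return RegionCountTable(pd.concat([t.df for t in tables], ignore_index=True))


# --------------------------------------------------------------------------
# quality checking


def remove_outliers(table: RegionCountTable, k: float = 2.0) -> RegionCountTable:
    """Drop rows whose density lies more than k group-sample SDs from the
    (group, region, channel) mean.

    Single pass: the mean and SD include the candidate row and are not
    recomputed after removals. Sample SD uses n − 1; an all-equal group
    (SD = 0) removes nothing.
    """
    df = table.df.copy()

    def flag(group: pd.Series) -> pd.Series:
        if len(group) < 2:
            return pd.Series(False, index=group.index)
        sd = group.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            return pd.Series(False, index=group.index)
        return (group - group.mean()).abs() > k * sd

    outlier = df.groupby(["group", "region", "channel"])["density"].transform(flag)
    return RegionCountTable(df[~outlier.astype(bool)])


def shared_regions_filter(
    table_a: RegionCountTable,
    table_b: RegionCountTable,
    min_mice: int | None = None,
) -> tuple[RegionCountTable, RegionCountTable]:
    """Keep only (region, channel) pairs represented in both groups.

    By default "represented" means every mouse of each group has a retained
    row for the pair; pass ``min_mice`` to relax to at-least-that-many mice
    per group. Disjoint region sets raise.
    """
    if not len(table_a) or not len(table_b):
        raise ValueError("both group tables must be nonempty")

    def eligible(table: RegionCountTable) -> set[tuple[str, str]]:
        need = len(table.mice) if min_mice is None else min_mice
        counts = table.df.groupby(["region", "channel"])["mouse_id"].nunique()
        return {pair for pair, n in counts.items() if n >= need}

    shared = eligible(table_a) & eligible(table_b)
    if not shared:
        raise ValueError("no (region, channel) pair is represented in both groups")

    def restrict(table: RegionCountTable) -> RegionCountTable:
        keep = table.df.apply(
            lambda r: (r["region"], r["channel"]) in shared, axis=1
        )
        return RegionCountTable(table.df[keep])

    return restrict(table_a), restrict(table_b)


def reactivation_proportions(
    table: RegionCountTable,
    coloc_channel: str = "colabel",
    reference_channel: str = "ch1",
) -> RegionCountTable:
    """Per region and mouse: co-labeled count divided by the reference
    channel's count, carried as a density-like value (the ratio is
    volume-invariant because both channels share the mapped volume)."""
    df = table.df
    co = df[df["channel"] == coloc_channel].set_index(["mouse_id", "region"])
    ref = df[df["channel"] == reference_channel].set_index(["mouse_id", "region"])
    joined = co.join(ref, lsuffix="_co", rsuffix="_ref", how="inner")
    joined = joined[joined["count_ref"] > 0]
    out = joined.reset_index()
    out["channel"] = f"{coloc_channel}/{reference_channel}"
    out["count"] = out["count_co"]
    out["volume_mm3"] = out["volume_mm3_co"]
    out["density"] = out["count_co"] / out["count_ref"]
    out["group"] = out["group_co"]
    return RegionCountTable(out[COLUMNS])
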