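"""Toy atlas plates: labeled, non-overlapping polygons with a matching
ontology subtree. Stands in for full vectorized reference plates so that
registration and mapping can be exercised with exact expected areas."""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

from ..atlas import AtlasPlate, RegionPolygon
from ..ontology import Ontology, RegionNode


def make_toy_atlas_plate(
    layout: list[dict],
    ap_coordinate: float = 0.0,
    parent_acronym: str = "root",
) -> tuple[AtlasPlate, Ontology]:
    """Build a plate from a layout of labeled polygons.

    ``layout`` entries: {"acronym": str, "vertices": [[x, y], ...] in µm,
    optional "hemisphere", optional "parent"}. Polygons must not overlap
    (shared boundaries are allowed); an empty layout is an error. Returns
    the plate plus the ontology subtree it uses (entries without an explicit
    parent hang off ``parent_acronym``).
    """
    if not layout:
        raise ValueError("empty atlas layout")
    regions = []
    shapes = []
    for entry in layout:
        verts = np.asarray(entry["vertices"], dtype=float)
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"region {entry['acronym']!r} is not a simple polygon")
        shapes.append((entry["acronym"], poly))
        regions.append(
            RegionPolygon(
                acronym=entry["acronym"],
                vertices=verts,
                hemisphere=entry.get("hemisphere", "both"),
            )
        )
    for i in range(len(shapes)):
        for j in range(i + 1, len(shapes)):
            inter = shapes[i][1].intersection(shapes[j][1]).area
            if inter > 1e-9 * min(shapes[i][1].area, shapes[j][1].area):
                raise ValueError(
                    f"regions {shapes[i][0]!r} and {shapes[j][0]!r} overlap"
                )

    nodes = {e["acronym"]: RegionNode(e["acronym"]) for e in layout}
    root = RegionNode(parent_acronym)
    for entry in layout:
        parent = entry.get("parent", parent_acronym)
        node = nodes[entry["acronym"]]
        if parent == parent_acronym:
            root.children.append(node)
        else:
            if parent not in nodes:  # implicit intermediate parent
                nodes[parent] = RegionNode(parent)
                root.children.append(nodes[parent])
            nodes[parent].children.append(node)
    ontology = Ontology(root)
    return AtlasPlate(ap_coordinate=ap_coordinate, regions=regions), ontology


def toy_grid_layout(side_um: float = 1.0) -> list[dict]:
    """2 × 2 grid of squares named A (lower left), B (lower right),
    C (upper left), D (upper right); total area 4 × side²."""
    s = side_um

    def square(x0, y0):
        return [[x0, y0], [x0 + s, y0], [x0 + s, y0 + s], [x0, y0 + s]]

    return [
        {"acronym": "A", "vertices": square(0, 0)},
        {"acronym": "B", "vertices": square(s, 0)},
        {"acronym": "C", "vertices": square(0, s)},
        {"acronym": "D", "vertices": square(s, s)},
    ]


def toy_ontology() -> Ontology:
    """A miniature acronym tree with the structures the tests exercise,
    including the always-excluded fiber tracts and ventricular systems."""
    return Ontology(
        RegionNode(
            "root",
            "root",
            [
                RegionNode("HPC", "hippocampus", [
                    RegionNode("dDG", "dorsal dentate gyrus"),
                    RegionNode("dCA1", "dorsal CA1"),
                    RegionNode("dCA3", "dorsal CA3"),
                ]),
                RegionNode("AMY", "amygdala", [
                    RegionNode("LA", "lateral amygdala"),
                    RegionNode("BLA", "basolateral amygdala"),
                    RegionNode("CEA", "central amygdala"),
                ]),
                RegionNode("ACA", "anterior cingulate area"),
                RegionNode("AI", "agranular insula"),
                RegionNode("fiber tracts", "fiber tracts"),
                RegionNode("VS", "ventricular systems"),
            ],
        )
    )
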