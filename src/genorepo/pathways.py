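"""Pathway-map coverage: parse annotated SVG maps, count covering genomes,
and recolor reaction boxes on a white -> yellow -> red scale.

The SVG dialect is deliberately simple so maps can be drawn with any editor:
a shape participates in coverage iff it carries a ``data-annotations``
attribute holding a whitespace-separated list of annotation identifiers (and
a unique ``id``).  All other shapes are inert decoration.  A genome *covers*
a box iff at least one of its genes carries at least one of the box's
annotations.  With two genome groups, each box is split 50/50 with a
hard-stop linear gradient: left half = group 1, right half = group 2.

Colors: 0 covering genomes -> white (#FFFFFF); 1 -> yellow (#FFFF00);
the full group -> red (#FF0000); linear RGB interpolation in between.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from lxml import etree

from . import annotations as _ann
from .errors import InvalidInputError, ParseError

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass
class PathwayBox:
    shape_id: str
    annotations: frozenset[str]


@dataclass
class PathwayMap:
    """A named pathway map: coverable boxes plus the underlying SVG tree."""

    name: str
    boxes: list[PathwayBox]
    tree: etree._ElementTree = None

    def box(self, shape_id: str) -> PathwayBox:
        for b in self.boxes:
            if b.shape_id == shape_id:
                return b
        raise KeyError(shape_id)


def parse_pathway_svg(path: str | Path) -> PathwayMap:
    """Parse an SVG pathway map; boxes are shapes with a data-annotations attribute."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path.name}: malformed SVG: {exc}") from exc
    boxes = []
    seen = set()
    for el in tree.iter():
        ann = el.get("data-annotations")
        if ann is None:
            continue
        idents = frozenset(ann.split())
        if not idents:
            raise ParseError(f"{path.name}: empty data-annotations on a shape")
        shape_id = el.get("id")
        if shape_id is None:
            raise ParseError(f"{path.name}: annotated shape without an id attribute")
        if shape_id in seen:
            raise ParseError(f"{path.name}: duplicate shape id '{shape_id}'")
        seen.add(shape_id)
        boxes.append(PathwayBox(shape_id=shape_id, annotations=idents))
    return PathwayMap(name=path.stem, boxes=boxes, tree=tree)


@dataclass
class CoverageResult:
    """Per-box, per-group covering-genome counts, group sizes and colors."""

    map_name: str
    group_sizes: list[int]
    counts: dict[str, list[int]] = field(default_factory=dict)  # shape_id -> per group
    colors: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for shape_id in sorted(self.counts):
            row: dict = {"box": shape_id}
            for gi, (count, size) in enumerate(
                zip(self.counts[shape_id], self.group_sizes), start=1
            ):
                row[f"group{gi}_count"] = count
                row[f"group{gi}_size"] = size
                row[f"group{gi}_color"] = self.colors[shape_id][gi - 1]
            rows.append(row)
        return pd.DataFrame(rows)


def color_for_count(count: int, group_size: int) -> str:
    """Hex fill for a box covered by *count* of *group_size* genomes."""
    if group_size < 1:
        raise InvalidInputError("group size must be >= 1")
    if count < 0 or count > group_size:
        raise InvalidInputError(f"count {count} outside [0, {group_size}]")
    if count == 0:
        return "#FFFFFF"
    t = 1.0 if group_size == 1 else (count - 1) / (group_size - 1)
    green = round(255 * (1.0 - t))
    return f"#FF{green:02X}00"


def coverage_from_sets(
    pmap: PathwayMap,
    groups: Sequence[Sequence[str]],
    annotation_sets: Mapping[str, set[str]],
) -> CoverageResult:
    """Coverage counts given precomputed genome -> annotation-set mapping."""
    if not 1 <= len(groups) <= 2:
        raise InvalidInputError("coverage supports 1 or 2 genome groups")
    groups = [list(g) for g in groups]
    if any(not g for g in groups):
        raise InvalidInputError("groups must be non-empty")
    if len(groups) == 2 and set(groups[0]) & set(groups[1]):
        raise InvalidInputError("groups must be disjoint")
    result = CoverageResult(map_name=pmap.name, group_sizes=[len(g) for g in groups])
    for box in pmap.boxes:
        counts = [
            sum(1 for g in group if annotation_sets[g] & box.annotations)
            for group in groups
        ]
        result.counts[box.shape_id] = counts
        result.colors[box.shape_id] = [
            color_for_count(c, len(g)) for c, g in zip(counts, groups)
        ]
    return result


def compute_coverage(
    pmap: PathwayMap, groups: Sequence[Sequence[str]], root: str | Path
) -> CoverageResult:
    """Coverage of a pathway map by 1 or 2 genome groups from the repository."""
    if not 1 <= len(groups) <= 2:
        raise InvalidInputError("coverage supports 1 or 2 genome groups")
    genomes = sorted({g for group in groups for g in group})
    sets = _ann.genome_annotation_sets(root, genomes)
    return coverage_from_sets(pmap, groups, sets)


def render_colored_svg(pmap: PathwayMap, coverage: CoverageResult) -> bytes:
    """Return the map's SVG with each box's fill set to its coverage color(s).

    With two groups, a two-stop hard-edge linear gradient splits each box
    50/50 (left = group 1, right = group 2).  Inert shapes are untouched.
    """
    tree = copy.deepcopy(pmap.tree)
    svg_root = tree.getroot()
    two_groups = len(coverage.group_sizes) == 2
    defs = None
    if two_groups:
        defs = svg_root.find(f"{{{SVG_NS}}}defs")
        if defs is None:
            defs = etree.SubElement(svg_root, f"{{{SVG_NS}}}defs")
            svg_root.insert(0, defs)
    for el in tree.iter():
        if el.get("data-annotations") is None:
            continue
        shape_id = el.get("id")
        colors = coverage.colors.get(shape_id)
        if colors is None:
            continue
        if el.get("style"):
            # a style fill would shadow the fill attribute
            rules = [
                r for r in el.get("style").split(";")
                if r.strip() and not r.strip().startswith("fill")
            ]
            el.set("style", ";".join(rules))
        if not two_groups:
            el.set("fill", colors[0])
        else:
            grad_id = f"coverage-split-{shape_id}"
            grad = etree.SubElement(
                defs,
                f"{{{SVG_NS}}}linearGradient",
                id=grad_id,
                x1="0", y1="0", x2="1", y2="0",
            )
            for offset, color in (("0", colors[0]), ("0.5", colors[0]),
                                  ("0.5", colors[1]), ("1", colors[1])):
                etree.SubElement(
                    grad, f"{{{SVG_NS}}}stop",
                    offset=offset, attrib={"stop-color": color},
                )
            el.set("fill", f"url(#{grad_id})")
    return etree.tostring(tree, xml_declaration=True, encoding="UTF-8")
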