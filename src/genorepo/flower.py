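"""Shared-genomic-content ("flower plot") statistics.

For a selection of n >= 2 genomes, every distinct annotation identifier is
classified by how many of the genomes carry it: carried by all -> *core*
(the flower's center), carried only by one genome -> *unique* to that genome,
anything in between -> *shared*.  Per genome, unique + shared + core equals
its total number of distinct annotations.  Statistics are computed on
annotation identifiers, not gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import annotations as _ann
from .errors import InvalidInputError


@dataclass(frozen=True)
class PetalStats:
    unique: int
    shared: int
    total: int


@dataclass
class FlowerStats:
    """Core count plus per-genome (unique, shared, total) annotation counts."""

    core: int
    petals: dict[str, PetalStats] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genome": list(self.petals),
                "unique": [p.unique for p in self.petals.values()],
                "shared": [p.shared for p in self.petals.values()],
                "core": self.core,
                "total": [p.total for p in self.petals.values()],
            }
        )


def flower_from_sets(sets: Mapping[str, set[str]]) -> FlowerStats:
    """Flower statistics from a genome -> annotation-set mapping."""
    if len(sets) < 2:
        raise InvalidInputError("flower statistics require at least 2 genomes")
    n = len(sets)
    membership: dict[str, int] = {}
    for s in sets.values():
        for ann in s:
            membership[ann] = membership.get(ann, 0) + 1
    core = sum(1 for count in membership.values() if count == n)
    petals = {}
    for genome in sorted(sets):
        s = sets[genome]
        unique = sum(1 for ann in s if membership[ann] == 1)
        shared = sum(1 for ann in s if 1 < membership[ann] < n)
        petals[genome] = PetalStats(unique=unique, shared=shared, total=len(s))
    return FlowerStats(core=core, petals=petals)


def compute_flower_stats(
    genomes: Iterable[str], root: str | Path, annotation_type: str | None = None
) -> FlowerStats:
    """Flower statistics over repository genomes (optionally one annotation type)."""
    genomes = sorted(set(genomes))
    if len(genomes) < 2:
        raise InvalidInputError("flower statistics require at least 2 genomes")
    sets = _ann.genome_annotation_sets(root, genomes, type_key=annotation_type)
    return flower_from_sets(sets)


def plot_flower(stats: FlowerStats, path: str | Path) -> None:
    """Minimal static flower figure: one petal (ellipse) per genome."""
    import math

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    n = len(stats.petals)
    fig, ax = plt.subplots(figsize=(6, 6))
    for i, (genome, petal) in enumerate(stats.petals.items()):
        angle = 360.0 * i / n
        theta = math.radians(angle)
        cx, cy = 0.9 * math.cos(theta), 0.9 * math.sin(theta)
        ax.add_patch(
            Ellipse((cx, cy), 1.6, 0.7, angle=angle, alpha=0.3, facecolor=f"C{i % 10}")
        )
        tx, ty = 1.2 * math.cos(theta), 1.2 * math.sin(theta)
        ax.text(tx, ty, f"{genome}\nu={petal.unique} s={petal.shared}",
                ha="center", va="center", fontsize=8)
    ax.text(0, 0, str(stats.core), ha="center", va="center", fontsize=14, weight="bold")
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.2, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)
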