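"""Annotation tables, description maps and annotation x genome coverage matrices.

Annotation files are two-column TSVs (gene identifier, annotation identifier);
repeated gene rows accumulate into a set — a gene listed twice with the same
annotation counts once, because the coverage matrix counts genes, not lines.
Identifiers are whitespace-trimmed and case-sensitive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import repo
from .errors import NotFoundError, ParseError


@dataclass(frozen=True)
class AnnotationType:
    """A namespace of functional identifiers with a validating regex."""

    key: str
    name: str
    pattern: str

    def matches(self, identifier: str) -> bool:
        return re.match(self.pattern, identifier) is not None


def load_annotation_types(root: str | Path) -> dict[str, AnnotationType]:
    cfg = repo.load_config(root)
    return {
        t["key"]: AnnotationType(t["key"], t.get("name", t["key"]), t["pattern"])
        for t in cfg.get("annotation_types", [])
    }


@dataclass
class AnnotationTable:
    """Per-genome mapping gene -> set of (type key, annotation identifier)."""

    genome: str
    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    invalid: list[tuple[str, str, str]] = field(default_factory=list)  # (gene, key, id)

    def annotation_set(self, type_key: str | None = None) -> set[str]:
        """All distinct annotation identifiers of this genome (optionally one type)."""
        return {
            ident
            for pairs in self.entries.values()
            for key, ident in pairs
            if type_key is None or key == type_key
        }

    def genes_with(self, annotation: str) -> list[str]:
        return sorted(
            g for g, pairs in self.entries.items() if any(a == annotation for _, a in pairs)
        )

    def merge(self, other: "AnnotationTable") -> None:
        for gene, pairs in other.entries.items():
            self.entries.setdefault(gene, set()).update(pairs)
        self.invalid.extend(other.invalid)


@dataclass
class DescriptionMap:
    """identifier -> human readable description, for one annotation type."""

    key: str
    descriptions: dict[str, str] = field(default_factory=dict)


def parse_annotation_table(
    path: str | Path, annotation_type: AnnotationType, genome: str | None = None
) -> AnnotationTable:
    """Parse a two-column TSV annotation file.

    Lines with other than two tab-separated columns raise ParseError with the
    line number.  Identifiers that do not match the type's pattern are kept out
    of the entries and collected in ``table.invalid``.
    """
    path = Path(path)
    if genome is None:
        genome = path.name.split(".")[0]
    table = AnnotationTable(genome=genome)
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path.name}: expected 2 tab-separated columns, got {len(fields)}",
                    line=i,
                )
            gene, ident = fields[0].strip(), fields[1].strip()
            if not gene or not ident:
                raise ParseError(f"{path.name}: empty field", line=i)
            if not annotation_type.matches(ident):
                table.invalid.append((gene, annotation_type.key, ident))
                continue
            table.entries.setdefault(gene, set()).add((annotation_type.key, ident))
    return table


def write_annotation_table(table: AnnotationTable, path: str | Path, type_key: str) -> None:
    """Serialize one type's entries back to the two-column TSV format."""
    rows = sorted(
        (gene, ident)
        for gene, pairs in table.entries.items()
        for key, ident in pairs
        if key == type_key
    )
    with open(path, "w", encoding="utf-8") as fh:
        for gene, ident in rows:
            fh.write(f"{gene}\t{ident}\n")


def parse_description_map(path: str | Path, key: str | None = None) -> DescriptionMap:
    path = Path(path)
    if key is None:
        key = path.stem
    dm = DescriptionMap(key=key)
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t", 1)
            if len(fields) != 2:
                raise ParseError(f"{path.name}: expected 2 columns", line=i)
            dm.descriptions[fields[0].strip()] = fields[1].strip()
    return dm


def load_genome_annotations(root: str | Path, genome: str) -> AnnotationTable:
    """All annotation tables of one genome, merged across configured types."""
    gdir = repo.genome_dir(root, genome)
    types = load_annotation_types(root)
    merged = AnnotationTable(genome=genome)
    for key, atype in types.items():
        path = gdir / f"{genome}.{key}.tsv"
        if path.is_file():
            merged.merge(parse_annotation_table(path, atype, genome=genome))
    return merged


def genome_annotation_sets(
    root: str | Path, genomes: Iterable[str], type_key: str | None = None
) -> dict[str, set[str]]:
    """Genome -> set of distinct annotation identifiers (optionally one type)."""
    return {
        g: load_genome_annotations(root, g).annotation_set(type_key)
        for g in genomes
    }


def coverage_matrix(
    annotations: Sequence[str], genomes: Sequence[str], root: str | Path
) -> pd.DataFrame:
    """Annotation x genome matrix of gene counts.

    Cell (a, g) is the number of distinct genes of genome g carrying annotation
    a.  Rows and columns keep the order they were given in.
    """
    genomes = list(genomes)
    tables = {g: load_genome_annotations(root, g) for g in genomes}  # raises NotFound
    data = {
        g: [len(tables[g].genes_with(a)) for a in annotations]
        for g in genomes
    }
    return pd.DataFrame(data, index=list(annotations), columns=genomes, dtype=int)


def genes_for_annotation(annotation: str, genome: str, root: str | Path) -> list[str]:
    """Sorted distinct gene identifiers of *genome* carrying *annotation*."""
    return load_genome_annotations(root, genome).genes_with(annotation)


def load_descriptions(root: str | Path) -> dict[str, DescriptionMap]:
    """All description maps shipped in annotation-descriptions/."""
    ddir = Path(root) / repo.DESCRIPTIONS_DIR
    out = {}
    if ddir.is_dir():
        for path in sorted(ddir.glob("*.tsv")):
            out[path.stem] = parse_description_map(path)
    return out


def describe(root: str | Path, annotation: str) -> str | None:
    for dm in load_descriptions(root).values():
        if annotation in dm.descriptions:
            return dm.descriptions[annotation]
    return None
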