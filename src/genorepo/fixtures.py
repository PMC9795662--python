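"""Deterministic synthetic genome repositories for testing and demonstration.

The generator emulates a small sequencing project: a handful of bacterial
organisms split across two phyla, one or two genome versions each, random
assemblies with evenly spaced genes (FASTA + minimal but parseable GenBank +
GFF3 with consistent 1-based inclusive coordinates), per-genome annotation
tables with a planted sharing structure (core annotations present in every
organism, globally unique annotations per organism, a random shared pool),
a lineage table, tags, description maps and an annotated SVG pathway map.

Optionally one annotation is *planted* to separate the two tag groups
perfectly — every organism of the first tag carries it, none of the second —
which gives gene-trait matching a known best hit.  The seed fully determines
every generated byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from . import repo
from .errors import RepoError
from .repo import GenomeRecord, OrganismRecord, ValidationReport, _dump_json
from .taxonomy import TaxonNode, Taxonomy

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneModel:
    """One fixture gene: 0-based half-open interval internally, GFF is 1-based."""

    gene_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'


@dataclass
class FixtureSpec:
    """Shape of the synthetic repository; the seed determines all bytes."""

    n_organisms: int = 4
    versions_per_organism: int = 1
    genome_length: int = 3000
    n_genes: int = 15
    tags: tuple[str, str] = ("halophile", "mesophile")
    n_core_annotations: int = 5
    n_unique_annotations: int = 3
    n_shared_pool: int = 10
    planted_trait_annotation: str | None = "K09999"
    seed: int = 0

    def organism_names(self) -> list[str]:
        return [f"ORG{i + 1:03d}" for i in range(self.n_organisms)]


_PHYLA = [
    (1239, "Firmicutes", 1578, "Lactobacillus"),
    (201174, "Actinobacteria", 1678, "Bifidobacterium"),
]


def fixture_taxonomy(spec: FixtureSpec) -> tuple[Taxonomy, dict[str, int]]:
    """Two-phylum taxonomy with one species node per organism."""
    nodes = [TaxonNode(1, 1, "root", "root")]
    for phylum_id, phylum, genus_id, genus in _PHYLA:
        nodes.append(TaxonNode(phylum_id, 1, "phylum", phylum))
        nodes.append(TaxonNode(genus_id, phylum_id, "genus", genus))
    organism_taxids = {}
    n_first = (spec.n_organisms + 1) // 2
    for i, name in enumerate(spec.organism_names()):
        _, _, genus_id, genus = _PHYLA[0] if i < n_first else _PHYLA[1]
        taxid = 100001 + i
        nodes.append(TaxonNode(taxid, genus_id, "species", f"{genus} sp{i + 1}"))
        organism_taxids[name] = taxid
    return Taxonomy(nodes), organism_taxids


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float = 0.01) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    arr[hits] = _ALPHABET[rng.integers(0, 4, size=len(hits))]
    return arr.tobytes().decode("ascii")


def _gene_models(identifier: str, genome_length: int, n_genes: int) -> list[GeneModel]:
    spacing = genome_length // n_genes
    gene_len = min(60, max(6, (spacing - 20) // 3 * 3))
    out = []
    for i in range(n_genes):
        start = i * spacing + 5
        out.append(
            GeneModel(
                gene_id=f"{identifier}_{i + 1:04d}",
                start=start,
                end=start + gene_len,
                strand="+" if i % 2 == 0 else "-",
            )
        )
    return out


def write_genome_files(
    target: Path,
    identifier: str,
    sequence: str,
    genes: Sequence[GeneModel],
    annotations_by_type: dict[str, list[tuple[str, str]]],
    basename: str | None = None,
) -> None:
    """Write <basename>.fna/.gbk/.gff plus annotation TSVs into *target*.

    GenBank and GFF3 carry the same gene coordinates; GFF3 is written 1-based
    inclusive, the in-memory gene model is 0-based half-open.
    """
    target.mkdir(parents=True, exist_ok=True)
    basename = basename or identifier
    contig = f"{identifier}_c1"
    record = SeqRecord(
        Seq(sequence),
        id=contig,
        name=contig[:16],
        description=f"synthetic assembly of {identifier}",
        annotations={
            "molecule_type": "DNA",
            "topology": "linear",
            "data_file_division": "BCT",
            "date": "01-JAN-2024",
        },
    )
    for gene in genes:
        strand = 1 if gene.strand == "+" else -1
        loc = FeatureLocation(gene.start, gene.end, strand=strand)
        quals = {"locus_tag": [gene.gene_id]}
        record.features.append(SeqFeature(loc, type="gene", qualifiers=dict(quals)))
        record.features.append(SeqFeature(loc, type="CDS", qualifiers=dict(quals)))
    SeqIO.write([record], str(target / f"{basename}.fna"), "fasta")
    SeqIO.write([record], str(target / f"{basename}.gbk"), "genbank")
    with open(target / f"{basename}.gff", "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig} 1 {len(sequence)}\n")
        for gene in genes:
            attrs = f"ID=gene-{gene.gene_id};locus_tag={gene.gene_id}"
            fh.write(
                f"{contig}\tgenorepo-fixture\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
    for key, rows in annotations_by_type.items():
        with open(target / f"{basename}.{key}.tsv", "w", encoding="utf-8") as fh:
            for gene_id, ident in sorted(rows):
                fh.write(f"{gene_id}\t{ident}\n")


def _assign_to_genes(
    rng: np.random.Generator, idents: Sequence[str], genes: Sequence[GeneModel]
) -> list[tuple[str, str]]:
    """Attach each annotation to 1-2 distinct random genes."""
    rows = []
    for ident in idents:
        k = int(rng.integers(1, 3))
        picks = rng.choice(len(genes), size=min(k, len(genes)), replace=False)
        for p in sorted(picks):
            rows.append((genes[p].gene_id, ident))
    return rows


def _organism_annotations(
    spec: FixtureSpec, rng: np.random.Generator, index: int
) -> dict[str, list[str]]:
    """Annotation identifiers per type for organism *index* (planted structure)."""
    core_kg = [f"K{i + 1:05d}" for i in range(spec.n_core_annotations)]
    unique_kg = [
        f"K{10000 + index * spec.n_unique_annotations + j:05d}"
        for j in range(spec.n_unique_annotations)
    ]
    pool = [f"K{20000 + j:05d}" for j in range(spec.n_shared_pool)]
    take = rng.random(spec.n_shared_pool) < 0.5
    shared_kg = [p for p, keep in zip(pool, take) if keep]
    kg = core_kg + unique_kg + shared_kg
    n_first = (spec.n_organisms + 1) // 2
    if spec.planted_trait_annotation and index < n_first:
        kg.append(spec.planted_trait_annotation)
    ec_pool = [f"EC:1.1.1.{j + 1}" for j in range(6)]
    ec = ["EC:1.1.1.1"] + [
        e for e, keep in zip(ec_pool[1:], rng.random(5) < 0.5) if keep
    ]
    return {"KG": kg, "EC": ec}


def _write_pathway_map(spec: FixtureSpec, root: Path) -> None:
    from lxml import etree

    from .pathways import SVG_NS

    nsmap = {None: SVG_NS}
    svg = etree.Element(f"{{{SVG_NS}}}svg", nsmap=nsmap, width="400", height="160")
    boxes = [
        ("box-core", "K00001", 10),
        ("box-multi", "K00002 EC:1.1.1.1", 110),
        ("box-absent", "K99998", 210),
    ]
    if spec.planted_trait_annotation:
        boxes.append(("box-trait", spec.planted_trait_annotation, 310))
    for shape_id, anns, x in boxes:
        etree.SubElement(
            svg, f"{{{SVG_NS}}}rect",
            id=shape_id, x=str(x), y="40", width="80", height="40",
            fill="#FFFFFF", stroke="#000000",
            attrib={"data-annotations": anns},
        )
        label = etree.SubElement(
            svg, f"{{{SVG_NS}}}text", x=str(x + 5), y="100",
        )
        label.text = shape_id
    (root / repo.PATHWAY_MAPS_DIR / "demo_pathway.svg").write_bytes(
        etree.tostring(svg, xml_declaration=True, encoding="UTF-8", pretty_print=True)
    )


def generate_fixture_repo(spec: FixtureSpec, root: str | Path) -> ValidationReport:
    """Generate a complete, valid synthetic repository at *root* (must be empty)."""
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        raise RepoError(f"refusing to write fixture into non-empty directory {root}")
    repo.init_folder_structure(root)
    rng = np.random.default_rng(spec.seed)

    taxonomy, organism_taxids = fixture_taxonomy(spec)
    taxonomy.to_tsv(root / "taxonomy.tsv")

    n_first = (spec.n_organisms + 1) // 2
    used_kg: set[str] = set()
    used_ec: set[str] = set()
    for i, organism in enumerate(spec.organism_names()):
        tag = spec.tags[0] if i < n_first else spec.tags[1]
        ann_ids = _organism_annotations(spec, rng, i)
        used_kg.update(ann_ids["KG"])
        used_ec.update(ann_ids["EC"])
        base_seq = _random_sequence(rng, spec.genome_length)
        org_dir = root / repo.ORGANISMS_DIR / organism
        versions = [
            f"{organism}-{v + 1}" for v in range(spec.versions_per_organism)
        ]
        seq = base_seq
        for v, identifier in enumerate(versions):
            if v > 0:
                seq = _mutate(rng, seq)
            genes = _gene_models(identifier, spec.genome_length, spec.n_genes)
            rows_by_type = {
                key: _assign_to_genes(rng, idents, genes)
                for key, idents in sorted(ann_ids.items())
            }
            gdir = org_dir / "genomes" / identifier
            write_genome_files(gdir, identifier, seq, genes, rows_by_type)
            _dump_json(
                GenomeRecord(
                    identifier=identifier,
                    organism=organism,
                    sequencing_tech="synthetic",
                    assembly_tool="genorepo-fixture",
                    annotation_tool="genorepo-fixture",
                    custom={"version": v + 1},
                ).to_json(),
                gdir / "genome.json",
            )
        _dump_json(
            OrganismRecord(
                name=organism,
                representative=versions[-1],
                taxid=organism_taxids[organism],
                tags={tag},
            ).to_json(),
            org_dir / "organism.json",
        )

    ddir = root / repo.DESCRIPTIONS_DIR
    with open(ddir / "KG.tsv", "w", encoding="utf-8") as fh:
        for ident in sorted(used_kg):
            fh.write(f"{ident}\tsynthetic enzyme {ident[1:].lstrip('0') or '0'}\n")
    with open(ddir / "EC.tsv", "w", encoding="utf-8") as fh:
        for ident in sorted(used_ec):
            fh.write(f"{ident}\tsynthetic activity {ident.split(':')[1]}\n")

    _write_pathway_map(spec, root)
    return repo.validate_repo(root)


def make_import_dir(target: str | Path, name: str = "sample", seed: int = 0) -> Path:
    """A minimal annotation-pipeline-style output directory (for import tests)."""
    target = Path(target)
    rng = np.random.default_rng(seed)
    seq = _random_sequence(rng, 1200)
    genes = _gene_models(name, 1200, 5)
    rows = _assign_to_genes(rng, ["K00001", "K00002"], genes)
    write_genome_files(target, name, seq, genes, {"KG": rows}, basename=name)
    return target
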