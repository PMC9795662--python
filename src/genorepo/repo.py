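"""The versioned on-disk genome repository: layout, metadata, validation, selectors.

Layout::

    <root>/
        config.json                  # annotation types, taxonomy file name
        taxonomy.tsv                 # optional lineage table (taxid, parent, rank, name)
        annotation-descriptions/     # <type-key>.tsv maps identifier -> description
        pathway-maps/                # *.svg pathway maps
        organisms/<organism>/organism.json
        organisms/<organism>/genomes/<genome>/<genome>.{fna,gbk,gff}
        organisms/<organism>/genomes/<genome>/<genome>.<type-key>.tsv
        organisms/<organism>/genomes/<genome>/genome.json

Each organism owns one or more genome versions; exactly one is designated the
representative in organism.json.  Selector queries ("@tag:halophile",
"@taxphylum:Firmicutes", "@tax:Firmicutes", bare identifiers) resolve to sets of
genome identifiers; tag and taxon selectors are scoped to representative genomes.
Older genome versions are never modified by imports: updating an assembly means
importing a new version and re-pointing the representative.
"""

from __future__ import annotations

import json
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .errors import (
    AmbiguityError,
    DuplicateError,
    InvalidInputError,
    NotFoundError,
    RepoError,
)
from .taxonomy import Taxonomy

CONFIG_NAME = "config.json"
ORGANISMS_DIR = "organisms"
DESCRIPTIONS_DIR = "annotation-descriptions"
PATHWAY_MAPS_DIR = "pathway-maps"

#: annotation namespaces configured by default in a fresh repository
DEFAULT_ANNOTATION_TYPES = [
    {"key": "KG", "name": "KEGG gene", "pattern": r"^K\d{5}$"},
    {"key": "KR", "name": "KEGG reaction", "pattern": r"^R\d{5}$"},
    {"key": "EC", "name": "Enzyme Commission number", "pattern": r"^EC:\d+(\.(\d+|-)){0,3}$"},
    {"key": "GO", "name": "Gene Ontology term", "pattern": r"^GO:\d{7}$"},
    {"key": "custom", "name": "Custom annotation", "pattern": r"^\S+$"},
]

_DATA_SUFFIXES = {
    "fna": (".fna", ".fasta", ".fa"),
    "gbk": (".gbk", ".gbff", ".gb"),
    "gff": (".gff", ".gff3"),
}


def _dump_json(obj, path: Path) -> None:
    # sorted keys + trailing newline for reproducible diffs
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n", encoding="utf-8")


@dataclass
class OrganismRecord:
    """Metadata for one biological entity (organism.json)."""

    name: str
    representative: str
    taxid: int = 1
    tags: set[str] = field(default_factory=set)
    restricted: bool = False

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "representative": self.representative,
            "taxid": self.taxid,
            "tags": sorted(self.tags),
            "restricted": self.restricted,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "OrganismRecord":
        return cls(
            name=obj["name"],
            representative=obj["representative"],
            taxid=int(obj.get("taxid", 1)),
            tags=set(obj.get("tags", [])),
            restricted=bool(obj.get("restricted", False)),
        )


@dataclass
class GenomeRecord:
    """Metadata for one genome version (genome.json)."""

    identifier: str
    organism: str
    sequencing_tech: str = ""
    assembly_tool: str = ""
    annotation_tool: str = ""
    custom: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "identifier": self.identifier,
            "organism": self.organism,
            "sequencing_tech": self.sequencing_tech,
            "assembly_tool": self.assembly_tool,
            "annotation_tool": self.annotation_tool,
            "custom": self.custom,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GenomeRecord":
        return cls(
            identifier=obj["identifier"],
            organism=obj["organism"],
            sequencing_tech=obj.get("sequencing_tech", ""),
            assembly_tool=obj.get("assembly_tool", ""),
            annotation_tool=obj.get("annotation_tool", ""),
            custom=dict(obj.get("custom", {})),
        )


@dataclass
class ValidationReport:
    """Outcome of validate_repo: a (path, rule-id, message) triple per violation."""

    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, path: str, rule: str, message: str) -> None:
        self.violations.append((path, rule, message))

    def sorted(self) -> "ValidationReport":
        return ValidationReport(sorted(self.violations))

    def __str__(self) -> str:
        if self.ok:
            return "OK: no violations"
        return "\n".join(f"{p}\t{r}\t{m}" for p, r, m in self.violations)


@dataclass(frozen=True)
class GenomeSelector:
    """A parsed selector token: bare identifier, @tag:..., @tax:... or @taxRANK:..."""

    raw: str
    kind: str  # identifier | tag | taxon | taxon_rank
    argument: str
    rank: str | None = None


# ---------------------------------------------------------------------------
# config + traversal helpers


def load_config(root: str | Path) -> dict:
    path = Path(root) / CONFIG_NAME
    if not path.is_file():
        raise NotFoundError(f"no repository config at {path}")
    return json.loads(path.read_text(encoding="utf-8"))


def load_taxonomy(root: str | Path) -> Taxonomy | None:
    """The repository's lineage table, or None if it does not ship one."""
    cfg = load_config(root)
    name = cfg.get("taxonomy")
    if not name:
        return None
    path = Path(root) / name
    if not path.is_file():
        return None
    return Taxonomy.from_tsv(path)


def iter_organisms(root: str | Path) -> Iterator[tuple[OrganismRecord, Path]]:
    """Yield (record, organism directory) sorted by organism name."""
    org_root = Path(root) / ORGANISMS_DIR
    if not org_root.is_dir():
        return
    for org_dir in sorted(p for p in org_root.iterdir() if p.is_dir()):
        meta = org_dir / "organism.json"
        if not meta.is_file():
            continue
        yield OrganismRecord.from_json(json.loads(meta.read_text(encoding="utf-8"))), org_dir


def iter_genomes(root: str | Path) -> Iterator[tuple[GenomeRecord, Path]]:
    """Yield (record, genome directory) for every genome version in the repository."""
    for _org, org_dir in iter_organisms(root):
        genomes_dir = org_dir / "genomes"
        if not genomes_dir.is_dir():
            continue
        for gdir in sorted(p for p in genomes_dir.iterdir() if p.is_dir()):
            meta = gdir / "genome.json"
            if not meta.is_file():
                continue
            yield GenomeRecord.from_json(json.loads(meta.read_text(encoding="utf-8"))), gdir


def genome_dir(root: str | Path, identifier: str) -> Path:
    """Directory of a genome version; NotFoundError if absent."""
    for rec, gdir in iter_genomes(root):
        if rec.identifier == identifier:
            return gdir
    raise NotFoundError(f"genome '{identifier}' not found in repository")


def representative_genomes(root: str | Path) -> dict[str, str]:
    """organism name -> representative genome identifier."""
    return {org.name: org.representative for org, _ in iter_organisms(root)}


def genome_taxids(root: str | Path, genomes: set[str] | None = None) -> dict[str, int]:
    """Genome identifier -> owning organism's taxid (all genomes by default)."""
    out = {}
    orgs = {org.name: org for org, _ in iter_organisms(root)}
    for rec, _gdir in iter_genomes(root):
        if genomes is None or rec.identifier in genomes:
            out[rec.identifier] = orgs[rec.organism].taxid
    if genomes is not None:
        missing = set(genomes) - set(out)
        if missing:
            raise NotFoundError(f"genomes not found: {sorted(missing)}")
    return out


# ---------------------------------------------------------------------------
# operations


def init_folder_structure(root: str | Path) -> ValidationReport:
    """Create a bare-bone repository at *root*.

    Refuses to touch a non-empty directory: existing data is never overwritten.
    """
    root = Path(root)
    if root.exists():
        if not root.is_dir():
            raise RepoError(f"{root} exists and is not a directory")
        if any(root.iterdir()):
            raise RepoError(f"refusing to initialise non-empty directory {root}")
    root.mkdir(parents=True, exist_ok=True)
    for sub in (ORGANISMS_DIR, DESCRIPTIONS_DIR, PATHWAY_MAPS_DIR):
        (root / sub).mkdir()
    _dump_json(
        {"annotation_types": DEFAULT_ANNOTATION_TYPES, "taxonomy": "taxonomy.tsv"},
        root / CONFIG_NAME,
    )
    return validate_repo(root)


def _find_one(import_dir: Path, suffixes: tuple[str, ...], what: str) -> Path:
    candidates = sorted(
        p
        for p in import_dir.iterdir()
        if p.is_file() and p.suffix.lower() in suffixes
    )
    if not candidates:
        raise NotFoundError(
            f"import dir {import_dir} is missing the required {what} file "
            f"(one of {'/'.join(suffixes)})"
        )
    if len(candidates) > 1:
        raise AmbiguityError(
            f"import dir {import_dir} has {len(candidates)} candidate {what} files: "
            f"{[p.name for p in candidates]}"
        )
    return candidates[0]


def import_genome(
    import_dir: str | Path,
    root: str | Path,
    organism: str,
    identifier: str,
    set_representative: bool = False,
    taxid: int | None = None,
    tags: set[str] | None = None,
    metadata: Mapping[str, str] | None = None,
) -> GenomeRecord:
    """Copy an annotation-pipeline output directory into the repository.

    The import directory must contain exactly one assembly FASTA (.fna), one
    GenBank file (.gbk) and one GFF3 (.gff) — Prokka and PGAP output naming is
    accepted; files are renamed to <identifier>.<suffix>.  Two-column annotation
    tables named *.<type-key>.tsv are copied along if present.  Pre-existing
    genome folders are never modified; a duplicate identifier is an error.
    """
    import_dir, root = Path(import_dir), Path(root)
    cfg = load_config(root)
    if not import_dir.is_dir():
        raise NotFoundError(f"import dir {import_dir} does not exist")
    existing = {rec.identifier for rec, _ in iter_genomes(root)}
    if identifier in existing:
        raise DuplicateError(f"genome identifier '{identifier}' already exists in repository")

    found = {
        kind: _find_one(import_dir, suffixes, kind)
        for kind, suffixes in _DATA_SUFFIXES.items()
    }
    type_keys = [t["key"] for t in cfg.get("annotation_types", [])]
    annotation_files: dict[str, Path] = {}
    for key in type_keys:
        hits = sorted(p for p in import_dir.iterdir() if p.name.endswith(f".{key}.tsv"))
        if len(hits) > 1:
            raise AmbiguityError(f"multiple .{key}.tsv annotation tables in {import_dir}")
        if hits:
            annotation_files[key] = hits[0]

    org_dir = root / ORGANISMS_DIR / organism
    target = org_dir / "genomes" / identifier
    if target.exists():
        raise DuplicateError(f"genome folder {target} already exists")
    target.mkdir(parents=True)
    for kind, src in found.items():
        shutil.copyfile(src, target / f"{identifier}.{kind}")
    for key, src in annotation_files.items():
        shutil.copyfile(src, target / f"{identifier}.{key}.tsv")

    record = GenomeRecord(identifier=identifier, organism=organism, **dict(metadata or {}))
    _dump_json(record.to_json(), target / "genome.json")

    org_meta = org_dir / "organism.json"
    if org_meta.is_file():
        org = OrganismRecord.from_json(json.loads(org_meta.read_text(encoding="utf-8")))
        changed = False
        if set_representative:
            org.representative = identifier
            changed = True
        if taxid is not None and org.taxid != taxid:
            org.taxid = taxid
            changed = True
        if tags:
            org.tags |= set(tags)
            changed = True
        if changed:
            _dump_json(org.to_json(), org_meta)
    else:
        org = OrganismRecord(
            name=organism,
            representative=identifier,
            taxid=taxid if taxid is not None else 1,
            tags=set(tags or ()),
        )
        _dump_json(org.to_json(), org_meta)
    return record


_TAG_RE = re.compile(r"^\S+$")


def validate_repo(root: str | Path) -> ValidationReport:
    """Check every structural invariant; violations sorted by path then rule-id."""
    root = Path(root)
    report = ValidationReport()
    if not root.is_dir():
        report.add(str(root), "root-missing", "repository root does not exist")
        return report.sorted()
    try:
        load_config(root)
    except (NotFoundError, json.JSONDecodeError) as exc:
        report.add(str(root / CONFIG_NAME), "config-invalid", str(exc))
        return report.sorted()
    for sub in (ORGANISMS_DIR, DESCRIPTIONS_DIR, PATHWAY_MAPS_DIR):
        if not (root / sub).is_dir():
            report.add(str(root / sub), "dir-missing", f"required directory {sub}/ missing")

    seen_ids: dict[str, str] = {}
    org_root = root / ORGANISMS_DIR
    if not org_root.is_dir():
        return report.sorted()
    for org_dir in sorted(p for p in org_root.iterdir() if p.is_dir()):
        meta = org_dir / "organism.json"
        rel = str(meta)
        if not meta.is_file():
            report.add(str(org_dir), "organism-json-missing", "organism.json missing")
            continue
        try:
            org = OrganismRecord.from_json(json.loads(meta.read_text(encoding="utf-8")))
        except (KeyError, ValueError) as exc:
            report.add(rel, "organism-json-invalid", f"cannot parse organism.json: {exc!r}")
            continue
        if org.name != org_dir.name:
            report.add(rel, "organism-name-mismatch",
                       f"name '{org.name}' does not match directory '{org_dir.name}'")
        for tag in org.tags:
            if not tag or not _TAG_RE.match(tag):
                report.add(rel, "tag-invalid", f"tag {tag!r} is empty or contains whitespace")
        genomes_dir = org_dir / "genomes"
        genome_names = (
            sorted(p.name for p in genomes_dir.iterdir() if p.is_dir())
            if genomes_dir.is_dir()
            else []
        )
        if org.representative not in genome_names:
            report.add(rel, "representative-missing",
                       f"representative '{org.representative}' has no genome folder")
        for gname in genome_names:
            gdir = genomes_dir / gname
            gmeta = gdir / "genome.json"
            if not gmeta.is_file():
                report.add(str(gdir), "genome-json-missing", "genome.json missing")
                continue
            try:
                rec = GenomeRecord.from_json(json.loads(gmeta.read_text(encoding="utf-8")))
            except (KeyError, ValueError) as exc:
                report.add(str(gmeta), "genome-json-invalid", f"cannot parse genome.json: {exc!r}")
                continue
            if rec.identifier != gname:
                report.add(str(gmeta), "genome-id-mismatch",
                           f"identifier '{rec.identifier}' does not match directory '{gname}'")
            if rec.organism != org_dir.name:
                report.add(str(gmeta), "genome-organism-mismatch",
                           f"organism '{rec.organism}' does not match '{org_dir.name}'")
            if rec.identifier in seen_ids:
                report.add(str(gmeta), "duplicate-identifier",
                           f"identifier '{rec.identifier}' also used by {seen_ids[rec.identifier]}")
            else:
                seen_ids[rec.identifier] = str(gdir)
            for suffix in ("fna", "gbk", "gff"):
                f = gdir / f"{gname}.{suffix}"
                if not f.is_file():
                    report.add(str(gdir), "file-missing", f"required file {f.name} missing")
    return report.sorted()


def parse_selector(token: str) -> GenomeSelector:
    token = token.strip()
    if token.startswith("@tag:"):
        return GenomeSelector(token, "tag", token[len("@tag:"):])
    if token.startswith("@tax"):
        head, sep, name = token.partition(":")
        if not sep:
            raise InvalidInputError(f"malformed taxon selector {token!r}")
        rank = head[len("@tax"):]
        if rank:
            return GenomeSelector(token, "taxon_rank", name, rank=rank)
        return GenomeSelector(token, "taxon", name)
    return GenomeSelector(token, "identifier", token)


def resolve_selector(
    query: str, root: str | Path, taxonomy: Taxonomy | None = None
) -> set[str]:
    """Resolve a selector query to a set of genome identifiers.

    Comma-separated tokens union.  Tag and taxon selectors are scoped to
    representative genomes; bare tokens name any genome version directly.
    """
    if taxonomy is None:
        taxonomy = load_taxonomy(root)
    result: set[str] = set()
    for token in filter(None, (t.strip() for t in query.split(","))):
        sel = parse_selector(token)
        if sel.kind == "identifier":
            all_ids = {rec.identifier for rec, _ in iter_genomes(root)}
            if sel.argument not in all_ids:
                raise NotFoundError(f"no genome named '{sel.argument}'")
            result.add(sel.argument)
        elif sel.kind == "tag":
            hits = {
                org.representative for org, _ in iter_organisms(root) if sel.argument in org.tags
            }
            if not hits:
                raise NotFoundError(f"no organism carries tag '{sel.argument}'")
            result |= hits
        else:  # taxon / taxon_rank
            if taxonomy is None:
                raise InvalidInputError(
                    f"taxonomic selector {token!r} requires a taxonomy table"
                )
            if not taxonomy.has_name(sel.argument):
                raise NotFoundError(f"taxon '{sel.argument}' not in taxonomy")
            rank = sel.rank if sel.kind == "taxon_rank" else None
            result |= {
                org.representative
                for org, _ in iter_organisms(root)
                if taxonomy.lineage_contains(org.taxid, sel.argument, rank=rank)
            }
    return result
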