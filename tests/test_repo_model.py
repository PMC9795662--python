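"""Folder structure, metadata validation, genome import and selector queries."""

import hashlib
import json
from pathlib import Path

import pytest

from genorepo import (
    AmbiguityError,
    DuplicateError,
    NotFoundError,
    RepoError,
    import_genome,
    init_folder_structure,
    resolve_selector,
    validate_repo,
)
from genorepo.fixtures import make_import_dir
from genorepo.repo import (
    iter_organisms,
    load_config,
    parse_selector,
    representative_genomes,
)


def repo_hash(root: Path) -> dict[str, str]:
    """Per-file content hashes of a directory tree."""
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


# ---------------------------------------------------------------------------
# init


def test_init_creates_empty_valid_repo(tmp_path):
    root = tmp_path / "repo"
    report = init_folder_structure(root)
    assert report.ok
    for sub in ("organisms", "annotation-descriptions", "pathway-maps"):
        assert (root / sub).is_dir()
    cfg = load_config(root)
    assert {t["key"] for t in cfg["annotation_types"]} >= {"KG", "KR", "EC", "GO"}
    assert validate_repo(root).ok


def test_init_refuses_non_empty_dir(tmp_path):
    (tmp_path / "stray.txt").write_text("x")
    with pytest.raises(RepoError):
        init_folder_structure(tmp_path)
    assert not (tmp_path / "organisms").exists()


# ---------------------------------------------------------------------------
# import


@pytest.fixture()
def empty_repo(tmp_path):
    root = tmp_path / "repo"
    init_folder_structure(root)
    return root


def test_import_renames_and_validates(empty_repo, tmp_path):
    src = make_import_dir(tmp_path / "import", name="s", seed=3)
    rec = import_genome(src, empty_repo, organism="ORGX", identifier="ORGX-1")
    gdir = empty_repo / "organisms" / "ORGX" / "genomes" / "ORGX-1"
    for suffix in ("fna", "gbk", "gff"):
        assert (gdir / f"ORGX-1.{suffix}").is_file()
        assert (gdir / f"ORGX-1.{suffix}").read_bytes() == (src / f"s.{suffix}").read_bytes()
    assert (gdir / "ORGX-1.KG.tsv").is_file()
    meta = json.loads((gdir / "genome.json").read_text())
    assert meta["identifier"] == "ORGX-1" and meta["organism"] == "ORGX"
    assert rec.identifier == "ORGX-1"
    assert representative_genomes(empty_repo) == {"ORGX": "ORGX-1"}
    assert validate_repo(empty_repo).ok


def test_import_missing_gff_names_requirement(empty_repo, tmp_path):
    src = make_import_dir(tmp_path / "import", name="s")
    (src / "s.gff").unlink()
    with pytest.raises(NotFoundError, match="gff"):
        import_genome(src, empty_repo, organism="O", identifier="G1")


def test_import_ambiguous_fasta(empty_repo, tmp_path):
    src = make_import_dir(tmp_path / "import", name="s")
    (src / "other.fna").write_text(">x\nACGT\n")
    with pytest.raises(AmbiguityError):
        import_genome(src, empty_repo, organism="O", identifier="G1")


def test_reimport_same_identifier_is_refused_and_non_destructive(empty_repo, tmp_path):
    src = make_import_dir(tmp_path / "import", name="s")
    import_genome(src, empty_repo, organism="O", identifier="G1")
    before = repo_hash(empty_repo)
    with pytest.raises(DuplicateError):
        import_genome(src, empty_repo, organism="O", identifier="G1")
    assert repo_hash(empty_repo) == before


def test_second_version_updates_representative_only_on_request(empty_repo, tmp_path):
    src = make_import_dir(tmp_path / "import", name="s")
    import_genome(src, empty_repo, organism="O", identifier="O-1")
    v1_hashes = repo_hash(empty_repo / "organisms" / "O" / "genomes" / "O-1")

    import_genome(src, empty_repo, organism="O", identifier="O-2")
    assert representative_genomes(empty_repo) == {"O": "O-1"}

    import_genome(src, empty_repo, organism="O", identifier="O-3", set_representative=True)
    assert representative_genomes(empty_repo) == {"O": "O-3"}
    # exactly one representative, and older versions untouched
    orgs = list(iter_organisms(empty_repo))
    assert len(orgs) == 1
    assert repo_hash(empty_repo / "organisms" / "O" / "genomes" / "O-1") == v1_hashes
    assert validate_repo(empty_repo).ok


# ---------------------------------------------------------------------------
# validation


def test_fixture_repo_is_valid(fixture_repo):
    assert validate_repo(fixture_repo).ok


def test_broken_representative_is_reported(empty_repo, tmp_path):
    src = make_import_dir(tmp_path / "import", name="s")
    import_genome(src, empty_repo, organism="O", identifier="G1")
    meta = empty_repo / "organisms" / "O" / "organism.json"
    obj = json.loads(meta.read_text())
    obj["representative"] = "GHOST"
    meta.write_text(json.dumps(obj))
    report = validate_repo(empty_repo)
    assert any(rule == "representative-missing" and "GHOST" in msg
               for _, rule, msg in report.violations)


def test_duplicate_identifier_is_reported(empty_repo, tmp_path):
    src = make_import_dir(tmp_path / "import", name="s")
    import_genome(src, empty_repo, organism="O1", identifier="G1")
    import_genome(src, empty_repo, organism="O2", identifier="G2")
    # forge a duplicate identifier inside O2's genome.json
    meta = empty_repo / "organisms" / "O2" / "genomes" / "G2" / "genome.json"
    obj = json.loads(meta.read_text())
    obj["identifier"] = "G1"
    meta.write_text(json.dumps(obj))
    report = validate_repo(empty_repo)
    rules = {rule for _, rule, _ in report.violations}
    assert "duplicate-identifier" in rules
    assert "genome-id-mismatch" in rules


def test_violations_sorted_by_path_then_rule(empty_repo, tmp_path):
    src = make_import_dir(tmp_path / "import", name="s")
    import_genome(src, empty_repo, organism="O", identifier="G1")
    (empty_repo / "organisms" / "O" / "genomes" / "G1" / "G1.fna").unlink()
    (empty_repo / "organisms" / "O" / "genomes" / "G1" / "G1.gff").unlink()
    report = validate_repo(empty_repo)
    assert report.violations == sorted(report.violations)


# ---------------------------------------------------------------------------
# selectors


def test_selector_parsing_forms():
    assert parse_selector("@tag:halophile").kind == "tag"
    assert parse_selector("@tax:Firmicutes").kind == "taxon"
    sel = parse_selector("@taxphylum:Firmicutes")
    assert sel.kind == "taxon_rank" and sel.rank == "phylum"
    assert parse_selector("G1").kind == "identifier"


def test_tag_selector_returns_representatives(fixture_repo):
    hits = resolve_selector("@tag:halophile", fixture_repo)
    reps = set(representative_genomes(fixture_repo).values())
    assert hits and hits <= reps


def test_bare_identifier_selector(fixture_repo):
    assert resolve_selector("ORG001-1", fixture_repo) == {"ORG001-1"}


def test_taxon_rank_selector_subset_of_any_rank(fixture_repo):
    for name in ("Firmicutes", "Actinobacteria", "Lactobacillus"):
        any_rank = resolve_selector(f"@tax:{name}", fixture_repo)
        for rank in ("phylum", "genus", "species"):
            assert resolve_selector(f"@tax{rank}:{name}", fixture_repo) <= any_rank


def test_selector_union_and_idempotence(fixture_repo):
    combined = resolve_selector("@tag:halophile,@tag:mesophile,ORG001-1", fixture_repo)
    assert combined == (
        resolve_selector("@tag:halophile", fixture_repo)
        | resolve_selector("@tag:mesophile", fixture_repo)
        | {"ORG001-1"}
    )
    assert combined == resolve_selector("ORG001-1,@tag:mesophile,@tag:halophile", fixture_repo)


def test_unknown_tokens_raise_not_found(fixture_repo):
    with pytest.raises(NotFoundError, match="nosuchtag"):
        resolve_selector("@tag:nosuchtag", fixture_repo)
    with pytest.raises(NotFoundError, match="Klingon"):
        resolve_selector("@tax:Klingon", fixture_repo)
    with pytest.raises(NotFoundError, match="GHOST"):
        resolve_selector("GHOST", fixture_repo)
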