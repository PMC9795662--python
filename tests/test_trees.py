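"""K-mer signatures, distances, UPGMA, taxonomy trees and Newick round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix

from genorepo import (
    InvalidInputError,
    NotFoundError,
    ParseError,
    distance_matrix,
    kmer_profile,
    kmer_profile_from_seqs,
    parse_newick,
    taxid_tree,
    upgma,
    write_newick,
)
from genorepo.fixtures import FixtureSpec, fixture_taxonomy
from genorepo.trees import KmerProfile, cophenetic_distances, is_ultrametric
from oracles import upgma_cophenetic_reference

dna = st.text(alphabet="ACGT", min_size=6, max_size=200)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# k-mer profiles


def test_single_window_profile():
    profile = kmer_profile_from_seqs(["AAAAAA"], k=6)
    assert profile.freq[0] == 1.0
    assert profile.freq.sum() == pytest.approx(1.0)


def test_ambiguous_bases_invalidate_windows():
    # valid 3-windows of ACGTNACGT: ACG, CGT, ACG, CGT; all canonicalize to ACG
    profile = kmer_profile_from_seqs(["ACGTNACGT"], k=3)
    acg = 0 * 16 + 1 * 4 + 2
    assert profile.freq[acg] == 1.0
    assert np.count_nonzero(profile.freq) == 1


def test_profile_without_valid_window_raises():
    with pytest.raises(InvalidInputError):
        kmer_profile_from_seqs(["NNNNNNNN"], k=6)
    with pytest.raises(InvalidInputError):
        kmer_profile_from_seqs(["ACG"], k=6)


@given(dna)
@settings(max_examples=200, deadline=None)
def test_profile_strand_independent(seq):
    p = kmer_profile_from_seqs([seq], k=3)
    q = kmer_profile_from_seqs([revcomp(seq)], k=3)
    assert np.allclose(p.freq, q.freq, atol=1e-12)


def test_profile_from_fasta_matches_sequences(fixture_repo):
    from genorepo import repo

    rec, gdir = next(iter(repo.iter_genomes(fixture_repo)))
    profile = kmer_profile(gdir / f"{rec.identifier}.fna")
    assert profile.genome == rec.identifier
    assert profile.k == 6
    assert profile.freq.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# distances


def test_distance_identical_and_disjoint():
    a = KmerProfile("A", 1, [0.5, 0.5, 0.0, 0.0])
    b = KmerProfile("B", 1, [0.0, 0.0, 0.5, 0.5])
    dm = distance_matrix([a, b])
    assert dm["A", "A"] == 0.0
    assert dm["A", "B"] == pytest.approx(1.0)


def test_distance_hand_computed():
    p = KmerProfile("P", 1, [0.5, 0.5, 0.0, 0.0])
    q = KmerProfile("Q", 1, [0.25, 0.25, 0.5, 0.0])
    assert distance_matrix([p, q])["P", "Q"] == pytest.approx(0.5)


def test_distance_rejects_mixed_k():
    with pytest.raises(InvalidInputError):
        distance_matrix(
            [KmerProfile("A", 1, [1, 0, 0, 0]), KmerProfile("B", 2, [1.0] + [0] * 15)]
        )


@given(st.lists(dna, min_size=3, max_size=3, unique=True))
@settings(max_examples=100, deadline=None)
def test_distance_is_a_metric(seqs):
    profiles = [kmer_profile_from_seqs([s], k=2, genome=f"G{i}") for i, s in enumerate(seqs)]
    dm = distance_matrix(profiles)
    d = dm.data
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
    assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()
    for i in range(3):
        for j in range(3):
            for k in range(3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_worked_example():
    dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"])
    assert write_newick(upgma(dm)) == "((A:1,B:1):1,C:2);"


def test_upgma_two_labels():
    dm = DistanceMatrix([[0, 0.6], [0.6, 0]], ids=["A", "B"])
    assert write_newick(upgma(dm)) == "(A:0.3,B:0.3);"


def test_upgma_requires_two_labels():
    with pytest.raises(InvalidInputError):
        upgma(DistanceMatrix([[0.0]], ids=["A"]))


def test_upgma_tie_break_is_permutation_invariant():
    labels = ["D", "B", "A", "C"]
    d = np.full((4, 4), 0.8)
    np.fill_diagonal(d, 0.0)
    reference = None
    for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 3, 0, 2]):
        ids = [labels[i] for i in perm]
        newick = write_newick(upgma(DistanceMatrix(d, ids=ids)))
        reference = reference or newick
        assert newick == reference


def test_upgma_matches_average_linkage_reference():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(3, 13))
        x = rng.random((n, 5))
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        np.fill_diagonal(d, 0.0)
        labels = [f"L{i:02d}" for i in range(n)]
        tree = upgma(DistanceMatrix(d, ids=labels))
        assert is_ultrametric(tree)
        coph = cophenetic_distances(tree, labels)
        assert np.allclose(coph, upgma_cophenetic_reference(d), atol=1e-8)


def test_duplicate_genome_forms_zero_length_cherry():
    p = KmerProfile("A", 1, [0.25, 0.25, 0.25, 0.25])
    twin = KmerProfile("A2", 1, [0.25, 0.25, 0.25, 0.25])
    q = KmerProfile("B", 1, [1.0, 0.0, 0.0, 0.0])
    dm = distance_matrix([p, twin, q])
    assert dm["A", "A2"] == 0.0
    tree = upgma(dm)
    tip = tree.find("A")
    assert tip.length == 0.0
    assert {t.name for t in tip.parent.tips()} == {"A", "A2"}


# ---------------------------------------------------------------------------
# taxonomy trees


@pytest.fixture(scope="module")
def small_taxonomy():
    taxonomy, taxids = fixture_taxonomy(FixtureSpec(n_organisms=4))
    return taxonomy, taxids


def test_taxid_tree_groups_congeneric_genomes(small_taxonomy):
    taxonomy, taxids = small_taxonomy
    # G1, G2 congeneric (Firmicutes genus), G3 in the other phylum
    tree = taxid_tree(
        {"G1": taxids["ORG001"], "G2": taxids["ORG002"], "G3": taxids["ORG003"]},
        taxonomy,
    )
    g1 = tree.find("G1")
    assert {t.name for t in g1.parent.tips()} == {"G1", "G2"}
    assert {t.name for t in tree.tips()} == {"G1", "G2", "G3"}


def test_taxid_tree_single_genome(small_taxonomy):
    taxonomy, taxids = small_taxonomy
    tree = taxid_tree({"G1": taxids["ORG001"]}, taxonomy)
    assert write_newick(tree) == "G1;"


def test_taxid_tree_same_taxid_star(small_taxonomy):
    taxonomy, taxids = small_taxonomy
    tree = taxid_tree({g: taxids["ORG001"] for g in ("G1", "G2", "G3")}, taxonomy)
    root_children = {c.name for c in tree.children}
    assert root_children == {"G1", "G2", "G3"}


def test_taxid_tree_unknown_taxid(small_taxonomy):
    taxonomy, _ = small_taxonomy
    with pytest.raises(NotFoundError, match="G1.*999999"):
        taxid_tree({"G1": 999999}, taxonomy)


# ---------------------------------------------------------------------------
# Newick


def test_newick_single_leaf():
    from skbio import TreeNode

    assert write_newick(TreeNode(name="A")) == "A;"


def test_newick_round_trip_upgma():
    dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ids=["A", "B", "C"])
    tree = upgma(dm)
    text = write_newick(tree)
    assert write_newick(parse_newick(text)) == text


def test_newick_quotes_labels_with_spaces():
    dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["my genome", "B"])
    text = write_newick(upgma(dm))
    assert "'my genome'" in text
    parsed = parse_newick(text)
    assert {t.name for t in parsed.tips()} == {"my genome", "B"}


def test_newick_parse_error():
    with pytest.raises(ParseError):
        parse_newick("((A:1,B:1:1,C:2);")
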