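"""Phylogenetic trees: k-mer signature trees (UPGMA) and taxonomy trees.

The signature tree follows the classic oligonucleotide-frequency approach:
each assembly is summarised as a vector of canonical k-mer frequencies
(hexanucleotides by default, a resolution with accuracy comparable to average
nucleotide identity for distinguishing microbial genomes), genome pairs are
compared with the total-variation distance d = 1/2 * sum |p_i - q_i|
(similarity = 1 - d), and the distance matrix is clustered with UPGMA into an
ultrametric dendrogram.

Canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement) make signatures strand-independent; windows containing ambiguity
codes are skipped rather than expanded.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

from .errors import InvalidInputError, NotFoundError, ParseError
from .taxonomy import Taxonomy

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _b, _v in zip(b"ACGT", range(4)):
    _BASE_CODE[_b] = _v
    _BASE_CODE[_b + 32] = _v  # lowercase


@lru_cache(maxsize=8)
def _canonical_codes(k: int) -> np.ndarray:
    """Map each k-mer code to the code of its canonical (strand-min) form."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    c = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (c & 3))
        c >>= 2
    return np.minimum(codes, rc)


@dataclass
class KmerProfile:
    """Canonical k-mer frequency vector of one genome assembly."""

    genome: str
    k: int
    freq: np.ndarray  # length 4**k, sums to 1

    def __post_init__(self):
        if self.k < 1:
            raise InvalidInputError("k must be >= 1")
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (4**self.k,):
            raise InvalidInputError(f"frequency vector must have length 4^{self.k}")


def kmer_profile_from_seqs(
    seqs: Iterable[str], k: int = 6, genome: str = ""
) -> KmerProfile:
    """Canonical k-mer profile of a set of sequences (e.g. contigs).

    Every k-length window consisting only of A/C/G/T (case-insensitive) is
    counted under its canonical code; counts are normalised to frequencies.
    Raises if no valid window exists.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    counts = np.zeros(4**k, dtype=np.int64)
    weights = (4 ** np.arange(k - 1, -1, -1, dtype=np.int64))
    canon = _canonical_codes(k)
    for seq in seqs:
        vals = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if len(vals) < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(vals, k)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        codes = windows[valid] @ weights
        counts += np.bincount(canon[codes], minlength=4**k)
    total = counts.sum()
    if total == 0:
        raise InvalidInputError(f"no valid {k}-mer window in input sequences")
    return KmerProfile(genome=genome, k=k, freq=counts / total)


def kmer_profile(fasta: str | Path, k: int = 6, genome: str | None = None) -> KmerProfile:
    """Canonical k-mer profile of all sequences in a FASTA file."""
    fasta = Path(fasta)
    if genome is None:
        genome = fasta.name.split(".")[0]
    seqs = [str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")]
    if not seqs:
        raise InvalidInputError(f"{fasta} contains no sequences")
    return kmer_profile_from_seqs(seqs, k=k, genome=genome)


def distance_matrix(profiles: Sequence[KmerProfile]) -> DistanceMatrix:
    """Total-variation distances between profiles: d = 1/2 * sum |p - q| in [0, 1]."""
    if len({p.k for p in profiles}) > 1:
        raise InvalidInputError("profiles have mixed k; cannot be compared")
    labels = [p.genome for p in profiles]
    mat = np.stack([p.freq for p in profiles])
    d = 0.5 * np.abs(mat[:, None, :] - mat[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return DistanceMatrix(d, ids=labels)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) dendrogram of a distance matrix.

    At each step the pair of clusters at minimal distance is merged; ties are
    broken by the lexicographically smallest pair of cluster labels (a cluster
    is labelled by its smallest leaf).  The merged node sits at half the merge
    distance; distances to other clusters are size-weighted means.  The result
    is ultrametric.
    """
    labels = list(dm.ids)
    if len(labels) < 2:
        raise InvalidInputError("UPGMA requires at least 2 labels")
    if len(set(labels)) != len(labels):
        raise InvalidInputError("distance matrix labels must be unique")
    clusters: dict[str, tuple[TreeNode, int, float]] = {
        lab: (TreeNode(name=lab), 1, 0.0) for lab in labels
    }
    dist: dict[frozenset, float] = {
        frozenset((a, b)): float(dm[a, b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }
    while len(clusters) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], tuple(sorted(kv[0]))))
        (pair, d) = best
        la, lb = sorted(pair)
        node_a, size_a, h_a = clusters.pop(la)
        node_b, size_b, h_b = clusters.pop(lb)
        height = d / 2.0
        node_a.length = height - h_a
        node_b.length = height - h_b
        merged = TreeNode(children=[node_a, node_b])
        new_label = la  # la < lb, so la is the smallest leaf of the merged cluster
        for other in clusters:
            da = dist.pop(frozenset((la, other)))
            db = dist.pop(frozenset((lb, other)))
            dist[frozenset((new_label, other))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        del dist[pair]
        clusters[new_label] = (merged, size_a + size_b, height)
    (root, _, _) = next(iter(clusters.values()))
    return root


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    """True if all root-to-leaf path lengths agree within *tol*."""
    depths = [
        sum(n.length or 0.0 for n in tip.ancestors() if n.length is not None)
        + (tip.length or 0.0)
        for tip in tree.tips()
    ]
    return max(depths) - min(depths) <= tol


def cophenetic_distances(tree: TreeNode, labels: Sequence[str]) -> np.ndarray:
    """Pairwise tree (path-length) distances between the given leaf labels."""
    dm = tree.tip_tip_distances(endpoints=list(labels))
    order = [list(dm.ids).index(l) for l in labels]
    return dm.data[np.ix_(order, order)]


def taxid_tree(
    genome_taxids: Mapping[str, int], taxonomy: Taxonomy
) -> TreeNode:
    """Taxonomy tree of a genome set (unit branch lengths, not ultrametric).

    The taxonomy is pruned to the union of the genomes' lineages, internal
    nodes with a single child and no attached genome are collapsed, and each
    genome is attached as a leaf under its organism's taxid.  Internal nodes
    are named by scientific name.
    """
    if not genome_taxids:
        raise InvalidInputError("no genomes given")
    lineages = {}
    for genome, taxid in sorted(genome_taxids.items()):
        if taxid not in taxonomy:
            raise NotFoundError(f"genome '{genome}': taxid {taxid} not in taxonomy")
        lineages[genome] = [n.taxid for n in taxonomy.lineage(taxid)]
    if len(lineages) == 1:
        (genome,) = lineages
        return TreeNode(name=genome)

    children: dict[int, set[int]] = {}
    genomes_at: dict[int, list[str]] = {}
    roots = set()
    for genome, lin in lineages.items():
        genomes_at.setdefault(lin[-1], []).append(genome)
        roots.add(lin[0])
        for parent, child in zip(lin, lin[1:]):
            children.setdefault(parent, set()).add(child)
    if len(roots) != 1:
        raise InvalidInputError("lineages do not share a single root")

    def build(taxid: int) -> TreeNode:
        kids = [build(c) for c in sorted(children.get(taxid, ()))]
        kids += [
            TreeNode(name=g, length=1.0) for g in sorted(genomes_at.get(taxid, ()))
        ]
        if len(kids) == 1:
            return kids[0]  # collapse unary taxon nodes
        node = TreeNode(name=taxonomy.node(taxid).scientific_name, children=kids)
        node.length = 1.0
        return node

    root = build(next(iter(roots)))
    root.length = None
    return root


# ---------------------------------------------------------------------------
# Newick serialization

_NEEDS_QUOTE = set(" ()[]':;,")


def _format_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode, digits: int = 6) -> str:
    """Serialize a tree to Newick with branch lengths at 6 significant digits."""

    def fmt(node: TreeNode) -> str:
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner})" + (_format_label(node.name) if node.name else "")
        else:
            s = _format_label(node.name or "")
        if node.length is not None:
            s += f":{node.length:.{digits}g}"
        return s

    return fmt(tree) + ";"


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string into a tree (no underscore munging)."""
    try:
        return TreeNode.read(StringIO(newick), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises its own parse error type
        raise ParseError(f"invalid Newick: {exc}") from exc
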