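"""NCBI-style taxonomy lineages backed by a flat TSV table.

The on-disk format is a four-column TSV (taxid, parent, rank, scientific_name),
one node per line, readable from an NCBI taxdump-derived export or written by
the fixture generator.  The root node is its own parent.  Nothing is ever
downloaded; the table ships with the repository.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import NotFoundError, ParseError


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy: taxid, parent taxid, rank and name."""

    taxid: int
    parent: int
    rank: str
    scientific_name: str


class Taxonomy:
    """An in-memory taxonomy supporting lineage queries by taxid or name."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self.nodes:
                raise ParseError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
        self._check_chains()
        self._by_name: dict[str, list[int]] = {}
        for node in self.nodes.values():
            self._by_name.setdefault(node.scientific_name, []).append(node.taxid)

    def _check_chains(self) -> None:
        for taxid in self.nodes:
            seen: set[int] = set()
            cur = taxid
            while True:
                if cur in seen:
                    raise ParseError(f"taxonomy cycle involving taxid {cur}")
                seen.add(cur)
                node = self.nodes.get(cur)
                if node is None:
                    raise ParseError(f"taxid {cur} has unknown parent chain member")
                if node.parent == cur:  # root
                    break
                cur = node.parent

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        nodes = []
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ParseError("expected 4 tab-separated columns", line=i)
                try:
                    taxid, parent = int(fields[0]), int(fields[1])
                except ValueError:
                    raise ParseError(f"non-integer taxid in {fields[:2]}", line=i)
                nodes.append(TaxonNode(taxid, parent, fields[2], fields[3]))
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for taxid in sorted(self.nodes):
                n = self.nodes[taxid]
                fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.scientific_name}\n")

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise NotFoundError(f"taxid {taxid} not in taxonomy")

    def lineage(self, taxid: int) -> list[TaxonNode]:
        """Root-first list of nodes from the root down to *taxid* (inclusive)."""
        out = []
        cur = taxid
        while True:
            node = self.node(cur)
            out.append(node)
            if node.parent == cur:
                break
            cur = node.parent
        return list(reversed(out))

    def has_name(self, name: str) -> bool:
        return name in self._by_name

    def lineage_contains(self, taxid: int, name: str, rank: str | None = None) -> bool:
        """True if *name* occurs in the lineage of *taxid*, optionally at *rank*."""
        for node in self.lineage(taxid):
            if node.scientific_name == name and (rank is None or node.rank == rank):
                return True
        return False
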