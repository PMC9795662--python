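"""Gene-trait matching: exact association tests between annotation presence
and a binary phenotype across two disjoint genome groups.

For every annotation seen in at least one selected genome, a 2x2 presence/
absence table is built (a genome "has" an annotation if at least one of its
genes carries it), a two-sided Fisher's exact test is computed with exact
rational arithmetic, and Benjamini-Hochberg correction is applied jointly
across all tested annotations (default alpha = 0.10).

The two-sided p-value follows the probability-mass ordering used by R's
fisher.test: the sum of hypergeometric probabilities of all tables with the
same margins whose probability does not exceed that of the observed table.
Exact integer binomial coefficients avoid ties being broken by float noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import annotations as _ann
from .errors import InvalidInputError


@dataclass(frozen=True)
class ContingencyTable:
    """Presence/absence counts: a/b = group1 with/without, c/d = group2 with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidInputError("contingency table cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact_fraction(table: ContingencyTable) -> Fraction:
    """Two-sided exact p-value as an exact rational number."""
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    k = a + c  # first-column margin
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or k == 0 or k == n:
        return Fraction(1)
    # weight of a table with top-left x is C(r1, x) * C(r2, k - x);
    # probabilities share the denominator C(n, k)
    obs = comb(r1, a) * comb(r2, c)
    lo, hi = max(0, k - r2), min(r1, k)
    total = sum(
        w for x in range(lo, hi + 1) if (w := comb(r1, x) * comb(r2, k - x)) <= obs
    )
    return Fraction(total, comb(n, k))


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact test p-value (float, capped at 1.0)."""
    return min(1.0, float(fisher_exact_fraction(table)))


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return fisher_exact(ContingencyTable(a, b, c, d))


def benjamini_hochberg(
    pvalues: Sequence[float], alpha: float = 0.1
) -> tuple[list[float], list[bool]]:
    """Step-up Benjamini-Hochberg: q-values (in input order) and rejections.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; a hypothesis is rejected
    iff its q-value is at most *alpha*.
    """
    pvalues = list(pvalues)
    if any(not (0.0 <= p <= 1.0) for p in pvalues):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if not pvalues:
        return [], []
    rejected, qvalues, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return [float(q) for q in qvalues], [bool(r) for r in rejected]


@dataclass
class TraitMatchResult:
    """One annotation's association with the trait."""

    annotation: str
    table: ContingencyTable
    p: float
    q: float
    significant: bool


def trait_tests_from_presence(
    presence: Mapping[str, set[str]] | pd.DataFrame,
    group1: Iterable[str],
    group2: Iterable[str],
    alpha: float = 0.1,
) -> list[TraitMatchResult]:
    """Core gene-trait matching on a presence structure.

    *presence* is either a boolean DataFrame (annotations x genomes) or a
    mapping genome -> set of annotation identifiers.  Annotations absent from
    every selected genome are not tested (they would inflate the number of
    hypotheses arbitrarily).  Results are sorted by q, then p, then identifier.
    """
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise InvalidInputError("both groups must be non-empty")
    overlap = set(g1) & set(g2)
    if overlap:
        raise InvalidInputError(f"groups must be disjoint; shared: {sorted(overlap)}")

    if isinstance(presence, pd.DataFrame):
        sets = {g: set(presence.index[presence[g].astype(bool)]) for g in g1 + g2}
    else:
        sets = {g: set(presence[g]) for g in g1 + g2}
    tested = sorted(set().union(*sets.values())) if sets else []

    results = []
    for ann in tested:
        a = sum(1 for g in g1 if ann in sets[g])
        c = sum(1 for g in g2 if ann in sets[g])
        table = ContingencyTable(a, len(g1) - a, c, len(g2) - c)
        results.append((ann, table, _fisher_cached(a, table.b, c, table.d)))
    qvalues, rejected = benjamini_hochberg([p for _, _, p in results], alpha=alpha)
    out = [
        TraitMatchResult(ann, table, p, q, sig)
        for (ann, table, p), q, sig in zip(results, qvalues, rejected)
    ]
    out.sort(key=lambda r: (r.q, r.p, r.annotation))
    return out


def gene_trait_match(
    group1: Iterable[str],
    group2: Iterable[str],
    root: str | Path,
    alpha: float = 0.1,
    annotation_type: str | None = None,
) -> list[TraitMatchResult]:
    """Gene-trait matching over repository genomes (optionally one annotation type)."""
    g1, g2 = list(group1), list(group2)
    if not g1 or not g2:
        raise InvalidInputError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise InvalidInputError("groups must be disjoint")
    sets = _ann.genome_annotation_sets(root, g1 + g2, type_key=annotation_type)
    return trait_tests_from_presence(sets, g1, g2, alpha=alpha)


def results_to_frame(results: Sequence[TraitMatchResult]) -> pd.DataFrame:
    """Tabular view (one row per annotation) suitable for TSV export."""
    return pd.DataFrame(
        {
            "annotation": [r.annotation for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
        }
    )
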