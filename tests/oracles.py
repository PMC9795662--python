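"""Independent brute-force reference implementations used only by the tests."""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> Fraction:
    """Literal definition: enumerate every table with the observed margins and
    sum the probabilities of those no more probable than the observed one.

    Probabilities are integer arrangement counts C(r1, x) * C(r2, k - x) over
    the common denominator, so the comparison is exact.
    """
    r1, r2, k = a + b, c + d, a + c
    tables = []
    for x in range(0, min(r1, k) + 1):
        y = k - x
        if 0 <= y <= r2:
            tables.append((x, y))
    weights = {t: comb(r1, t[0]) * comb(r2, t[1]) for t in tables}
    total = sum(weights.values())
    if total == 0:
        return Fraction(1)
    w_obs = weights[(a, c)]
    return Fraction(sum(w for w in weights.values() if w <= w_obs), total)


def bh_step_up(pvalues, alpha):
    """The Benjamini-Hochberg step-up procedure applied literally."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank, 1.0)
        q[i] = running
    return q, [qi <= alpha for qi in q]


def upgma_cophenetic_reference(d: np.ndarray) -> np.ndarray:
    """Cophenetic (first-merge) distances from scipy's average linkage."""
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    z = linkage(squareform(d, checks=False), method="average")
    return squareform(cophenet(z))


def flower_brute_force(sets):
    """Classify every annotation by its genome-membership count."""
    genomes = sorted(sets)
    n = len(genomes)
    anns = set().union(*(sets[g] for g in genomes))
    core = 0
    unique = {g: 0 for g in genomes}
    shared = {g: 0 for g in genomes}
    for ann in anns:
        members = [g for g in genomes if ann in sets[g]]
        if len(members) == n:
            core += 1
        elif len(members) == 1:
            unique[members[0]] += 1
        else:
            for g in members:
                shared[g] += 1
    return core, unique, shared
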