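"""Independent brute-force oracles used by the test suite.

Every function here recomputes a statistic by direct enumeration or
first-principles summation, deliberately avoiding the code paths (and where
possible the libraries) the implementation uses.
"""
from __future__ import annotations

import itertools
from math import comb

from Bio.Seq import Seq


def hypergeom_depletion_p(a: int, n1: int, c: int, n2: int) -> float:
    """One-sided (depletion) Fisher p for table [[a, n1-a], [c, n2-c]] by
    direct hypergeometric summation with exact integer combinatorics."""
    col1 = a + c
    n = n1 + n2
    denom = comb(n, col1)
    num = 0
    for k in range(0, a + 1):
        if col1 - k <= n2:
            num += comb(n1, k) * comb(n2, col1 - k)
    return num / denom


def bh_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg q-values by the textbook step-up recursion."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p_values[i] * m / rank)
        q[i] = min(1.0, val)
        prev = val
    return q


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites(codon: str) -> tuple[float, float]:
    """Site counts by trying every single-nucleotide mutation against the
    standard genetic code (via Biopython translation)."""
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = non_stop = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            t = _translate(codon[:pos] + nt + codon[pos + 1 :])
            if t == "*":
                continue
            non_stop += 1
            if t == aa:
                syn += 1
        if non_stop:
            s += syn / non_stop
    return s, 3.0 - s


def ng86_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Difference counts by explicit enumeration of every mutational pathway
    (all orderings of the differing positions), dropping stop-passing paths."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = codon_a
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if _translate(nxt) == "*":
                ok = False
                break
            steps.append(_translate(cur) == _translate(nxt))
            cur = nxt
        if ok:
            paths.append(steps)
    if not paths:
        return None  # caller handles the no-stop-free-path case separately
    s = sum(sum(p) for p in paths) / len(paths)
    n = sum(len(p) - sum(p) for p in paths) / len(paths)
    return s, n


def mannwhitney_exact_two_sided(a: list[float], b: list[float]) -> float:
    """Exact two-sided Mann-Whitney p by enumerating index permutations and
    computing U from midranks: P(|U - n_a n_b/2| >= |U_obs - n_a n_b/2|)."""
    from scipy.stats import rankdata

    pooled = list(a) + list(b)
    na, nb = len(a), len(b)
    ranks = rankdata(pooled)

    def u_of(indices: tuple[int, ...]) -> float:
        r_a = sum(ranks[i] for i in indices)
        return r_a - na * (na + 1) / 2.0

    center = na * nb / 2.0
    u_obs = u_of(tuple(range(na)))
    hits = total = 0
    for combo in itertools.combinations(range(na + nb), na):
        total += 1
        if abs(u_of(combo) - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return hits / total
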