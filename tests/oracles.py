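"""Independent brute-force oracles used by the test suite.

Each oracle derives its expected value by a different route than the
implementation it checks: exhaustive pair enumeration for HGT calls,
exact rational hypergeometric enumeration for the 2x2 test, and a
first-paired-position decomposition (memoised but exhaustive over
structures) for maximum base pairing.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb

from integronhgt.model import CassetteRecord, reverse_complement


def brute_force_hgt_pairs(records: list[CassetteRecord]) -> set[tuple[str, str]]:
    """All unordered cross-species pairs where the shorter sequence is an
    exact substring (or equal) of the longer, on either strand; shorter
    sequences containing N never match."""
    out: set[tuple[str, str]] = set()
    for a in records:
        for b in records:
            if a.cassette_id >= b.cassette_id:
                continue
            if a.species_label == b.species_label:
                continue
            s, l = sorted((a.sequence, b.sequence), key=len)
            if "N" in s:
                continue
            if s in l or s in reverse_complement(l):
                out.add((a.cassette_id, b.cassette_id))
    return out


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher p by full enumeration over tables with the
    observed margins, using exact rational probabilities."""
    (a, b), (c, d) = table
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), denom)

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = prob(a)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(total)


def max_pairs_exhaustive(seq: str, min_loop: int = 3, allow_gu: bool = True) -> int:
    """Maximum number of nested base pairs, derived by decomposing on the
    5'-most paired position and its partner (memoised exhaustive search,
    a different recursion than the folding DP)."""
    rna = seq.upper().replace("T", "U")
    ok = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    if allow_gu:
        ok |= {("G", "U"), ("U", "G")}

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = 0
        for k in range(i, j):  # first paired position; [i, k) unpaired
            for l in range(k + min_loop + 1, j + 1):
                if (rna[k], rna[l]) in ok:
                    cand = 1 + f(k + 1, l - 1) + f(l + 1, j)
                    if cand > best:
                        best = cand
        return best

    return f(0, len(rna) - 1) if rna else 0
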