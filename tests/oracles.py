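"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths they check: plain-Python dynamic
programming for alignment scores, genetic-code table lookups for codon
effects, and outcome enumeration for the exact binomial test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

# plain dict genetic code, written out independently of Biopython
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def nw_score(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
             gap: float = -2.0) -> float:
    """Optimal global alignment score by full-table Needleman-Wunsch DP."""
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0.0] * m
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def classify_codon_pair(ref: str, alt: str) -> str:
    """Translate-and-compare classification of a single-position codon pair."""
    aa_ref, aa_alt = GENETIC_CODE[ref], GENETIC_CODE[alt]
    if "*" in (aa_ref, aa_alt):
        return "stop_involved"
    n_diff = sum(x != y for x, y in zip(ref, alt))
    if n_diff == 0:
        return "none"
    if n_diff >= 2:
        return "multi_hit"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def exact_binomial_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p at p0=1/2 by enumeration over all counts,
    summing the probability of every outcome no more likely than observed
    (minimum-likelihood definition). Exact rational arithmetic."""
    denom = Fraction(1, 2**n)
    p_obs = comb(n, k)
    total = sum(comb(n, j) for j in range(n + 1) if comb(n, j) <= p_obs)
    return float(total * denom)


def column_identity(row_a: str, row_b: str) -> float:
    """Percent identity over gap-free columns by direct column counting."""
    comparable = matches = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y and x != "N":
            matches += 1
    return 100.0 * matches / comparable
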