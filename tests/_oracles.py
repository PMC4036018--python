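"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain dynamic programs
and exact-arithmetic Bayes calculations that the fast implementations are
checked against.
"""

from __future__ import annotations

from fractions import Fraction

# IUPAC base sets, re-derived here independently of the package tables.
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_compatible(a: str, b: str) -> bool:
    return bool(set(_IUPAC[a.upper()]) & set(_IUPAC[b.upper()]))


def semiglobal_edit_distance(window: str, primer: str) -> int:
    """Ends-free (on the window) Levenshtein with IUPAC zero-cost matches."""
    if not window:
        return len(primer)
    np_, nw = len(primer), len(window)
    prev = [0] * (nw + 1)  # primer prefix length 0: free placement
    for i in range(1, np_ + 1):
        cur = [i] + [0] * nw
        for j in range(1, nw + 1):
            sub = 0 if iupac_compatible(window[j - 1], primer[i - 1]) else 1
            cur[j] = min(prev[j - 1] + sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def gotoh_local_score(
    q: str, s: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> float:
    """Affine-gap local alignment score; a gap of length k costs
    gap_open + (k-1)*gap_extend.  Plain cubic-memory DP."""
    NEG = float("-inf")
    nq, ns = len(q), len(s)
    H = [[0.0] * (ns + 1) for _ in range(nq + 1)]
    E = [[NEG] * (ns + 1) for _ in range(nq + 1)]
    F = [[NEG] * (ns + 1) for _ in range(nq + 1)]
    best = 0.0
    for i in range(1, nq + 1):
        for j in range(1, ns + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            both_acgt = q[i - 1] in "ACGT" and q[i - 1] == s[j - 1]
            sub = match if both_acgt else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def words_of(seq: str, w: int) -> list[str]:
    return sorted({
        seq[i:i + w] for i in range(len(seq) - w + 1)
        if set(seq[i:i + w]) <= set("ACGT")
    })


def bayes_posteriors(
    training: dict[str, list[str]], query: str, w: int
) -> dict[str, Fraction]:
    """Exact joint word likelihood per genus, computed with Fractions.

    training maps genus -> training sequences.  Uses presence/absence counts
    per training sequence: P(word) = (n+1/2)/(N+1),
    P(word|G) = (m + P(word))/(M_G + 1), likelihood = product over the
    distinct query words.
    """
    N = sum(len(seqs) for seqs in training.values())
    result: dict[str, Fraction] = {}
    qwords = words_of(query, w)
    for genus, seqs in training.items():
        prob = Fraction(1)
        for word in qwords:
            n = sum(
                1 for other in training.values() for t in other if word in t
            )
            m = sum(1 for t in seqs if word in t)
            p_word = Fraction(2 * n + 1, 2 * (N + 1))
            prob *= (m + p_word) / (len(seqs) + 1)
        result[genus] = prob
    return result


def bayes_argmax(training: dict[str, list[str]], query: str, w: int) -> set[str]:
    """The set of genera attaining the exact maximum likelihood."""
    post = bayes_posteriors(training, query, w)
    best = max(post.values())
    return {g for g, p in post.items() if p == best}
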