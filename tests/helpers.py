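"""Independent oracles used by the test suite.

These deliberately re-derive results through different routes than the
package: a full (unbanded) dynamic program for alignment scores, exact
rational hypergeometric tail sums for Fisher p-values, and Biopython's
translate for protein consequences.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

NEG = -(10 ** 9)


def full_dp_glocal_score(query: str, ref: str, match=2, mismatch=-3,
                         gap_open=-5, gap_extend=-2) -> int:
    """Unbanded affine-gap glocal score (query global, reference free ends).

    Same state semantics as the package aligner (D opens from M only, I
    opens from M only), but computed over the full matrix with numpy row
    recurrences instead of a banded kernel.
    """
    enc = {c: i for i, c in enumerate("ACGTN")}
    q = np.array([enc[c] for c in query.upper()])
    r = np.array([enc[c] for c in ref.upper()])
    m, n = len(q), len(r)
    M = np.zeros(n + 1, dtype=np.int64)  # row 0: free reference prefix
    D = np.full(n + 1, NEG, dtype=np.int64)
    I = np.full(n + 1, NEG, dtype=np.int64)
    ge = gap_extend
    go = gap_open
    idx = np.arange(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        prev_best = np.maximum(np.maximum(M, D), I)  # previous row
        sub = np.where((r == q[i - 1]) & (q[i - 1] < 4), match, mismatch)
        M_new = np.full(n + 1, NEG, dtype=np.int64)
        M_new[1:] = prev_best[:-1] + sub
        I_new = np.maximum(M + go + ge, I + ge)
        # D along the row: D[j] = max_{k<j}(M_new[k]) + go + (j-k)*ge
        run = np.maximum.accumulate(M_new - idx * ge)
        D_new = np.full(n + 1, NEG, dtype=np.int64)
        D_new[1:] = run[:-1] + go + ge + idx[1:] * ge - ge
        M, D, I = M_new, D_new, I_new
    return int(max(M.max(), I.max()))


def exact_fisher_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact one-sided (enrichment of a) Fisher p for [[a, b], [c, d]].

    P[X >= a] for X hypergeometric with N=a+b+c+d, K=a+c successes, sample
    n=a+b, computed as an exact rational via binomial coefficients.
    """
    N, K, n = a + b + c + d, a + c, a + b
    total = comb(N, n)
    s = sum(comb(K, k) * comb(N - K, n - k)
            for k in range(a, min(K, n) + 1))
    return Fraction(s, total)


def translate_to_stop(cds: str) -> str:
    """Protein (including trailing '*') via Biopython, independent route."""
    from Bio.Seq import Seq

    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    if "*" in prot:
        return prot[: prot.index("*") + 1]
    return prot
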