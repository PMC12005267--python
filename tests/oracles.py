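"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately literal: they re-derive each quantity from first
principles (explicit reverse-complement strands, exact Fraction
arithmetic, the textbook step-up definition) and share no code with the
package paths they verify.
"""

from fractions import Fraction
from math import comb

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def oracle_window_counts(seq: str, pos: int, window: int = 20):
    """Literal both-strand scan for cytosines and gCn motifs in the
    window [pos-window, pos+window] (1-based, truncated at contig ends).

    The minus strand is materialised explicitly as the reverse
    complement with its own coordinates.  A motif's 5' guanine is read
    wherever it lies on the contig, even outside the window; the 3'
    wildcard base imposes nothing.
    """
    L = len(seq)
    lo, hi = max(1, pos - window), min(L, pos + window)
    n_cyt = n_gcn = 0
    for i in range(lo, hi + 1):
        if seq[i - 1] == "C":
            n_cyt += 1
            if i >= 2 and seq[i - 2] == "G":
                n_gcn += 1
    minus = rc(seq)
    for i in range(lo, hi + 1):
        j = L - i + 1  # coordinate of plus-position i on the minus strand
        if minus[j - 1] == "C":
            n_cyt += 1
            if j >= 2 and minus[j - 2] == "G":
                n_gcn += 1
    return n_cyt, n_gcn


def oracle_classify(seq: str, pos: int, ref: str, alt: str):
    """(klass, context) by explicit reverse complementation, or None if
    the 3-mer is unavailable (edge or N)."""
    assert seq[pos - 1] == ref
    if pos == 1 or pos == len(seq):
        return None
    trimer = seq[pos - 2 : pos + 1]
    if "N" in trimer:
        return None
    if ref in "AG":
        trimer = rc(trimer)
        ref, alt = COMP[ref], COMP[alt]
    return f"{ref}>{alt}", trimer[0].lower() + trimer[1] + trimer[2].lower()


def oracle_fisher_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact one-sided (greater) Fisher p for [[a, b], [c, d]] by direct
    hypergeometric tail enumeration in rational arithmetic."""
    row1, k = a + b, a + c
    N = a + b + c + d
    denom = comb(N, k)
    hi = min(row1, k)
    num = sum(comb(row1, x) * comb(N - row1, k - x) for x in range(a, hi + 1))
    return Fraction(num, denom)


def oracle_bh(pvals):
    """Textbook Benjamini-Hochberg step-up with monotonicity, preserving
    input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def oracle_build_table(contig_seqs: dict, mutations, window: int = 20):
    """Brute-force contingency table for gCn->A over a pooled cohort.

    ``mutations`` are (contig, pos, ref, alt) tuples.
    """
    mut_sig = mut_all = ctx_sig = ctx_all = 0
    for contig, pos, ref, alt in mutations:
        seq = contig_seqs[contig]
        classified = oracle_classify(seq, pos, ref, alt)
        if classified is None:
            continue
        klass, context = classified
        if klass != "C>A":
            continue
        mut_all += 1
        if context[0] == "g":
            mut_sig += 1
        n_cyt, n_gcn = oracle_window_counts(seq, pos, window)
        ctx_sig += n_gcn
        ctx_all += n_cyt
    return mut_sig, mut_all, ctx_sig, ctx_all
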