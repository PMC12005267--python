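"""Strand-collapsed substitution classes, trinucleotide contexts and
windowed motif counting.

Mutation spectra follow the field convention of reporting every single
base substitution as a pyrimidine change: a G→T call is counted as C→A
on the opposite strand, and its trinucleotide context is reverse
complemented accordingly.  Contexts are written with lowercase flanks
and an uppercase mutated base ("gCa").

Motif counting serves the signature-enrichment statistic: for a motif
such as gCn (mutated cytosine with a 5' guanine, any 3' base) we need,
around each mutated residue, the number of cytosines and the number of
motif-context cytosines on *both* strands.  Both counts are properties
of the genome position, so a cytosine at the edge of a window keeps its
motif status even when its flanking guanine lies just outside the
window.  A plus-strand 5'-GC-3' dinucleotide therefore contributes two
motif cytosines (one per strand) — the numerical convention mirroring
the strand collapse applied to the mutations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ContextUndefined, RefMismatchError, ValidationError
from .io_formats import COMPLEMENT, Genome, MutationRecord, revcomp

PYRIMIDINE_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

IUPAC = {
    "a": "A", "c": "C", "g": "G", "t": "T",
    "r": "AG", "y": "CT", "s": "CG", "w": "AT",
    "k": "GT", "m": "AC", "b": "CGT", "d": "AGT",
    "h": "ACT", "v": "ACG", "n": "ACGT",
}
_COMP_SET = {frozenset(v): frozenset(COMPLEMENT[b] for b in v) for v in IUPAC.values()}


@dataclass(frozen=True)
class Motif:
    """A central-pyrimidine trinucleotide motif such as ``gCn`` or ``tCw``.

    The string form uses lowercase IUPAC flanks and an uppercase central
    pyrimidine.  A constrained flank (anything narrower than ``n``) must
    lie inside the contig and be A/C/G/T for a site to match — a C at a
    contig end with no 5' neighbor is not a gCn cytosine — whereas a
    wildcard ``n`` flank imposes nothing, so a 3'-terminal gC still
    counts as gCn.  Genome N never satisfies a constrained flank.
    """

    left: frozenset
    center: str
    right: frozenset
    text: str

    @classmethod
    def parse(cls, text: str) -> "Motif":
        if len(text) != 3:
            raise ValidationError(f"motif {text!r} must be 3 characters")
        lo, ce, hi = text[0], text[1], text[2]
        if ce not in ("C", "T"):
            raise ValidationError(
                f"motif {text!r}: central base must be an uppercase pyrimidine (C or T)"
            )
        try:
            left, right = frozenset(IUPAC[lo]), frozenset(IUPAC[hi])
        except KeyError:
            raise ValidationError(
                f"motif {text!r}: flanks must be lowercase IUPAC codes"
            ) from None
        return cls(left=left, center=ce, right=right, text=text)

    def matches_context(self, context: str) -> bool:
        """Does a pyrimidine-frame context string ("gCa") match?"""
        return (
            context[1] == self.center
            and context[0].upper() in self.left
            and context[2].upper() in self.right
        )


GCN = Motif.parse("gCn")


@dataclass(frozen=True)
class PyrimidineChange:
    """A strand-collapsed substitution: class plus pyrimidine-frame context."""

    klass: str  # one of PYRIMIDINE_CLASSES
    context: str  # e.g. "gCa": lowercase flanks, uppercase mutated base

    def __post_init__(self):
        if self.klass not in PYRIMIDINE_CLASSES:
            raise ValidationError(f"unknown substitution class {self.klass!r}")
        if self.context[1] != self.klass[0]:
            raise ValidationError(
                f"context {self.context!r} center disagrees with class {self.klass}"
            )


def classify_sbs(genome: Genome, m: MutationRecord) -> PyrimidineChange:
    """Classify one SNV as a pyrimidine change with trinucleotide context.

    Purine-reference mutations are reverse complemented so the mutated
    base is reported as a pyrimidine.  A reference mismatch is a hard
    error; a contig-edge position or an N anywhere in the 3-mer raises
    :class:`ContextUndefined` (a skip signal the caller counts).
    """
    m.check_against(genome)
    seq = genome[m.contig]
    if m.pos == 1 or m.pos == len(seq):
        raise ContextUndefined(
            f"{m.contig}:{m.pos}: no trinucleotide context at contig edge"
        )
    trimer = seq[m.pos - 2 : m.pos + 1]
    if "N" in trimer:
        raise ContextUndefined(f"{m.contig}:{m.pos}: N in trinucleotide context")
    ref, alt = m.ref, m.alt
    if ref in PURINES:
        trimer = revcomp(trimer)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    context = trimer[0].lower() + trimer[1] + trimer[2].lower()
    return PyrimidineChange(klass=f"{ref}>{alt}", context=context)


# ---------------------------------------------------------------------------
# Windowed counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowCounts:
    """Both-strand counts in a window around a mutated residue."""

    n_cyt: int
    n_motif: int

    def __post_init__(self):
        if not 0 <= self.n_motif <= self.n_cyt:
            raise ValidationError(
                f"motif count {self.n_motif} exceeds cytosine count {self.n_cyt}"
            )


class ContextIndex:
    """Per-genome prefix sums for O(1) windowed motif/cytosine queries.

    For a central-pyrimidine motif the per-position indicators are:

    * ``center``: the position carries the motif's central base on either
      strand (for C-motifs: the plus-strand base is C or G);
    * ``motif``: the full trinucleotide matches on the plus strand
      (left·center·right at i−1..i+1) or on the minus strand (the
      reverse complement pattern read from the plus strand).

    Neighbors are evaluated wherever they lie in the contig, even just
    outside a query window.
    """

    def __init__(self, genome: Genome, motif: Motif = GCN):
        self.genome = genome
        self.motif = motif
        self._cum_center: dict[str, np.ndarray] = {}
        self._cum_motif: dict[str, np.ndarray] = {}
        self._is_motif: dict[str, np.ndarray] = {}
        self._is_center: dict[str, np.ndarray] = {}
        comp_center = COMPLEMENT[motif.center]
        comp_left = _COMP_SET[motif.left]
        comp_right = _COMP_SET[motif.right]
        any_base = frozenset("ACGT")

        def flank_ok(arr: np.ndarray, charset: frozenset, shift: int) -> np.ndarray:
            """True where the flank ``shift`` bases away satisfies ``charset``.

            A wildcard flank constrains nothing (even off-contig); a
            constrained flank off the contig end never matches.
            """
            n = len(arr)
            if charset == any_base:
                return np.ones(n, dtype=bool)
            member = np.isin(arr, [b.encode() for b in sorted(charset)])
            out = np.zeros(n, dtype=bool)
            if shift == -1:
                out[1:] = member[:-1]
            else:
                out[:-1] = member[1:]
            return out

        for name, seq in genome.contigs.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
            is_center = (arr == motif.center.encode()) | (arr == comp_center.encode())
            # plus strand: left flank at i-1, center at i, right at i+1
            plus = (
                (arr == motif.center.encode())
                & flank_ok(arr, motif.left, -1)
                & flank_ok(arr, motif.right, +1)
            )
            # minus strand: plus-strand base complements the center; the
            # motif's left flank sits at i+1, its right flank at i-1
            minus = (
                (arr == comp_center.encode())
                & flank_ok(arr, comp_left, +1)
                & flank_ok(arr, comp_right, -1)
            )
            is_motif = plus | minus
            self._is_center[name] = is_center
            self._is_motif[name] = is_motif
            self._cum_center[name] = np.concatenate(
                ([0], np.cumsum(is_center, dtype=np.int64))
            )
            self._cum_motif[name] = np.concatenate(
                ([0], np.cumsum(is_motif, dtype=np.int64))
            )

    def window_counts(self, contig: str, pos: int, window: int = 20) -> WindowCounts:
        """Counts over positions [pos−window, pos+window] ∩ contig."""
        length = self.genome.length(contig)
        if not 1 <= pos <= length:
            raise ValidationError(
                f"position {pos} outside contig {contig!r} (length {length})"
            )
        lo = max(1, pos - window)
        hi = min(length, pos + window)
        cum_c, cum_m = self._cum_center[contig], self._cum_motif[contig]
        return WindowCounts(
            n_cyt=int(cum_c[hi] - cum_c[lo - 1]),
            n_motif=int(cum_m[hi] - cum_m[lo - 1]),
        )

    def site_arrays(self, contig: str) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (is_center, is_motif) arrays, 0-based, for one contig."""
        return self._is_center[contig], self._is_motif[contig]


def window_counts(
    genome: Genome,
    contig: str,
    pos: int,
    window: int = 20,
    motif: Motif | str = GCN,
    index: ContextIndex | None = None,
) -> WindowCounts:
    """Count cytosines and motif-context cytosines (both strands) within
    ``window`` bp of a mutated residue, the residue itself included.

    The window is symmetric and truncated at contig ends; motif flanks
    may be evaluated one base beyond the window edge (but never beyond
    the contig).
    """
    if isinstance(motif, str):
        motif = Motif.parse(motif)
    if index is None:
        index = ContextIndex(genome, motif)
    elif index.motif.text != motif.text:
        raise ValidationError(
            f"index built for motif {index.motif.text}, queried with {motif.text}"
        )
    return index.window_counts(contig, pos, window)


# ---------------------------------------------------------------------------
# Spectrum tables
# ---------------------------------------------------------------------------

def all_contexts() -> list[str]:
    """The 96 strand-collapsed context-substitution labels, sorted."""
    out = []
    for klass in PYRIMIDINE_CLASSES:
        src, dst = klass.split(">")
        for lo in "acgt":
            for hi in "acgt":
                out.append(f"{lo}{src}{hi}>{dst}")
    return out


@dataclass
class SpectrumTable:
    """Per-isolate and cohort-level strand-collapsed mutation spectra.

    ``per_isolate`` maps sample -> {class -> count} over the 6 pyrimidine
    classes; ``per_context`` maps sample -> {context label -> count} over
    the 96 trinucleotide categories (label form "gCa>A").  ``skipped``
    counts records without a defined context (contig edge or N).
    """

    per_isolate: dict[str, dict[str, int]] = field(default_factory=dict)
    per_context: dict[str, dict[str, int]] = field(default_factory=dict)
    skipped: dict[str, int] = field(default_factory=dict)

    def cohort_mean(self, samples: Iterable[str] | None = None) -> dict[str, float]:
        """Arithmetic mean count per isolate for each of the 6 classes."""
        names = list(samples) if samples is not None else list(self.per_isolate)
        if not names:
            raise ValidationError("cohort mean of an empty sample set")
        return {
            k: float(np.mean([self.per_isolate[s].get(k, 0) for s in names]))
            for k in PYRIMIDINE_CLASSES
        }

    def to_frames(self):
        """(6-class, 96-context) pandas views for writing."""
        import pandas as pd

        rows6 = [
            {"sample": s, **{k: c.get(k, 0) for k in PYRIMIDINE_CLASSES},
             "skipped": self.skipped.get(s, 0)}
            for s, c in self.per_isolate.items()
        ]
        ctx = all_contexts()
        rows96 = [
            {"sample": s, **{k: c.get(k, 0) for k in ctx}}
            for s, c in self.per_context.items()
        ]
        return pd.DataFrame(rows6), pd.DataFrame(rows96)


def spectrum(
    genome: Genome, per_sample: Mapping[str, Iterable[MutationRecord]]
) -> SpectrumTable:
    """Tally strand-collapsed substitution classes and 96 contexts per
    isolate.  Records without a defined trinucleotide context are counted
    under ``skipped``, never silently dropped."""
    table = SpectrumTable()
    for sample, records in per_sample.items():
        by_class = {k: 0 for k in PYRIMIDINE_CLASSES}
        by_ctx: dict[str, int] = {}
        skipped = 0
        for rec in records:
            try:
                change = classify_sbs(genome, rec)
            except ContextUndefined:
                skipped += 1
                continue
            by_class[change.klass] += 1
            label = f"{change.context}>{change.klass[2]}"
            by_ctx[label] = by_ctx.get(label, 0) + 1
        table.per_isolate[sample] = by_class
        table.per_context[sample] = by_ctx
        table.skipped[sample] = skipped
    return table
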