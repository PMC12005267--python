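"""TriMS: trinucleotide mutation-signature enrichment with Fisher testing.

The statistic asks whether, among the strand-collapsed C→A mutations of
a cohort, the fraction falling in the signature context (gCn by default)
exceeds the fraction of cytosines carrying that context in the ±20 bp
genomic background around the same mutated residues:

    enrichment = (mut_sig / mut_all) / (ctx_sig / ctx_all)

where ``mut_sig`` counts signature-context target-class mutations,
``mut_all`` all target-class mutations, and ``ctx_sig`` / ``ctx_all``
the summed window counts of motif-context cytosines and of all
cytosines (both strands) over each counted mutation's window.  A value
above 1 indicates positive enrichment.  Significance comes from a
one-sided (greater) Fisher's exact test on the disjoint 2×2 table

    [[mut_sig, mut_all − mut_sig], [ctx_sig, ctx_all − ctx_sig]]

and q-values are Benjamini–Hochberg over the cohorts analysed together.
Because induced mutation counts per isolate are small, cohorts pool all
isolates of one genotype × treatment condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy.stats import fisher_exact

from .errors import ContextUndefined, UndefinedStatistic, ValidationError
from .genome_context import GCN, ContextIndex, Motif, classify_sbs
from .io_formats import Genome, MutationRecord


@dataclass(frozen=True)
class ContingencyTable:
    """Counts feeding the enrichment ratio and Fisher's test.

    ``n_skipped`` (not part of the table identity) counts records whose
    trinucleotide context was undefined and which were therefore
    excluded from both the mutation and the background counts.
    """

    mut_sig: int
    mut_all: int
    ctx_sig: int
    ctx_all: int
    n_skipped: int = field(default=0, compare=False)

    def __post_init__(self):
        if min(self.mut_sig, self.mut_all, self.ctx_sig, self.ctx_all) < 0:
            raise ValidationError("contingency counts must be non-negative")
        if self.mut_sig > self.mut_all:
            raise ValidationError(
                f"mut_sig {self.mut_sig} exceeds mut_all {self.mut_all}"
            )
        if self.ctx_sig > self.ctx_all:
            raise ValidationError(
                f"ctx_sig {self.ctx_sig} exceeds ctx_all {self.ctx_all}"
            )

    @property
    def is_empty(self) -> bool:
        """No target-class mutations: enrichment is undefined downstream."""
        return self.mut_all == 0


def build_table(
    genome: Genome,
    mutations: Iterable[MutationRecord],
    window: int = 20,
    motif: Motif | str = GCN,
    target_alt: str = "A",
    index: ContextIndex | None = None,
) -> ContingencyTable:
    """Assemble the signature contingency table for one pooled cohort.

    Only strand-collapsed mutations of the target class (central motif
    base → ``target_alt``; gCn→A by default, so G→T at nGc on the plus
    strand is included) enter the table.  Background windows are taken
    around exactly those mutations.  Records whose context is undefined
    (contig edge, N) are excluded from numerator and background alike and
    tallied in ``n_skipped``.
    """
    if isinstance(motif, str):
        motif = Motif.parse(motif)
    if index is None:
        index = ContextIndex(genome, motif)
    target_class = f"{motif.center}>{target_alt}"
    mut_sig = mut_all = ctx_sig = ctx_all = skipped = 0
    for rec in mutations:
        try:
            change = classify_sbs(genome, rec)
        except ContextUndefined:
            skipped += 1
            continue
        if change.klass != target_class:
            continue
        mut_all += 1
        if motif.matches_context(change.context):
            mut_sig += 1
        wc = index.window_counts(rec.contig, rec.pos, window)
        ctx_sig += wc.n_motif
        ctx_all += wc.n_cyt
    return ContingencyTable(mut_sig, mut_all, ctx_sig, ctx_all, n_skipped=skipped)


def enrichment(table: ContingencyTable) -> float:
    """The signature enrichment ratio.

    Returns 0 when no signature mutations were seen, +inf when signature
    mutations occur over a zero motif background, and raises
    :class:`UndefinedStatistic` on an empty table.  No pseudocounts.
    """
    if table.is_empty:
        raise UndefinedStatistic("no target-class mutations: enrichment undefined")
    if table.mut_sig == 0:
        return 0.0
    if table.ctx_sig == 0:
        return math.inf
    return (table.mut_sig / table.mut_all) / (table.ctx_sig / table.ctx_all)


def fisher_one_sided(table: ContingencyTable) -> float:
    """One-sided (greater) Fisher's exact p-value for the 2×2 table
    [[mut_sig, mut_all−mut_sig], [ctx_sig, ctx_all−ctx_sig]]."""
    if table.is_empty:
        raise UndefinedStatistic("no target-class mutations: test undefined")
    _, p = fisher_exact(
        [
            [table.mut_sig, table.mut_all - table.mut_sig],
            [table.ctx_sig, table.ctx_all - table.ctx_sig],
        ],
        alternative="greater",
    )
    return float(p)


@dataclass(frozen=True)
class EnrichmentResult:
    """One cohort's enrichment call; ``enrichment``/``p``/``q`` are None
    when the cohort had no target-class mutations."""

    cohort: str
    table: ContingencyTable
    enrichment: float | None
    p: float | None
    q: float | None

    @property
    def defined(self) -> bool:
        return self.p is not None


def analyze_cohorts(
    genome: Genome,
    cohorts: Mapping[str, Iterable[MutationRecord]],
    window: int = 20,
    motif: Motif | str = GCN,
    target_alt: str = "A",
) -> list[EnrichmentResult]:
    """Run the enrichment statistic over several pooled cohorts.

    The Benjamini–Hochberg family is the set of cohorts with a defined
    test in this call; undefined cohorts are reported with None markers
    and excluded from the correction.
    """
    from .assay_stats import bh_correct

    if not cohorts:
        raise ValidationError("analyze_cohorts needs at least one cohort")
    if isinstance(motif, str):
        motif = Motif.parse(motif)
    index = ContextIndex(genome, motif)
    names, tables, enrichments, pvals = [], [], [], []
    for name, muts in cohorts.items():
        table = build_table(
            genome, muts, window=window, motif=motif,
            target_alt=target_alt, index=index,
        )
        names.append(name)
        tables.append(table)
        if table.is_empty:
            enrichments.append(None)
            pvals.append(None)
        else:
            enrichments.append(enrichment(table))
            pvals.append(fisher_one_sided(table))
    defined = [p for p in pvals if p is not None]
    qmap = iter(bh_correct(defined)) if defined else iter(())
    results = []
    for name, table, e, p in zip(names, tables, enrichments, pvals):
        q = next(qmap) if p is not None else None
        results.append(EnrichmentResult(name, table, e, p, q))
    return results


def results_frame(results: Iterable[EnrichmentResult]):
    """Tabular view with columns cohort,n_mut,n_sig,ctx_sig,ctx_all,
    enrichment,p,q (None rendered as NA by the writer)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cohort": r.cohort,
                "n_mut": r.table.mut_all,
                "n_sig": r.table.mut_sig,
                "ctx_sig": r.table.ctx_sig,
                "ctx_all": r.table.ctx_all,
                "n_skipped": r.table.n_skipped,
                "enrichment": r.enrichment,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    )
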