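"""Mutation curation: VAF filtering and removal of preexisting calls.

Sequenced mutant isolates carry, besides the induced mutations of
interest, (a) sub-clonal calls with low variant allele frequency,
(b) variants already present in the original pre-treatment culture, and
(c) variants shared by two or more isolates, which in a clonal plating
experiment indicates a preexisting event rather than independent
induction.  Curation removes all three, with an exact accounting of
every record's fate.

Fates are assigned with fixed precedence — VAF first, then baseline,
then shared — so a record failing several rules is counted exactly once
and the report always partitions the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ValidationError
from .io_formats import MutationKey, MutationRecord

FATES = ("kept", "below_vaf", "baseline", "shared")


@dataclass(frozen=True)
class FilterReport:
    """Exact partition of curated records by fate."""

    n_input: int
    n_below_vaf: int
    n_preexisting_baseline: int
    n_shared: int
    n_kept: int

    def __post_init__(self):
        total = (
            self.n_below_vaf
            + self.n_preexisting_baseline
            + self.n_shared
            + self.n_kept
        )
        if total != self.n_input:
            raise ValidationError(
                f"filter report does not partition input: {total} != {self.n_input}"
            )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "n_input": self.n_input,
                    "n_below_vaf": self.n_below_vaf,
                    "n_preexisting_baseline": self.n_preexisting_baseline,
                    "n_shared": self.n_shared,
                    "n_kept": self.n_kept,
                }
            ]
        )


def vaf_filter(
    records: Iterable[MutationRecord], threshold: float = 0.90
) -> list[MutationRecord]:
    """Keep records with VAF >= threshold (inclusive); order preserved.

    The inclusive boundary keeps homozygous-like calls sitting exactly at
    the threshold.  A record without a VAF is a hard error.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"VAF threshold {threshold} not in (0, 1]")
    kept = []
    for rec in records:
        if rec.vaf is None:
            raise ValidationError(
                f"record {rec.sample} {rec.contig}:{rec.pos} "
                f"{rec.ref}>{rec.alt} lacks a VAF; cannot apply VAF filter"
            )
        if rec.vaf >= threshold:
            kept.append(rec)
    return kept


def _shared_keys(
    per_sample: Mapping[str, Iterable[MutationRecord]], share_min: int
) -> set[MutationKey]:
    # sample-set based: duplicates within one sample count once
    carriers: dict[MutationKey, set[str]] = {}
    for sample, records in per_sample.items():
        for rec in records:
            carriers.setdefault(rec.key, set()).add(sample)
    return {k for k, s in carriers.items() if len(s) >= share_min}


def remove_preexisting(
    per_sample: Mapping[str, list[MutationRecord]],
    baseline: Iterable[MutationRecord] = (),
    share_min: int = 2,
) -> tuple[dict[str, list[MutationRecord]], FilterReport]:
    """Drop baseline-resident keys, then keys shared by >= share_min samples.

    ``baseline`` is the mutation set of the sequenced original
    (pre-treatment) culture.  The shared rule counts *distinct* carrier
    samples across the whole batch and removes the key from every
    carrier.  Each removed record is counted once, baseline taking
    precedence over shared.
    """
    if share_min < 2:
        raise ValidationError(f"share_min must be >= 2, got {share_min}")
    baseline_keys = {rec.key for rec in baseline}
    shared = _shared_keys(per_sample, share_min)
    n_input = n_base = n_shared = n_kept = 0
    filtered: dict[str, list[MutationRecord]] = {}
    for sample, records in per_sample.items():
        kept = []
        for rec in records:
            n_input += 1
            if rec.key in baseline_keys:
                n_base += 1
            elif rec.key in shared:
                n_shared += 1
            else:
                kept.append(rec)
                n_kept += 1
        filtered[sample] = kept
    report = FilterReport(
        n_input=n_input,
        n_below_vaf=0,
        n_preexisting_baseline=n_base,
        n_shared=n_shared,
        n_kept=n_kept,
    )
    return filtered, report


def curate(
    per_sample: Mapping[str, list[MutationRecord]],
    baseline: Iterable[MutationRecord] = (),
    vaf_threshold: float = 0.90,
    share_min: int = 2,
) -> tuple[dict[str, list[MutationRecord]], FilterReport]:
    """Full curation: VAF filter first, then baseline/shared removal.

    Deterministic given inputs; the report partitions every input record
    into exactly one of {below_vaf, baseline, shared, kept}.
    """
    n_input = 0
    high_vaf: dict[str, list[MutationRecord]] = {}
    n_below = 0
    for sample, records in per_sample.items():
        n_input += len(records)
        kept = vaf_filter(records, vaf_threshold)
        n_below += len(records) - len(kept)
        high_vaf[sample] = kept
    filtered, sub = remove_preexisting(high_vaf, baseline, share_min)
    report = FilterReport(
        n_input=n_input,
        n_below_vaf=n_below,
        n_preexisting_baseline=sub.n_preexisting_baseline,
        n_shared=sub.n_shared,
        n_kept=sub.n_kept,
    )
    return filtered, report
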