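"""Plating-assay and qPCR statistics.

A canavanine-resistance (CanR) plating assay measures mutagenesis: CAN1
is counter-selectable, so inactivating point mutations let colonies grow
on canavanine.  For each culture

    mutation frequency = CanR colonies/mL ÷ viable colonies/mL

and cellular viability after treatment is

    viability % = 100 × viable/mL (treated) ÷ viable/mL (untreated),

with water-treated cultures annotated at 100% by definition.  Treatment
arms are compared with a Mann–Whitney U test (exact enumeration for
small arms, tie-corrected normal approximation otherwise) on a fold
change defined as the ratio of arm medians, with Benjamini–Hochberg
q-values across all tests of one analysis run.

qPCR expression is double-normalized: ΔCt = target − reference (ACT1)
per strain, ΔΔCt = ΔCt(strain) − ΔCt(wild type, same growth condition),
fold change = 2^−ΔΔCt; the wild type is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import UndefinedStatistic, ValidationError
from .io_formats import AssayMeasurement, CtRecord

EXACT_MAX_N = 8  # per-arm size up to which the exact U distribution is used


def mutation_frequency(m: AssayMeasurement) -> float:
    """CanR colonies/mL over viable colonies/mL for one culture."""
    if m.viable_per_ml <= 0:
        raise ValidationError(
            f"{m.genotype}: viable colonies/mL must be positive"
        )
    return m.canr_per_ml / m.viable_per_ml


def viability_percent(treated_viable: float, untreated_viable: float) -> float:
    """100 × treated / untreated viable colony densities."""
    if untreated_viable <= 0:
        raise ValidationError("untreated viable colonies/mL must be positive")
    return 100.0 * treated_viable / untreated_viable


def _mwu_p(x: Sequence[float], y: Sequence[float]) -> float:
    # exact U distribution for small arms; tie-corrected normal beyond
    method = "exact" if max(len(x), len(y)) <= EXACT_MAX_N else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_arms(
    untreated: Sequence[float], treated: Sequence[float]
) -> tuple[float | None, float]:
    """Fold change (ratio of medians, treated/untreated) and two-sided
    Mann–Whitney p-value.

    Fold is None (undefined) when the untreated median is zero.
    """
    if len(untreated) == 0 or len(treated) == 0:
        raise ValidationError("both arms need at least one measurement")
    med_u = float(np.median(untreated))
    med_t = float(np.median(treated))
    fold = med_t / med_u if med_u > 0 else None
    return fold, _mwu_p(untreated, treated)


def bh_correct(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    pvals = list(pvals)
    if not pvals:
        return []
    for p in pvals:
        if not 0.0 < p <= 1.0:
            raise ValidationError(f"p-value {p} outside (0, 1]")
    return [float(q) for q in multipletests(pvals, method="fdr_bh")[1]]


@dataclass(frozen=True)
class FrequencyResult:
    genotype: str
    median_untreated: float
    median_treated: float
    fold: float | None
    p: float
    q: float
    n_untreated: int
    n_treated: int


@dataclass(frozen=True)
class ViabilityResult:
    genotype: str
    viabilities: tuple
    median_viability: float
    p: float | None
    q: float | None


def _group(measurements: Iterable[AssayMeasurement]):
    groups: dict[str, dict[str, list[AssayMeasurement]]] = {}
    for m in measurements:
        groups.setdefault(m.genotype, {"untreated": [], "treated": []})[
            m.treatment
        ].append(m)
    return groups


def analyze_frequency(
    measurements: Iterable[AssayMeasurement],
) -> list[FrequencyResult]:
    """Per-genotype treated-vs-untreated mutation-frequency comparison.

    The BH family is all genotypes in this call, mirroring a q-value
    correction across every frequency assay of one study.
    """
    groups = _group(measurements)
    partial = []
    for genotype, arms in groups.items():
        if not arms["untreated"] or not arms["treated"]:
            raise ValidationError(
                f"genotype {genotype!r} lacks one of the treatment arms"
            )
        freq_u = [mutation_frequency(m) for m in arms["untreated"]]
        freq_t = [mutation_frequency(m) for m in arms["treated"]]
        fold, p = compare_arms(freq_u, freq_t)
        partial.append((genotype, freq_u, freq_t, fold, p))
    qvals = bh_correct([p for *_, p in partial])
    return [
        FrequencyResult(
            genotype=g,
            median_untreated=float(np.median(fu)),
            median_treated=float(np.median(ft)),
            fold=fold,
            p=p,
            q=q,
            n_untreated=len(fu),
            n_treated=len(ft),
        )
        for (g, fu, ft, fold, p), q in zip(partial, qvals)
    ]


def analyze_viability(
    measurements: Iterable[AssayMeasurement],
    mode: str = "vs_wildtype",
    wildtype: str = "WT",
) -> list[ViabilityResult]:
    """Per-genotype viability percentages with rank tests.

    Each treated culture's viability is 100 × its viable density over
    the median untreated viable density of the same genotype (the
    untreated arm sits at 100% by definition).  ``mode`` selects the
    comparison: "vs_wildtype" tests each genotype's treated viabilities
    against the wild-type strain's, "vs_untreated" against the 100%
    baseline.  The wild type itself (or a degenerate comparison) gets
    p = None and is excluded from BH.
    """
    if mode not in ("vs_wildtype", "vs_untreated"):
        raise ValidationError(f"unknown viability comparison mode {mode!r}")
    groups = _group(measurements)
    if mode == "vs_wildtype" and wildtype not in groups:
        raise ValidationError(
            f"wild-type genotype {wildtype!r} absent from the assay table"
        )
    viab: dict[str, list[float]] = {}
    for genotype, arms in groups.items():
        if not arms["untreated"] or not arms["treated"]:
            raise ValidationError(
                f"genotype {genotype!r} lacks one of the treatment arms"
            )
        ref = float(np.median([m.viable_per_ml for m in arms["untreated"]]))
        viab[genotype] = [
            viability_percent(m.viable_per_ml, ref) for m in arms["treated"]
        ]
    partial: list[tuple[str, list[float], float | None]] = []
    for genotype, values in viab.items():
        if mode == "vs_wildtype":
            p = None if genotype == wildtype else _mwu_p(viab[wildtype], values)
        else:
            p = _mwu_p([100.0] * len(values), values)
        partial.append((genotype, values, p))
    defined = [p for *_, p in partial if p is not None]
    qiter = iter(bh_correct(defined))
    return [
        ViabilityResult(
            genotype=g,
            viabilities=tuple(v),
            median_viability=float(np.median(v)),
            p=p,
            q=next(qiter) if p is not None else None,
        )
        for g, v, p in partial
    ]


def ddct_fold(sample: CtRecord, baseline: CtRecord) -> float:
    """Expression fold change 2^−ΔΔCt of ``sample`` relative to the
    condition-matched wild-type ``baseline``."""
    if sample.condition != baseline.condition:
        raise ValidationError(
            f"condition mismatch: sample grown in {sample.condition!r}, "
            f"baseline in {baseline.condition!r}"
        )
    dct_sample = sample.target_ct - sample.reference_ct
    dct_base = baseline.target_ct - baseline.reference_ct
    ddct = dct_sample - dct_base
    return float(2.0 ** (-ddct))


def qpcr_folds(records: Sequence[CtRecord], wildtype: str = "WT"):
    """Fold-change table for a batch of Ct measurements.

    Each record is normalized against the mean ΔCt of the wild-type
    records grown in the same condition.  Returns a pandas DataFrame
    with columns sample, condition, ddct, fold.
    """
    import pandas as pd

    base_dct: dict[str, float] = {}
    for condition in sorted({r.condition for r in records}):
        wt = [r for r in records if r.sample == wildtype and r.condition == condition]
        if not wt:
            raise ValidationError(
                f"no wild-type ({wildtype!r}) Ct record for condition {condition!r}"
            )
        base_dct[condition] = float(
            np.mean([r.target_ct - r.reference_ct for r in wt])
        )
    rows = []
    for r in records:
        ddct = (r.target_ct - r.reference_ct) - base_dct[r.condition]
        rows.append(
            {
                "sample": r.sample,
                "condition": r.condition,
                "ddct": ddct,
                "fold": float(2.0 ** (-ddct)),
            }
        )
    return pd.DataFrame(rows)
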