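"""Synthetic inputs with known ground truth.

Every input the analysis consumes can be generated here: small random
genomes, per-isolate SNV cohorts with a controlled excess of C→A
changes in gCn context, variant tables contaminated with preexisting /
shared / sub-threshold calls, plating-assay colony counts with a
specified treated/untreated fold difference, and a four-cohort study
layout (two genotypes × two treatments) with the signature spiked into
a single cohort.

All randomness flows through :class:`numpy.random.Generator` seeded
explicitly, so outputs are bit-reproducible across platforms.

Signature injection
-------------------
C→A mutations are placed on cytosine sites of the genome (plus-strand C
or G — the latter being a minus-strand cytosine, emitted as a G→T
record).  The default ``calibration="windowed"`` mode chooses the
fraction ``f`` of mutations landing on motif-context sites by solving

    f / [ f·m̄ᵍₛ + (1−f)·m̄ᵍₙ ] × [ f·m̄ᶜₛ + (1−f)·m̄ᶜₙ ] = E

where m̄ᵍ/m̄ᶜ are the genome's exact mean window counts of motif
cytosines / all cytosines around motif (s) and non-motif (n) sites —
i.e. ``f`` is calibrated so the *windowed* enrichment statistic has
expectation equal to the target ``E``.  The alternative
``calibration="odds"`` multiplies the motif-vs-non-motif selection odds
by ``E`` directly (at E = 1 this is exactly uniform placement over
cytosines, the null used for calibration tests); its expected windowed
estimate falls below E for E > 1 because window backgrounds around
signature mutations contain the signature site and its partner-strand
mate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .genome_context import GCN, ContextIndex, Motif
from .io_formats import COMPLEMENT, AssayMeasurement, Genome, MutationKey, MutationRecord

BASES = np.array([b"A", b"C", b"G", b"T"])

# fixed plating-model constants: untreated viable cell density and the
# lognormal sigma of plating/counting noise on viable counts
UNTREATED_VIABLE_PER_ML = 2.0e7
VIABLE_NOISE_SIGMA = 0.05

OTHER_CLASSES = ("C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class SpikeConfig:
    """How to spike one cohort of isolates with mutations.

    Defaults emulate a weak-mutagen experiment: a handful of mutations
    per sequenced isolate, a majority of C→A changes, and a twofold
    signature enrichment.
    """

    n_mutations: int = 15
    frac_CtoA: float = 0.6
    target_enrichment: float = 2.0
    background_classes: Mapping[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in OTHER_CLASSES}
    )
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.frac_CtoA <= 1.0:
            raise ValidationError(f"frac_CtoA {self.frac_CtoA} not in [0, 1]")
        if self.target_enrichment < 0:
            raise ValidationError("target_enrichment must be >= 0")
        if self.n_mutations < 0:
            raise ValidationError("n_mutations must be >= 0")
        bad = set(self.background_classes) - set(OTHER_CLASSES)
        if bad:
            raise ValidationError(f"unknown background classes {sorted(bad)}")


@dataclass(frozen=True)
class AssaySimConfig:
    """Plating-assay simulation parameters.

    Defaults mirror an acute-exposure fluctuation-style experiment:
    12 cultures per arm, untreated CanR frequency around 1e-6,
    a 2.5-fold treatment effect, half-log culture-to-culture lognormal
    spread, and a 56% viability drop in the treated arm.
    """

    n_cultures_per_arm: int = 12
    base_frequency: float = 1.0e-6
    true_fold: float = 2.5
    lognormal_sigma: float = 0.5
    viability_drop: float = 0.56
    seed: int = 0

    def __post_init__(self):
        if self.n_cultures_per_arm < 1:
            raise ValidationError("need at least one culture per arm")
        if self.base_frequency <= 0 or self.true_fold < 0:
            raise ValidationError("base_frequency must be > 0 and true_fold >= 0")
        if self.lognormal_sigma < 0:
            raise ValidationError("lognormal_sigma must be >= 0")
        if not 0.0 <= self.viability_drop < 1.0:
            raise ValidationError("viability_drop must be in [0, 1)")


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def gen_genome(
    n_contigs: int = 2,
    length_per_contig: int = 50_000,
    gc_fraction: float = 0.38,
    seed: int = 0,
) -> Genome:
    """Random i.i.d. genome at a target GC content (yeast-like 0.38
    by default).  Reproducible for a fixed seed."""
    if n_contigs < 1 or length_per_contig < 100:
        raise ValidationError(
            "need n_contigs >= 1 and length_per_contig >= 100"
        )
    if not 0.0 < gc_fraction < 1.0:
        raise ValidationError(f"gc_fraction {gc_fraction} not in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    probs = [at, gc, gc, at]
    contigs = {}
    for i in range(n_contigs):
        draw = rng.choice(BASES, size=length_per_contig, p=probs)
        contigs[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return Genome(contigs)


# ---------------------------------------------------------------------------
# Mutation spike-in
# ---------------------------------------------------------------------------

class _SitePools:
    """Flattened genome site pools and window statistics for one motif."""

    def __init__(self, genome: Genome, motif: Motif, window: int = 20):
        self.genome = genome
        self.names = list(genome.contigs)
        self.offsets = np.cumsum([0] + [genome.length(n) for n in self.names])
        index = ContextIndex(genome, motif)
        self.index = index
        motif_idx, non_idx, t_idx = [], [], []
        sum_gs = sum_cs = n_s = 0.0
        sum_gn = sum_cn = n_n = 0.0
        for ci, name in enumerate(self.names):
            is_center, is_motif = index.site_arrays(name)
            seq = np.frombuffer(genome[name].encode("ascii"), dtype="S1")
            off = self.offsets[ci]
            length = len(seq)
            m = np.flatnonzero(is_motif)
            n = np.flatnonzero(is_center & ~is_motif)
            t = np.flatnonzero((seq == b"A") | (seq == b"T"))
            motif_idx.append(m + off)
            non_idx.append(n + off)
            t_idx.append(t + off)
            # vectorized window sums via the index's prefix arrays
            cum_c = index._cum_center[name]
            cum_m = index._cum_motif[name]
            for pool, which in ((m, "s"), (n, "n")):
                if len(pool) == 0:
                    continue
                pos1 = pool + 1  # 1-based
                lo = np.maximum(1, pos1 - window)
                hi = np.minimum(length, pos1 + window)
                g = (cum_m[hi] - cum_m[lo - 1]).astype(float)
                c = (cum_c[hi] - cum_c[lo - 1]).astype(float)
                if which == "s":
                    sum_gs += g.sum()
                    sum_cs += c.sum()
                    n_s += len(pool)
                else:
                    sum_gn += g.sum()
                    sum_cn += c.sum()
                    n_n += len(pool)
        self.motif_idx = np.concatenate(motif_idx)
        self.non_idx = np.concatenate(non_idx)
        self.t_idx = np.concatenate(t_idx)
        self.mean_motif_win = (
            sum_gs / n_s if n_s else 0.0,
            sum_cs / n_s if n_s else 0.0,
        )
        self.mean_non_win = (
            sum_gn / n_n if n_n else 0.0,
            sum_cn / n_n if n_n else 0.0,
        )

    def locate(self, gidx: int) -> tuple[str, int]:
        """Global 0-based index -> (contig, 1-based position)."""
        ci = int(np.searchsorted(self.offsets, gidx, side="right")) - 1
        return self.names[ci], int(gidx - self.offsets[ci]) + 1


def signature_fraction(
    pools: _SitePools, target_enrichment: float, calibration: str
) -> float:
    """The probability that a spiked C→A mutation lands on a motif site."""
    E = target_enrichment
    M, NM = len(pools.motif_idx), len(pools.non_idx)
    if M == 0 or NM == 0:
        raise ValidationError(
            "genome needs both motif and non-motif cytosines for spiking"
        )
    if E == 0:
        return 0.0
    if calibration == "odds":
        return E * M / (E * M + NM)
    if calibration != "windowed":
        raise ValidationError(f"unknown calibration mode {calibration!r}")
    mg_s, mc_s = pools.mean_motif_win
    mg_n, mc_n = pools.mean_non_win

    def g(f: float) -> float:
        ctx_sig = f * mg_s + (1.0 - f) * mg_n
        ctx_all = f * mc_s + (1.0 - f) * mc_n
        return f * ctx_all - E * ctx_sig

    if g(1.0) < 0:
        raise ValidationError(
            f"target enrichment {E} not achievable on this genome "
            "(motif background too dense)"
        )
    return float(brentq(g, 0.0, 1.0, xtol=1e-12))


def _record_for_site(
    pools: _SitePools, gidx: int, klass: str, sample: str
) -> MutationRecord:
    contig, pos = pools.locate(int(gidx))
    src, dst = klass.split(">")
    base = pools.genome.base(contig, pos)
    if base == src:
        ref, alt = src, dst
    else:
        ref, alt = COMPLEMENT[src], COMPLEMENT[dst]
    if ref != base:  # defensive: pool membership guarantees this
        raise ValidationError(f"site pool inconsistent at {contig}:{pos}")
    return MutationRecord(sample, contig, pos, ref, alt, vaf=1.0)


def spike_mutations(
    genome: Genome,
    cfg: SpikeConfig,
    n_samples: int = 1,
    motif: Motif | str = GCN,
    window: int = 20,
    calibration: str = "windowed",
    sample_prefix: str = "S",
    pools: _SitePools | None = None,
) -> dict[str, list[MutationRecord]]:
    """Generate per-isolate SNV cohorts with a controlled gCn→A excess.

    C→A mutations land on cytosine sites (both strands; minus-strand
    cytosines yield G→T records) with the motif-site probability set by
    ``signature_fraction``; the other five pyrimidine classes are placed
    uniformly on their source bases.  Positions are disjoint within a
    sample *and* across the samples of one call — independent isolates
    essentially never acquire the same induced mutation, and disjoint
    placement keeps downstream ground-truth fate labels unambiguous.
    Every record carries VAF 1.0.
    """
    if isinstance(motif, str):
        motif = Motif.parse(motif)
    if pools is None:
        pools = _SitePools(genome, motif, window)
    f_sig = signature_fraction(pools, cfg.target_enrichment, calibration)
    rng = np.random.default_rng(cfg.seed)
    weights = np.array(
        [float(cfg.background_classes.get(k, 0.0)) for k in OTHER_CLASSES]
    )
    n_ca = int(round(cfg.n_mutations * cfg.frac_CtoA))
    n_other = cfg.n_mutations - n_ca
    if weights.sum() <= 0 and n_other > 0:
        raise ValidationError(
            "background_classes weights sum to zero but non-C>A mutations requested"
        )
    out: dict[str, list[MutationRecord]] = {}
    used = np.zeros(int(pools.offsets[-1]), dtype=bool)
    for s in range(n_samples):
        sample = f"{sample_prefix}{s + 1}"
        counts_other = (
            rng.multinomial(n_other, weights / weights.sum())
            if n_other > 0
            else np.zeros(5, dtype=int)
        )
        n_sig = int(rng.binomial(n_ca, f_sig)) if n_ca > 0 else 0
        n_nonsig = n_ca - n_sig
        n_other_c = int(counts_other[0] + counts_other[1])  # C>G, C>T
        n_t = int(counts_other[2] + counts_other[3] + counts_other[4])
        motif_free = pools.motif_idx[~used[pools.motif_idx]]
        non_free = pools.non_idx[~used[pools.non_idx]]
        t_free = pools.t_idx[~used[pools.t_idx]]
        if n_sig > len(motif_free) or n_nonsig > len(non_free):
            raise ValidationError(
                "more C>A mutations requested than available cytosine sites"
            )
        mperm = rng.permutation(motif_free)
        nperm = rng.permutation(non_free)
        sig_sites = mperm[:n_sig]
        nonsig_sites = nperm[:n_nonsig]
        rest_c = np.concatenate([mperm[n_sig:], nperm[n_nonsig:]])
        if n_other_c > len(rest_c) or n_t > len(t_free):
            raise ValidationError(
                "more mutations requested than available genome sites"
            )
        other_c = rng.choice(rest_c, size=n_other_c, replace=False)
        t_sites = rng.choice(t_free, size=n_t, replace=False)
        records: list[MutationRecord] = []
        for g in np.concatenate([sig_sites, nonsig_sites]):
            records.append(_record_for_site(pools, g, "C>A", sample))
        cursor = 0
        for klass, cnt in zip(("C>G", "C>T"), counts_other[:2]):
            for g in other_c[cursor : cursor + cnt]:
                records.append(_record_for_site(pools, g, klass, sample))
            cursor += int(cnt)
        cursor = 0
        for klass, cnt in zip(("T>A", "T>C", "T>G"), counts_other[2:]):
            for g in t_sites[cursor : cursor + cnt]:
                records.append(_record_for_site(pools, g, klass, sample))
            cursor += int(cnt)
        for chosen in (sig_sites, nonsig_sites, other_c, t_sites):
            if len(chosen):
                used[chosen.astype(np.int64)] = True
        out[sample] = records
    return out


# ---------------------------------------------------------------------------
# Contamination of variant tables
# ---------------------------------------------------------------------------

def contaminate(
    per_sample: Mapping[str, list[MutationRecord]],
    genome: Genome,
    n_preexisting: int = 5,
    n_shared_pairs: int = 5,
    frac_low_vaf: float = 0.1,
    seed: int = 0,
) -> tuple[dict[str, list[MutationRecord]], list[MutationRecord], dict]:
    """Inject the artefacts the curation filters must remove.

    Adds ``n_preexisting`` fresh baseline-resident keys (each also
    planted into one random sample), ``n_shared_pairs`` fresh keys each
    planted into two distinct samples, and re-assigns a sub-threshold
    VAF (uniform on [0.2, 0.85]) to each original record independently
    with probability ``frac_low_vaf``.

    Returns ``(contaminated map, baseline records, truth)`` where
    ``truth[(sample, key)]`` is the expected curation fate of every
    record: "kept", "below_vaf", "baseline" or "shared".
    """
    if not 0.0 <= frac_low_vaf <= 1.0:
        raise ValidationError(f"frac_low_vaf {frac_low_vaf} not in [0, 1]")
    samples = list(per_sample)
    if n_shared_pairs > 0 and len(samples) < 2:
        raise ValidationError("shared contamination needs at least 2 samples")
    rng = np.random.default_rng(seed)
    used: set[tuple[str, int]] = {
        (r.contig, r.pos) for recs in per_sample.values() for r in recs
    }
    names = list(genome.contigs)
    lengths = np.array([genome.length(n) for n in names], dtype=float)

    def fresh_key() -> MutationKey:
        while True:
            ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
            pos = int(rng.integers(1, lengths[ci] + 1))
            contig = names[ci]
            if (contig, pos) in used:
                continue
            ref = genome.base(contig, pos)
            if ref == "N":
                continue
            used.add((contig, pos))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            return MutationKey(contig, pos, ref, alt)

    out = {s: list(recs) for s, recs in per_sample.items()}
    truth: dict[tuple[str, MutationKey], str] = {}

    # sub-threshold VAFs on the original records
    for s in samples:
        adjusted = []
        for rec in out[s]:
            if rng.random() < frac_low_vaf:
                low = float(rng.uniform(0.2, 0.85))
                rec = MutationRecord(rec.sample, rec.contig, rec.pos,
                                     rec.ref, rec.alt, vaf=low)
                truth[(s, rec.key)] = "below_vaf"
            else:
                truth[(s, rec.key)] = "kept"
            adjusted.append(rec)
        out[s] = adjusted

    baseline: list[MutationRecord] = []
    for _ in range(n_preexisting):
        key = fresh_key()
        baseline.append(MutationRecord("baseline", *key, vaf=1.0))
        carrier = samples[int(rng.integers(len(samples)))]
        out[carrier].append(MutationRecord(carrier, *key, vaf=1.0))
        truth[(carrier, key)] = "baseline"

    for _ in range(n_shared_pairs):
        key = fresh_key()
        pair = rng.choice(len(samples), size=2, replace=False)
        for si in pair:
            carrier = samples[int(si)]
            out[carrier].append(MutationRecord(carrier, *key, vaf=1.0))
            truth[(carrier, key)] = "shared"

    return out, baseline, truth


# ---------------------------------------------------------------------------
# Plating-assay simulation
# ---------------------------------------------------------------------------

def simulate_assay(
    cfg: AssaySimConfig, genotype: str = "strain"
) -> list[AssayMeasurement]:
    """Colony counts for one genotype's untreated and treated arms.

    Per-culture CanR frequencies are lognormal with median
    ``base_frequency`` (× ``true_fold`` in the treated arm); viable
    densities are lognormal around the plating constant, reduced by
    ``viability_drop`` when treated; CanR colonies/mL are Poisson with
    mean frequency × viable density (plating is a count process on top
    of culture-to-culture variation).
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[AssayMeasurement] = []
    for treatment in ("untreated", "treated"):
        fold = cfg.true_fold if treatment == "treated" else 1.0
        surv = 1.0 - cfg.viability_drop if treatment == "treated" else 1.0
        for _ in range(cfg.n_cultures_per_arm):
            freq = cfg.base_frequency * fold * float(
                np.exp(cfg.lognormal_sigma * rng.standard_normal())
            )
            viable = UNTREATED_VIABLE_PER_ML * surv * float(
                np.exp(VIABLE_NOISE_SIGMA * rng.standard_normal())
            )
            canr = float(rng.poisson(freq * viable))
            out.append(AssayMeasurement(genotype, treatment, canr, viable))
    return out


# ---------------------------------------------------------------------------
# Whole-study layout
# ---------------------------------------------------------------------------

STUDY_COHORTS = (
    ("wt_water", 17, 1.0),
    ("wt_acetaldehyde", 19, 1.0),
    ("rad1_water", 27, 1.0),
    ("rad1_acetaldehyde", 28, 2.0),
)


def simulate_study(
    genome: Genome,
    seed: int = 0,
    cohorts=STUDY_COHORTS,
    n_mutations: int = 15,
    frac_CtoA: float = 0.6,
    motif: Motif | str = GCN,
    window: int = 20,
) -> dict[str, dict[str, list[MutationRecord]]]:
    """Four-cohort study design: two genotypes × two treatments, with
    the signature enriched only where the cohort's target enrichment
    exceeds 1.  Isolate counts default to the 17/19/27/28 layout of a
    repair-deficiency sequencing screen.  Returns cohort -> sample ->
    records."""
    if isinstance(motif, str):
        motif = Motif.parse(motif)
    pools = _SitePools(genome, motif, window)
    out: dict[str, dict[str, list[MutationRecord]]] = {}
    for i, (name, n_isolates, target) in enumerate(cohorts):
        cfg = SpikeConfig(
            n_mutations=n_mutations,
            frac_CtoA=frac_CtoA,
            target_enrichment=target,
            seed=(seed * 1000 + i * 7919) % (2**31),
        )
        calibration = "windowed" if target != 1.0 else "odds"
        out[name] = spike_mutations(
            genome, cfg, n_samples=n_isolates, motif=motif, window=window,
            calibration=calibration, sample_prefix=f"{name}_", pools=pools,
        )
    return out
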