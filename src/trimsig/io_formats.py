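"""Readers and writers for the formats the pipeline touches.

Genomes arrive as FASTA (plain or gzipped), per-isolate SNV calls as
VCF 4.x or a VarScan2-style tab-separated table, plating-assay and qPCR
measurements as small delimited tables.  Everything is validated on the
way in: coordinates are 1-based throughout (the convention of both
variant dialects), sequences are upper-cased, and records that violate
their invariants raise :class:`~trimsig.errors.ValidationError` rather
than propagating silently.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO

from .errors import RefMismatchError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
GENOME_ALPHABET = frozenset("ACGTN")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class Genome:
    """A small multi-contig genome: ordered map contig-name -> sequence.

    Sequences are stored uppercase over {A,C,G,T,N}.  All positional
    queries are 1-based inclusive.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValidationError("genome has no contigs")
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if not seq:
                raise ValidationError(f"contig {name!r} is empty")
            bad = re.search("[^ACGTN]", seq)
            if bad:
                raise ValidationError(
                    f"contig {name!r}: invalid character {bad.group()!r} "
                    f"at position {bad.start() + 1}"
                )
            if name in self.contigs:
                raise ValidationError(f"duplicate contig name {name!r}")
            self.contigs[name] = seq

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        try:
            return self.contigs[name]
        except KeyError:
            raise ValidationError(f"unknown contig {name!r}") from None

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def length(self, name: str) -> int:
        return len(self[name])

    def base(self, contig: str, pos: int) -> str:
        """Base at 1-based position ``pos`` of ``contig``."""
        seq = self[contig]
        if not 1 <= pos <= len(seq):
            raise ValidationError(
                f"position {pos} outside contig {contig!r} (length {len(seq)})"
            )
        return seq[pos - 1]

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


class MutationKey(NamedTuple):
    """Sample-agnostic identity of a point mutation."""

    contig: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class MutationRecord:
    """One single-nucleotide variant call in one isolate.

    ``pos`` is 1-based; ``vaf`` is the variant allele frequency as a
    fraction in [0, 1], or None for post-filter tables that no longer
    carry it.
    """

    sample: str
    contig: str
    pos: int
    ref: str
    alt: str
    vaf: float | None = None

    def __post_init__(self):
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValidationError(
                f"{self.sample} {self.contig}:{self.pos} "
                f"{self.ref}>{self.alt}: bases must be one of A,C,G,T"
            )
        if self.ref == self.alt:
            raise ValidationError(
                f"{self.sample} {self.contig}:{self.pos}: ref equals alt ({self.ref})"
            )
        if self.pos < 1:
            raise ValidationError(
                f"{self.sample} {self.contig}:{self.pos}: position must be >= 1"
            )
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(
                f"{self.sample} {self.contig}:{self.pos}: VAF {self.vaf} not in [0, 1]"
            )

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.contig, self.pos, self.ref, self.alt)

    def check_against(self, genome: Genome) -> None:
        """Verify the coordinate and reference base against a genome."""
        actual = genome.base(self.contig, self.pos)
        if actual != self.ref:
            raise RefMismatchError(
                f"{self.sample} {self.contig}:{self.pos}: record says ref "
                f"{self.ref} but genome has {actual}"
            )


@dataclass(frozen=True)
class AssayMeasurement:
    """One culture's plating counts with genotype and treatment labels."""

    genotype: str
    treatment: str  # "untreated" | "treated"
    canr_per_ml: float
    viable_per_ml: float

    def __post_init__(self):
        if self.treatment not in ("untreated", "treated"):
            raise ValidationError(
                f"treatment must be 'untreated' or 'treated', got {self.treatment!r}"
            )
        if self.canr_per_ml < 0:
            raise ValidationError(
                f"{self.genotype}: negative CanR count {self.canr_per_ml}"
            )
        if self.viable_per_ml <= 0:
            raise ValidationError(
                f"{self.genotype}: viable colonies/mL must be positive, "
                f"got {self.viable_per_ml}"
            )


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference-channel Ct values."""

    sample: str
    condition: str  # "plain" | "doxycycline"
    target_ct: float
    reference_ct: float

    def __post_init__(self):
        if self.condition not in ("plain", "doxycycline"):
            raise ValidationError(
                f"condition must be 'plain' or 'doxycycline', got {self.condition!r}"
            )
        if not (math.isfinite(self.target_ct) and math.isfinite(self.reference_ct)):
            raise ValidationError(f"{self.sample}: Ct values must be finite")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def read_fasta(path: str | Path) -> Genome:
    """Load a FASTA genome; lowercase is accepted and upcased.

    Duplicate contig names, empty files and non-ACGTN characters are
    hard errors.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in contigs:
                raise ValidationError(f"{path}: duplicate contig name {rec.id!r}")
            contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise ValidationError(f"{path}: no FASTA records found")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as out:
        for name, seq in genome.contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def parse_vaf(text: str) -> float:
    """Parse a VAF given either as a VarScan-style percent ('92.3%')
    or a fraction ('0.923'); returns a fraction in [0, 1]."""
    text = text.strip()
    try:
        if text.endswith("%"):
            value = float(text[:-1]) / 100.0
        else:
            value = float(text)
            if value > 1.0:  # bare percent without the sign
                value /= 100.0
    except ValueError:
        raise ValidationError(f"cannot parse VAF value {text!r}") from None
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"VAF {text!r} outside [0, 100%]")
    return value


_VARSCAN_COLUMNS = ("chrom", "pos", "ref", "alt", "vaf", "sample")


def _read_varscan_tsv(path: str | Path) -> list[MutationRecord]:
    records: list[MutationRecord] = []
    n_skipped = 0
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"{path}: empty variant table")
        header = [h.strip().lower() for h in header]
        missing = [c for c in _VARSCAN_COLUMNS if c not in header]
        if missing:
            raise ValidationError(f"{path}: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in _VARSCAN_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                ref = row[idx["ref"]].strip().upper()
                alt = row[idx["alt"]].strip().upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES \
                        or alt not in VALID_BASES:
                    n_skipped += 1  # indel / MNV / symbolic allele
                    continue
                records.append(
                    MutationRecord(
                        sample=row[idx["sample"]].strip(),
                        contig=row[idx["chrom"]].strip(),
                        pos=int(row[idx["pos"]]),
                        ref=ref,
                        alt=alt,
                        vaf=parse_vaf(row[idx["vaf"]]),
                    )
                )
            except (IndexError, ValueError, ValidationError) as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from None
    if n_skipped:
        logger.info("%s: skipped %d non-SNV rows", path, n_skipped)
    return records


def _read_vcf(path: str | Path) -> list[MutationRecord]:
    import pysam

    records: list[MutationRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) > 1:
            raise ValidationError(
                f"{path}: multi-sample VCF ({len(samples)} samples); "
                "the pipeline expects one isolate per file"
            )
        sample = samples[0] if samples else Path(path).stem.removesuffix(".vcf")
        for rec in vcf:
            if rec.ref is None or rec.alts is None:
                n_skipped += 1
                continue
            ref = rec.ref.upper()
            for alt in rec.alts:
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES \
                        or alt not in VALID_BASES:
                    n_skipped += 1
                    continue
                vaf = None
                af = rec.info.get("AF")
                if af is not None:
                    # htslib stores AF as float32; round away the excess digits
                    vaf = float(f"{float(af[0] if isinstance(af, tuple) else af):.6g}")
                records.append(
                    MutationRecord(sample, rec.chrom, rec.pos, ref, alt, vaf=vaf)
                )
    if n_skipped:
        logger.info("%s: skipped %d non-SNV alleles", path, n_skipped)
    return records


def read_mutations(path: str | Path, dialect: str = "varscan_tsv") -> list[MutationRecord]:
    """Read SNV calls from a VCF or a VarScan2-style TSV.

    Multi-allelic VCF rows are expanded to one record per alternate
    allele; indels and MNVs are skipped with a logged count.  Positions
    stay 1-based as in both source formats.
    """
    if dialect == "varscan_tsv":
        return _read_varscan_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValidationError(f"unknown variant dialect {dialect!r}")


def check_records(records: Iterable[MutationRecord], genome: Genome) -> int:
    """Validate every record's reference base against the genome.

    Returns the number checked; raises on the first mismatch.
    """
    n = 0
    for rec in records:
        rec.check_against(genome)
        n += 1
    return n


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment="#")


def read_assay_table(path: str | Path) -> list[AssayMeasurement]:
    """Read plating-assay measurements (TSV or CSV).

    Required columns: genotype, treatment, canr_per_ml, viable_per_ml.
    """
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["genotype", "treatment", "canr_per_ml", "viable_per_ml"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: assay table has no data rows", path)
        return []
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                AssayMeasurement(
                    genotype=str(row["genotype"]).strip(),
                    treatment=str(row["treatment"]).strip().lower(),
                    canr_per_ml=float(row["canr_per_ml"]),
                    viable_per_ml=float(row["viable_per_ml"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} data row {i + 1}: {exc}") from None
    return out


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read qPCR Ct values: sample, condition, target_ct, reference_ct."""
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["sample", "condition", "target_ct", "reference_ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                CtRecord(
                    sample=str(row["sample"]).strip(),
                    condition=str(row["condition"]).strip().lower(),
                    target_ct=float(row["target_ct"]),
                    reference_ct=float(row["reference_ct"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} data row {i + 1}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as tab-separated UTF-8.

    Floats are serialized with 6 significant digits; an empty table
    yields a header-only file.  Column order is the DataFrame's.
    """
    try:
        table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise ValidationError(f"cannot write {path}: {exc}") from None


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write mutation records back out in the VarScan-style TSV dialect."""
    rows = [
        {
            "chrom": r.contig,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "vaf": "" if r.vaf is None else f"{r.vaf:.6g}",
            "sample": r.sample,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vaf", "sample"])
    write_results(df, path)
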