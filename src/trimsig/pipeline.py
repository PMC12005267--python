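"""End-to-end orchestration: curate → spectrum → signature enrichment.

A single YAML config names the genome, the variant table, the
sample-to-cohort assignment, the baseline samples, the filter
thresholds and the enrichment motif/window.  ``run_all`` executes the
stages in order, writes every result table as TSV, and records a
reproducibility manifest (config hash, input checksums, package
version) so a rerun with identical inputs yields byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .assay_stats import bh_correct  # noqa: F401  (stage import sanity)
from .errors import TrimsigError, ValidationError
from .genome_context import spectrum
from .io_formats import Genome, read_fasta, read_mutations, write_results
from .trims_enrichment import analyze_cohorts, results_frame
from .variant_filters import curate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration for one full analysis run."""

    genome: str
    mutations: str
    cohorts: dict[str, list[str]]  # cohort -> sample ids
    baseline_samples: list[str] = field(default_factory=list)
    mutation_dialect: str = "varscan_tsv"
    vaf_threshold: float = 0.90
    share_min: int = 2
    window: int = 20
    motif: str = "gCn"
    target_alt: str = "A"
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self):
        if not self.cohorts:
            raise ValidationError("config defines no cohorts")
        seen: dict[str, str] = {}
        for cohort, samples in self.cohorts.items():
            if not samples:
                raise ValidationError(f"cohort {cohort!r} is empty")
            for s in samples:
                if s in seen:
                    raise ValidationError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {cohort!r}"
                    )
                seen[s] = cohort
        for path in (self.genome, self.mutations):
            if not Path(path).exists():
                raise ValidationError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stages: load genome and variants → curate (VAF, baseline, shared) →
    per-isolate spectra → pooled per-cohort signature enrichment.  Any
    stage error aborts with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        genome: Genome = read_fasta(config.genome)
        records = read_mutations(config.mutations, config.mutation_dialect)
        known = {s for ss in config.cohorts.values() for s in ss} | set(
            config.baseline_samples
        )
        per_sample: dict[str, list] = {
            s: [] for ss in config.cohorts.values() for s in ss
        }
        baseline = []
        n_unassigned = 0
        for rec in records:
            rec.check_against(genome)
            if rec.sample in config.baseline_samples:
                baseline.append(rec)
            elif rec.sample in per_sample:
                per_sample[rec.sample].append(rec)
            else:
                n_unassigned += 1
        if n_unassigned:
            logger.warning("%d records from samples outside the config", n_unassigned)
        if not known:
            raise ValidationError("no samples configured")

        stage = "curate"
        logger.info("curate: %d records in", sum(map(len, per_sample.values())))
        curated, report = curate(
            per_sample, baseline, config.vaf_threshold, config.share_min
        )
        logger.info(
            "curate: kept %d (below_vaf %d, baseline %d, shared %d)",
            report.n_kept, report.n_below_vaf,
            report.n_preexisting_baseline, report.n_shared,
        )
        write_results(report.to_frame(), outdir / "filter_report.tsv")

        stage = "spectrum"
        spec = spectrum(genome, curated)
        six, ninety_six = spec.to_frames()
        write_results(six, outdir / "spectrum_6class.tsv")
        write_results(ninety_six, outdir / "spectrum_96context.tsv")

        stage = "enrichment"
        cohort_muts = {
            cohort: [r for s in samples for r in curated.get(s, [])]
            for cohort, samples in config.cohorts.items()
        }
        results = analyze_cohorts(
            genome, cohort_muts, window=config.window,
            motif=config.motif, target_alt=config.target_alt,
        )
        write_results(results_frame(results), outdir / "enrichment.tsv")
    except TrimsigError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    manifest = {
        "tool": "trimsig",
        "version": __version__,
        "config_sha256": hashlib.sha256(
            config.canonical().encode()
        ).hexdigest(),
        "inputs": {
            "genome": _sha256(config.genome),
            "mutations": _sha256(config.mutations),
        },
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.suffix == ".tsv"
        ),
        "filter_report": {
            "n_input": report.n_input,
            "n_below_vaf": report.n_below_vaf,
            "n_preexisting_baseline": report.n_preexisting_baseline,
            "n_shared": report.n_shared,
            "n_kept": report.n_kept,
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
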