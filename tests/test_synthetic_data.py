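import numpy as np
import pytest

from trimsig import (
    AssaySimConfig,
    SpikeConfig,
    ValidationError,
    classify_sbs,
    contaminate,
    curate,
    gen_genome,
    simulate_assay,
    simulate_study,
    spike_mutations,
)
from trimsig.genome_context import GCN
from trimsig.synthetic_data import UNTREATED_VIABLE_PER_ML, _SitePools, signature_fraction


class TestGenGenome:
    def test_deterministic_for_fixed_seed(self):
        a = gen_genome(1, 10_000, 0.38, seed=7)
        b = gen_genome(1, 10_000, 0.38, seed=7)
        assert a.contigs == b.contigs

    def test_seed_changes_sequence(self):
        a = gen_genome(1, 1_000, 0.38, seed=7)
        b = gen_genome(1, 1_000, 0.38, seed=8)
        assert a.contigs != b.contigs

    def test_gc_concentration(self):
        g = gen_genome(1, 100_000, 0.38, seed=3)
        seq = g["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.36 <= gc <= 0.40

    def test_contig_layout(self):
        g = gen_genome(2, 500, 0.5, seed=1)
        assert list(g) == ["chr1", "chr2"]
        assert all(g.length(c) == 500 for c in g)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValidationError):
            gen_genome(1, 50, 0.4, seed=0)
        with pytest.raises(ValidationError):
            gen_genome(1, 1000, 0.0, seed=0)


class TestSpikeMutations:
    def test_zero_enrichment_excludes_signature(self, random_genome):
        cfg = SpikeConfig(n_mutations=200, frac_CtoA=1.0, target_enrichment=0.0, seed=5)
        per = spike_mutations(random_genome, cfg)
        for rec in per["S1"]:
            change = classify_sbs(random_genome, rec)
            assert change.klass == "C>A"
            assert not GCN.matches_context(change.context)

    def test_records_valid_disjoint_full_vaf(self, random_genome):
        cfg = SpikeConfig(n_mutations=300, frac_CtoA=0.6, seed=6)
        per = spike_mutations(random_genome, cfg, n_samples=3)
        assert set(per) == {"S1", "S2", "S3"}
        for sample, recs in per.items():
            assert len(recs) == 300
            positions = {(r.contig, r.pos) for r in recs}
            assert len(positions) == 300  # disjoint within sample
            for r in recs:
                assert r.vaf == 1.0
                r.check_against(random_genome)  # ref matches genome

    def test_class_mix_follows_config(self, random_genome):
        cfg = SpikeConfig(
            n_mutations=400,
            frac_CtoA=0.5,
            background_classes={"T>C": 1.0},
            seed=8,
        )
        per = spike_mutations(random_genome, cfg)
        klasses = [classify_sbs(random_genome, r).klass for r in per["S1"]]
        assert klasses.count("C>A") == 200
        assert klasses.count("T>C") == 200

    def test_deterministic_for_fixed_seed(self, random_genome):
        cfg = SpikeConfig(n_mutations=50, seed=9)
        assert spike_mutations(random_genome, cfg) == spike_mutations(random_genome, cfg)

    def test_overdraw_rejected(self):
        g = gen_genome(1, 200, 0.4, seed=0)
        cfg = SpikeConfig(n_mutations=10_000, frac_CtoA=1.0, seed=0)
        with pytest.raises(ValidationError):
            spike_mutations(g, cfg)

    def test_odds_mode_at_unit_enrichment_is_uniform(self, random_genome):
        """With E=1 the odds mode reduces to uniform placement: the
        signature fraction equals the motif-site abundance."""
        pools = _SitePools(random_genome, GCN, 20)
        f = signature_fraction(pools, 1.0, "odds")
        abundance = len(pools.motif_idx) / (
            len(pools.motif_idx) + len(pools.non_idx)
        )
        assert f == pytest.approx(abundance)


class TestContaminate:
    def test_curate_recovers_exact_labels(self, random_genome):
        cfg = SpikeConfig(n_mutations=40, frac_CtoA=0.6, seed=21)
        clean = spike_mutations(random_genome, cfg, n_samples=4)
        dirty, baseline, truth = contaminate(
            clean, random_genome, n_preexisting=5, n_shared_pairs=4,
            frac_low_vaf=0.15, seed=22,
        )
        curated, report = curate(dirty, baseline, vaf_threshold=0.90)
        from collections import Counter

        expected = Counter(truth.values())
        assert report.n_below_vaf == expected["below_vaf"]
        assert report.n_preexisting_baseline == expected["baseline"]
        assert report.n_shared == expected["shared"]
        assert report.n_kept == expected["kept"]
        kept_keys = {(s, r.key) for s, recs in curated.items() for r in recs}
        assert kept_keys == {k for k, fate in truth.items() if fate == "kept"}

    def test_low_vaf_fraction_binomial(self, random_genome):
        cfg = SpikeConfig(n_mutations=250, frac_CtoA=0.6, seed=31)
        clean = spike_mutations(random_genome, cfg, n_samples=4)  # 1000 records
        dirty, baseline, truth = contaminate(
            clean, random_genome, n_preexisting=0, n_shared_pairs=0,
            frac_low_vaf=0.1, seed=32,
        )
        n_low = sum(1 for fate in truth.values() if fate == "below_vaf")
        sigma = np.sqrt(1000 * 0.1 * 0.9)
        assert abs(n_low - 100) <= 3 * sigma

    def test_zero_contamination_is_identity(self, random_genome):
        cfg = SpikeConfig(n_mutations=30, seed=41)
        clean = spike_mutations(random_genome, cfg, n_samples=3)
        dirty, baseline, _ = contaminate(
            clean, random_genome, n_preexisting=0, n_shared_pairs=0,
            frac_low_vaf=0.0, seed=42,
        )
        assert baseline == []
        curated, report = curate(dirty, baseline)
        assert curated == clean and report.n_kept == report.n_input


class TestSimulateAssay:
    def test_deterministic_and_shaped(self):
        cfg = AssaySimConfig(seed=3)
        a, b = simulate_assay(cfg), simulate_assay(cfg)
        assert a == b
        assert sum(m.treatment == "treated" for m in a) == 12
        assert sum(m.treatment == "untreated" for m in a) == 12

    def test_viability_drop_recovered(self):
        """viability_drop=0.56 -> median treated/untreated viability ~44%."""
        medians = []
        for rep in range(200):
            ms = simulate_assay(AssaySimConfig(seed=rep))
            u = np.median([m.viable_per_ml for m in ms if m.treatment == "untreated"])
            t = [100 * m.viable_per_ml / u for m in ms if m.treatment == "treated"]
            medians.append(np.median(t))
        assert abs(float(np.median(medians)) - 44.0) <= 3.0

    def test_untreated_viable_near_plating_constant(self):
        ms = simulate_assay(AssaySimConfig(seed=11))
        u = np.median([m.viable_per_ml for m in ms if m.treatment == "untreated"])
        assert 0.8 * UNTREATED_VIABLE_PER_ML <= u <= 1.2 * UNTREATED_VIABLE_PER_ML


class TestSimulateStudy:
    def test_layout_and_isolate_counts(self, random_genome):
        study = simulate_study(random_genome, seed=2, n_mutations=5)
        assert list(study) == [
            "wt_water", "wt_acetaldehyde", "rad1_water", "rad1_acetaldehyde",
        ]
        assert len(study["wt_water"]) == 17
        assert len(study["rad1_acetaldehyde"]) == 28
        assert all(len(r) == 5 for r in study["wt_water"].values())
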