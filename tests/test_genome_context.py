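import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import oracle_classify, oracle_window_counts
from trimsig import (
    ContextIndex,
    ContextUndefined,
    Genome,
    Motif,
    MutationRecord,
    RefMismatchError,
    classify_sbs,
    spectrum,
    window_counts,
)
from trimsig.genome_context import GCN, PYRIMIDINE_CLASSES, all_contexts
from trimsig.io_formats import COMPLEMENT, revcomp
from conftest import random_snvs


class TestClassify:
    def test_purine_ref_reverse_complemented(self):
        genome = Genome({"c": "AAGCAA"})  # G at 3 in context aGc
        change = classify_sbs(genome, MutationRecord("s", "c", 3, "G", "T"))
        assert (change.klass, change.context) == ("C>A", "gCt")

    def test_pyrimidine_ref_kept(self):
        genome = Genome({"c": "AGCATA"})  # C at 3 in gCa
        change = classify_sbs(genome, MutationRecord("s", "c", 3, "C", "A"))
        assert (change.klass, change.context) == ("C>A", "gCa")

    def test_t_class(self):
        genome = Genome({"c": "CATGC"})  # T at 3 in aTg
        change = classify_sbs(genome, MutationRecord("s", "c", 3, "T", "C"))
        assert (change.klass, change.context) == ("T>C", "aTg")

    def test_ref_mismatch_hard_error(self):
        genome = Genome({"c": "AAAA"})
        with pytest.raises(RefMismatchError):
            classify_sbs(genome, MutationRecord("s", "c", 2, "C", "A"))

    @pytest.mark.parametrize("pos", [1, 6])
    def test_contig_edge_is_skip_signal(self, pos):
        genome = Genome({"c": "CAAAAC"})
        with pytest.raises(ContextUndefined):
            classify_sbs(genome, MutationRecord("s", "c", pos, "C", "A"))

    def test_n_in_context_is_skip_signal(self):
        genome = Genome({"c": "ANCAA"})
        with pytest.raises(ContextUndefined):
            classify_sbs(genome, MutationRecord("s", "c", 3, "C", "A"))

    def test_agrees_with_oracle_on_random_sites(self, random_genome):
        for rec in random_snvs(random_genome, 300, seed=17):
            expected = oracle_classify(
                random_genome[rec.contig], rec.pos, rec.ref, rec.alt
            )
            if expected is None:
                with pytest.raises(ContextUndefined):
                    classify_sbs(random_genome, rec)
            else:
                change = classify_sbs(random_genome, rec)
                assert (change.klass, change.context) == expected


class TestWindowCounts:
    def test_at_only_window_is_zero(self):
        genome = Genome({"c": "ATATATAT"})
        wc = window_counts(genome, "c", 4, 20)
        assert (wc.n_cyt, wc.n_motif) == (0, 0)

    def test_gca_both_strand_motifs(self):
        # plus strand: gC at 2 (3' wildcard off-contig still counts);
        # minus strand: the G at 1 is a cytosine in gCn context
        genome = Genome({"c": "GCA"})
        wc = window_counts(genome, "c", 2, 20)
        assert (wc.n_cyt, wc.n_motif) == (2, 2)

    def test_terminal_c_without_5prime_g_not_motif(self):
        genome = Genome({"c": "CAT"})  # C at 1: no 5' neighbor
        wc = window_counts(genome, "c", 2, 20)
        assert (wc.n_cyt, wc.n_motif) == (1, 0)

    def test_off_contig_position_rejected(self, tiny_genome):
        from trimsig import ValidationError

        with pytest.raises(ValidationError):
            window_counts(tiny_genome, "c1", 0, 20)

    def test_oracle_equivalence_random_draws(self, random_genome):
        rng = np.random.default_rng(23)
        index = ContextIndex(random_genome, GCN)
        for _ in range(100):
            contig = list(random_genome)[int(rng.integers(2))]
            pos = int(rng.integers(1, random_genome.length(contig) + 1))
            window = int(rng.integers(1, 40))
            wc = window_counts(random_genome, contig, pos, window, index=index)
            assert (wc.n_cyt, wc.n_motif) == oracle_window_counts(
                random_genome[contig], pos, window
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=1, max_size=60),
        pos_frac=st.floats(0, 1),
        window=st.integers(0, 30),
    )
    def test_oracle_equivalence_property(self, seq, pos_frac, window):
        genome = Genome({"c": seq})
        pos = 1 + int(pos_frac * (len(seq) - 1))
        wc = window_counts(genome, "c", pos, window)
        assert (wc.n_cyt, wc.n_motif) == oracle_window_counts(seq, pos, window)

    def test_monotone_in_window(self, random_genome):
        index = ContextIndex(random_genome, GCN)
        prev = (0, 0)
        for window in range(0, 60, 5):
            wc = index.window_counts("chr1", 5000, window)
            assert wc.n_cyt >= prev[0] and wc.n_motif >= prev[1]
            prev = (wc.n_cyt, wc.n_motif)

    def test_generic_motif_tcw(self):
        genome = Genome({"c": "ATCAAT"})  # tCa at pos 3 matches tCw
        index = ContextIndex(genome, Motif.parse("tCw"))
        wc = index.window_counts("c", 3, 20)
        assert wc.n_motif == 1


def flip(genome: Genome):
    return Genome({name: revcomp(seq) for name, seq in genome.contigs.items()})


def flip_record(genome: Genome, rec: MutationRecord) -> MutationRecord:
    length = genome.length(rec.contig)
    return MutationRecord(
        rec.sample,
        rec.contig,
        length - rec.pos + 1,
        COMPLEMENT[rec.ref],
        COMPLEMENT[rec.alt],
        vaf=rec.vaf,
    )


class TestStrandFlipInvariance:
    def test_window_counts_invariant(self, random_genome):
        flipped = flip(random_genome)
        rng = np.random.default_rng(3)
        for _ in range(50):
            pos = int(rng.integers(1, random_genome.length("chr1") + 1))
            a = window_counts(random_genome, "chr1", pos, 20)
            b = window_counts(flipped, "chr1", random_genome.length("chr1") - pos + 1, 20)
            assert (a.n_cyt, a.n_motif) == (b.n_cyt, b.n_motif)

    def test_spectrum_invariant(self, random_genome):
        recs = random_snvs(random_genome, 200, seed=9)
        flipped = flip(random_genome)
        flipped_recs = [flip_record(random_genome, r) for r in recs]
        a = spectrum(random_genome, {"S1": recs})
        b = spectrum(flipped, {"S1": flipped_recs})
        assert a.per_isolate == b.per_isolate
        assert a.per_context == b.per_context


class TestSpectrum:
    def test_strand_collapse_pools_complementary_changes(self):
        genome = Genome({"c": "AGCATTGAA"})
        recs = [
            MutationRecord("S1", "c", 3, "C", "A"),  # C>A
            MutationRecord("S1", "c", 8, "A", "C"),  # -> T>G
        ]
        recs.append(MutationRecord("S1", "c", 7, "G", "T"))  # -> C>A
        table = spectrum(genome, {"S1": recs})
        assert table.per_isolate["S1"]["C>A"] == 2
        assert table.per_isolate["S1"]["T>G"] == 1

    def test_cohort_mean(self):
        genome = Genome({"c": "AGCAGCAGCA"})
        m = lambda s, p: MutationRecord(s, "c", p, "C", "A")
        table = spectrum(genome, {"A": [m("A", 3), m("A", 6), m("A", 9)], "B": [m("B", 3)]})
        assert table.cohort_mean()["C>A"] == 2.0

    def test_totals_match_brute_force_recount(self, random_genome):
        recs = random_snvs(random_genome, 500, seed=31)
        table = spectrum(random_genome, {"S1": recs})
        # independent tally straight from the oracle classifier
        expected = {k: 0 for k in PYRIMIDINE_CLASSES}
        skipped = 0
        for r in recs:
            out = oracle_classify(random_genome[r.contig], r.pos, r.ref, r.alt)
            if out is None:
                skipped += 1
            else:
                expected[out[0]] += 1
        assert table.per_isolate["S1"] == expected
        assert table.skipped["S1"] == skipped
        # conservation: class totals = context totals = classified count
        assert sum(table.per_isolate["S1"].values()) == 500 - skipped
        assert sum(table.per_context["S1"].values()) == 500 - skipped
        assert set(table.per_context["S1"]) <= set(all_contexts())
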