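import numpy as np
import pandas as pd
import pytest

from crispridesign import (
    Genome,
    TssRecord,
    build_seed_index,
    classify_targeting_strand,
    design_for_tss,
    design_genome_wide,
    random_planted_fixture,
    reverse_complement,
    transcript_window,
)


class TestTranscriptWindow:
    def test_plus_strand_default_window(self):
        g = Genome(contigs={"c": "A" * 2000})
        w = transcript_window(TssRecord("x", "c", 1000, "+"), g)
        assert (w.start, w.end) == (949, 1099)
        assert w.end - w.start == 150

    def test_minus_strand_default_window(self):
        g = Genome(contigs={"c": "A" * 2000})
        w = transcript_window(TssRecord("x", "c", 1000, "-"), g)
        assert (w.start, w.end) == (900, 1050)
        assert w.end - w.start == 150

    def test_clipping_at_contig_start(self):
        g = Genome(contigs={"c": "A" * 2000})
        w = transcript_window(TssRecord("x", "c", 10, "+"), g)
        assert (w.start, w.end) == (0, 109)

    def test_window_entirely_off_contig_is_empty(self):
        g = Genome(contigs={"c": "A" * 30})
        w = transcript_window(TssRecord("x", "c", 10, "-"), g, upstream=50, downstream=200)
        assert w.start == w.end

    def test_tss_base_inside_window_when_offsets_straddle_zero(self):
        g = Genome(contigs={"c": "A" * 2000})
        for strand in "+-":
            w = transcript_window(TssRecord("x", "c", 700, strand), g)
            assert w.start <= 699 < w.end  # 0-based TSS position

    def test_inverted_offsets_rejected(self):
        g = Genome(contigs={"c": "A" * 100})
        with pytest.raises(ValueError):
            transcript_window(TssRecord("x", "c", 50, "+"), g, upstream=10, downstream=10)


class TestClassifyTargetingStrand:
    @pytest.mark.parametrize(
        "proto,gene,expected",
        [
            ("-", "+", "nontemplate"),
            ("+", "+", "template"),
            ("+", "-", "nontemplate"),
            ("-", "-", "template"),
        ],
    )
    def test_rule(self, proto, gene, expected):
        assert classify_targeting_strand(proto, gene) == expected

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            classify_targeting_strand("+", "*")


class TestDesignForTss:
    def test_polyt_genome_minus_gene_yields_nontemplate_candidate(self, polyt_genome, sth3):
        idx = build_seed_index(polyt_genome, sth3)
        tss = TssRecord("g", "c1", 28, "-")
        cands = design_for_tss(polyt_genome, tss, sth3, idx)
        assert len(cands) == 1
        c = cands[0]
        assert (c.protospacer.proto_start, c.protospacer.proto_end) == (0, 20)
        assert c.protospacer.strand == "+"
        assert c.targeting_class == "nontemplate"
        assert c.unique

    def test_polyt_genome_plus_gene_is_template_only(self, polyt_genome, sth3):
        idx = build_seed_index(polyt_genome, sth3)
        tss = TssRecord("g", "c1", 1, "+")
        assert design_for_tss(polyt_genome, tss, sth3, idx) == []
        allc = design_for_tss(polyt_genome, tss, sth3, idx, class_filter="all")
        assert [c.targeting_class for c in allc] == ["template"]

    def test_no_pam_in_window_gives_empty_result(self, sth3):
        g = Genome(contigs={"c": "A" * 500})
        idx = build_seed_index(g, sth3)
        assert design_for_tss(g, TssRecord("g", "c", 250, "+"), sth3, idx) == []

    def test_window_containment_of_every_candidate(self, sth3):
        genome, tss_records, _ = random_planted_fixture(3, n_genes=5)
        idx = build_seed_index(genome, sth3)
        for tss in tss_records:
            w = transcript_window(tss, genome)
            for c in design_for_tss(genome, tss, sth3, idx, class_filter="all"):
                assert w.start <= c.protospacer.proto_start
                assert c.protospacer.proto_end <= w.end

    def test_nontemplate_sequence_matches_gene_strand_sequence(self, sth3):
        # reverse-complementing the spacer reproduces the nontemplate
        # (mRNA-like) strand text at the locus
        genome, tss_records, _ = random_planted_fixture(11, n_genes=5)
        idx = build_seed_index(genome, sth3)
        (cid,) = genome.contigs
        for tss in tss_records:
            for c in design_for_tss(genome, tss, sth3, idx):
                p = c.protospacer
                forward = genome.contigs[cid][p.proto_start : p.proto_end]
                mrna_like = forward if tss.strand == "+" else reverse_complement(forward)
                assert reverse_complement(p.targeting_sequence) == mrna_like

    def test_beyond_cds_start_flag(self, sth3):
        genome, tss_records, ledger = random_planted_fixture(17, n_genes=8)
        idx = build_seed_index(genome, sth3)
        by_gene = {e.feature_id: e for e in ledger}
        for tss in tss_records:
            (cand,) = design_for_tss(genome, tss, sth3, idx)
            e = by_gene[tss.feature_id]
            p0 = tss.tss_position - 1
            ends = (e.proto_start, e.proto_end - 1)
            offsets = [x - p0 if tss.strand == "+" else p0 - x for x in ends]
            # cds_start sits at transcript offset 45 in this fixture
            assert cand.beyond_cds_start == (max(offsets) >= 45)


class TestDesignGenomeWide:
    def test_recovers_planted_sites_exactly(self, sth3):
        for seed in range(20):
            genome, tss_records, ledger = random_planted_fixture(seed, n_genes=6)
            table = design_genome_wide(genome, tss_records, [sth3])
            got = set(zip(table["feature_id"], table["start"] - 1, table["end"]))
            planted = {(e.feature_id, e.proto_start, e.proto_end) for e in ledger}
            assert got == planted
            assert table["unique"].all()  # this fixture plants only unique sites

    def test_uniqueness_annotation_matches_planting(self, sth3):
        genome, tss_records, ledger = random_planted_fixture(
            29, n_genes=6, nonunique_every=3
        )
        table = design_genome_wide(genome, tss_records, [sth3])
        verdict = dict(zip(table["feature_id"], table["unique"]))
        for e in ledger:
            assert verdict[e.feature_id] == e.expected_unique

    def test_mirror_property(self, sth3):
        genome, tss_records, _ = random_planted_fixture(41, n_genes=5)
        (cid,) = genome.contigs
        L = len(genome.contigs[cid])
        mirrored = Genome(contigs={cid: reverse_complement(genome.contigs[cid])})
        flipped = [
            TssRecord(
                t.feature_id, cid, L - t.tss_position + 1,
                "-" if t.strand == "+" else "+",
                operon_id=t.operon_id,
                cds_start=(L - t.cds_start + 1) if t.cds_start else None,
            )
            for t in tss_records
        ]
        a = design_genome_wide(genome, tss_records, [sth3])
        b = design_genome_wide(mirrored, flipped, [sth3])
        assert len(a) == len(b)
        key_a = sorted(zip(a["feature_id"], a["start"], a["end"], a["targeting_sequence"]))
        key_b = sorted(
            zip(b["feature_id"], L - b["end"] + 1, L - b["start"] + 1,
                b["targeting_sequence"])
        )
        assert key_a == key_b

    def test_deterministic_across_runs(self, sth3):
        genome, tss_records, _ = random_planted_fixture(53, n_genes=4)
        a = design_genome_wide(genome, tss_records, [sth3])
        b = design_genome_wide(genome, tss_records, [sth3])
        pd.testing.assert_frame_equal(a, b)

    def test_candidates_sorted_by_distance_to_tss(self, sth3):
        # two planted sites at different offsets from one TSS
        seq = list("T" * 300)
        # site 1: proto [100,120) + PAM at 120 (+ strand)
        seq[120:125] = list("AGGAG")
        # make proto seeds distinct
        seq[100:120] = list("ACGTACGTACGTACGTACGA")
        # site 2: proto [140,160) + PAM at 160
        seq[160:165] = list("AGGAG")
        seq[140:160] = list("CAGTCAGTCAGTCAGTCAGT")
        g = Genome(contigs={"c": "".join(seq)})
        idx = build_seed_index(g, sth3)
        tss = TssRecord("g", "c", 120, "-")  # 0-based 119
        cands = design_for_tss(g, tss, sth3, idx, class_filter="all")
        offsets = [abs(c.tss_offset) for c in cands]
        assert offsets == sorted(offsets)
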