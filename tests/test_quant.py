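import numpy as np
import pandas as pd
import pytest

from crispridesign import (
    fragment_coverage,
    gene_rpkm,
    generate_genome,
    log2_fold_change,
    make_fixture_bundle,
    read_fasta,
    write_sam,
)


@pytest.fixture
def small_genome():
    return generate_genome(2000, 0.5, seed=7, contig_id="chr")


def _write(tmp_path, genome, fragments, name="r.sam"):
    p = tmp_path / name
    write_sam(p, genome, fragments)
    return p


def _genes(rows):
    return pd.DataFrame(rows, columns=["feature_id", "contig", "start", "end"])


class TestFragmentCoverage:
    def test_single_pair_spreads_mass_uniformly(self, tmp_path, small_genome):
        sam = _write(tmp_path, small_genome, [("chr", 100, 200)])
        cov = fragment_coverage(sam, small_genome)
        vec = cov.vectors["chr"]
        assert cov.total_fragments == 1
        assert np.allclose(vec[100:200], 0.01)
        assert vec[:100].sum() == 0 and vec[200:].sum() == 0
        assert abs(cov.mass() - 1.0) < 1e-9

    def test_empty_sam_gives_zero_vector(self, tmp_path, small_genome):
        sam = _write(tmp_path, small_genome, [])
        cov = fragment_coverage(sam, small_genome)
        assert cov.total_fragments == 0
        assert cov.mass() == 0.0

    def test_planted_spans_give_expected_plateaus(self, tmp_path, small_genome):
        spans = [("chr", 0, 50), ("chr", 300, 400), ("chr", 1000, 1150)]
        sam = _write(tmp_path, small_genome, spans)
        cov = fragment_coverage(sam, small_genome)
        vec = cov.vectors["chr"]
        assert abs(cov.mass() - 3.0) < 1e-9
        assert np.allclose(vec[0:50], 1 / 50)
        assert np.allclose(vec[300:400], 1 / 100)
        assert np.allclose(vec[1000:1150], 1 / 150)

    def test_mass_conservation_on_random_libraries(self, tmp_path, small_genome):
        rng = np.random.default_rng(13)
        frags = []
        for _ in range(250):
            start = int(rng.integers(0, 1800))
            span = int(rng.integers(60, 200))
            frags.append(("chr", start, min(start + span, 2000)))
        sam = _write(tmp_path, small_genome, frags)
        cov = fragment_coverage(sam, small_genome)
        assert cov.total_fragments == 250
        assert abs(cov.mass() - 250) / 250 < 1e-6

    def test_unmapped_and_secondary_records_skipped(self, tmp_path, small_genome):
        sam = tmp_path / "mixed.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr\tLN:2000\n"
            # unpaired mapped read of 50 bp: counts 1/50 over its span
            "r1\t0\tchr\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
            # unmapped
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\tIIII\n"
            # secondary
            "r3\t256\tchr\t301\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t" + "I" * 50 + "\n"
        )
        cov = fragment_coverage(sam, small_genome)
        assert cov.total_fragments == 1
        assert np.allclose(cov.vectors["chr"][100:150], 1 / 50)
        assert cov.n_skipped == 2


class TestGeneRpkm:
    def test_unit_arithmetic_without_pseudocount(self, tmp_path, small_genome):
        # 10 fragments fully inside a 1 kb gene
        frags = [("chr", 200, 300)] * 10
        sam = _write(tmp_path, small_genome, frags)
        cov = fragment_coverage(sam, small_genome)
        genes = _genes([("g1", "chr", 101, 1100)])
        table = gene_rpkm(cov, genes, pseudocount_mode="off")
        # RPKM = 10 / 1 kb / (10 / 1e6 million) = 1e6
        assert table.rpkm[0] == pytest.approx(1e6)

    def test_per_gene_pseudocount_floor(self, tmp_path, small_genome):
        sam = _write(tmp_path, small_genome, [("chr", 1500, 1600)])
        cov = fragment_coverage(sam, small_genome)
        genes = _genes([("silent", "chr", 101, 1100)])
        table = gene_rpkm(cov, genes, pseudocount_mode="per-gene")
        # mass floor 1 over 1 kb with a 1-fragment library
        assert table.fragment_mass[0] == pytest.approx(1.0)
        assert table.rpkm[0] == pytest.approx(1.0 / 1.0 / 1e-6)

    def test_per_position_pseudocount_scales_with_length(self, tmp_path, small_genome):
        sam = _write(tmp_path, small_genome, [("chr", 1500, 1600)])
        cov = fragment_coverage(sam, small_genome)
        genes = _genes([("a", "chr", 1, 100), ("b", "chr", 101, 300)])
        table = gene_rpkm(cov, genes, pseudocount_mode="per-position",
                          pseudocount=1e-3)
        assert table.fragment_mass[0] == pytest.approx(0.1)
        assert table.fragment_mass[1] == pytest.approx(0.2)

    def test_planted_mass_ratio_preserved(self, tmp_path, small_genome):
        frags = [("chr", 100, 200)] * 9 + [("chr", 1000, 1100)] * 3
        sam = _write(tmp_path, small_genome, frags)
        cov = fragment_coverage(sam, small_genome)
        genes = _genes([("hi", "chr", 51, 450), ("lo", "chr", 951, 1350)])
        table = gene_rpkm(cov, genes, pseudocount_mode="off")
        assert table.rpkm[0] / table.rpkm[1] == pytest.approx(3.0)

    def test_scale_invariance_under_alignment_duplication(self, tmp_path, small_genome):
        frags = [("chr", 100, 250), ("chr", 600, 700), ("chr", 900, 1100)]
        genes = _genes([("g1", "chr", 51, 450), ("g2", "chr", 551, 1200)])
        t1 = gene_rpkm(
            fragment_coverage(_write(tmp_path, small_genome, frags, "one.sam"),
                              small_genome),
            genes, pseudocount_mode="off",
        )
        t2 = gene_rpkm(
            fragment_coverage(_write(tmp_path, small_genome, frags * 2, "two.sam"),
                              small_genome),
            genes, pseudocount_mode="off",
        )
        assert np.allclose(t1.rpkm, t2.rpkm)

    def test_zero_library_errors(self, tmp_path, small_genome):
        sam = _write(tmp_path, small_genome, [])
        cov = fragment_coverage(sam, small_genome)
        with pytest.raises(ValueError, match="zero fragments"):
            gene_rpkm(cov, _genes([("g", "chr", 1, 100)]))


class TestLog2FoldChange:
    def _table(self, rpkms):
        return pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(len(rpkms))],
            "rpkm": rpkms,
        })

    def test_identical_tables_give_zero(self):
        t = self._table([5.0, 2.5, 100.0])
        assert np.allclose(log2_fold_change(t, t)["log2_ratio"], 0.0)

    def test_doubling_gives_one(self):
        a = self._table([4.0, 10.0])
        b = self._table([2.0, 5.0])
        assert np.allclose(log2_fold_change(a, b)["log2_ratio"], 1.0)

    def test_mismatched_gene_sets_error_lists_difference(self):
        a = self._table([1.0, 2.0])
        b = self._table([1.0, 2.0]).assign(feature_id=["g0", "gX"])
        with pytest.raises(ValueError, match="g1.*gX"):
            log2_fold_change(a, b)

    def test_planted_fold_change_recovered_from_fixture(self, tmp_path):
        bundle = make_fixture_bundle("rnaseq-demo", 3, tmp_path / "fx")
        genome = read_fasta(bundle.genome_path)
        genes = pd.read_csv(bundle.genes_path, sep="\t")
        cov_a = fragment_coverage(bundle.sam_paths["a"], genome)
        cov_b = fragment_coverage(bundle.sam_paths["b"], genome)
        assert cov_a.total_fragments == bundle.expectations["fragments_per_condition"]["a"]
        assert abs(cov_a.mass() - cov_a.total_fragments) / cov_a.total_fragments < 1e-6
        lfc = log2_fold_change(gene_rpkm(cov_a, genes), gene_rpkm(cov_b, genes))
        lfc = lfc.set_index("feature_id")["log2_ratio"]
        induced = bundle.expectations["induced_gene"]
        # pseudocount compresses log2(80/20) to log2(81/21) ~ 1.95
        assert lfc[induced] == pytest.approx(2.0, abs=0.1)
        others = lfc.drop(induced)
        assert np.abs(others).max() < 0.1
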