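"""Junction parsing, merging, window extraction, splits, serialization."""

import numpy as np
import pytest

from plantglm.junctions import (
    JunctionRecord,
    LabeledWindow,
    acceptor_motif_slice,
    donor_motif_slice,
    extract_site_windows,
    merge_junctions,
    read_dataset,
    read_junctions,
    sample_negatives,
    split_by_chromosome,
    write_dataset,
)


def J(chrom="chr1", d=1000, a=1100, strand="+", reads=10):
    return JunctionRecord(chrom, d, a, strand, reads)


class TestReadJunctions:
    def test_star_line_converts_to_zero_based(self, tmp_path):
        path = tmp_path / "SJ.out.tab"
        path.write_text("chr1\t1001\t1100\t1\t1\t1\t25\t0\t38\n")
        (rec,) = read_junctions(path, "star_sj")
        assert rec == JunctionRecord("chr1", 1000, 1099, "+", 25)

    def test_strand_codes(self, tmp_path):
        path = tmp_path / "SJ.out.tab"
        path.write_text(
            "chr1\t101\t200\t2\t1\t1\t5\t0\t20\n"
            "chr1\t301\t400\t0\t1\t1\t7\t0\t20\n"
        )
        minus, unknown = read_junctions(path, "star_sj")
        assert minus.strand == "-"
        assert unknown.strand == "unknown" and unknown.effective_strand == "+"

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tab"
        path.write_text("")
        assert read_junctions(path, "star_sj") == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "SJ.out.tab"
        path.write_text(
            "chr1\t1001\t1100\t1\t1\t1\t25\t0\t38\n"
            "chr1\tnotanumber\t1100\t1\t1\t1\t25\t0\t38\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_junctions(path, "star_sj")

    def test_bed_dialect_half_open(self, tmp_path):
        path = tmp_path / "junctions.bed"
        path.write_text("chr2\t1000\t1100\tj1\t12\t-\n")
        (rec,) = read_junctions(path, "bed")
        assert (rec.donor_pos, rec.acceptor_pos, rec.strand) == (1000, 1099, "-")

    def test_unknown_dialect_rejected(self, tmp_path):
        path = tmp_path / "x.tab"
        path.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            read_junctions(path, "gtf")


class TestMergeJunctions:
    def test_offset_2_merges(self):
        merged = merge_junctions([J(d=1000, a=1100), J(d=1002, a=1102, reads=3)])
        assert len(merged) == 1 and len(merged[0].members) == 2

    def test_offset_3_does_not_merge(self):
        merged = merge_junctions([J(d=1000, a=1100), J(d=1003, a=1103)])
        assert len(merged) == 2

    def test_acceptor_offset_alone_blocks_merge(self):
        # both coordinates must be within tolerance
        merged = merge_junctions([J(d=1000, a=1100), J(d=1000, a=1104)])
        assert len(merged) == 2

    def test_duplicate_junction_sums_reads(self):
        merged = merge_junctions([J(reads=10), J(reads=15)])
        assert len(merged) == 1
        assert merged[0].total_unique_reads == 25
        assert merged[0].representative.unique_reads == 15

    def test_representative_has_max_support(self):
        merged = merge_junctions([J(d=1000, a=1100, reads=4), J(d=1001, a=1101, reads=40)])
        assert merged[0].representative.donor_pos == 1001

    def test_chrom_and_strand_separate_groups(self):
        merged = merge_junctions([J(), J(chrom="chr2"), J(strand="-")])
        assert len(merged) == 3

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            merge_junctions([J()], tolerance_bp=-1)

    def test_transitive_chain_single_linkage(self):
        # 1000-1002-1004: adjacent pairs within 2, ends 4 apart
        merged = merge_junctions(
            [J(d=1000, a=1100), J(d=1002, a=1102), J(d=1004, a=1104)]
        )
        assert len(merged) == 1 and len(merged[0].members) == 3

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotent_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        juncs = [
            J(chrom=f"chr{rng.integers(1, 3)}",
              d=int(d), a=int(d) + 50 + int(rng.integers(0, 5)),
              reads=int(rng.integers(1, 100)))
            for d in rng.integers(0, 2000, size=250)
        ]
        merged = merge_junctions(juncs)
        reps = [m.representative for m in merged]
        again = merge_junctions(reps)
        assert [m.representative for m in again] == reps  # idempotent

        shuffled = list(juncs)
        rng.shuffle(shuffled)
        merged2 = merge_junctions(shuffled)
        assert [tuple(m.members) for m in merged2] == [tuple(m.members) for m in merged]


class TestExtractWindows:
    def test_two_160bp_windows_per_junction(self, small_genome):
        genome, truth = small_genome
        merged = merge_junctions(truth)
        windows = extract_site_windows(merged, genome)
        assert len(windows) == 2 * len(merged)
        assert all(w.end - w.start == 160 for w in windows)

    def test_planted_motifs_at_fixed_offsets(self, small_genome):
        genome, truth = small_genome
        windows = extract_site_windows(merge_junctions(truth), genome)
        for w in windows:
            if w.label == "donor":
                assert w.sequence[donor_motif_slice()] == "GT"
            else:
                assert w.sequence[acceptor_motif_slice()] == "AG"

    def test_minus_strand_windows_read_5prime_to_3prime(self, stranded_genome):
        genome, truth = stranded_genome
        windows = extract_site_windows(merge_junctions(truth), genome)
        minus = [w for w in windows if w.strand == "-"]
        assert minus, "fixture should contain minus-strand junctions"
        for w in minus:
            motif = "GT" if w.label == "donor" else "AG"
            sl = donor_motif_slice() if w.label == "donor" else acceptor_motif_slice()
            assert w.sequence[sl] == motif

    def test_edge_junction_skipped_with_warning(self, caplog):
        genome = {"chr1": "A" * 500}
        merged = merge_junctions([J(d=10, a=300)])
        with caplog.at_level("WARNING"):
            windows = extract_site_windows(merged, genome)
        labels = {w.label for w in windows}
        assert labels == {"acceptor"}  # donor window clipped at the edge
        assert "contig edge" in caplog.text

    def test_missing_chromosome_raises(self):
        with pytest.raises(KeyError, match="chrX"):
            extract_site_windows(merge_junctions([J(chrom="chrX")]), {"chr1": "A" * 2000})


class TestSampleNegatives:
    def test_ratio_two_doubles_positive_count(self, small_genome, rng):
        genome, truth = small_genome
        merged = merge_junctions(truth)
        negs = sample_negatives(genome, merged, ratio=2.0, rng=rng,
                                n_positive_windows=10)
        assert len(negs) == 20

    def test_ratio_zero_empty(self, small_genome, rng):
        genome, truth = small_genome
        assert sample_negatives(genome, merge_junctions(truth), ratio=0.0, rng=rng) == []

    def test_negatives_avoid_all_site_positions(self, small_genome, rng):
        genome, truth = small_genome
        merged = merge_junctions(truth)
        negs = sample_negatives(genome, merged, rng=rng)
        sites = {
            (m.representative.chrom, p)
            for m in merged
            for p in (m.representative.donor_pos, m.representative.acceptor_pos)
        }
        for w in negs:  # exhaustive brute-force interval check
            assert not any((w.chrom, p) in sites for p in range(w.start, w.end))

    def test_infeasible_sampling_raises(self, rng):
        genome = {"chr1": "A" * 200}
        merged = merge_junctions([J(d=50, a=150)])  # every window hits a site
        with pytest.raises(RuntimeError, match="rejection"):
            sample_negatives(genome, merged, ratio=5.0, rng=rng)

    def test_seeded_determinism(self, small_genome):
        genome, truth = small_genome
        merged = merge_junctions(truth)
        a = sample_negatives(genome, merged, rng=np.random.default_rng(5))
        b = sample_negatives(genome, merged, rng=np.random.default_rng(5))
        assert a == b


def W(chrom, start=0, label="negative"):
    return LabeledWindow(chrom, start, start + 160, "+", "A" * 160, label)


class TestSplit:
    def test_default_rule_chr5_lands_in_test(self):
        windows = [W(f"chr{i}", start=100 * i) for i in range(1, 6)]
        ds = split_by_chromosome(windows)
        assert [w.chrom for w in ds.train] == ["chr1", "chr2", "chr3"]
        assert [w.chrom for w in ds.validation] == ["chr4"]
        assert [w.chrom for w in ds.test] == ["chr5"]

    def test_all_chr4_gives_validation_only(self):
        ds = split_by_chromosome([W("chr4", start=s) for s in (0, 200)])
        assert not ds.train and not ds.test and len(ds.validation) == 2

    def test_duplicates_removed(self):
        ds = split_by_chromosome([W("chr1"), W("chr1")])
        assert len(ds.train) == 1

    def test_bare_numeric_chromosome_names(self):
        ds = split_by_chromosome([W("1"), W("4"), W("Chr2", start=300)])
        assert len(ds.train) == 2 and len(ds.validation) == 1


class TestSerialization:
    def test_round_trip_identity(self, small_genome, rng, tmp_path):
        genome, truth = small_genome
        merged = merge_junctions(truth)
        windows = extract_site_windows(merged, genome)
        windows += sample_negatives(genome, merged, rng=rng)
        ds = split_by_chromosome(windows)
        manifest = write_dataset(ds, tmp_path / "data", config={"flank_bp": 80}, seed=7)
        again = read_dataset(tmp_path / "data")
        assert again.train == ds.train
        assert again.validation == ds.validation
        assert again.test == ds.test
        assert manifest["seed"] == 7
        assert manifest["counts"] == ds.counts()
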