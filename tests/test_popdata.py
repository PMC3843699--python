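import numpy as np
import pytest

from parapop.popdata import (FormatError, HaplotypeAlignment, Outgroup,
                             RegionMap, call_segregating_sites,
                             collapse_haplotypes, consensus_sequence,
                             polarize_sites, read_fasta_alignment,
                             read_site_table, subset_columns,
                             write_fasta_alignment, write_site_table)


def _aln(seqs, counts=None, **kw):
    counts = counts or [1] * len(seqs)
    return HaplotypeAlignment([f"h{i}" for i in range(len(seqs))], seqs, counts, **kw)


class TestFastaIO:
    def test_plain_records(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGTACGTAA\n>b\nACGTACGTAC\n>c\nACGTACGTAG\n>d\nACGTACGTAT\n")
        aln = read_fasta_alignment(p)
        assert (aln.n, aln.L) == (4, 10)

    def test_count_tags_sum_to_sample_size(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">h1;count=32\nACGT\n>h2;count=32\nACGA\n")
        aln = read_fasta_alignment(p, counts_from_header=True)
        assert aln.n == 64
        assert aln.counts == [32, 32]

    def test_unequal_lengths_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGTACGTAA\n>b\nACGTACGTA\n")
        with pytest.raises(FormatError):
            read_fasta_alignment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta_alignment(p)

    def test_round_trip(self, tmp_path):
        aln = _aln(["ACGT", "ACGA", "TCGA"], [5, 2, 1])
        p = tmp_path / "rt.fa"
        write_fasta_alignment(aln, p)
        back = read_fasta_alignment(p, counts_from_header=True)
        assert back.seqs == aln.seqs and back.counts == aln.counts


class TestSiteTableIO:
    def test_round_trip_and_reconstruction(self, tmp_path):
        aln = _aln(["AG", "AT", "CT"], [2, 1, 1], positions=[10, 25])
        p = tmp_path / "sites.tsv"
        write_site_table(aln, p)
        back, sites = read_site_table(p)
        assert back.seqs == aln.seqs and back.counts == aln.counts
        assert sites.positions == [10, 25] and sites.n == 4

    def test_monomorphic_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("pos\tcount\t10\t25\nh1\t2\tA\tG\nh2\t1\tA\tT\nh3\t1\tA\tT\n")
        with pytest.raises(FormatError):
            read_site_table(p)

    def test_duplicate_positions_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("pos\tcount\t10\t10\nh1\t1\tA\tG\nh2\t1\tC\tT\n")
        with pytest.raises(FormatError):
            read_site_table(p)

    def test_invalid_symbols_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("pos\tcount\t10\t25\nh1\t1\tA\tG\nh2\t1\tX\tT\n")
        with pytest.raises(FormatError):
            read_site_table(p)


class TestCollapse:
    def test_identical_sequences_collapse(self):
        spec = collapse_haplotypes(_aln(["ACGT"] * 4))
        assert spec == [("ACGT", 4)]

    def test_spectrum_counts(self):
        spec = collapse_haplotypes(_aln(["AAAA", "AAAA", "CCCC", "GGGG"]))
        assert [c for _, c in spec] == [2, 1, 1]
        assert sum(c for _, c in spec) == 4

    def test_tie_break_lexicographic(self):
        spec = collapse_haplotypes(_aln(["TTTT", "AAAA"]))
        assert [s for s, _ in spec] == ["AAAA", "TTTT"]


class TestSegregatingSites:
    def test_maf_boundary_inclusive(self):
        aln = _aln(["A", "C"], [99, 1])
        assert call_segregating_sites(aln, 0.01).S == 1

    def test_maf_below_threshold_excluded(self):
        aln = _aln(["A", "C"], [199, 1])
        assert call_segregating_sites(aln, 0.01).S == 0

    def test_zero_threshold_keeps_all_polymorphic(self):
        aln = _aln(["AAG", "ACG", "ACG"])
        sites = call_segregating_sites(aln, 0.0)
        assert sites.positions == [2]

    def test_gap_column_dropped(self):
        aln = _aln(["A-G", "ACG", "TCG"])
        sites = call_segregating_sites(aln)
        assert sites.positions == [1]

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError):
            call_segregating_sites(_aln(["ACGT"]))

    def test_sites_only_alignment_round_trip(self, default_dataset):
        """Calling sites at threshold 0 on a sites-only alignment returns the
        original site positions exactly."""
        from parapop.synth import dataset_site_tables
        sa, _ = dataset_site_tables(default_dataset)
        sub = subset_columns(default_dataset.aln_a,
                             [(p, p) for p in sa.positions], "keep")
        again = call_segregating_sites(sub, 0.0)
        assert again.positions == sa.positions


class TestPolarize:
    def test_matching_outgroup_sets_derived(self):
        aln = _aln(["A", "G"], [60, 4])
        sites = call_segregating_sites(aln)
        pol = polarize_sites(sites, Outgroup("A"))
        assert pol.records[0].derived_count == 4

    def test_mismatching_outgroup_flags_unpolarizable(self):
        aln = _aln(["A", "G"], [32, 32])
        pol = polarize_sites(call_segregating_sites(aln), Outgroup("C"))
        assert pol.records[0].polarizable is False
        assert pol.polarized().S == 0

    def test_high_frequency_derived(self):
        aln = _aln(["A", "G"], [1, 63])
        pol = polarize_sites(call_segregating_sites(aln), Outgroup("A"))
        assert pol.records[0].derived_count == 63

    def test_gap_outgroup_unpolarizable(self):
        aln = _aln(["A", "G"], [2, 2])
        pol = polarize_sites(call_segregating_sites(aln), Outgroup("-"))
        assert pol.records[0].polarizable is False


class TestSubsetColumns:
    def test_keep_drop_complement_identical(self):
        aln = _aln(["ACGTACGTAA", "ACCTACGAAA", "TCGTACGTAT"])
        kept = subset_columns(aln, [(3, 6)], "keep")
        dropped = subset_columns(aln, [(1, 2), (7, 10)], "drop")
        assert kept.seqs == dropped.seqs
        assert kept.column_positions() == dropped.column_positions() == [3, 4, 5, 6]

    def test_drop_empty_is_identity(self):
        aln = _aln(["ACGT", "ACGA"])
        out = subset_columns(aln, [], "drop")
        assert out.seqs == aln.seqs

    def test_out_of_range_interval_rejected(self):
        with pytest.raises(ValueError):
            subset_columns(_aln(["ACGT"], [2]), [(3, 9)], "keep")

    def test_keep_region_length(self, default_dataset):
        regions = default_dataset.config.regions
        sub = subset_columns(default_dataset.aln_a,
                             regions.intervals_for("intron2"), "keep")
        assert sub.L == 282


class TestRegionMap:
    def test_lengths_sum_to_frame(self, default_dataset):
        regions = default_dataset.config.regions
        assert regions.length("intron2") == 282
        assert regions.length("cds") == 1488
        assert regions.length("noncds") == 1587
        assert 282 + 1488 + 1587 == 3357

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            RegionMap([("a", 1, 10), ("b", 10, 20)])

    def test_tsv_round_trip(self, tmp_path):
        rm = RegionMap([("x", 1, 5), ("y", 6, 9)])
        p = tmp_path / "regions.tsv"
        rm.write_tsv(p)
        back = RegionMap.read_tsv(p)
        assert back.intervals == rm.intervals
        assert back.label_of(7) == "y" and back.label_of(99) == "other"


def test_consensus_majority_with_gap_ignored():
    aln = _aln(["ACG", "ACG", "-TG"])
    assert consensus_sequence(aln) == "ACG"
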