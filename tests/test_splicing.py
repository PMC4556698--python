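"""Alignment parsing, coverage, splice-proportion and rank tests."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from splicelocus import splicing as sp
from splicelocus.genes import TranscriptModel
from splicelocus.ranktests import mann_whitney, mann_whitney_u
from splicelocus.sim import locus
from splicelocus.sim.rnaseq import simulate_rnaseq


def write_sam(path, records, chrom="geneX", length=10_000):
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for i, (pos, cigar, seq) in enumerate(records):
        lines.append(
            f"ind|r{i}\t0\t{chrom}\t{pos}\t255\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestParseAlignments:
    def test_spliced_cigar_arithmetic(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam", [(1, "10M100N10M", "A" * 20), (50, "5S10M", "A" * 15)]
        )
        reads = list(sp.parse_alignments(sam))
        assert reads[0].segments == ((1, 10), (111, 120))
        assert reads[0].gaps == ((11, 110),)
        assert reads[1].segments == ((50, 59),)
        assert reads[1].gaps == ()

    def test_deletion_extends_covered_span(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [(10, "5M2D5M", "A" * 10)])
        (read,) = sp.parse_alignments(sam)
        assert read.segments == ((10, 21),)

    def test_base_lookup_respects_insertions(self, tmp_path):
        seq = "ACGTA" + "TT" + "GGGGG"  # 5M2I5M
        sam = write_sam(tmp_path / "a.sam", [(100, "5M2I5M", seq)])
        (read,) = sp.parse_alignments(sam)
        assert read.base_at(100) == "A"
        assert read.base_at(104) == "A"
        assert read.base_at(105) == "G"  # insertion skipped
        assert read.base_at(99) is None

    def test_malformed_record_skipped(self, tmp_path):
        path = tmp_path / "a.sam"
        good = "ind|ok\t0\tgeneX\t5\t255\t4M\t*\t0\t0\tACGT\t*"
        bad = "ind|bad\t0\tgeneX\tnotanumber\t255\t4M\t*\t0\t0\tACGT\t*"
        path.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:geneX\tLN:1000\n" + bad + "\n" + good + "\n"
        )
        reads = list(sp.parse_alignments(str(path)))
        assert [r.pos for r in reads] == [5]


class TestCoverage:
    def test_unit_normalization(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [(11, "10M", "A" * 10)])
        prof = sp.coverage_profile(
            sp.parse_alignments(sam), ("geneX", 11, 20), total_aligned=1e9
        )
        assert prof.normalized == pytest.approx(np.ones(10))

    def test_scaling_law(self, tmp_path):
        sam = write_sam(
            tmp_path / "a.sam", [(11, "10M", "A" * 10), (15, "10M", "A" * 10)]
        )
        p1 = sp.coverage_profile(
            sp.parse_alignments(sam), ("geneX", 11, 30), total_aligned=1e8
        )
        p2 = sp.coverage_profile(
            sp.parse_alignments(sam), ("geneX", 11, 30), total_aligned=2e8
        )
        assert p1.normalized == pytest.approx(2 * p2.normalized)

    def test_gap_bases_uncovered(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [(1, "5M10N5M", "A" * 10)])
        prof = sp.coverage_profile(
            sp.parse_alignments(sam), ("geneX", 1, 20), total_aligned=1e9
        )
        assert prof.normalized[5:15] == pytest.approx(np.zeros(10))
        assert prof.normalized[:5].sum() == pytest.approx(5.0)


class TestSpliceProportion:
    def test_all_spliced(self, tmp_path):
        model = TranscriptModel("g", "geneX", "+", ((1, 100), (201, 300)))
        # reads covering base 100 and splicing 101-200
        sam = write_sam(
            tmp_path / "a.sam",
            [(91, "10M100N10M", "A" * 20), (96, "5M100N15M", "A" * 20)],
        )
        stats_df = sp.splice_proportion(sp.parse_alignments(sam), model, 1)
        assert stats_df["proportion"].iloc[0] == 1.0

    def test_intron_read_covers_but_does_not_splice(self, tmp_path):
        model = TranscriptModel("g", "geneX", "+", ((1, 100), (201, 300)))
        records = [
            (91, "10M100N10M", "A" * 20),  # spliced
            (95, "20M", "A" * 20),  # runs into the intron
            (150, "20M", "A" * 20),  # intronic only: no junction coverage
        ]
        stats_df = sp.splice_proportion(
            sp.parse_alignments(write_sam(tmp_path / "a.sam", records)), model, 1
        )
        row = stats_df.iloc[0]
        assert (row["n_covering"], row["n_spliced"]) == (2, 1)
        assert row["proportion"] == 0.5

    def test_partial_gap_not_spliced(self, tmp_path):
        model = TranscriptModel("g", "geneX", "+", ((1, 100), (201, 300)))
        # gap 101-150 does not reach the downstream exon start
        sam = write_sam(tmp_path / "a.sam", [(91, "10M50N10M", "A" * 20)])
        stats_df = sp.splice_proportion(sp.parse_alignments(sam), model, 1)
        row = stats_df.iloc[0]
        assert (row["n_covering"], row["n_spliced"]) == (1, 0)

    def test_minus_strand_junction(self, tmp_path):
        """On the minus strand the 'last base' of the upstream exon is the
        genomic start coordinate of that exon."""
        model = TranscriptModel("g", "geneX", "-", ((201, 300), (1, 100)))
        sam = write_sam(tmp_path / "a.sam", [(91, "10M100N10M", "A" * 20)])
        stats_df = sp.splice_proportion(sp.parse_alignments(sam), model, 1)
        row = stats_df.iloc[0]
        assert (row["n_covering"], row["n_spliced"]) == (1, 1)

    def test_homozygote_unbiasedness(self, tmp_path):
        """Mean splice proportion over many homozygotes tracks the retained
        fraction's complement (up to the junction-end-read correction)."""
        cfg = locus.rna_config(depth=60.0, seed=81)
        geno = {f"H{i:03d}": 2 for i in range(200)}
        sam = tmp_path / "h.sam"
        simulate_rnaseq(geno, locus.gene_model(), locus.genome(), cfg, str(sam))
        stats_df = sp.splice_proportion(
            sp.parse_alignments(str(sam)), locus.gene_model(), locus.RETAINED_INTRON
        )
        expected = 0.5 * (cfg.read_length - 1) / cfg.read_length
        assert stats_df["proportion"].mean() == pytest.approx(expected, abs=0.01)
        # count conservation
        assert (stats_df["n_spliced"] <= stats_df["n_covering"]).all()


class TestIntronExonRatio:
    @pytest.mark.parametrize("retention,expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)])
    def test_uniform_model_ratio(self, tmp_path, retention, expected):
        cfg = locus.rna_config(depth=400.0, seed=82)
        gene, genome = locus.gene_model(), locus.genome()
        cfg = locus.rna_config(
            depth=400.0, retention_fraction_background=retention, seed=82
        )
        sam = tmp_path / "r.sam"
        simulate_rnaseq({"A": 0}, gene, genome, cfg, str(sam))
        region = (locus.GENE_CHROM, gene.exons[0][0], gene.exons[-1][1])
        profs = sp.coverage_profiles(
            sp.parse_alignments(str(sam)), region, cfg.total_aligned
        )
        ratio = sp.intron_exon_ratio(profs["A"], gene, locus.RETAINED_INTRON)
        assert ratio == pytest.approx(expected, abs=0.06)


class TestExpressionSummary:
    def test_identical_individuals_zero_mad(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", [(1, "100M", "A" * 100)])
        model = TranscriptModel("g", "geneX", "+", ((1, 50), (61, 100)))
        prof = sp.coverage_profile(
            sp.parse_alignments(sam), ("geneX", 1, 100), 1e9, individual="x"
        )
        summ = sp.exon_group_summary({"grp": [prof, prof]}, model)
        assert (summ["mad"] == 0).all()

    def test_empty_group_warns(self, tmp_path):
        model = TranscriptModel("g", "geneX", "+", ((1, 50), (61, 100)))
        with pytest.warns(UserWarning, match="empty"):
            sp.exon_group_summary({"none": []}, model)

    def test_shift_test_identical_groups(self):
        p, _ = sp.expression_shift_test({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert p == pytest.approx(1.0)

    def test_shift_test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            sp.expression_shift_test({"a": [1.0], "b": [1.0, 2.0]})


class TestMannWhitney:
    def test_equal_singletons(self):
        res = mann_whitney([1.0], [1.0])
        assert res.p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        """Small-group exact P equals an independent rank-sum enumeration
        (including tied data)."""
        rng = np.random.default_rng(83)
        for n1, n2 in [(3, 4), (2, 6), (5, 5), (4, 8)]:
            x = np.round(rng.normal(size=n1), 1)
            y = np.round(rng.normal(0.5, size=n2), 1)
            res = mann_whitney(x, y)
            assert res.method == "exact"
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            centre = n1 * n2 / 2.0
            obs = abs(mann_whitney_u(x, y) - centre)
            hits = sum(
                1
                for chosen in itertools.combinations(range(n1 + n2), n1)
                # U from the rank-sum identity, a different route than the
                # implementation's pairwise count
                if abs(
                    ranks[list(chosen)].sum() - n1 * (n1 + 1) / 2 - centre
                )
                >= obs - 1e-12
            )
            assert res.p == pytest.approx(hits / comb(n1 + n2, n1))

    def test_large_sample_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(84)
        a, b = rng.normal(size=30), rng.normal(0.3, size=40)
        res = mann_whitney(a, b)
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.method == "asymptotic"
        assert res.p == pytest.approx(p)

    def test_power_at_study_group_sizes(self):
        """Simulated heterozygote vs non-carrier splice proportions at the
        study's group sizes (15 vs 238) reject the null at P < 1e-4."""
        rng = np.random.default_rng(85)
        hits = 0
        for _ in range(20):
            nc = rng.normal(0.95, 0.02, 238).clip(0, 1)
            het = rng.normal(0.70, 0.05, 15).clip(0, 1)
            if mann_whitney(het, nc).p < 1e-4:
                hits += 1
        assert hits >= 19
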