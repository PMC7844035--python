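"""VCF parsing, hard filtering, site filtering and annotation arithmetic."""

import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.variants import (
    FilterThresholds,
    GeneModels,
    classify_variants,
    hard_filter,
    read_vcf,
    site_filter,
    summarize_annotation,
)
from conftest import make_gm

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB
chr1\t101\t.\tA\tG\t50\tPASS\t.\tGT\t0|1\t1|1
chr1\t201\t.\tC\tCTT\t50\tPASS\t.\tGT\t0|0\t0|1
chr1\t301\t.\tT\tC\t50\tPASS\t.\tGT\t./.\t0|0
chr1\t401\t.\tG\tA\t50\tPASS\t.\tGT\t1|0\t0|0
"""


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(VCF_TEXT)
    pm = tmp_path / "popmap.tsv"
    pm.write_text("sA\tpopX\nsB\tpopY\n")
    return p, pm


def test_read_vcf_parses_biallelic_snps_and_skips_indels(toy_vcf):
    gm, popmap = read_vcf(*toy_vcf)
    # the indel at POS 201 is skipped
    assert gm.n_variants == 3
    assert gm.n_skipped_records == 1
    assert list(gm.pos) == [100, 300, 400]  # 0-based internally
    assert gm.samples == ["sA", "sB"]
    assert popmap["sA"] == "popX"
    # genotype codes: first record 0|1, 1|1
    assert gm.alleles[0].tolist() == [[0, 1], [1, 1]]
    # missing ./. becomes (-1, -1)
    assert gm.alleles[1, 0].tolist() == [-1, -1]
    assert gm.phased
    assert gm.chrom_lengths == {"chr1": 100000}


def test_read_vcf_requires_popmap_coverage(toy_vcf, tmp_path):
    vcf, _ = toy_vcf
    bad = tmp_path / "bad.tsv"
    bad.write_text("sA\tpopX\n")
    with pytest.raises(ValueError, match="absent from popmap"):
        read_vcf(vcf, bad)


def _rec(qual=50.0, **info):
    return SimpleNamespace(QUAL=qual, INFO=info)


class TestHardFilter:
    def test_all_passing_record_kept(self):
        kept, tally = hard_filter(
            [_rec(QD=12, FS=2, DP=10, ReadPosRankSum=0)]
        )
        assert len(kept) == 1 and tally.removed == 0

    @pytest.mark.parametrize(
        "rec,criterion",
        [
            (_rec(QD=5.0), "qd"),
            (_rec(FS=11.0), "fs"),
            (_rec(DP=3), "dp"),
            (_rec(ReadPosRankSum=-9.0), "readpos_ranksum"),
            (_rec(qual=10.0), "qual"),
        ],
    )
    def test_single_violation_removed_and_tallied(self, rec, criterion):
        kept, tally = hard_filter([rec])
        assert kept == []
        assert getattr(tally, criterion) == 1
        assert tally.removed == 1

    def test_missing_fields_do_not_trigger_removal(self):
        kept, tally = hard_filter([_rec(qual=100.0)])
        assert len(kept) == 1

    def test_strict_missing_mode_removes_on_absence(self):
        kept, _ = hard_filter([_rec(qual=100.0)], strict_missing=True)
        assert kept == []

    @given(
        qd=st.floats(0, 40),
        fs=st.floats(0, 40),
        qual=st.floats(0, 100),
        dp=st.integers(0, 30),
        rprs=st.floats(-20, 20),
        loosen=st.sampled_from(["qd_min", "fs_max", "qual_min", "dp_min", "readpos_ranksum_min"]),
    )
    @settings(max_examples=50, derandomize=True)
    def test_loosening_a_threshold_never_removes_more(self, qd, fs, qual, dp, rprs, loosen):
        rec = _rec(qual=qual, QD=qd, FS=fs, DP=dp, ReadPosRankSum=rprs)
        base = FilterThresholds()
        kept_base, _ = hard_filter([rec], base)
        delta = {"qd_min": -1, "fs_max": +1, "qual_min": -1, "dp_min": -1, "readpos_ranksum_min": -1}
        loose = FilterThresholds(
            **{
                f: getattr(base, f) + (delta[f] if f == loosen else 0)
                for f in delta
            }
        )
        kept_loose, _ = hard_filter([rec], loose)
        assert len(kept_loose) >= len(kept_base)


class TestSiteFilter:
    def test_all_missing_site_removed(self):
        gm = make_gm([[(0, 1), (0, 0)], [(-1, -1), (-1, -1)]])
        out = site_filter(gm, min_call_rate=0.5, min_maf=0.0)
        assert out.n_variants == 1

    def test_maf_threshold_counts(self):
        # 10 sites; 3 monomorphic (MAF 0), 7 polymorphic in 4 samples
        rows = []
        for i in range(10):
            if i < 3:
                rows.append([(0, 0)] * 4)
            else:
                rows.append([(0, 1)] + [(0, 0)] * 3)
        gm = make_gm(rows)
        out = site_filter(gm, min_call_rate=0.9, min_maf=0.01)
        assert out.n_variants == 7

    def test_maf_zero_only_call_rate_applies(self):
        gm = make_gm([[(0, 0), (0, 0)], [(0, 1), (-1, -1)]])
        out = site_filter(gm, min_call_rate=0.9, min_maf=0.0)
        assert out.n_variants == 1  # second site has call rate 0.5


class TestClassifyVariants:
    @pytest.fixture
    def models(self):
        genes = pd.DataFrame(
            [("chr1", 100, 400, "g1")], columns=["chrom", "start", "end", "name"]
        )
        exons = pd.DataFrame(
            [("chr1", 100, 200, "g1"), ("chr1", 300, 400, "g1")],
            columns=["chrom", "start", "end", "name"],
        )
        return GeneModels(genes, exons)

    def test_exon_intron_intergenic(self, models):
        gm = make_gm([[(0, 1)]] * 4, pos=[150, 250, 399, 450])
        labels = classify_variants(gm, models)
        assert labels.tolist() == ["exonic", "intronic", "exonic", "intergenic"]

    def test_half_open_boundaries(self, models):
        gm = make_gm([[(0, 1)]] * 3, pos=[99, 100, 400])
        assert classify_variants(gm, models).tolist() == [
            "intergenic",
            "exonic",
            "intergenic",
        ]

    def test_chromosome_without_genes_is_intergenic(self, models):
        gm = make_gm([[(0, 1)]], pos=[150], chrom=["chr9"])
        assert classify_variants(gm, models).tolist() == ["intergenic"]

    def test_gff3_coordinates_converted(self, tmp_path):
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1;Name=g1\n"
            "chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=g1e1;Parent=g1\n"
            "chr1\tsrc\texon\t301\t400\t.\t+\t.\tID=g1e2;Parent=g1\n"
        )
        models = GeneModels.from_gff3(gff)
        assert models.genes[["start", "end"]].values.tolist() == [[100, 400]]
        gm = make_gm([[(0, 1)]] * 3, pos=[150, 250, 399])
        assert classify_variants(gm, models).tolist() == [
            "exonic",
            "intronic",
            "exonic",
        ]

    def test_categories_partition_variants(self, models):
        rng = np.random.default_rng(0)
        gm = make_gm([[(0, 1)]] * 50, pos=sorted(rng.choice(1000, 50, replace=False)))
        labels = classify_variants(gm, models)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == gm.n_variants


class TestSummarizeAnnotation:
    def test_percentages_use_stated_denominators(self):
        s = summarize_annotation(
            {"exonic": 10, "intronic": 30, "intergenic": 60},
            {"nonsynonymous": 4, "synonymous": 5},
        )
        assert s.category_pct["exonic"] == pytest.approx(10.0)
        assert s.effect_pct["nonsynonymous"] == pytest.approx(40.0)
        assert s.ns_s_ratio == pytest.approx(0.8)

    def test_zero_synonymous_yields_nan_not_crash(self):
        s = summarize_annotation({"exonic": 1}, {"nonsynonymous": 1, "synonymous": 0})
        assert math.isnan(s.ns_s_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            summarize_annotation({"exonic": -1})
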