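"""Region extraction, gene overlap, enrichment and the pipeline driver."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.report import (
    PipelineConfig,
    hypergeom_enrich,
    genes_in_regions,
    merge_regions,
    overlap_genes,
    run_pipeline,
    select_windows,
)
from sweepscan.simulate import SimConfig
from sweepscan.variants import GeneModels
from oracles import hypergeom_upper_tail_exact


def _scores(zhps):
    n = len(zhps)
    return pd.DataFrame(
        {
            "chrom": ["c"] * n,
            "start": np.arange(n) * 100,
            "end": np.arange(n) * 100 + 100,
            "zhp": zhps,
        }
    )


class TestSelectWindows:
    def test_zhp_rule_counts(self):
        out = select_windows(_scores([-5, -2, 0, -4.1]), "zhp")
        assert len(out) == 2

    def test_empty_result_is_fine(self):
        out = select_windows(_scores([0, 1]), "zhp")
        assert out.empty

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            select_windows(_scores([0]), "bogus")


class TestMergeRegions:
    def _w(self, spans, scores=None):
        df = pd.DataFrame(spans, columns=["start", "end"])
        df.insert(0, "chrom", "c")
        if scores is not None:
            df["score"] = scores
        return df

    def test_overlapping_windows_merge(self):
        out = merge_regions(self._w([(0, 100_000), (50_000, 150_000)]))
        assert out[["start", "end"]].values.tolist() == [[0, 150_000]]

    def test_disjoint_windows_stay_separate(self):
        out = merge_regions(self._w([(0, 100), (200, 300)]))
        assert len(out) == 2

    def test_identical_windows_collapse(self):
        out = merge_regions(self._w([(0, 100)] * 3))
        assert out[["start", "end"]].values.tolist() == [[0, 100]]

    def test_peak_score_is_most_extreme(self):
        out = merge_regions(self._w([(0, 100), (50, 150)], scores=[-5.0, -7.5]))
        assert out["peak_score"].iloc[0] == -7.5

    @given(
        spans=st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 30)).map(
                lambda t: (t[0] * 10, t[0] * 10 + t[1] * 10)
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=40, derandomize=True)
    def test_idempotent(self, spans):
        once = merge_regions(self._w(spans))
        twice = merge_regions(once)
        assert once[["chrom", "start", "end"]].equals(
            twice[["chrom", "start", "end"]]
        )


class TestGenesInRegions:
    @pytest.fixture
    def models(self):
        genes = pd.DataFrame(
            [("c", 100, 200, "g1"), ("c", 250, 350, "g2"), ("c", 400, 500, "g3")],
            columns=["chrom", "start", "end", "name"],
        )
        return GeneModels(genes)

    def test_one_bp_overlap_reported(self, models):
        regions = pd.DataFrame([("c", 150, 300)], columns=["chrom", "start", "end"])
        per, union = genes_in_regions(regions, models)
        assert per[0] == ["g1", "g2"]

    def test_bookended_region_not_reported(self, models):
        regions = pd.DataFrame([("c", 200, 250)], columns=["chrom", "start", "end"])
        per, union = genes_in_regions(regions, models)
        assert per[0] == [] and union == []

    def test_region_covering_all(self, models):
        regions = pd.DataFrame([("c", 0, 1000)], columns=["chrom", "start", "end"])
        _, union = genes_in_regions(regions, models)
        assert union == ["g1", "g2", "g3"]


class TestOverlapGenes:
    def test_basic_intersection(self):
        assert overlap_genes([{"A", "B", "C"}, {"B", "C", "D"}]) == ["B", "C"]

    def test_empty_set_dominates(self):
        assert overlap_genes([{"A"}, set()]) == []

    def test_identical_sets(self):
        assert overlap_genes([{"x", "y"}] * 3) == ["x", "y"]

    def test_order_invariant(self):
        s = [{"a", "b"}, {"b", "c"}, {"b"}]
        assert overlap_genes(s) == overlap_genes(list(reversed(s)))

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_genes([{"a"}])


class TestHypergeomEnrich:
    def test_forced_full_overlap(self):
        bg = [f"g{i}" for i in range(10)]
        res = hypergeom_enrich(bg[:5], {"T": bg[:5]}, bg)
        assert res["p"].iloc[0] == pytest.approx(1 / 252)

    def test_zero_hits_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        res = hypergeom_enrich(bg[:3], {"T": bg[5:]}, bg)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(11)
        bg = [f"g{i}" for i in range(30)]
        for _ in range(20):
            K = int(rng.integers(1, 20))
            n = int(rng.integers(1, 20))
            term = list(rng.choice(bg, K, replace=False))
            study = list(rng.choice(bg, n, replace=False))
            res = hypergeom_enrich(study, {"T": term}, bg)
            k = len(set(term) & set(study))
            assert res["p"].iloc[0] == pytest.approx(
                hypergeom_upper_tail_exact(k, 30, K, n), abs=1e-12
            )

    def test_study_gene_outside_background_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            hypergeom_enrich(["zz"], {"T": ["a"]}, ["a", "b"])

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(12)
        bg = [f"g{i}" for i in range(40)]
        term = bg[:10]
        n_reject = 0
        n_draws = 1000
        for _ in range(n_draws):
            study = list(rng.choice(bg, 8, replace=False))
            res = hypergeom_enrich(study, {"T": term}, bg)
            n_reject += bool(res["significant"].iloc[0])
        # discrete test is conservative: empirical rate <= 0.05 + 3 se
        se = np.sqrt(0.05 * 0.95 / n_draws)
        assert n_reject / n_draws <= 0.05 + 3 * se


class TestPipeline:
    def _cfg(self, outdir, seed=2):
        return PipelineConfig(
            outdir=str(outdir),
            sim=SimConfig(
                seed=seed,
                n_pops=2,
                samples_per_pop=10,
                chrom_lengths=[3_000_000],
                n_snps_per_chrom=600,
            ),
        )

    def test_end_to_end_outputs_present(self, tmp_path):
        man = run_pipeline(self._cfg(tmp_path / "run"))
        for name in (
            "diversity.tsv",
            "hp_pop1.tsv",
            "fst_pop1_pop2.tsv",
            "xpehh_pop1_pop2.tsv",
            "roh.tsv",
            "ld_pop1.tsv",
            "pca.tsv",
            "tree.nwk",
            "candidate_regions.tsv",
        ):
            assert name in man["files"], name
        assert (tmp_path / "run" / "manifest.json").exists()

    def test_rerun_same_seed_identical_outputs(self, tmp_path):
        run_pipeline(self._cfg(tmp_path / "a"))
        run_pipeline(self._cfg(tmp_path / "b"))
        for name in ("hp_pop1.tsv", "fst_pop1_pop2.tsv", "xpehh_pop1_pop2.tsv", "pca.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_missing_inputs_report_stage(self, tmp_path):
        with pytest.raises(RuntimeError, match="stage"):
            run_pipeline(PipelineConfig(outdir=str(tmp_path / "x")))

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "outdir": str(tmp_path / "out"),
                    "zfst_min": 3.5,
                    "sim": {"seed": 1, "n_pops": 2, "samples_per_pop": 6,
                            "chrom_lengths": [1_000_000], "n_snps_per_chrom": 200},
                }
            )
        )
        cfg = PipelineConfig.from_yaml(cfg_path)
        assert cfg.zfst_min == 3.5
        assert cfg.sim.samples_per_pop == 6
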