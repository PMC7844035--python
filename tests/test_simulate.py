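"""Synthetic-panel generator: determinism, differentiation recovery, LD,
planted sweeps/ROH and file round-trips."""

import numpy as np
import pytest

from sweepscan import (
    ROHSpec,
    SimConfig,
    SweepSpec,
    make_windows,
    pooled_heterozygosity,
    plant_roh,
    plant_sweep,
    read_vcf,
    simulate_panel,
    write_panel,
)
from sweepscan.fst import genome_fst, wc_components
from sweepscan.homozygosity import ld_decay


def small_cfg(**kw):
    base = dict(
        seed=1,
        n_pops=2,
        samples_per_pop=10,
        chrom_lengths=[2_000_000],
        n_snps_per_chrom=400,
    )
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_gives_identical_panels():
    g1, _, _ = simulate_panel(small_cfg())
    g2, _, _ = simulate_panel(small_cfg())
    assert np.array_equal(g1.alleles, g2.alleles)
    assert np.array_equal(g1.pos, g2.pos)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        simulate_panel(small_cfg(fst_target=1.0))
    with pytest.raises(ValueError):
        simulate_panel(small_cfg(n_founders=1))
    with pytest.raises(ValueError):
        simulate_panel(small_cfg(samples_per_pop=0))


@pytest.mark.parametrize("target", [0.0, 0.05, 0.15])
def test_fst_target_recovered(target):
    cfg = SimConfig(
        seed=7,
        n_pops=2,
        samples_per_pop=25,
        chrom_lengths=[60_000_000],
        n_snps_per_chrom=12_000,
        fst_target=target,
    )
    gm, popmap, _ = simulate_panel(cfg)
    est = genome_fst(wc_components(gm, popmap, "pop1", "pop2"))
    if target == 0.0:
        assert est <= 0.01
    else:
        assert est == pytest.approx(target, abs=0.03)


def test_mosaic_ld_decays_with_distance():
    cfg = SimConfig(
        seed=3,
        n_pops=1,
        samples_per_pop=25,
        chrom_lengths=[8_000_000],
        n_snps_per_chrom=1600,
        mosaic_break_rate=1e-5,
    )
    gm, popmap, _ = simulate_panel(cfg)
    ld = ld_decay(gm, popmap, "pop1", max_dist=300_000, bin_size=5_000)
    near = ld[ld["bin_lo"] < 10_000]["mean_r2"].mean()
    far = ld[ld["bin_lo"] >= 200_000]["mean_r2"].mean()
    assert near > far


class TestPlantSweep:
    def test_full_sweep_makes_interval_monomorphic(self):
        cfg = small_cfg(
            sweep_specs=[
                SweepSpec("pop1", "chr1", 500_000, 1_000_000, 700_000, 1.0, 1.0)
            ]
        )
        gm, popmap, _ = simulate_panel(cfg)
        idx = popmap.indices(gm, "pop1")
        m = (gm.pos >= 500_000) & (gm.pos < 1_000_000)
        hap = gm.haplotypes(idx)[m]
        assert (hap == 1).all()
        windows = make_windows({"chr1": 2_000_000})
        hp = pooled_heterozygosity(gm, popmap, "pop1", windows)
        sweep_win = hp[(hp["start"] >= 500_000) & (hp["end"] <= 1_000_000)]
        assert (sweep_win["hp"].dropna() == 0).all()

    def test_zero_founder_fraction_only_shifts_frequencies(self):
        base, popmap, _ = simulate_panel(small_cfg())
        swept, _, _ = simulate_panel(
            small_cfg(
                sweep_specs=[
                    SweepSpec("pop1", "chr1", 500_000, 1_000_000, 700_000, 0.9, 0.0)
                ]
            )
        )
        m = (base.pos >= 500_000) & (base.pos < 1_000_000)
        idx = popmap.indices(base, "pop1")
        freq_before = base.haplotypes(idx)[m].mean(axis=1)
        freq_after = swept.haplotypes(idx)[m].mean(axis=1)
        assert (freq_after >= freq_before - 1e-12).all()
        assert (freq_after >= 0.9 - 0.5 / (2 * len(idx))).all()
        # pop2 untouched
        idx2 = popmap.indices(base, "pop2")
        assert np.array_equal(base.alleles[:, idx2], swept.alleles[:, idx2])

    def test_hp_monotone_in_founder_fraction(self):
        windows = make_windows({"chr1": 2_000_000})
        hps = []
        for frac in (0.0, 0.5, 1.0):
            gm, popmap, _ = simulate_panel(
                small_cfg(
                    sweep_specs=[
                        SweepSpec("pop1", "chr1", 500_000, 1_000_000, 700_000, 0.9, frac)
                    ]
                )
            )
            hp = pooled_heterozygosity(gm, popmap, "pop1", windows, min_snps=1)
            inside = hp[(hp["start"] >= 500_000) & (hp["end"] <= 1_000_000)]
            hps.append(inside["hp"].mean())
        assert hps[0] >= hps[1] >= hps[2]

    def test_unknown_population_rejected(self):
        gm, popmap, _ = simulate_panel(small_cfg())
        with pytest.raises(KeyError):
            plant_sweep(gm, popmap, SweepSpec("nope", "chr1", 0, 1000, 500))


class TestPlantRoh:
    def test_interval_becomes_homozygous(self):
        cfg = small_cfg(roh_specs=[ROHSpec("pop1", 2, "chr1", 400_000, 1_500_000)])
        gm, popmap, truth = simulate_panel(cfg)
        col = gm.sample_indices([popmap.samples_in("pop1")[2]])[0]
        m = (gm.pos >= 400_000) & (gm.pos < 1_500_000)
        a = gm.alleles[m, col]
        assert (a[:, 0] == a[:, 1]).all()
        assert len(truth.rohs) == 1

    def test_empty_interval_leaves_panel_unchanged_but_recorded(self):
        gm, popmap, truth = simulate_panel(small_cfg())
        before = gm.alleles.copy()
        # choose an interval between two SNPs (covers no SNP)
        gaps = np.diff(gm.pos)
        j = int(np.argmax(gaps))
        lo, hi = int(gm.pos[j]) + 1, int(gm.pos[j + 1])
        plant_roh(gm, popmap, ROHSpec("pop1", 0, "chr1", lo, hi), truth)
        assert np.array_equal(gm.alleles, before)
        assert len(truth.rohs) == 1

    def test_sample_index_out_of_range(self):
        gm, popmap, _ = simulate_panel(small_cfg())
        with pytest.raises(IndexError):
            plant_roh(gm, popmap, ROHSpec("pop1", 99, "chr1", 0, 1000))


class TestWritePanel:
    def test_round_trip_preserves_genotypes(self, tmp_path):
        gm, popmap, truth = simulate_panel(small_cfg())
        paths = write_panel(gm, popmap, truth, tmp_path)
        gm2, popmap2 = read_vcf(paths["vcf"], paths["popmap"])
        assert np.array_equal(gm.alleles, gm2.alleles)
        assert np.array_equal(gm.pos, gm2.pos)
        assert gm2.phased

    def test_vcf_pos_strictly_increasing_per_chrom(self, tmp_path):
        gm, popmap, truth = simulate_panel(small_cfg(chrom_lengths=[1_000_000, 1_000_000]))
        paths = write_panel(gm, popmap, truth, tmp_path)
        by_chrom = {}
        for line in open(paths["vcf"]):
            if line.startswith("#"):
                continue
            c, p = line.split("\t")[:2]
            by_chrom.setdefault(c, []).append(int(p))
        for plist in by_chrom.values():
            assert all(b > a for a, b in zip(plist, plist[1:]))

    def test_popmap_lists_every_sample_exactly_once(self, tmp_path):
        gm, popmap, truth = simulate_panel(small_cfg())
        paths = write_panel(gm, popmap, truth, tmp_path)
        lines = [l.split("\t")[0] for l in open(paths["popmap"]).read().splitlines()]
        assert sorted(lines) == sorted(gm.samples)
        assert len(set(lines)) == len(lines)

    def test_identical_config_writes_identical_files(self, tmp_path):
        for d in ("a", "b"):
            gm, popmap, truth = simulate_panel(small_cfg())
            write_panel(gm, popmap, truth, tmp_path / d)
        for name in ("panel.vcf", "popmap.tsv", "genes.bed", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
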