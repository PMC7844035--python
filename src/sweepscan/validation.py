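"""Simulation-recovery benchmarks.

These experiments exercise the whole stack against panels with known
truth: Weir-Cockerham FST recovery of the Balding-Nichols target, planted
hard-sweep detection by all three scans, null-panel calibration, planted
ROH recovery, and PCA population separation.  They are used both by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diversity, fst, homozygosity, simulate, structure
from .xpehh import xpehh as xpehh_scan, top_fraction
from .report import select_windows
from .variants import GenotypeMatrix, PopulationMap

__all__ = [
    "fst_recovery",
    "sweep_panel_config",
    "sweep_detection",
    "null_calibration",
    "roh_fixture",
    "roh_recovery",
    "pca_separation",
]


def fst_recovery(
    seed: int,
    fst_target: float = 0.15,
    n_pops: int = 3,
    samples_per_pop: int = 30,
    n_snps: int = 20_000,
) -> float:
    """Genome-wide ratio-of-sums Weir-Cockerham FST of a simulated panel,
    averaged over all population pairs."""
    cfg = simulate.SimConfig(
        seed=seed,
        n_pops=n_pops,
        samples_per_pop=samples_per_pop,
        chrom_lengths=[100_000_000],
        n_snps_per_chrom=n_snps,
        fst_target=fst_target,
    )
    gm, popmap, _ = simulate.simulate_panel(cfg)
    pops = popmap.populations
    vals = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            vals.append(fst.genome_fst(fst.wc_components(gm, popmap, a, b)))
    return float(np.mean(vals))


def sweep_panel_config(
    seed: int,
    derived_freq: float = 0.95,
    founder_fraction: float = 0.9,
    with_sweep: bool = True,
) -> simulate.SimConfig:
    """Two-population panel (2 chromosomes, 10 + 6 Mb at 200 SNPs/Mb) with
    an optional 500-kb hard sweep on chr1 in pop1."""
    sweeps = []
    if with_sweep:
        sweeps = [
            simulate.SweepSpec(
                pop="pop1",
                chrom="chr1",
                start=4_500_000,
                end=5_000_000,
                core_pos=4_750_000,
                derived_freq=derived_freq,
                founder_fraction=founder_fraction,
            )
        ]
    return simulate.SimConfig(
        seed=seed,
        n_pops=2,
        samples_per_pop=30,
        chrom_lengths=[10_000_000, 6_000_000],
        n_snps_per_chrom=2000,
        fst_target=0.15,
        sweep_specs=sweeps,
    )


def _windows_overlapping(df: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    return df[(df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)]


def sweep_detection(seed: int) -> dict[str, bool]:
    """Run the three scans on a planted-sweep panel and report whether each
    detects the sweep interval.

    Criteria: the interval overlaps >= 1 window with ZHp < -4 in the
    selected population; >= 1 window with ZFst > 4 in selected-vs-control;
    and at least half of the selected-tail (top 1 %, upper) XP-EHH SNPs lie
    within the interval +- 100 kb.
    """
    cfg = sweep_panel_config(seed)
    sw = cfg.sweep_specs[0]
    gm, popmap, _ = simulate.simulate_panel(cfg)
    windows = diversity.make_windows(gm.lengths_or_inferred())

    hp = diversity.pooled_heterozygosity(gm, popmap, sw.pop, windows)
    hp_hit = not _windows_overlapping(
        select_windows(hp, "zhp"), sw.chrom, sw.start, sw.end
    ).empty

    comp = fst.wc_components(gm, popmap, "pop1", "pop2")
    wf = fst.windowed_fst(comp, windows)
    fst_hit = not _windows_overlapping(
        select_windows(wf, "zfst"), sw.chrom, sw.start, sw.end
    ).empty

    xp = xpehh_scan(gm, popmap, "pop1", "pop2")
    xp = top_fraction(xp, q=0.01, side="upper")
    tail = xp[xp["tail"]]
    near = tail[
        (tail["chrom"] == sw.chrom)
        & (tail["pos"] >= sw.start - 100_000)
        & (tail["pos"] < sw.end + 100_000)
    ]
    xp_hit = len(tail) > 0 and len(near) >= len(tail) / 2
    xp_overlap = not _windows_overlapping(
        tail.rename(columns={"pos": "start"}).assign(end=lambda d: d["start"] + 1),
        sw.chrom,
        sw.start,
        sw.end,
    ).empty

    return {
        "zhp": bool(hp_hit),
        "zfst": bool(fst_hit),
        "xpehh_tail_concentrated": bool(xp_hit),
        "xpehh_tail_in_interval": bool(xp_overlap),
    }


def null_calibration(seed: int) -> bool:
    """True if a sweep-free panel yields no window jointly passing
    ZHp < -4 and ZFst > 4."""
    cfg = sweep_panel_config(seed, with_sweep=False)
    gm, popmap, _ = simulate.simulate_panel(cfg)
    windows = diversity.make_windows(gm.lengths_or_inferred())
    hp = diversity.pooled_heterozygosity(gm, popmap, "pop1", windows)
    wf = fst.windowed_fst(fst.wc_components(gm, popmap, "pop1", "pop2"), windows)
    joint = (hp["zhp"].to_numpy() < -4) & (wf["zfst"].to_numpy() > 4)
    return not bool(np.nansum(joint))


def roh_fixture(
    seed: int,
    roh_start: int = 2_000_000,
    roh_end: int = 2_600_000,
    chrom_length: int = 6_000_000,
    n_snps: int = 1200,
) -> tuple[GenotypeMatrix, PopulationMap, int, int]:
    """Synthetic single-chromosome two-sample fixture for ROH recovery.

    Sample ``roh_carrier`` is heterozygous at every SNP outside the planted
    interval and homozygous inside it, so the detectable boundary is sharp;
    sample ``het_control`` is heterozygous everywhere.  Returns the matrix,
    popmap and the first/last SNP positions inside the planted interval
    (the recoverable truth boundaries).
    """
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(chrom_length, size=n_snps, replace=False))
    V = len(pos)
    alleles = np.zeros((V, 2, 2), dtype=np.int8)
    alleles[:, :, 0] = 0
    alleles[:, :, 1] = 1  # everyone heterozygous 0|1
    inside = (pos >= roh_start) & (pos < roh_end)
    alleles[inside, 0, 1] = 0  # carrier homozygous ref inside the interval
    gm = GenotypeMatrix(
        chrom=np.full(V, "chr1", dtype=object),
        pos=pos,
        ref=np.full(V, "A", dtype=object),
        alt=np.full(V, "G", dtype=object),
        alleles=alleles,
        samples=["roh_carrier", "het_control"],
        phased=True,
        chrom_lengths={"chr1": chrom_length},
    )
    popmap = PopulationMap({"roh_carrier": "pop1", "het_control": "pop1"})
    first = int(pos[inside][0])
    last = int(pos[inside][-1])
    return gm, popmap, first, last


def roh_recovery(seed: int) -> dict:
    """Planted-ROH recovery with default (PLINK flag) parameters.

    Reports recall of the planted segment, boundary errors in units of the
    local inter-SNP gap, and the number of segments called on the fully
    heterozygous control sample.
    """
    gm, _, first, last = roh_fixture(seed)
    segs = homozygosity.detect_roh(gm, "roh_carrier")
    control = homozygosity.detect_roh(gm, "het_control")
    hit = [s for s in segs if s.start < last + 1 and s.end > first]
    result = {
        "recalled": len(hit) == 1,
        "n_segments": len(segs),
        "control_segments": len(control),
        "start_error_gaps": np.nan,
        "end_error_gaps": np.nan,
    }
    if hit:
        seg = hit[0]
        pos = gm.pos
        i_first = int(np.searchsorted(pos, first))
        i_last = int(np.searchsorted(pos, last))
        i_s = int(np.searchsorted(pos, seg.start))
        i_e = int(np.searchsorted(pos, seg.end - 1))
        result["start_error_gaps"] = abs(i_s - i_first)
        result["end_error_gaps"] = abs(i_e - i_last)
    return result


def pca_separation(seed: int, fst_target: float = 0.15) -> float:
    """k-means label agreement on PC1-PC2 of a 3-population panel.

    Returns the fraction of samples whose k-means cluster (best label
    assignment) matches their true population.
    """
    from scipy.optimize import linear_sum_assignment
    from sklearn.cluster import KMeans

    cfg = simulate.SimConfig(
        seed=seed,
        n_pops=3,
        samples_per_pop=20,
        chrom_lengths=[20_000_000],
        n_snps_per_chrom=4000,
        fst_target=fst_target,
    )
    gm, popmap, _ = simulate.simulate_panel(cfg)
    res = structure.pca(gm, k=4)
    xy = res.coords[:, :2]
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(xy)
    true = np.array([popmap.populations.index(popmap[s]) for s in gm.samples])
    # best cluster -> population assignment
    conf = np.zeros((3, 3), dtype=int)
    for t, c in zip(true, km.labels_):
        conf[t, c] += 1
    r, c = linear_sum_assignment(-conf)
    return float(conf[r, c].sum() / len(true))
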