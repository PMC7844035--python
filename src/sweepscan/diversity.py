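"""Per-population diversity statistics, the pooled-heterozygosity (Hp)
sliding-window scan, and the shared window / Z-transform machinery.

The window statistic is the pooled heterozygosity of Rubin-style sweep
scans: Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))**2, where
nMAJ/nMIN are the per-SNP major and minor allele counts pooled over a
population, summed over the SNPs of a window.  Window scores are
Z-transformed genome-wide; strongly negative ZHp marks depleted
heterozygosity, the footprint of a sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix, PopulationMap

__all__ = [
    "DiversitySummary",
    "allele_counts",
    "diversity_stats",
    "make_windows",
    "pooled_heterozygosity",
    "z_transform",
]

WINDOW_COLUMNS = ["chrom", "start", "end"]


@dataclass
class DiversitySummary:
    """Mean He, Ho, MAF over polymorphic sites, and FIS = 1 - Ho/He."""

    pop: str
    he: float
    ho: float
    maf: float
    fis: float
    n_sites: int


def allele_counts(
    gm: GenotypeMatrix, popmap: PopulationMap, pop: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant (ref_count, alt_count, n_called_genotypes) for one
    population, counting non-missing alleles only."""
    idx = popmap.indices(gm, pop)
    a = gm.alleles[:, idx, :]
    called_allele = a >= 0
    alt = ((a == 1) & called_allele).sum(axis=(1, 2))
    ref = ((a == 0) & called_allele).sum(axis=(1, 2))
    n_called = called_allele.all(axis=2).sum(axis=1)
    return ref, alt, n_called


def diversity_stats(
    gm: GenotypeMatrix, popmap: PopulationMap, pop: str
) -> DiversitySummary:
    """Genotype-frequency diversity summary for one population.

    Per site: He = 2p(1-p) with p the alt-allele frequency over called
    alleles, Ho = fraction heterozygous among fully called genotypes,
    MAF = min(p, 1-p).  Summaries are unweighted means over sites that are
    polymorphic in the population (He > 0); FIS = 1 - mean(Ho)/mean(He).
    """
    idx = popmap.indices(gm, pop)
    if len(idx) < 2:
        raise ValueError(f"population {pop!r} has fewer than 2 samples")
    a = gm.alleles[:, idx, :]
    called = (a >= 0).all(axis=2)
    alt = ((a == 1) & (a >= 0)).sum(axis=(1, 2))
    # allele frequency over all non-missing alleles (incl. half-calls)
    alleles_called = (a >= 0).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(alleles_called > 0, alt / np.maximum(alleles_called, 1), np.nan)
    he = 2 * p * (1 - p)
    het = (a[:, :, 0] != a[:, :, 1]) & called
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_called > 0, het.sum(axis=1) / np.maximum(n_called, 1), np.nan)
    poly = (he > 0) & ~np.isnan(ho) & (n_called >= 2)
    he_m = float(np.mean(he[poly]))
    ho_m = float(np.mean(ho[poly]))
    maf_m = float(np.mean(np.fmin(p[poly], 1 - p[poly])))
    fis = 1.0 - ho_m / he_m if he_m > 0 else float("nan")
    return DiversitySummary(
        pop=pop, he=he_m, ho=ho_m, maf=maf_m, fis=fis, n_sites=int(poly.sum())
    )


def make_windows(
    chrom_lengths: dict[str, int], size: int = 100_000, step: int = 50_000
) -> pd.DataFrame:
    """Sliding windows [start, start+size) truncated at the chromosome end.

    Starts at 0, step apart; every start < chromosome length is emitted.
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, step):
            rows.append((chrom, start, min(start + size, length)))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def _window_sums(
    chrom: np.ndarray, pos: np.ndarray, values: list[np.ndarray], windows: pd.DataFrame
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-window SNP counts and sums of each array in *values* (NaN-skipping).

    Uses cumulative sums over position-sorted SNPs per chromosome.
    """
    n_snps = np.zeros(len(windows), dtype=np.int64)
    sums = [np.zeros(len(windows)) for _ in values]
    for c in pd.unique(windows["chrom"]):
        wmask = (windows["chrom"] == c).to_numpy()
        smask = chrom == c
        p = pos[smask]
        starts = windows.loc[wmask, "start"].to_numpy()
        ends = windows.loc[wmask, "end"].to_numpy()
        lo = np.searchsorted(p, starts, side="left")
        hi = np.searchsorted(p, ends, side="left")
        for k, v in enumerate(values):
            vc = v[smask]
            ok = ~np.isnan(vc)
            cs = np.concatenate([[0.0], np.cumsum(np.where(ok, vc, 0.0))])
            sums[k][wmask] = cs[hi] - cs[lo]
            if k == 0:
                cnt = np.concatenate([[0], np.cumsum(ok.astype(np.int64))])
                n_snps[wmask] = cnt[hi] - cnt[lo]
    return n_snps, sums


def pooled_heterozygosity(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop: str,
    windows: pd.DataFrame,
    min_snps: int = 10,
) -> pd.DataFrame:
    """Windowed pooled heterozygosity for one population, Z-transformed.

    Major/minor assignment is per SNP from the population's pooled counts
    (ties count the reference allele as major).  Windows with fewer than
    *min_snps* SNPs carry no score (NaN hp and zhp).
    """
    if windows.empty:
        raise ValueError("window set is empty")
    ref, alt, _ = allele_counts(gm, popmap, pop)
    maj = np.where(alt > ref, alt, ref).astype(float)
    mino = np.where(alt > ref, ref, alt).astype(float)
    # sites with no called alleles contribute nothing
    none_called = (ref + alt) == 0
    maj[none_called] = np.nan
    mino[none_called] = np.nan
    n_snps, (s_maj, s_min) = _window_sums(gm.chrom, gm.pos, [maj, mino], windows)
    total = s_maj + s_min
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = np.where(total > 0, 2 * s_maj * s_min / np.maximum(total, 1) ** 2, np.nan)
    hp = np.where(n_snps >= min_snps, hp, np.nan)
    out = windows.copy()
    out["n_snps"] = n_snps
    out["hp"] = hp
    out["zhp"] = z_transform(hp)
    return out


def z_transform(values) -> np.ndarray:
    """Standardize to mean 0, sample sd 1 (ddof=1); NaNs propagate.

    A constant (zero-spread) input yields all-NaN output with a warning.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        warnings.warn("z_transform: fewer than 2 defined values")
        return np.full_like(x, np.nan)
    mu = x[ok].mean()
    sd = x[ok].std(ddof=1)
    if sd == 0:
        warnings.warn("z_transform: zero spread, z-scores undefined")
        return np.full_like(x, np.nan)
    return (x - mu) / sd
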