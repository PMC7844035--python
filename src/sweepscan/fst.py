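"""Weir-Cockerham (1984) FST between two populations, per locus and
aggregated over sliding windows.

Per locus the estimator decomposes allele-frequency variance into three
components: a (among populations), b (among individuals within
populations) and c (within individuals).  The per-locus estimate is
a / (a + b + c); the window estimate is the ratio-of-sums
sum(a) / sum(a + b + c), the "weighted" windowed statistic of vcftools.
Negative estimates are retained (not clamped) so that the genome-wide
Z-transformation is not distorted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import _window_sums, z_transform
from .variants import GenotypeMatrix, PopulationMap

__all__ = [
    "wc_components",
    "windowed_fst",
    "genome_fst",
    "significant_fst_windows",
]


def _pop_stats(gm: GenotypeMatrix, popmap: PopulationMap, pop: str):
    """Per-locus sample size, alt frequency and heterozygote fraction for
    fully called genotypes of one population."""
    idx = popmap.indices(gm, pop)
    a = gm.alleles[:, idx, :]
    called = (a >= 0).all(axis=2)
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, (a == 1).sum(axis=2), 0).sum(axis=1).astype(float)
    het = np.where(called, a[:, :, 0] != a[:, :, 1], False).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def wc_components(
    gm: GenotypeMatrix, popmap: PopulationMap, pop_a: str, pop_b: str
) -> pd.DataFrame:
    """Per-locus Weir-Cockerham variance components for two populations.

    Returns a DataFrame with columns chrom, pos, a, b, c and fst
    (= a/(a+b+c) where the denominator is positive).  Components are NaN
    for loci where either population has no called genotype, where the
    mean sample size is <= 1, or where the locus is monomorphic across
    both populations (such loci contribute nothing downstream).
    """
    n1, p1, h1 = _pop_stats(gm, popmap, pop_a)
    n2, p2, h2 = _pop_stats(gm, popmap, pop_b)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0

    mono = ((p1 == 0) | np.isnan(p1)) & ((p2 == 0) | np.isnan(p2))
    mono |= ((p1 == 1) | np.isnan(p1)) & ((p2 == 1) | np.isnan(p2))
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | mono
    for arr in (a, b, c):
        arr[bad] = np.nan
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom > 0, a / denom, np.nan)
    return pd.DataFrame(
        {"chrom": gm.chrom, "pos": gm.pos, "a": a, "b": b, "c": c, "fst": fst}
    )


def windowed_fst(
    components: pd.DataFrame,
    windows: pd.DataFrame,
    min_snps: int = 10,
    mode: str = "ratio_of_sums",
) -> pd.DataFrame:
    """Aggregate per-locus components into window FST with Z-scores.

    ``ratio_of_sums`` (default) computes sum(a)/sum(a+b+c) per window, the
    vcftools "weighted" statistic; ``mean_of_ratios`` averages per-locus
    estimates instead.  Windows with fewer than *min_snps* informative
    loci are unscored (NaN).
    """
    if components.empty:
        raise ValueError("empty component set")
    if mode not in ("ratio_of_sums", "mean_of_ratios"):
        raise ValueError(f"unknown mode {mode!r}")
    chrom = components["chrom"].to_numpy()
    pos = components["pos"].to_numpy()
    a = components["a"].to_numpy(dtype=float)
    denom = (components["a"] + components["b"] + components["c"]).to_numpy(dtype=float)
    ratio = components["fst"].to_numpy(dtype=float)

    if mode == "ratio_of_sums":
        # count a locus only where the components are defined
        a_masked = np.where(np.isnan(denom), np.nan, a)
        n_snps, (s_a, s_d) = _window_sums(chrom, pos, [a_masked, denom], windows)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(s_d != 0, s_a / np.where(s_d != 0, s_d, 1), np.nan)
    else:
        n_snps, (s_r,) = _window_sums(chrom, pos, [ratio], windows)
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(n_snps > 0, s_r / np.maximum(n_snps, 1), np.nan)
    fst = np.where(n_snps >= min_snps, fst, np.nan)
    out = windows.copy()
    out["n_snps"] = n_snps
    out["fst"] = fst
    out["zfst"] = z_transform(fst)
    return out


def genome_fst(components: pd.DataFrame) -> float:
    """Genome-wide ratio-of-sums Weir-Cockerham FST."""
    a = components["a"].to_numpy(dtype=float)
    d = (components["a"] + components["b"] + components["c"]).to_numpy(dtype=float)
    ok = ~np.isnan(d)
    s = d[ok].sum()
    return float(a[ok].sum() / s) if s != 0 else float("nan")


def significant_fst_windows(scores: pd.DataFrame, z_min: float = 4.0) -> pd.DataFrame:
    """Windows with ZFst > *z_min*, sorted by Z descending."""
    hit = scores[scores["zfst"] > z_min]
    return hit.sort_values("zfst", ascending=False).reset_index(drop=True)
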