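"""PLINK-style runs-of-homozygosity detection and binned LD-decay curves.

ROH detection follows the scanning-window procedure behind PLINK's
``--homozyg`` flag family: a window of ``window_snp`` consecutive SNPs
(capped at ``window_kb`` span) passes if it contains at most
``window_het`` heterozygous and ``window_missing`` missing calls; each
SNP's hit rate is the fraction of passing windows among the windows that
cover it; SNPs at or above ``hit_threshold`` form candidate runs, which
are split at large gaps, trimmed to homozygous endpoints and kept only if
they satisfy the SNP-count, length and density constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix, PopulationMap

__all__ = ["ROHParams", "ROHSegment", "detect_roh", "detect_roh_all", "r2", "ld_decay"]


@dataclass(frozen=True)
class ROHParams:
    """Scanning-window ROH parameters (defaults follow the PLINK flag set
    --homozyg-window-kb 5000 --homozyg-window-snp 50 --homozyg-window-het 1
    --homozyg-window-missing 5 --homozyg-snp 10 --homozyg-kb 200
    --homozyg-density 50 --homozyg-gap 1000; hit_threshold is PLINK's
    --homozyg-window-threshold default)."""

    window_kb: float = 5000.0
    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    min_snp: int = 10
    min_kb: float = 200.0
    max_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    hit_threshold: float = 0.05


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # bp position of first SNP in the run (0-based)
    end: int    # bp position one past the last SNP in the run
    n_snps: int
    length_kb: float


def detect_roh(
    gm: GenotypeMatrix, sample: str, params: ROHParams = ROHParams()
) -> list[ROHSegment]:
    """Detect runs of homozygosity for one sample."""
    col = gm.sample_indices([sample])[0]
    a = gm.alleles[:, col, :]
    segments: list[ROHSegment] = []
    for c in gm.chromosomes:
        m = gm.chrom_mask(c)
        pos = gm.pos[m]
        g = a[m]
        miss = (g < 0).any(axis=1)
        het = (~miss) & (g[:, 0] != g[:, 1])
        segments.extend(_roh_one_chrom(sample, c, pos, het, miss, params))
    return segments


def detect_roh_all(
    gm: GenotypeMatrix, params: ROHParams = ROHParams()
) -> pd.DataFrame:
    """ROH for every sample, as a DataFrame."""
    rows = []
    for s in gm.samples:
        for seg in detect_roh(gm, s, params):
            rows.append(
                (seg.sample, seg.chrom, seg.start, seg.end, seg.n_snps, seg.length_kb)
            )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snps", "length_kb"]
    )


def _roh_one_chrom(sample, chrom, pos, het, miss, params: ROHParams):
    V = len(pos)
    if V == 0:
        return []
    het_c = np.concatenate([[0], np.cumsum(het.astype(np.int64))])
    mis_c = np.concatenate([[0], np.cumsum(miss.astype(np.int64))])

    # window start i covers SNPs [i, j_i); j bounded by SNP count and bp span
    starts = np.arange(V)
    j_snp = starts + params.window_snp
    j_kb = np.searchsorted(pos, pos + int(params.window_kb * 1000) + 1, side="left")
    ends = np.minimum(j_snp, j_kb)
    full = j_snp <= V  # only full-length (by SNP count or span cap) windows slide
    ends = np.minimum(ends, V)

    n_het = het_c[ends] - het_c[starts]
    n_mis = mis_c[ends] - mis_c[starts]
    passing = full & (n_het <= params.window_het) & (n_mis <= params.window_missing)

    # per-SNP covering/passing window counts via difference arrays
    cover = np.zeros(V + 1, dtype=np.int64)
    hits = np.zeros(V + 1, dtype=np.int64)
    for i in np.flatnonzero(full):
        cover[i] += 1
        cover[ends[i]] -= 1
    for i in np.flatnonzero(passing):
        hits[i] += 1
        hits[ends[i]] -= 1
    cover = np.cumsum(cover[:-1])
    hits = np.cumsum(hits[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(cover > 0, hits / np.maximum(cover, 1), 0.0)
    candidate = rate >= params.hit_threshold

    segments = []
    max_gap = params.max_gap_kb * 1000
    idx = np.flatnonzero(candidate)
    if len(idx) == 0:
        return segments
    # split candidate SNPs into runs (consecutive indices, bounded gaps)
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > max_gap)
    )
    run_bounds = np.split(idx, breaks + 1)
    for run in run_bounds:
        # trim to homozygous called endpoints
        ok = ~(het[run] | miss[run])
        if not ok.any():
            continue
        first = run[np.argmax(ok)]
        last = run[len(run) - 1 - np.argmax(ok[::-1])]
        run = run[(run >= first) & (run <= last)]
        n_snps = len(run)
        length_kb = (pos[last] - pos[first] + 1) / 1000.0
        if n_snps < params.min_snp:
            continue
        if length_kb < params.min_kb:
            continue
        if length_kb / n_snps > params.max_density_kb_per_snp:
            continue
        segments.append(
            ROHSegment(
                sample=sample,
                chrom=chrom,
                start=int(pos[first]),
                end=int(pos[last]) + 1,
                n_snps=int(n_snps),
                length_kb=float(length_kb),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def r2(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared haplotype correlation r^2 = D^2 / (pA qA pB qB).

    Computed over haplotypes with no missing allele at either site;
    undefined (NaN) if either site is monomorphic among those haplotypes.
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if len(a) == 0:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    d = (a * b).mean() - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_decay(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop: str,
    max_dist: int = 300_000,
    bin_size: int = 5_000,
) -> pd.DataFrame:
    """Binned mean r^2 against physical distance for one population.

    All SNP pairs within *max_dist* on the same chromosome contribute;
    pairs with a monomorphic member are skipped.  Returns bin_lo, bin_hi,
    n_pairs, mean_r2 (NaN for empty bins).
    """
    idx = popmap.indices(gm, pop)
    if len(idx) * 2 < 4:
        raise ValueError("need at least 4 haplotypes for LD")
    n_bins = int(np.ceil(max_dist / bin_size))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in gm.chromosomes:
        m = gm.chrom_mask(c)
        pos = gm.pos[m]
        hap = gm.haplotypes(idx)[m].astype(float)
        hap[hap < 0] = np.nan
        p = np.nanmean(hap, axis=1)
        poly = (p > 0) & (p < 1)
        pos = pos[poly]
        hap = hap[poly]
        V = len(pos)
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(V):
            j0, j1 = i + 1, hi[i]
            if j1 <= j0:
                continue
            x = hap[i]
            block = hap[j0:j1]
            ok = ~np.isnan(x)[None, :] & ~np.isnan(block)
            nn = ok.sum(axis=1).astype(float)
            xs = np.where(ok, x[None, :], 0.0)
            ys = np.where(ok, block, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                pa = xs.sum(axis=1) / nn
                pb = ys.sum(axis=1) / nn
                d = (xs * ys).sum(axis=1) / nn - pa * pb
                var = pa * (1 - pa) * pb * (1 - pb)
                val = np.where(var > 0, d * d / np.where(var > 0, var, 1), np.nan)
            dist = pos[j0:j1] - pos[i]
            b = np.minimum(dist // bin_size, n_bins - 1).astype(np.int64)
            good = ~np.isnan(val) & (nn >= 4)
            np.add.at(sums, b[good], val[good])
            np.add.at(counts, b[good], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lo": np.arange(n_bins) * bin_size,
            "bin_hi": np.minimum((np.arange(n_bins) + 1) * bin_size, max_dist),
            "n_pairs": counts,
            "mean_r2": mean,
        }
    )
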