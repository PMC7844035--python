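"""Extended haplotype homozygosity (EHH), its physical-distance integral
(iHH) and the cross-population XP-EHH statistic.

EHH at distance x from a core SNP is the probability that two randomly
drawn haplotypes are identical over every SNP from the core out to x:
EHH(x) = sum_h C(n_h, 2) / C(n, 2), where n_h are the sizes of the groups
of haplotypes identical over that stretch.  Following the cross-population
convention, EHH is computed over *all* haplotypes of a population at each
core (not split by core allele).  iHH is the trapezoidal integral of EHH
over physical distance, both directions, truncated where EHH drops below
a cutoff or an inter-SNP gap exceeds a maximum.  XP-EHH is
ln(iHH_A / iHH_B), standardized genome-wide to mean 0, sd 1; positive
scores mean longer haplotype homozygosity (more recent selection) in
population A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import z_transform
from .variants import GenotypeMatrix, PopulationMap

__all__ = ["EHHProfile", "ehh", "ihh", "xpehh", "top_fraction", "xpehh_window_scores"]

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000


@dataclass
class EHHProfile:
    """EHH decay in one direction from a core SNP.

    ``positions`` are bp offsets from the core (0 first), ``ehh`` the
    corresponding values (1.0 at the core).  ``truncated`` records why the
    profile ended: "cutoff", "gap" or "chrom_end".
    """

    core_index: int
    direction: str  # "upstream" (decreasing pos) or "downstream"
    positions: np.ndarray
    ehh: np.ndarray
    truncated: str


def ehh(
    hap: np.ndarray,
    pos: np.ndarray,
    core_index: int,
    direction: str,
    cutoff: float = 0.0,
    max_gap: int | None = None,
) -> EHHProfile:
    """EHH profile from a core SNP in one direction.

    *hap* is a phased haplotype matrix (n_variants, n_haplotypes) for one
    chromosome; missing alleles (-1) break identity.  With the default
    ``cutoff=0`` the profile runs to the chromosome end (or to the first
    gap exceeding *max_gap* if given).
    """
    if hap.shape[1] < 2:
        raise ValueError("need >= 2 haplotypes")
    if direction not in ("upstream", "downstream"):
        raise ValueError("direction must be 'upstream' or 'downstream'")
    if direction == "downstream":
        order = np.arange(core_index + 1, hap.shape[0])
    else:
        order = np.arange(core_index - 1, -1, -1)
    offsets = [0]
    values = [1.0]
    truncated = "chrom_end"
    prev = pos[core_index]
    n = hap.shape[1]
    denom = n * (n - 1) / 2.0
    g = np.zeros(n, dtype=np.int64)
    for row in order:
        gap = abs(int(pos[row]) - int(prev))
        if max_gap is not None and gap > max_gap:
            truncated = "gap"
            break
        a = hap[row]
        key = g * 2 + a
        miss = a < 0
        if miss.any():
            key = key.copy()
            key[miss] = -(np.flatnonzero(miss) + 1)
        _, g = np.unique(key, return_inverse=True)
        counts = np.bincount(g)
        e = (counts * (counts - 1)).sum() / 2.0 / denom
        offsets.append(abs(int(pos[row]) - int(pos[core_index])))
        values.append(e)
        prev = pos[row]
        if e < cutoff:
            truncated = "cutoff"
            break
    return EHHProfile(
        core_index=core_index,
        direction=direction,
        positions=np.array(offsets),
        ehh=np.array(values),
        truncated=truncated,
    )


def ihh(
    profile: EHHProfile,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
) -> float:
    """Trapezoidal integral of an EHH profile over physical distance.

    Integration stops at the first point where EHH < *cutoff* (that final
    trapezoid is included) and excludes everything beyond an inter-SNP gap
    larger than *max_gap*.
    """
    posn = profile.positions
    e = profile.ehh
    total = 0.0
    for k in range(1, len(posn)):
        gap = posn[k] - posn[k - 1]
        if gap > max_gap:
            break
        total += (e[k] + e[k - 1]) / 2.0 * gap
        if e[k] < cutoff:
            break
    return float(total)


def _ihh_at_core(
    hap: np.ndarray,
    pos: np.ndarray,
    core: int,
    cutoff: float,
    max_gap: int,
) -> float:
    """Both-direction iHH with early truncation (fast path for the scan)."""
    n = hap.shape[1]
    denom = n * (n - 1) / 2.0
    total = 0.0
    for order in (
        range(core + 1, hap.shape[0]),
        range(core - 1, -1, -1),
    ):
        g = np.zeros(n, dtype=np.int64)
        prev_e = 1.0
        prev_pos = int(pos[core])
        for row in order:
            gap = abs(int(pos[row]) - prev_pos)
            if gap > max_gap:
                break
            a = hap[row]
            key = g * 2 + a
            miss = a < 0
            if miss.any():
                key = key.copy()
                key[miss] = -(np.flatnonzero(miss) + 1)
            _, g = np.unique(key, return_inverse=True)
            counts = np.bincount(g)
            e = (counts * (counts - 1)).sum() / 2.0 / denom
            total += (e + prev_e) / 2.0 * gap
            prev_e = e
            prev_pos = int(pos[row])
            if e < cutoff:
                break
    return total


def xpehh(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int = DEFAULT_MAX_GAP,
) -> pd.DataFrame:
    """Genome-wide XP-EHH scan between two populations.

    Returns a DataFrame with chrom, pos, ihh_a, ihh_b, raw
    (= ln(iHH_A/iHH_B)) and norm (genome-wide standardized raw scores).
    Cores where either iHH is zero are undefined (NaN), not errors.
    """
    if not gm.phased:
        raise ValueError(
            "XP-EHH requires phased genotypes; phase the input before scanning"
        )
    ia = popmap.indices(gm, pop_a)
    ib = popmap.indices(gm, pop_b)
    if len(ia) * 2 < 5 or len(ib) * 2 < 5:
        raise ValueError("each population needs at least 5 haplotypes")
    rows = []
    for c in gm.chromosomes:
        m = gm.chrom_mask(c)
        pos = gm.pos[m]
        hap_a = gm.haplotypes(ia)[m]
        hap_b = gm.haplotypes(ib)[m]
        for core in range(len(pos)):
            va = _ihh_at_core(hap_a, pos, core, cutoff, max_gap)
            vb = _ihh_at_core(hap_b, pos, core, cutoff, max_gap)
            raw = np.log(va / vb) if va > 0 and vb > 0 else np.nan
            rows.append((c, int(pos[core]), va, vb, raw))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ihh_a", "ihh_b", "raw"])
    df["norm"] = z_transform(df["raw"].to_numpy())
    return df


def top_fraction(
    result: pd.DataFrame,
    q: float = 0.01,
    side: str = "both",
    mode: str = "empirical",
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Flag the extreme tail of normalized XP-EHH scores.

    ``empirical`` mode selects the top fraction *q* per requested tail
    (``upper``: most positive, ``lower``: most negative, ``both``: q from
    each tail) by rank.  ``pvalue`` mode instead flags two-sided normal
    p <= *p_max*.  Returns a copy of *result* with a boolean ``tail``
    column.
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must lie in (0, 0.5]")
    if side not in ("both", "upper", "lower"):
        raise ValueError(f"unknown side {side!r}")
    out = result.copy()
    norm = out["norm"].to_numpy(dtype=float)
    ok = ~np.isnan(norm)
    flag = np.zeros(len(out), dtype=bool)
    if mode == "pvalue":
        from scipy.stats import norm as normal

        p = 2 * normal.sf(np.abs(norm))
        flag[ok] = p[ok] <= p_max
    elif mode == "empirical":
        n_def = int(ok.sum())
        k = int(round(q * n_def))
        idx = np.flatnonzero(ok)
        order = np.argsort(norm[idx], kind="stable")
        if side in ("upper", "both") and k > 0:
            flag[idx[order[-k:]]] = True
        if side in ("lower", "both") and k > 0:
            flag[idx[order[:k]]] = True
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["tail"] = flag
    return out


def xpehh_window_scores(result: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Lift SNP-level XP-EHH scores to windows.

    Window score = max |norm| within the window; a window is flagged as
    tail if it contains at least one tail SNP (requires a ``tail`` column
    from :func:`top_fraction`).
    """
    out = windows.copy()
    score = np.full(len(windows), np.nan)
    n_snps = np.zeros(len(windows), dtype=np.int64)
    tail = np.zeros(len(windows), dtype=bool)
    has_tail = "tail" in result.columns
    for c in pd.unique(windows["chrom"]):
        wmask = (windows["chrom"] == c).to_numpy()
        sub = result[result["chrom"] == c]
        pos = sub["pos"].to_numpy()
        norm = sub["norm"].to_numpy(dtype=float)
        t = sub["tail"].to_numpy() if has_tail else np.zeros(len(sub), dtype=bool)
        starts = windows.loc[wmask, "start"].to_numpy()
        ends = windows.loc[wmask, "end"].to_numpy()
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        sc = np.full(wmask.sum(), np.nan)
        ns = np.zeros(wmask.sum(), dtype=np.int64)
        tl = np.zeros(wmask.sum(), dtype=bool)
        for k, (l, h) in enumerate(zip(lo, hi)):
            seg = norm[l:h]
            seg = seg[~np.isnan(seg)]
            ns[k] = len(seg)
            if len(seg):
                sc[k] = np.abs(seg).max()
            tl[k] = bool(t[l:h].any())
        score[wmask] = sc
        n_snps[wmask] = ns
        tail[wmask] = tl
    out["n_snps"] = n_snps
    out["score"] = score
    out["tail"] = tail
    return out
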