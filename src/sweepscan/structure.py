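"""Population structure: PCA of the genotype matrix and a neighbor-joining
tree from pairwise allele-sharing p-distances."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

__all__ = ["PCAResult", "pca", "p_distance_matrix", "nj_tree"]


@dataclass
class PCAResult:
    """Sample coordinates on the top-k axes plus eigenvalues and the
    fraction of total variance each axis explains."""

    coords: np.ndarray        # (n_samples, k)
    eigenvalues: np.ndarray   # (k,)
    variance_fraction: np.ndarray
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])],
        )
        df.insert(0, "sample", self.samples)
        return df


def pca(gm: GenotypeMatrix, k: int = 4) -> PCAResult:
    """PCA of alt-allele dosages, smartpca-style.

    Missing dosages are mean-imputed per site; each site is centered and
    scaled by sqrt(2 p (1-p)) with p the sample alt-allele frequency;
    monomorphic sites are dropped.  Coordinates are the projections of the
    samples onto the top-k eigenvectors of the sample covariance matrix.
    """
    if k >= gm.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    d = gm.dosage()  # (V, S)
    mean = np.nanmean(d, axis=1)
    p = mean / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    d = d[poly]
    mean = mean[poly]
    p = p[poly]
    # mean imputation, centering, variance scaling
    d = np.where(np.isnan(d), mean[:, None], d)
    x = (d - mean[:, None]) / np.sqrt(2.0 * p * (1 - p))[:, None]
    x = x.T  # (S, V)
    n = x.shape[0]
    u, s, _ = np.linalg.svd(x / np.sqrt(n - 1), full_matrices=False)
    eigvals = s**2
    total = eigvals.sum()
    coords = u[:, :k] * (s[:k] * np.sqrt(n - 1))
    return PCAResult(
        coords=coords,
        eigenvalues=eigvals[:k],
        variance_fraction=eigvals[:k] / total,
        samples=list(gm.samples),
    )


def p_distance_matrix(gm: GenotypeMatrix, allow_missing_pairs: bool = False) -> pd.DataFrame:
    """Pairwise allele-sharing p-distance between individuals.

    Per co-called site a pair contributes (number of allele differences
    between unordered genotypes)/2: identical genotypes 0, heterozygote vs
    homozygote 0.5, opposite homozygotes 1; the distance is the mean over
    co-called sites.  A pair with zero co-called sites is an error unless
    *allow_missing_pairs* is set (NaN entry).
    """
    d = gm.dosage()  # (V, S) with NaN missing
    S = gm.n_samples
    out = np.zeros((S, S))
    for i in range(S):
        diff = np.abs(d[:, i][:, None] - d[:, i + 1:]) / 2.0
        n = (~np.isnan(diff)).sum(axis=0)
        if (n == 0).any() and not allow_missing_pairs:
            raise ValueError("sample pair with zero co-called sites")
        with np.errstate(invalid="ignore"):
            mean = np.nansum(diff, axis=0) / np.where(n > 0, n, np.nan)
        out[i, i + 1:] = mean
        out[i + 1:, i] = mean
    return pd.DataFrame(out, index=gm.samples, columns=gm.samples)


def nj_tree(dm: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining; returns a newick string.

    Tie-breaks on the Q criterion are deterministic (lexicographically
    smallest label pair).  Negative branch lengths are clamped to zero
    with the deficit transferred to the sister branch, preserving the
    pair's summed length.
    """
    labels = list(dm.index)
    if list(dm.columns) != labels:
        raise ValueError("distance matrix must have matching row/column labels")
    D = dm.to_numpy(dtype=float)
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")

    nodes = [f"{lab}" for lab in labels]  # newick fragment per active node
    names = list(labels)                  # sort keys for tie-breaking
    D = D.copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        merged = f"({nodes[i]}:{vi:.10g},{nodes[j]}:{vj:.10g})"
        merged_name = min(names[i], names[j])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [merged]
        names = [names[k] for k in keep] + [merged_name]

    # three-point formulas for the final star join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    v0 = max(0.0, (d01 + d02 - d12) / 2)
    v1 = max(0.0, (d01 + d12 - d02) / 2)
    v2 = max(0.0, (d02 + d12 - d01) / 2)
    return (
        f"({nodes[0]}:{v0:.10g},{nodes[1]}:{v1:.10g},{nodes[2]}:{v2:.10g});"
    )
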