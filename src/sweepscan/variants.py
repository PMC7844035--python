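"""Genotype containers, VCF/popmap/gene-model I/O, variant filtering and
annotation summaries.

The central container is :class:`GenotypeMatrix`: phased biallelic SNP
genotypes coded as an integer array of shape ``(n_variants, n_samples, 2)``
with 0 = reference allele, 1 = alternate allele and -1 = missing.  All
internal coordinates are 0-based half-open; conversion to/from 1-based VCF
(and GFF3) happens at I/O boundaries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("sweepscan")

__all__ = [
    "GenotypeMatrix",
    "PopulationMap",
    "FilterThresholds",
    "FilterTally",
    "AnnotationSummary",
    "GeneModels",
    "read_vcf",
    "read_popmap",
    "hard_filter",
    "filter_vcf",
    "site_filter",
    "classify_variants",
    "summarize_annotation",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Phased biallelic SNP genotypes for a panel of diploid samples.

    Attributes
    ----------
    chrom : ndarray of str, shape (n_variants,)
    pos : ndarray of int, shape (n_variants,)
        0-based positions, sorted within each chromosome.
    ref, alt : ndarray of str, shape (n_variants,)
    alleles : ndarray of int8, shape (n_variants, n_samples, 2)
        0 = ref, 1 = alt, -1 = missing.
    samples : list of str
    phased : bool
        True only if every genotype in the source was phased.
    chrom_lengths : dict or None
        Chromosome lengths in bp when known (VCF ``##contig`` lines or
        simulation config); used to build sliding windows.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    alleles: np.ndarray
    samples: list[str]
    phased: bool = True
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (variants, samples, 2)")
        if self.alleles.shape[0] != len(self.pos):
            raise ValueError("allele rows do not match number of variants")
        if self.alleles.shape[1] != len(self.samples):
            raise ValueError("allele columns do not match number of samples")
        bad = ~np.isin(self.alleles, (-1, 0, 1))
        if bad.any():
            raise ValueError("allele codes must be in {-1, 0, 1}")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom == chrom

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            alleles=self.alleles[index],
            samples=list(self.samples),
            phased=self.phased,
            chrom_lengths=dict(self.chrom_lengths) if self.chrom_lengths else None,
        )

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in samples], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def haplotypes(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Haplotype matrix of shape (n_variants, 2 * n_selected_samples)."""
        a = self.alleles if sample_idx is None else self.alleles[:, sample_idx, :]
        return a.reshape(a.shape[0], -1)

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0/1/2) with NaN for genotypes with any missing allele."""
        a = self.alleles.astype(float)
        d = a.sum(axis=2)
        d[(self.alleles < 0).any(axis=2)] = np.nan
        return d

    def lengths_or_inferred(self) -> dict[str, int]:
        """Chromosome lengths; fall back to last position + 1 when unknown."""
        if self.chrom_lengths:
            return dict(self.chrom_lengths)
        return {
            c: int(self.pos[self.chrom == c].max()) + 1 for c in self.chromosomes
        }


class PopulationMap:
    """Sample -> population assignment."""

    def __init__(self, mapping: Mapping[str, str]):
        self._map = dict(mapping)
        pops: dict[str, list[str]] = {}
        for s, p in self._map.items():
            pops.setdefault(p, []).append(s)
        self._pops = pops

    def __getitem__(self, sample: str) -> str:
        return self._map[sample]

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def samples(self) -> list[str]:
        return list(self._map)

    @property
    def populations(self) -> list[str]:
        return list(self._pops)

    def samples_in(self, pop: str) -> list[str]:
        if pop not in self._pops:
            raise KeyError(f"unknown population {pop!r}")
        return list(self._pops[pop])

    def indices(self, gm: GenotypeMatrix, pop: str) -> np.ndarray:
        return gm.sample_indices(self.samples_in(pop))

    def items(self):
        return self._map.items()


@dataclass(frozen=True)
class FilterThresholds:
    """GATK-style hard-filter thresholds; a record is removed when a present
    field violates the corresponding inequality."""

    qd_min: float = 10.0
    readpos_ranksum_min: float = -8.0
    fs_max: float = 10.0
    qual_min: float = 30.0
    dp_min: float = 4.0


@dataclass
class FilterTally:
    """Per-criterion removal counts from :func:`hard_filter`."""

    qd: int = 0
    readpos_ranksum: int = 0
    fs: int = 0
    qual: int = 0
    dp: int = 0
    removed: int = 0
    kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "qd": self.qd,
            "readpos_ranksum": self.readpos_ranksum,
            "fs": self.fs,
            "qual": self.qual,
            "dp": self.dp,
            "removed": self.removed,
            "kept": self.kept,
        }


@dataclass
class AnnotationSummary:
    """Arithmetic summary of variant annotation counts.

    Category percentages are computed against the total variant count,
    effect percentages against the exonic count, and the
    non-synonymous/synonymous ratio from the effect counts.  Division by
    zero yields NaN rather than an error.
    """

    category_counts: dict[str, int]
    effect_counts: dict[str, int]
    total: int
    category_pct: dict[str, float]
    effect_pct: dict[str, float]
    ns_s_ratio: float


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

class GeneModels:
    """Gene and exon intervals on 0-based half-open coordinates.

    ``genes`` and ``exons`` are DataFrames with columns
    ``chrom, start, end, name`` (exons carry the parent gene in ``name``).
    Overlapping or unsorted intervals are accepted; classification uses
    interval-union semantics.
    """

    def __init__(self, genes: pd.DataFrame, exons: pd.DataFrame | None = None):
        cols = ["chrom", "start", "end", "name"]
        self.genes = genes[cols].reset_index(drop=True)
        if exons is None:
            exons = genes.iloc[0:0]
        self.exons = exons[cols].reset_index(drop=True)

    @property
    def gene_names(self) -> list[str]:
        return list(self.genes["name"])

    @classmethod
    def from_bed(cls, path) -> "GeneModels":
        """Read a BED4(+2) file.

        Plain BED4 rows are treated as genes.  An optional 5th column may
        mark a row as ``gene`` or ``exon`` and an optional 6th column names
        an exon's parent gene (this is the format ``write_panel`` emits).
        """
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str},
        )
        df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
        if df.shape[1] >= 5 and df[4].isin(["gene", "exon"]).all():
            feature = df[4]
            genes = df[feature == "gene"][["chrom", "start", "end", "name"]]
            exons = df[feature == "exon"][["chrom", "start", "end"]].copy()
            exons["name"] = df.loc[feature == "exon", 5].values if df.shape[1] >= 6 else ""
        else:
            genes = df[["chrom", "start", "end", "name"]]
            exons = None
        return cls(genes, exons)

    @classmethod
    def from_gff3(cls, path) -> "GeneModels":
        """Read gene/exon features from GFF3 (1-based inclusive -> half-open)."""
        import gffutils

        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        rows_g, rows_e = [], []
        for f in db.features_of_type("gene"):
            name = f.attributes.get("Name", f.attributes.get("ID", [f.id]))[0]
            rows_g.append((f.seqid, f.start - 1, f.end, name))
        for f in db.features_of_type("exon"):
            parent = f.attributes.get("Parent", [""])[0]
            rows_e.append((f.seqid, f.start - 1, f.end, parent))
        genes = pd.DataFrame(rows_g, columns=["chrom", "start", "end", "name"])
        exons = pd.DataFrame(rows_e, columns=["chrom", "start", "end", "name"])
        return cls(genes, exons if len(exons) else None)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_popmap(path) -> PopulationMap:
    """Two-column, headerless TSV: sample, population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"], dtype=str)
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate samples in popmap: {dups}")
    return PopulationMap(dict(zip(df["sample"], df["pop"])))


def read_vcf(path, popmap_path=None) -> tuple[GenotypeMatrix, PopulationMap | None]:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and indel records are skipped (count logged).  The
    ``phased`` flag is set only if every non-missing genotype uses ``|``.
    When *popmap_path* is given, every VCF sample must be assigned a
    population.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)

    popmap = None
    if popmap_path is not None:
        popmap = read_popmap(popmap_path)
        missing = [s for s in samples if s not in popmap]
        if missing:
            raise ValueError(f"samples absent from popmap: {missing}")

    lengths: dict[str, int] = {}
    try:
        for name, ln in zip(vcf.seqnames, vcf.seqlens):
            lengths[name] = int(ln)
    except Exception:
        lengths = {}

    chroms, poss, refs, alts, codes = [], [], [], [], []
    n_skipped = 0
    all_phased = True
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            n_skipped += 1
            continue
        gts = np.array(v.genotypes, dtype=np.int64)  # (S, 3): a0, a1, phased
        if gts.shape[1] < 3:
            raise ValueError("malformed genotype field")
        a = gts[:, :2].astype(np.int8)
        a[a < 0] = -1
        called = (gts[:, :2] >= 0).any(axis=1)
        if called.any() and not gts[called, 2].all():
            all_phased = False
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # to 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        codes.append(a)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not poss:
        raise ValueError(f"no biallelic SNPs found in {path}")

    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        alleles=np.stack(codes),
        samples=samples,
        phased=all_phased,
        chrom_lengths=lengths or None,
    )
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm, popmap


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _info_get(record, key):
    info = getattr(record, "INFO", None)
    if info is None:
        return None
    try:
        return info.get(key)
    except AttributeError:
        try:
            return info[key]
        except (KeyError, TypeError):
            return None


def hard_filter(
    records: Iterable,
    thresholds: FilterThresholds = FilterThresholds(),
    strict_missing: bool = False,
) -> tuple[list, FilterTally]:
    """Apply GATK-style hard filters to VCF-like records.

    A record is removed iff a *present* field violates its threshold:
    QD < qd_min, ReadPosRankSum < readpos_ranksum_min, FS > fs_max,
    QUAL < qual_min, or DP < dp_min.  Absent fields do not trigger removal
    unless *strict_missing* is set, in which case a missing field counts as
    a violation of that criterion.  Records may be cyvcf2 variants or any
    objects exposing ``QUAL`` and an ``INFO`` mapping.
    """
    t = thresholds
    tally = FilterTally()
    kept: list = []
    checks = (
        ("qd", "QD", lambda x: x < t.qd_min),
        ("readpos_ranksum", "ReadPosRankSum", lambda x: x < t.readpos_ranksum_min),
        ("fs", "FS", lambda x: x > t.fs_max),
        ("dp", "DP", lambda x: x < t.dp_min),
    )
    for rec in records:
        failed = False
        for attr, key, bad in checks:
            val = _info_get(rec, key)
            if val is None:
                if strict_missing:
                    setattr(tally, attr, getattr(tally, attr) + 1)
                    failed = True
                continue
            if bad(float(val)):
                setattr(tally, attr, getattr(tally, attr) + 1)
                failed = True
        qual = getattr(rec, "QUAL", None)
        if qual is None:
            if strict_missing:
                tally.qual += 1
                failed = True
        elif float(qual) < t.qual_min:
            tally.qual += 1
            failed = True
        if failed:
            tally.removed += 1
        else:
            tally.kept += 1
            kept.append(rec)
    return kept, tally


def filter_vcf(
    path_in,
    path_out,
    thresholds: FilterThresholds = FilterThresholds(),
    strict_missing: bool = False,
) -> FilterTally:
    """Stream a VCF through :func:`hard_filter`, writing kept records."""
    from cyvcf2 import VCF, Writer

    vcf = VCF(str(path_in))
    out = Writer(str(path_out), vcf)
    tally = FilterTally()
    for rec in vcf:
        _, one = hard_filter([rec], thresholds, strict_missing)
        if one.kept:
            out.write_record(rec)
        for f in ("qd", "readpos_ranksum", "fs", "qual", "dp", "removed", "kept"):
            setattr(tally, f, getattr(tally, f) + getattr(one, f))
    out.close()
    return tally


def site_filter(
    gm: GenotypeMatrix, min_call_rate: float = 0.9, min_maf: float = 0.01
) -> GenotypeMatrix:
    """Retain sites with call rate >= *min_call_rate* and pooled minor-allele
    frequency >= *min_maf*."""
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    called = (gm.alleles >= 0).all(axis=2)
    call_rate = called.mean(axis=1)
    alt = np.where(called[:, :, None].repeat(2, axis=2), gm.alleles, 0).sum(axis=(1, 2))
    n_alleles = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        maf = np.fmin(p, 1 - p)
    keep = (call_rate >= min_call_rate) & ~np.isnan(maf) & (maf >= min_maf)
    return gm.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _union_starts_ends(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Merge intervals of a single chromosome into a disjoint sorted union."""
    iv = df.sort_values("start")[["start", "end"]].to_numpy()
    starts, ends = [], []
    for s, e in iv:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def _in_union(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < ends[idx[ok]]
    return res


def classify_variants(gm: GenotypeMatrix, gene_models: GeneModels) -> np.ndarray:
    """Label each variant ``exonic`` / ``intronic`` / ``intergenic``.

    A variant inside any exon is exonic; inside a gene but no exon,
    intronic; otherwise intergenic.  Half-open interval semantics.
    """
    out = np.full(gm.n_variants, "intergenic", dtype=object)
    for c in gm.chromosomes:
        m = gm.chrom_mask(c)
        pos = gm.pos[m]
        gs, ge = _union_starts_ends(gene_models.genes[gene_models.genes["chrom"] == c])
        es, ee = _union_starts_ends(gene_models.exons[gene_models.exons["chrom"] == c])
        in_gene = _in_union(pos, gs, ge)
        in_exon = _in_union(pos, es, ee)
        lab = np.where(in_exon, "exonic", np.where(in_gene, "intronic", "intergenic"))
        out[np.flatnonzero(m)] = lab
    return out


def summarize_annotation(
    category_counts: Mapping[str, int],
    effect_counts: Mapping[str, int] | None = None,
    total: int | None = None,
) -> AnnotationSummary:
    """Compute annotation proportions and the non-synonymous/synonymous ratio.

    Category percentages are relative to *total* (default: sum of category
    counts); effect percentages are relative to the exonic count.  The
    ns/s ratio is ``nonsynonymous / synonymous`` and NaN when the
    synonymous count is zero.
    """
    cats = dict(category_counts)
    effs = dict(effect_counts or {})
    for name, count in list(cats.items()) + list(effs.items()):
        if count < 0:
            raise ValueError(f"negative count for {name!r}")
    if total is None:
        total = sum(cats.values())
    category_pct = {
        k: (100.0 * v / total if total > 0 else float("nan")) for k, v in cats.items()
    }
    exonic = cats.get("exonic", 0)
    effect_pct = {
        k: (100.0 * v / exonic if exonic > 0 else float("nan"))
        for k, v in effs.items()
    }
    nonsyn = effs.get("nonsynonymous", 0)
    syn = effs.get("synonymous", 0)
    ratio = nonsyn / syn if syn > 0 else float("nan")
    return AnnotationSummary(
        category_counts=cats,
        effect_counts=effs,
        total=total,
        category_pct=category_pct,
        effect_pct=effect_pct,
        ns_s_ratio=ratio,
    )
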