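"""Synthetic multi-population diploid panels with known truth.

Populations are simulated under the Balding-Nichols model: for each SNP an
ancestral frequency p is drawn uniformly on [0.05, 0.95] and each
population's frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected
Weir-Cockerham FST relative to the ancestral pool is F.  Haplotypes are
mosaics of founder haplotypes with a per-bp switch probability, which gives
linkage disequilibrium that decays with physical distance; per-site allele
counts are then resampled to a Binomial(2n, q) draw around the population
frequency q so that allele-frequency sampling behaves exactly as under
independent binomial sampling (the property the Weir-Cockerham estimator
corrects for).

Hard selective sweeps and runs of homozygosity can be planted on top of a
panel, and every planted feature is recorded in a truth record so that
downstream scans can be validated against known signal locations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .variants import GenotypeMatrix, PopulationMap

__all__ = [
    "SimConfig",
    "SweepSpec",
    "ROHSpec",
    "TruthRecord",
    "simulate_panel",
    "plant_sweep",
    "plant_roh",
    "write_panel",
]


@dataclass
class SweepSpec:
    """A hard sweep: derived (alt) allele near fixation plus founder-haplotype
    sharing in one population over [start, end)."""

    pop: str
    chrom: str
    start: int
    end: int
    core_pos: int
    derived_freq: float = 0.95
    founder_fraction: float = 0.9

    def validate(self) -> None:
        if not (self.start <= self.core_pos < self.end):
            raise ValueError("core_pos must lie in [start, end)")
        if not (0.5 < self.derived_freq <= 1.0):
            raise ValueError("derived_freq must lie in (0.5, 1]")
        if not (0.0 <= self.founder_fraction <= 1.0):
            raise ValueError("founder_fraction must lie in [0, 1]")


@dataclass
class ROHSpec:
    """A planted homozygous segment for one sample (index within its pop)."""

    pop: str
    sample_index: int
    chrom: str
    start: int
    end: int

    def validate(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("ROH interval must have positive length")


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults emulate a small resequencing panel of three moderately
    differentiated populations: 3 pops x 15 diploid samples, two 10-Mb
    chromosomes at 200 SNPs/Mb, Balding-Nichols F = 0.15, founder mosaics
    with a 1e-5/bp switch rate.
    """

    seed: int = 0
    n_pops: int = 3
    samples_per_pop: int = 15
    chrom_lengths: list[int] = field(default_factory=lambda: [10_000_000, 10_000_000])
    n_snps_per_chrom: int = 2000
    fst_target: float = 0.15
    mosaic_break_rate: float = 1e-5
    n_founders: int = 12
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    roh_specs: list[ROHSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_pops < 1 or self.samples_per_pop < 1:
            raise ValueError("n_pops and samples_per_pop must be positive")
        if self.n_snps_per_chrom < 1 or any(l < 1 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths and SNP counts must be positive")
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must lie in [0, 1)")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        for s in self.sweep_specs:
            s.validate()
        for r in self.roh_specs:
            r.validate()

    @property
    def pop_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_pops)]

    @property
    def chrom_labels(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


@dataclass
class TruthRecord:
    """Planted features and the realized per-locus population frequencies."""

    sweeps: list[SweepSpec] = field(default_factory=list)
    rohs: list[ROHSpec] = field(default_factory=list)
    pop_freqs: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (P, V)
    pop_labels: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "sweeps": [asdict(s) for s in self.sweeps],
            "rohs": [asdict(r) for r in self.rohs],
            "pop_labels": self.pop_labels,
            "pop_freqs": {c: f.round(6).tolist() for c, f in self.pop_freqs.items()},
        }


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

def _mosaic_founder_index(rng, n_hap, pos, rate, n_founders):
    """Founder index per (haplotype, site): piecewise constant with switch
    probability 1 - exp(-rate * gap) at each inter-SNP transition."""
    V = len(pos)
    draws = rng.integers(0, n_founders, size=(n_hap, V))
    if V == 1:
        return draws
    p_switch = 1.0 - np.exp(-rate * np.diff(pos))
    switch = rng.random((n_hap, V - 1)) < p_switch
    new_seg = np.concatenate(
        [np.ones((n_hap, 1), dtype=bool), switch], axis=1
    )
    # forward-fill: index of the most recent segment start
    col = np.arange(V)
    last_start = np.maximum.accumulate(np.where(new_seg, col, -1), axis=1)
    return draws[np.arange(n_hap)[:, None], last_start]


def _match_counts(rng, hap, targets):
    """Flip a minimal random set of alleles per site so that the alt-allele
    count equals the target count.  hap has shape (n_hap, V)."""
    cur = hap.sum(axis=0)
    for j in np.flatnonzero(cur != targets):
        diff = int(targets[j] - cur[j])
        if diff > 0:
            zeros = np.flatnonzero(hap[:, j] == 0)
            pick = rng.choice(zeros, size=diff, replace=False)
            hap[pick, j] = 1
        else:
            ones = np.flatnonzero(hap[:, j] == 1)
            pick = rng.choice(ones, size=-diff, replace=False)
            hap[pick, j] = 0


def simulate_panel(config: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, TruthRecord]:
    """Simulate a phased multi-population panel under the Balding-Nichols
    model with founder-mosaic LD; see the module docstring for the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = config.pop_labels
    chroms = config.chrom_labels
    n_hap = 2 * config.samples_per_pop

    all_chrom, all_pos, all_codes = [], [], []
    truth = TruthRecord(pop_labels=pops)

    for chrom, length in zip(chroms, config.chrom_lengths):
        n = min(config.n_snps_per_chrom, length)
        pos = np.sort(rng.choice(length, size=n, replace=False))
        p_anc = rng.uniform(0.05, 0.95, size=n)
        F = config.fst_target
        freqs = np.empty((config.n_pops, n))
        for i in range(config.n_pops):
            if F == 0:
                freqs[i] = p_anc
            else:
                a = p_anc * (1 - F) / F
                b = (1 - p_anc) * (1 - F) / F
                freqs[i] = rng.beta(a, b)
        truth.pop_freqs[chrom] = freqs

        hap_cols = []
        for i in range(config.n_pops):
            founders = (
                rng.random((config.n_founders, n)) < freqs[i]
            ).astype(np.int8)
            idx = _mosaic_founder_index(
                rng, n_hap, pos, config.mosaic_break_rate, config.n_founders
            )
            hap = founders[idx, np.arange(n)]
            targets = rng.binomial(n_hap, freqs[i])
            _match_counts(rng, hap, targets)
            hap_cols.append(hap.T)  # (V, n_hap)
        hap_all = np.concatenate(hap_cols, axis=1)  # (V, P * n_hap)
        all_chrom.append(np.full(n, chrom, dtype=object))
        all_pos.append(pos)
        all_codes.append(hap_all.reshape(n, -1, 2))

    samples = [f"{p}_s{i + 1}" for p in pops for i in range(config.samples_per_pop)]
    gm = GenotypeMatrix(
        chrom=np.concatenate(all_chrom),
        pos=np.concatenate(all_pos),
        ref=np.full(sum(map(len, all_pos)), "A", dtype=object),
        alt=np.full(sum(map(len, all_pos)), "G", dtype=object),
        alleles=np.concatenate(all_codes, axis=0),
        samples=samples,
        phased=True,
        chrom_lengths=dict(zip(chroms, config.chrom_lengths)),
    )
    popmap = PopulationMap({s: s.rsplit("_", 1)[0] for s in samples})

    for spec in config.sweep_specs:
        plant_sweep(gm, popmap, spec, truth, rng)
    for spec in config.roh_specs:
        plant_roh(gm, popmap, spec, truth)
    return gm, popmap, truth


def plant_sweep(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    spec: SweepSpec,
    truth: TruthRecord | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Plant a hard sweep in place.

    Within [start, end) of the target population, the derived (alt) allele
    frequency at every SNP is raised to at least ``derived_freq``; then a
    fraction ``founder_fraction`` of the haplotypes carrying the derived
    allele at the core SNP is overwritten with the sweep founder haplotype
    (the haplotype carrying the derived allele at every interval SNP).
    Carrier subsets are nested in ``founder_fraction``, so a larger
    fraction never increases allelic diversity over the interval.
    """
    spec.validate()
    if spec.chrom not in gm.chromosomes:
        raise KeyError(f"unknown chromosome {spec.chrom!r}")
    rng = rng or np.random.default_rng(0)
    sidx = popmap.indices(gm, spec.pop)
    mask = gm.chrom_mask(spec.chrom) & (gm.pos >= spec.start) & (gm.pos < spec.end)
    sites = np.flatnonzero(mask)
    if len(sites):
        hap = gm.alleles[np.ix_(sites, sidx)].reshape(len(sites), -1)  # (V, H)
        H = hap.shape[1]
        # raise derived-allele frequency
        target = int(round(spec.derived_freq * H))
        for r in range(len(sites)):
            cur = int((hap[r] == 1).sum())
            need = target - cur
            if need > 0:
                candidates = np.flatnonzero(hap[r] != 1)
                pick = rng.choice(candidates, size=min(need, len(candidates)), replace=False)
                hap[r, pick] = 1
        # overwrite carriers of the core allele with the founder haplotype
        pos_in = gm.pos[sites]
        core_row = int(np.argmin(np.abs(pos_in - spec.core_pos)))
        carriers = np.flatnonzero(hap[core_row] == 1)
        order = rng.permutation(carriers)
        n_copy = int(round(spec.founder_fraction * len(carriers)))
        hap[:, order[:n_copy]] = 1  # founder haplotype = all-derived
        gm.alleles[np.ix_(sites, sidx)] = hap.reshape(len(sites), len(sidx), 2)
    if truth is not None:
        truth.sweeps.append(spec)
    return gm


def plant_roh(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    spec: ROHSpec,
    truth: TruthRecord | None = None,
) -> GenotypeMatrix:
    """Overwrite the sample's second haplotype with its first over
    [start, end), making every covered SNP homozygous."""
    spec.validate()
    samples = popmap.samples_in(spec.pop)
    if not (0 <= spec.sample_index < len(samples)):
        raise IndexError("sample index out of range")
    col = gm.sample_indices([samples[spec.sample_index]])[0]
    mask = gm.chrom_mask(spec.chrom) & (gm.pos >= spec.start) & (gm.pos < spec.end)
    gm.alleles[mask, col, 1] = gm.alleles[mask, col, 0]
    if truth is not None:
        truth.rohs.append(spec)
    return gm


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def synthetic_gene_models(
    chrom_lengths: dict[str, int],
    gene_spacing: int = 100_000,
    gene_length: int = 40_000,
    gene_offset: int = 20_000,
) -> list[tuple[str, int, int, str, str, str]]:
    """Tile synthetic genes (two exons each) over the chromosomes.

    Returns BED-like rows (chrom, start, end, name, feature, parent).
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        i = 0
        for off in range(gene_offset, length - gene_length, gene_spacing):
            name = f"{chrom}_g{i + 1}"
            rows.append((chrom, off, off + gene_length, name, "gene", "."))
            rows.append((chrom, off, off + 10_000, f"{name}_e1", "exon", name))
            rows.append(
                (chrom, off + gene_length - 10_000, off + gene_length, f"{name}_e2", "exon", name)
            )
            i += 1
    return rows


def write_panel(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    truth: TruthRecord | None,
    outdir,
) -> dict[str, Path]:
    """Write a panel as phased VCF + popmap TSV + synthetic gene BED + truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "panel.vcf",
        "popmap": outdir / "popmap.tsv",
        "genes": outdir / "genes.bed",
        "truth": outdir / "truth.json",
    }

    lengths = gm.lengths_or_inferred()
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-simulate\n")
        for c, ln in lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        a = gm.alleles
        for r in range(gm.n_variants):
            gts = "\t".join(
                f"{'.' if a[r, s, 0] < 0 else a[r, s, 0]}|{'.' if a[r, s, 1] < 0 else a[r, s, 1]}"
                for s in range(gm.n_samples)
            )
            fh.write(
                f"{gm.chrom[r]}\t{gm.pos[r] + 1}\t.\t{gm.ref[r]}\t{gm.alt[r]}\t.\tPASS\t.\tGT\t{gts}\n"
            )

    with open(paths["popmap"], "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\t{popmap[s]}\n")

    with open(paths["genes"], "w") as fh:
        for row in synthetic_gene_models(lengths):
            fh.write("\t".join(str(x) for x in row) + "\n")

    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json() if truth is not None else {}, fh, indent=1)
    return paths
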