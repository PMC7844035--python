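"""Candidate-region extraction, gene overlap, gene-set enrichment, and the
end-to-end pipeline driver.

Significant windows from the three scans (ZHp < -4 in a breed,
ZFst > 4 in a breed pair, XP-EHH extreme tail) are merged into candidate
regions, annotated with overlapping genes, intersected across methods, and
tested for gene-set over-representation with an upper-tail hypergeometric
test against the full gene-model background.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, fst, homozygosity, simulate, structure, variants
from .xpehh import xpehh as xpehh_scan, top_fraction, xpehh_window_scores

logger = logging.getLogger("sweepscan")

__all__ = [
    "select_windows",
    "merge_regions",
    "genes_in_regions",
    "overlap_genes",
    "hypergeom_enrich",
    "PipelineConfig",
    "run_pipeline",
]


def select_windows(scores: pd.DataFrame, rule: str, threshold: float | None = None) -> pd.DataFrame:
    """Apply a selection rule to window scores.

    Rules: ``zhp`` keeps windows with zhp < threshold (default -4);
    ``zfst`` keeps zfst > threshold (default 4); ``xpehh`` keeps windows
    flagged in the ``tail`` column.  Output is sorted by genome position.
    """
    if rule == "zhp":
        thr = -4.0 if threshold is None else threshold
        hit = scores[scores["zhp"] < thr]
        score_col = "zhp"
    elif rule == "zfst":
        thr = 4.0 if threshold is None else threshold
        hit = scores[scores["zfst"] > thr]
        score_col = "zfst"
    elif rule == "xpehh":
        hit = scores[scores["tail"].astype(bool)]
        score_col = "score"
    else:
        raise ValueError(f"unknown rule {rule!r}")
    out = hit.sort_values(["chrom", "start"]).reset_index(drop=True)
    out = out.rename(columns={score_col: "score"}) if score_col != "score" else out
    return out


def merge_regions(windows: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Merge overlapping/book-ended windows (gap <= max_gap) into maximal
    regions; the peak score is the most extreme score in the region."""
    if windows.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "peak_score", "n_windows"])
    w = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    has_score = "score" in w.columns
    rows = []
    cur = None
    for _, r in w.iterrows():
        score = float(r["score"]) if has_score and pd.notna(r.get("score")) else np.nan
        if (
            cur is not None
            and r["chrom"] == cur["chrom"]
            and r["start"] - cur["end"] <= max_gap
        ):
            cur["end"] = max(cur["end"], int(r["end"]))
            cur["n_windows"] += 1
            if not np.isnan(score) and (
                np.isnan(cur["peak_score"]) or abs(score) > abs(cur["peak_score"])
            ):
                cur["peak_score"] = score
        else:
            if cur is not None:
                rows.append(cur)
            cur = {
                "chrom": r["chrom"],
                "start": int(r["start"]),
                "end": int(r["end"]),
                "peak_score": score,
                "n_windows": 1,
            }
    rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_score", "n_windows"])


def genes_in_regions(
    regions: pd.DataFrame, gene_models: variants.GeneModels
) -> tuple[list[list[str]], list[str]]:
    """Genes overlapping each region by >= 1 bp (half-open semantics).

    Returns (per-region gene lists, sorted union).
    """
    genes = gene_models.genes
    per_region: list[list[str]] = []
    union: set[str] = set()
    for _, r in regions.iterrows():
        sub = genes[
            (genes["chrom"] == r["chrom"])
            & (genes["start"] < r["end"])
            & (genes["end"] > r["start"])
        ]
        names = sorted(sub["name"])
        per_region.append(names)
        union.update(names)
    return per_region, sorted(union)


def overlap_genes(sets: list[set[str] | list[str]]) -> list[str]:
    """Sorted intersection of >= 2 gene sets."""
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    inter = set(sets[0])
    for s in sets[1:]:
        inter &= set(s)
    return sorted(inter)


def hypergeom_enrich(
    study_genes,
    term_to_genes: dict[str, set[str] | list[str]],
    background,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    With N = |background|, K = |term ∩ background|, n = |study| and k the
    study hits in the term, p = P(X >= k).  Terms with p <= *alpha* are
    flagged; Benjamini-Hochberg adjusted values are reported alongside.
    Study genes absent from the background are an error.
    """
    from scipy.stats import hypergeom
    from statsmodels.stats.multitest import multipletests

    background = set(background)
    study = set(study_genes)
    offenders = sorted(study - background)
    if offenders:
        raise ValueError(f"study genes absent from background: {offenders}")
    N, n = len(background), len(study)
    rows = []
    for term, genes in term_to_genes.items():
        term_bg = set(genes) & background
        K = len(term_bg)
        k = len(term_bg & study)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append((term, K, k, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "K", "k", "n", "N", "p"])
    if len(df):
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p"] <= alpha
    else:
        df["p_bh"] = []
        df["significant"] = []
    return df.sort_values("p").reset_index(drop=True)


def read_gene_sets(path) -> dict[str, list[str]]:
    """TSV: term <tab> comma- or whitespace-separated gene list."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            term, genes = line.rstrip("\n").split("\t", 1)
            out[term] = [g for g in genes.replace(",", " ").split() if g]
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Provide either input paths (vcf/popmap/genes) or a simulation config.
    Every threshold of every stage is named here and recorded in the run
    manifest.
    """

    outdir: str = "sweepscan_out"
    vcf: str | None = None
    popmap: str | None = None
    genes: str | None = None
    gene_sets: str | None = None
    sim: simulate.SimConfig | None = None
    seed: int = 0
    window_size: int = 100_000
    window_step: int = 50_000
    min_snps: int = 10
    min_call_rate: float = 0.9
    min_maf: float = 0.01
    zhp_min: float = -4.0
    zfst_min: float = 4.0
    xpehh_top: float = 0.01
    xpehh_side: str = "both"
    xpehh_cutoff: float = 0.05
    xpehh_max_gap: int = 200_000
    merge_max_gap: int = 0
    roh: homozygosity.ROHParams = field(default_factory=homozygosity.ROHParams)
    ld_max_dist: int = 300_000
    ld_bin_size: int = 5_000
    pca_k: int = 4
    enrich_alpha: float = 0.05
    run_roh: bool = True
    run_ld: bool = True
    run_structure: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        roh = raw.pop("roh", None)
        cfg = cls(**raw)
        if sim is not None:
            sweeps = [simulate.SweepSpec(**s) for s in sim.pop("sweep_specs", [])]
            rohs = [simulate.ROHSpec(**s) for s in sim.pop("roh_specs", [])]
            cfg.sim = simulate.SimConfig(**sim, sweep_specs=sweeps, roh_specs=rohs)
        if roh is not None:
            cfg.roh = homozygosity.ROHParams(**roh)
        return cfg


_current_stage = {"name": "init"}


def _stage(name):
    _current_stage["name"] = name
    logger.info("pipeline stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write every declared output file.

    Stages: load/simulate -> site filter -> diversity -> Hp scan per pop ->
    pairwise FST scans -> XP-EHH per pair -> ROH -> LD decay -> PCA/NJ ->
    region merging -> gene overlap -> enrichment.  Returns a manifest dict
    (also written as JSON) naming every output file and parameter.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    files: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files[name] = str(path)

    try:
        if config.sim is not None:
            _stage("simulate")
            gm, popmap, truth = simulate.simulate_panel(config.sim)
            paths = simulate.write_panel(gm, popmap, truth, out / "panel")
            gene_models = variants.GeneModels.from_bed(paths["genes"])
            files.update({f"panel_{k}": str(v) for k, v in paths.items()})
        else:
            _stage("load")
            if not (config.vcf and config.popmap):
                raise ValueError("need vcf+popmap paths or a sim config")
            gm, popmap = variants.read_vcf(config.vcf, config.popmap)
            if config.genes:
                p = str(config.genes)
                gene_models = (
                    variants.GeneModels.from_gff3(p)
                    if p.endswith((".gff", ".gff3"))
                    else variants.GeneModels.from_bed(p)
                )
            else:
                gene_models = variants.GeneModels(
                    pd.DataFrame(columns=["chrom", "start", "end", "name"])
                )

        _stage("site_filter")
        n_before = gm.n_variants
        gm = variants.site_filter(gm, config.min_call_rate, config.min_maf)
        logger.info("site filter kept %d/%d SNPs", gm.n_variants, n_before)

        windows = diversity.make_windows(
            gm.lengths_or_inferred(), config.window_size, config.window_step
        )
        pops = popmap.populations

        _stage("diversity")
        div = pd.DataFrame([vars(diversity.diversity_stats(gm, popmap, p)) for p in pops])
        save(div, "diversity.tsv")

        _stage("hp_scan")
        gene_sets_by_method: dict[str, list[str]] = {}
        hp_scores = {}
        for p in pops:
            hp = diversity.pooled_heterozygosity(gm, popmap, p, windows, config.min_snps)
            hp_scores[p] = hp
            save(hp, f"hp_{p}.tsv")

        pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
        _stage("fst_scan")
        fst_scores = {}
        for a, b in pairs:
            comp = fst.wc_components(gm, popmap, a, b)
            wf = fst.windowed_fst(comp, windows, config.min_snps)
            fst_scores[(a, b)] = wf
            save(wf, f"fst_{a}_{b}.tsv")

        _stage("xpehh_scan")
        xp_scores = {}
        for a, b in pairs:
            res = xpehh_scan(
                gm, popmap, a, b, config.xpehh_cutoff, config.xpehh_max_gap
            )
            res = top_fraction(res, config.xpehh_top, config.xpehh_side)
            xp_scores[(a, b)] = res
            save(res, f"xpehh_{a}_{b}.tsv")

        if config.run_roh:
            _stage("roh")
            save(homozygosity.detect_roh_all(gm, config.roh), "roh.tsv")
        if config.run_ld:
            _stage("ld")
            for p in pops:
                save(
                    homozygosity.ld_decay(
                        gm, popmap, p, config.ld_max_dist, config.ld_bin_size
                    ),
                    f"ld_{p}.tsv",
                )
        if config.run_structure:
            _stage("structure")
            pr = structure.pca(gm, config.pca_k)
            pcadf = pr.to_frame()
            pcadf.insert(1, "pop", [popmap[s] for s in pcadf["sample"]])
            save(pcadf, "pca.tsv")
            newick = structure.nj_tree(structure.p_distance_matrix(gm))
            (out / "tree.nwk").write_text(newick + "\n")
            files["tree.nwk"] = str(out / "tree.nwk")

        _stage("regions")
        all_regions = []
        for p in pops:
            sel = select_windows(hp_scores[p], "zhp", config.zhp_min)
            reg = merge_regions(sel, config.merge_max_gap)
            reg.insert(0, "method", f"zhp_{p}")
            all_regions.append(reg)
        for (a, b) in pairs:
            sel = select_windows(fst_scores[(a, b)], "zfst", config.zfst_min)
            reg = merge_regions(sel, config.merge_max_gap)
            reg.insert(0, "method", f"zfst_{a}_{b}")
            all_regions.append(reg)
        for (a, b) in pairs:
            wscore = xpehh_window_scores(xp_scores[(a, b)], windows)
            sel = select_windows(wscore, "xpehh")
            reg = merge_regions(sel, config.merge_max_gap)
            reg.insert(0, "method", f"xpehh_{a}_{b}")
            all_regions.append(reg)
        non_empty = [r for r in all_regions if not r.empty]
        if non_empty:
            regions = pd.concat(non_empty, ignore_index=True)
        else:
            regions = pd.DataFrame(
                columns=["method", "chrom", "start", "end", "peak_score", "n_windows"]
            )
        save(regions, "candidate_regions.tsv")
        bed = regions[["chrom", "start", "end", "method"]]
        bed.to_csv(out / "candidate_regions.bed", sep="\t", index=False, header=False)
        files["candidate_regions.bed"] = str(out / "candidate_regions.bed")

        _stage("genes")
        gene_rows = []
        for method in regions["method"].unique():
            sub = regions[regions["method"] == method]
            _, union = genes_in_regions(sub, gene_models)
            gene_sets_by_method[method] = union
            for g in union:
                gene_rows.append((method, g))
        save(pd.DataFrame(gene_rows, columns=["method", "gene"]), "genes_by_method.tsv")

        fst_union = sorted(
            set().union(*(gene_sets_by_method.get(f"zfst_{a}_{b}", []) for a, b in pairs))
        ) if pairs else []
        xp_union = sorted(
            set().union(*(gene_sets_by_method.get(f"xpehh_{a}_{b}", []) for a, b in pairs))
        ) if pairs else []
        shared = (
            overlap_genes([fst_union, xp_union]) if fst_union or xp_union else []
        )
        save(pd.DataFrame({"gene": shared}), "overlap_fst_xpehh_genes.tsv")

        _stage("enrichment")
        if config.gene_sets and shared:
            terms = read_gene_sets(config.gene_sets)
            enr = hypergeom_enrich(
                shared, terms, gene_models.gene_names, config.enrich_alpha
            )
            save(enr, "enrichment.tsv")

        manifest = {
            "elapsed_s": round(time.time() - t0, 2),
            "n_snps": int(gm.n_variants),
            "n_samples": int(gm.n_samples),
            "populations": pops,
            "parameters": {
                k: v
                for k, v in asdict(config).items()
                if not isinstance(v, (dict,)) or k != "sim"
            },
            "files": files,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {_current_stage['name']!r}: {exc}"
        ) from exc
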