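"""End-to-end orchestration: simulate/load -> filter -> scan -> follow-up.

A single config (YAML/JSON-compatible dict) drives every stage with the
scan's standard defaults: 20-kb windows sliding by 5 kb, 5% joint empirical
tails, MAF < 0.05 site filter, FDR 0.05 for enrichment.  Each stage logs
its parameters and record counts, and a machine-readable ``summary.json``
collects per-comparison thresholds, region and gene counts, the shared-
region Venn partition, and follow-up results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import assoc, diversity, enrich, simdata, structure, sweep, vario

log = logging.getLogger(__name__)


@dataclass
class Comparison:
    label: str
    control: str   # ratio numerator (population A)
    case: str      # ratio denominator (population B)
    mode: str = "right"


@dataclass
class PipelineConfig:
    simulate: dict | None = None
    inputs: dict = field(default_factory=dict)
    comparisons: list[Comparison] = field(default_factory=list)
    window: int = diversity.WINDOW_SIZE
    step: int = diversity.WINDOW_STEP
    tail_fraction: float = 0.05
    maf: float = 0.05
    fdr: float = 0.05
    flank: int = 1000
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        comps = [Comparison(**c) for c in raw.pop("comparisons", [])]
        cfg = cls(comparisons=comps, **raw)
        if bool(cfg.simulate) == bool(cfg.inputs):
            raise ValueError("config needs exactly one of 'simulate' or 'inputs'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sim_config(block: dict, seed: int) -> simdata.SimConfig:
    block = dict(block)
    sweeps = tuple(simdata.SweepSpec(**s) for s in block.pop("sweeps", []))
    causal = block.pop("causal", None)
    return simdata.SimConfig(
        sweep_specs=sweeps,
        causal_spec=simdata.CausalSpec(**causal) if causal else None,
        seed=block.pop("seed", seed), **block)


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    pops = pd.read_csv(paths["populations"], sep="\t")
    pop_map = dict(zip(pops["sample_id"], pops["population"]))
    table = vario.read_vcf(paths["vcf"], pop_map)
    genes = vario.read_gff(paths["gff"], flank=cfg.flank) if paths.get("gff") else None
    pheno = (pd.read_csv(paths["phenotypes"], sep="\t")
             if paths.get("phenotypes") else None)
    lengths = None
    if paths.get("fasta"):
        from pyfaidx import Fasta

        fa = Fasta(paths["fasta"])
        lengths = {name: len(fa[name]) for name in fa.keys()}
    return table, genes, pheno, lengths, paths.get("fasta"), paths.get("gene_sets")


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Run every configured stage; returns (and writes) the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logging.getLogger("sweepscan").addHandler(handler)
    summary: dict[str, Any] = {"config": {
        "window": cfg.window, "step": cfg.step, "tail_fraction": cfg.tail_fraction,
        "maf": cfg.maf, "fdr": cfg.fdr, "seed": cfg.seed}}
    try:
        # ---- stage: input -------------------------------------------------
        gmt_path = None
        if cfg.simulate:
            sim_cfg = _sim_config(cfg.simulate, cfg.seed)
            table, truth = simdata.simulate_cohort(sim_cfg)
            fixture = simdata.write_fixture(table, truth, out / "fixture", sim_cfg)
            genes = vario.read_gff(fixture["gff"], flank=cfg.flank)
            pheno = truth.phenotypes
            lengths = dict(sim_cfg.chrom_names_lengths())
            fasta_path = str(fixture["fasta"])
            gmt_path = str(fixture["gmt"])
            summary["simulated"] = {"n_sites": table.n_sites,
                                    "n_samples": table.n_samples,
                                    "causal_sites": truth.causal_sites}
        else:
            table, genes, pheno, lengths, fasta_path, gmt_path = _load_inputs(cfg)
            truth = None
        if lengths is None:
            lengths = {c: int(g["pos"].max()) + cfg.window
                       for c, g in table.sites.groupby("chrom")}
        log.info("input: %d sites x %d samples", table.n_sites, table.n_samples)

        # ---- stage: variant filtering ------------------------------------
        filtered, report = vario.apply_hard_filters(table)
        filtered = vario.maf_filter(filtered, cfg.maf)
        summary["filtering"] = {
            "n_input_sites": report.n_input_sites,
            "n_failed_hard_filter": report.n_failed_sites,
            "n_genotypes_masked": report.n_genotypes_masked,
            "n_after_maf": filtered.n_sites,
            "tstv": vario.tstv_ratio(filtered),
        }
        vario.write_vcf(filtered, out / "filtered.vcf", contig_lengths=lengths)
        if genes is not None:
            _, props = vario.classify_sites(filtered, genes)
            summary["site_classes"] = props.round(4).to_dict()
            if fasta_path:
                _, nss = vario.consequence(filtered, genes, fasta_path)
                summary["consequence"] = {
                    "n_nonsynonymous": nss.n_nonsynonymous,
                    "n_synonymous": nss.n_synonymous,
                    "nonsyn_syn_ratio": (round(nss.ratio, 3)
                                         if nss.n_synonymous else None)}

        # ---- stage: diversity scan + sweep selection ---------------------
        grid = diversity.make_windows(lengths, cfg.window, cfg.step)
        results = []
        summary["comparisons"] = {}
        for comp in cfg.comparisons:
            stats, genome_fst = diversity.comparison_stats(
                filtered, grid, comp.control, comp.case)
            stats.to_csv(out / f"stats_{comp.label}.tsv", sep="\t", index=False)
            selected, thresholds = sweep.select_windows(
                stats, cfg.tail_fraction, comp.mode)
            regions = sweep.merge_regions(selected)
            gene_set: set[str] = set()
            if genes is not None:
                regions, gene_set = sweep.regions_to_genes(regions, genes)
            sweep.write_bed(regions, out / f"regions_{comp.label}.bed")
            res = sweep.ComparisonResult(
                label=comp.label, fst_threshold=thresholds["fst"],
                ratio_threshold_left=thresholds["ratio_left"],
                ratio_threshold_right=thresholds["ratio_right"],
                selected=selected, regions=regions, genes=gene_set)
            results.append(res)
            summary["comparisons"][comp.label] = {
                "genome_fst": genome_fst,
                "fst_threshold": thresholds["fst"],
                "ratio_threshold_left": thresholds["ratio_left"],
                "ratio_threshold_right": thresholds["ratio_right"],
                "n_windows": int(len(stats)),
                "n_selected_windows": int(len(selected)),
                "n_regions": int(len(regions)),
                "n_candidate_genes": len(gene_set),
            }
        if len(results) >= 2:
            shared, shared_genes, venn = sweep.shared_regions(results)
            sweep.write_bed(shared, out / "shared_regions.bed")
            summary["shared"] = {"n_shared_regions": int(len(shared)),
                                 "n_shared_genes": len(shared_genes),
                                 "venn": venn}

        # ---- stage: population structure ---------------------------------
        dm = structure.pairwise_distance(filtered)
        newick = structure.nj_tree(dm)
        (out / "nj_tree.nwk").write_text(newick + "\n")
        coords, explained = structure.pca(filtered, cfg.maf)
        coords.to_csv(out / "pca.tsv", sep="\t")
        summary["structure"] = {
            "pca_explained": [round(float(v), 4) for v in explained[:5]]}

        # ---- stage: association follow-up --------------------------------
        if pheno is not None:
            hits = assoc.snp_association(filtered, pheno)
            hits.to_csv(out / "association.tsv", sep="\t", index=False)
            tested = hits[hits["tested"]]
            if not tested.empty:
                top = tested.loc[tested["p"].idxmin()]
                summary["association"] = {
                    "n_tested": int(len(tested)),
                    "top_snp": {"chrom": str(top["chrom"]), "pos": int(top["pos"]),
                                "p": float(top["p"]), "q": float(top["q"])},
                }
                # LD/haplotype follow-up in a window around the top SNP
                near = filtered.sites.index[
                    (filtered.sites["chrom"] == top["chrom"])
                    & (abs(filtered.sites["pos"] - top["pos"]) <= 10_000)]
                if len(near) >= 2:
                    block = assoc.analyse_block(filtered, list(near)[:8],
                                                seed=cfg.seed)
                    if block is not None:
                        summary["association"]["block"] = {
                            "start": block.start, "end": block.end,
                            "n_snps": len(block.positions),
                            "n_haplotypes": len(block.em.present()),
                        }

        # ---- stage: enrichment -------------------------------------------
        if gmt_path and genes is not None and results and results[0].genes:
            universe = set(genes.gene_ids)
            collection = enrich.read_gmt(gmt_path, universe=universe)
            res = enrich.ora(results[0].genes, collection, fdr=cfg.fdr)
            res.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                "n_pathways": int(len(res)),
                "n_significant": int(res["significant"].sum())}
    except Exception as exc:  # annotate failing stage context and re-raise
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        logging.getLogger("sweepscan").removeHandler(handler)
        handler.close()
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
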