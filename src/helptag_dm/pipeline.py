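"""End-to-end orchestration: simulate -> score -> test -> dmr -> map -> enrich -> expr.

Each stage reads only the outputs of earlier stages, records its seed and
summary counts in a run manifest, and writes plain-text outputs under the
run directory. Comparisons are control-vs-exposed for every exposed
group (Con/UN, Con/ON, Con/Old under the default design).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dmr as dmr_mod
from . import io as io_mod
from .containers import LocusCountTable, MethylationMatrix
from .differential import (direction_enrichment, loci_t_test,
                           permutation_correction, select_candidates)
from .enrichment import compute_bias_weights, enrich_all
from .expression import analyze_expression
from .gene_mapping import build_windows, gene_summary, map_loci
from .scoring_qc import compute_scores, filter_loci, sample_qc
from .synthetic_data import (SimulationConfig, generate_annotation,
                             generate_counts, generate_ct_table,
                             generate_gene_sets, generate_loci)

log = logging.getLogger("helptag_dm")

ALL_STAGES = ["simulate", "score", "test", "dmr", "map", "enrich", "expr"]
STAGE_SEED_OFFSET = {s: 1000 * i for i, s in enumerate(ALL_STAGES)}


@dataclass
class AnalysisConfig:
    """Analysis thresholds, defaulting to the published cutoffs."""

    min_abs_delta: float = 30.0
    max_p: float = 0.005
    n_perm: int = 400
    run_permutation: bool = True
    dmr_min_loci: int = 4
    dmr_max_gap: int = 10_000
    window_upstream: int = 10_000
    window_downstream: int = 10_000
    window_mode: str = "results"
    enrichment_samples: int = 10_000
    enrichment_bins: int = 10
    confidence_threshold_factor: float = 0.5


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = {"simulation": asdict(self.simulation),
             "analysis": asdict(self.analysis),
             "stages": list(self.stages), "seed": self.seed}
        d["simulation"]["groups"] = [list(g) for g in self.simulation.groups]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        sim = d.get("simulation", {})
        if "groups" in sim:
            sim["groups"] = tuple(tuple(g) for g in sim["groups"])
        return cls(
            simulation=SimulationConfig(**sim),
            analysis=AnalysisConfig(**d.get("analysis", {})),
            stages=list(d.get("stages", ALL_STAGES)),
            seed=int(d.get("seed", 0)),
        )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def overlap_summary(candidate_sets: dict[str, set]) -> dict[str, int]:
    """Exact intersection counts for every combination of >= 2 sets."""
    if len(candidate_sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    names = list(candidate_sets)
    out: dict[str, int] = {f"{n}": len(candidate_sets[n]) for n in names}
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(set(candidate_sets[n]) for n in combo))
            out["&".join(combo)] = len(inter)
    return out


def _config_hash(config: PipelineConfig) -> str:
    d = {"simulation": asdict(config.simulation),
         "analysis": asdict(config.analysis),
         "stages": list(config.stages), "seed": config.seed}
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and return the run manifest.

    A stage failure aborts the run with the stage name; outputs of
    completed stages are left in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    ana = config.analysis
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {},
        "stages": {},
        "outputs": {},
    }
    state: dict = {}
    comparisons = [(sim.control_group, g) for g in sim.exposed_groups]

    handlers = {
        "simulate": _stage_simulate, "score": _stage_score,
        "test": _stage_test, "dmr": _stage_dmr, "map": _stage_map,
        "enrich": _stage_enrich, "expr": _stage_expr,
    }
    for stage in config.stages:
        if stage not in handlers:
            raise ValueError(f"unknown stage {stage!r}")
        seed = config.seed + STAGE_SEED_OFFSET[stage]
        manifest["stage_seeds"][stage] = seed
        t0 = time.time()
        log.info("stage %s: starting", stage)
        try:
            info = handlers[stage](state, sim, ana, comparisons, seed, outdir)
        except Exception as exc:  # keep partial outputs, name the stage
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            io_mod.write_json(manifest, outdir / "manifest.json")
            raise StageFailure(stage, exc) from exc
        dt = time.time() - t0
        info["elapsed_s"] = round(dt, 3)
        info["status"] = "ok"
        manifest["stages"][stage] = info
        log.info("stage %s: done in %.2fs", stage, dt)

    if "test" in manifest["stages"] and len(comparisons) >= 2:
        loci_sets = {b: state["candidate_ids"][b] for _, b in comparisons}
        manifest["overlap_loci"] = overlap_summary(loci_sets)
        if "map" in manifest["stages"]:
            gene_sets = {b: state["dm_gene_ids"][b] for _, b in comparisons}
            manifest["overlap_genes"] = overlap_summary(gene_sets)
    io_mod.write_json(manifest, outdir / "manifest.json")
    return manifest


def _stage_simulate(state, sim, ana, comparisons, seed, outdir) -> dict:
    rng = np.random.default_rng(seed)
    loci = generate_loci(sim, rng)
    counts, truth = generate_counts(sim, loci, rng)
    genes = generate_annotation(sim, loci, rng)
    gene_sets = generate_gene_sets(sim, genes, rng)
    ct = generate_ct_table(sim, rng)
    state.update(loci=loci, counts=counts, truth=truth, genes=genes,
                 gene_sets=gene_sets, ct=ct)
    io_mod.write_bed4(loci, outdir / "loci.bed")
    counts.to_tsv(outdir / "counts.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    io_mod.write_gtf(genes, outdir / "genes.gtf")
    io_mod.write_bed12(genes, outdir / "genes.bed12")
    io_mod.write_gmt(gene_sets, outdir / "gene_sets.gmt")
    ct.to_csv(outdir / "ct_table.csv", index=False)
    return {"n_loci": len(loci), "n_samples": len(counts.samples),
            "n_genes": len(genes), "n_truth_rows": len(truth)}


def _stage_score(state, sim, ana, comparisons, seed, outdir) -> dict:
    counts: LocusCountTable = state["counts"]
    matrix = compute_scores(counts)
    flagged = sample_qc(matrix)
    if flagged:
        matrix = matrix.drop_samples(flagged)
    matrix, report = filter_loci(
        matrix, threshold_factor=ana.confidence_threshold_factor)
    state.update(matrix=matrix, flagged_samples=flagged,
                 filter_report=report)
    matrix.to_tsv(outdir / "methylation_matrix.tsv")
    io_mod.write_json(report.to_dict(), outdir / "filter_report.json")
    return {"flagged_samples": flagged, "n_retained_loci": report.n_retained}


def _stage_test(state, sim, ana, comparisons, seed, outdir) -> dict:
    matrix: MethylationMatrix = state["matrix"]
    results, candidate_ids, summaries = {}, {}, {}
    for a, b in comparisons:
        res = loci_t_test(matrix, a, b)
        cands = select_candidates(res, ana.min_abs_delta, ana.max_p)
        odds, fisher_p = direction_enrichment(res)
        entry = {"n_testable": int(res["testable"].sum()),
                 "n_candidates": len(cands),
                 "direction_odds_ratio": odds,
                 "direction_fisher_p": fisher_p}
        if ana.run_permutation:
            corr = permutation_correction(
                matrix, a, b, res, n_perm=ana.n_perm, seed=seed)
            res["corrected_significant"] = res["locus_id"].isin(
                set(corr.corrected.index[corr.corrected]))
            entry["permutation_threshold_p"] = corr.threshold_p
            entry["n_corrected"] = int(corr.corrected.sum())
        results[b] = res
        candidate_ids[b] = set(cands["locus_id"])
        summaries[f"{a}_vs_{b}"] = entry
        res.to_csv(outdir / f"differential_{a}_vs_{b}.tsv",
                   sep="\t", index=False, float_format="%.6g")
    state.update(results=results, candidate_ids=candidate_ids)
    return {"comparisons": summaries}


def _stage_dmr(state, sim, ana, comparisons, seed, outdir) -> dict:
    counts = {}
    state["dmrs"] = {}
    for a, b in comparisons:
        found = dmr_mod.find_dmrs(
            state["results"][b], min_loci=ana.dmr_min_loci,
            max_gap=ana.dmr_max_gap)
        state["dmrs"][b] = found
        dmr_mod.write_bed(found, outdir / f"dmrs_{a}_vs_{b}.bed")
        counts[b] = len(found)
    return {"n_dmrs": counts}


def _stage_map(state, sim, ana, comparisons, seed, outdir) -> dict:
    genes = state["genes"]
    windows = build_windows(genes, ana.window_upstream,
                            ana.window_downstream, ana.window_mode)
    loci = state["matrix"].loci
    assoc = map_loci(loci, windows)
    dm_gene_ids = {}
    for _, b in comparisons:
        summary = gene_summary(assoc, state["candidate_ids"][b], windows)
        dm_gene_ids[b] = set(
            summary.loc[summary["differentially_methylated"], "gene_id"])
        summary.to_csv(outdir / f"gene_summary_{b}.tsv", sep="\t", index=False)
    assoc.to_csv(outdir / "locus_gene_associations.tsv", sep="\t", index=False)
    state.update(windows=windows, assoc=assoc, dm_gene_ids=dm_gene_ids)
    return {"n_associations": len(assoc),
            "n_dm_genes": {b: len(s) for b, s in dm_gene_ids.items()}}


def _stage_enrich(state, sim, ana, comparisons, seed, outdir) -> dict:
    genes = state["genes"]
    site_counts = genes.set_index("gene_id")["n_hpaii_sites"]
    info = {}
    for _, b in comparisons:
        dm = state["dm_gene_ids"][b]
        if not dm:
            info[b] = "no DM genes; skipped"
            continue
        flags = pd.Series({g: g in dm for g in site_counts.index})
        weights = compute_bias_weights(site_counts, flags, ana.enrichment_bins)
        table = enrich_all(state["gene_sets"], sorted(dm), weights,
                           ana.enrichment_samples, seed)
        table.to_csv(outdir / f"enrichment_{b}.tsv", sep="\t", index=False)
        info[b] = {"n_sets": len(table),
                   "min_p_over": float(table["p_over"].min()) if len(table) else None}
    return {"enrichment": info}


def _stage_expr(state, sim, ana, comparisons, seed, outdir) -> dict:
    ct = state["ct"]
    info = {}
    for gene in sim.ct_target_folds:
        res = analyze_expression(ct, gene, sim.ct_reference_gene,
                                 sim.control_group)
        res.group_stats.to_csv(outdir / f"expression_{gene}.tsv",
                               sep="\t", index=False, float_format="%.4g")
        info[gene] = {
            "anova_p": res.anova_p,
            "folds": {r["group"]: round(r["mean_fold"], 3)
                      for _, r in res.group_stats.iterrows()},
        }
        state.setdefault("expression", {})[gene] = res
    return {"expression": info}
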