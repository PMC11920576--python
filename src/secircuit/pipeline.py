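"""End-to-end pipeline: simulate -> call SEs (x2 conditions) -> differential
SE/DEG integration -> key-gene prioritisation -> CRC inference -> enrichment.

One global seed fans out to per-stage seeds through a stage-name hash, so a
stage rerun in isolation reproduces its output.  Each stage writes its
outputs under its own subdirectory and a ``.done`` marker; with
``resume=True`` a stage with an intact marker is skipped unless an upstream
stage reran.  All outputs are plain text with deterministic ordering, so
two runs from one seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import crc as crc_mod
from . import diffse, enrich, prioritize
from .io import (read_deg_table, read_expression_matrix, read_gene_annotation,
                 read_gene_sets, read_motif_library, read_peaks, write_table)
from .se_caller import call_super_enhancers
from .simulate import (SimulationConfig, read_annotation_table,
                       read_ontology_table, simulate_bundle, write_bundle)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters for a full run, with the standard field defaults
    (stitch 12,500 bp, TSS exclusion 2,500 bp, q 0.05, top-3, FIMO-style
    p 1e-4, 3 motif instances, 500 trees)."""

    seed: int = 0
    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500
    q_max: float = 0.05
    lfc_min: float = 0.0
    top_k: int = 3
    p_threshold: float = 1e-4
    min_instances: int = 3
    ntree_max: int = 500
    simulate: dict = field(default_factory=dict)   # SimulationConfig overrides

    def __post_init__(self) -> None:
        if self.stitch_distance < 0:
            raise ValueError("stitch_distance must be >= 0")
        if self.tss_exclusion < 0:
            raise ValueError("tss_exclusion must be >= 0")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must be in (0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.min_instances < 1:
            raise ValueError("min_instances must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.ntree_max < 1:
            raise ValueError("ntree_max must be >= 1")
        unknown = set(self.simulate) - {f.name for f in fields(SimulationConfig)}
        if unknown:
            raise ValueError(f"unknown simulate key(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)

    def sim_config(self) -> SimulationConfig:
        over = dict(self.simulate)
        over.setdefault("seed", self.stage_seed("simulate"))
        if "clique_tfs" in over:
            over["clique_tfs"] = tuple(over["clique_tfs"])
        return SimulationConfig(**over)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


class PipelineRun:
    """Stage driver with resume support."""

    def __init__(self, config: PipelineConfig, outdir: str | Path,
                 resume: bool = False):
        self.config = config
        self.outdir = Path(outdir)
        self.resume = resume
        self._upstream_ran = False
        self.summary: dict[str, object] = {"seed": config.seed}

    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _should_run(self, stage: str) -> bool:
        marker = self.outdir / stage / ".done"
        if self.resume and marker.exists() and not self._upstream_ran:
            logger.info("stage %s: resume, skipping", stage)
            return False
        self._upstream_ran = True
        return True

    def _finish(self, stage: str) -> None:
        (self.outdir / stage / ".done").touch()

    # -- stages -----------------------------------------------------------

    def stage_simulate(self) -> None:
        d = self._stage_dir("simulate")
        if self._should_run("simulate"):
            bundle = simulate_bundle(self.config.sim_config())
            write_bundle(bundle, d)
            self._finish("simulate")
        manifest = json.loads((d / "manifest.json").read_text())
        self.summary["simulate"] = {
            "n_genes": len(manifest["roles"]["gene_ids"]),
            "planted_se_model": len(manifest["roles"]["model_se_genes"]),
            "planted_se_ea": len(manifest["roles"]["ea_se_genes"]),
        }

    def stage_call_se(self) -> None:
        d = self._stage_dir("call_se")
        sim = self.outdir / "simulate"
        if self._should_run("call_se"):
            genes = read_gene_annotation(sim / "genes.tsv")
            for cond in ("model", "ea"):
                peaks = read_peaks(sim / f"peaks_{cond}.bed",
                                   dialect="bed6+signal")
                table, cutoff, ranked, _assign = call_super_enhancers(
                    peaks, genes, self.config.stitch_distance,
                    self.config.tss_exclusion)
                table.to_csv(d / f"ranked_{cond}.tsv", sep="\t", index=False,
                             float_format="%.10g")
                se = table[table["is_super"]]
                se[["chrom", "start", "end", "gene_id"]].to_csv(
                    d / f"se_{cond}.bed", sep="\t", index=False, header=False)
                rows = [(ranked.region_id(i), c.chrom, c.start, c.end, ci)
                        for i, e in enumerate(ranked.entries)
                        if bool(table["is_super"].iloc[i])
                        for ci, c in enumerate(e.constituents)]
                pd.DataFrame(rows, columns=["se_id", "chrom", "start", "end",
                                            "constituent"]).to_csv(
                    d / f"se_constituents_{cond}.tsv", sep="\t", index=False)
                _write_json({"cutoff_score": cutoff.cutoff_score,
                             "cutoff_index": cutoff.cutoff_index,
                             "n_super": cutoff.n_super,
                             "degenerate": cutoff.degenerate},
                            d / f"cutoff_{cond}.json")
            self._finish("call_se")
        counts = {}
        for cond in ("model", "ea"):
            cut = json.loads((d / f"cutoff_{cond}.json").read_text())
            counts[cond] = cut["n_super"]
        self.summary["call_se"] = {"n_super": counts}

    def _se_genes(self, cond: str) -> frozenset[str]:
        t = pd.read_csv(self.outdir / "call_se" / f"ranked_{cond}.tsv",
                        sep="\t")
        return frozenset(g for g in t.loc[t["is_super"], "gene_id"]
                         if isinstance(g, str) and g)

    def stage_diff_se(self) -> None:
        d = self._stage_dir("diff_se")
        if self._should_run("diff_se"):
            diff = diffse.diff_se_genes(self._se_genes("model"),
                                        self._se_genes("ea"))
            degs = read_deg_table(self.outdir / "simulate" / "deg.tsv")
            deg_sets = diffse.filter_degs(degs, self.config.q_max,
                                          self.config.lfc_min)
            lost_up = diffse.intersect_candidates(diff, deg_sets,
                                                  "lost_up_model")
            gained_up = diffse.intersect_candidates(diff, deg_sets,
                                                    "gained_up_ea")
            _write_json({
                "lost": len(diff.lost_after_ea),
                "gained": len(diff.gained_after_ea),
                "shared": len(diff.shared),
                "up_model": len(deg_sets.up),
                "up_after_ea": len(deg_sets.down),
                "candidates_lost_up_model": len(lost_up.genes),
                "candidates_gained_up_ea": len(gained_up.genes),
            }, d / "venn.json")
            write_table(pd.DataFrame({"gene_id": sorted(lost_up.genes)}),
                        d / "candidates.tsv")
            self._finish("diff_se")
        self.summary["diff_se"] = json.loads((d / "venn.json").read_text())

    def stage_prioritize(self) -> None:
        d = self._stage_dir("prioritize")
        sim = self.outdir / "simulate"
        if self._should_run("prioritize"):
            cand = pd.read_csv(self.outdir / "diff_se" / "candidates.tsv",
                               sep="\t")["gene_id"].tolist()
            expr = read_expression_matrix(sim / "expression.tsv")
            expr = expr.loc[[g for g in expr.index if g in set(cand)]]
            groups = pd.read_csv(sim / "sample_groups.tsv", sep="\t")
            labels = [dict(zip(groups["sample"], groups["group"]))[s]
                      for s in expr.columns]
            seed = self.config.stage_seed("prioritize")
            sel = prioritize.select_ntree(expr, labels,
                                          self.config.ntree_max, seed)
            pd.DataFrame({"ntree": np.arange(1, len(sel.error_by_ntree) + 1),
                          "oob_error": sel.error_by_ntree}).to_csv(
                d / "error_curve.tsv", sep="\t", index=False,
                float_format="%.10g")
            rf = prioritize.rank_genes_gini(expr, labels, sel.chosen_ntree,
                                            seed)
            rf.mdg.rename_axis("gene_id").reset_index().to_csv(
                d / "importance.tsv", sep="\t", index=False,
                float_format="%.10g")
            dag = read_ontology_table(sim / "ontology.tsv")
            ann = read_annotation_table(sim / "annotations.tsv")
            fr = prioritize.friends_rank(
                {g: ann.get(g, []) for g in cand}, dag)
            pd.DataFrame(fr.matrix, index=fr.genes, columns=fr.genes
                         ).to_csv(d / "similarity.tsv", sep="\t",
                                  float_format="%.10g")
            fr.mean_similarity.rename_axis("gene_id").reset_index().to_csv(
                d / "friends.tsv", sep="\t", index=False,
                float_format="%.10g")
            core = prioritize.core_gene_intersection(rf, fr,
                                                     self.config.top_k)
            _write_json({"chosen_ntree": sel.chosen_ntree,
                         "rf_top": rf.top(self.config.top_k),
                         "friends_top": fr.top(self.config.top_k),
                         "core_genes": sorted(core)}, d / "core_genes.json")
            self._finish("prioritize")
        self.summary["prioritize"] = json.loads(
            (d / "core_genes.json").read_text())

    def stage_crc(self) -> None:
        d = self._stage_dir("crc")
        sim = self.outdir / "simulate"
        if self._should_run("crc"):
            genes = read_gene_annotation(sim / "genes.tsv")
            pwms = read_motif_library(sim / "motifs.jaspar", "jaspar")
            se = pd.read_csv(self.outdir / "call_se" / "ranked_model.tsv",
                             sep="\t")
            se = se[se["is_super"]]
            assignment = {
                f"{r.chrom}:{r.start}-{r.end}": r.gene_id
                for r in se.itertuples(index=False)
                if isinstance(r.gene_id, str) and r.gene_id}
            tf_ses = crc_mod.identify_se_tfs(assignment, genes, pwms)
            cons = pd.read_csv(
                self.outdir / "call_se" / "se_constituents_model.tsv",
                sep="\t")
            wanted = {se_id for ses in tf_ses.values() for se_id in ses}
            fasta = Fasta(str(sim / "genome.fa"))
            seqs: dict[str, list[str]] = {}
            for r in cons.itertuples(index=False):
                if r.se_id in wanted:
                    seqs.setdefault(r.se_id, []).append(
                        str(fasta[r.chrom][r.start:r.end]).upper())
            tf_pwms = [p for p in pwms if p.tf_name in tf_ses]
            hits = crc_mod.scan_motifs(seqs, tf_pwms,
                                       self.config.p_threshold)
            write_table(crc_mod.hits_table(hits), d / "hits.tsv",
                        ["tf", "se_id", "constituent", "offset", "strand"])
            selfreg = crc_mod.detect_self_regulating(
                tf_ses, hits, self.config.min_instances)
            graph = crc_mod.build_tf_graph(selfreg, hits,
                                           self.config.min_instances)
            write_table(graph.degree_table(), d / "degrees.tsv", "tf")
            pd.DataFrame(sorted(graph.edges), columns=["from", "to"]).to_csv(
                d / "edges.tsv", sep="\t", index=False)
            circuits = crc_mod.enumerate_circuits(graph)
            scored, rep = crc_mod.score_circuits(circuits)
            pd.DataFrame(
                [(",".join(c.members), len(c.members), c.score)
                 for c in scored],
                columns=["members", "size", "score"]).to_csv(
                d / "circuits.tsv", sep="\t", index=False,
                float_format="%.10g")
            _write_json({
                "self_regulating": [t.tf_name for t in selfreg],
                "n_circuits": len(scored),
                "representative": list(rep.members) if rep else [],
                "representative_score": rep.score if rep else None,
            }, d / "crc.json")
            self._finish("crc")
        self.summary["crc"] = json.loads((d / "crc.json").read_text())

    def stage_enrich(self) -> None:
        d = self._stage_dir("enrich")
        sim = self.outdir / "simulate"
        if self._should_run("enrich"):
            cand = pd.read_csv(self.outdir / "diff_se" / "candidates.tsv",
                               sep="\t")["gene_id"].tolist()
            sets = read_gene_sets(sim / "gene_sets.gmt")
            genes = read_gene_annotation(sim / "genes.tsv")
            universe = {g.gene_id for g in genes}
            res = enrich.ora_test(cand, sets, universe)
            res.to_csv(d / "enrichment.tsv", sep="\t", index=False,
                       float_format="%.10g")
            self._finish("enrich")
        res = pd.read_csv(d / "enrichment.tsv", sep="\t")
        self.summary["enrich"] = {
            "n_sets_tested": int(len(res)),
            "n_significant": int(res["significant"].sum()) if len(res) else 0,
        }


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 resume: bool = False) -> dict:
    """Run all stages in dependency order; returns the run manifest.

    A failing stage aborts with its name; outputs of completed stages are
    left intact.
    """
    run = PipelineRun(config, outdir, resume=resume)
    stage_fns = [
        ("simulate", run.stage_simulate),
        ("call_se", run.stage_call_se),
        ("diff_se", run.stage_diff_se),
        ("prioritize", run.stage_prioritize),
        ("crc", run.stage_crc),
        ("enrich", run.stage_enrich),
    ]
    for name, fn in stage_fns:
        logger.info("stage %s (seed %d)", name, config.stage_seed(name))
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest = {"parameters": asdict(config), "summary": run.summary}
    _write_json(manifest, Path(outdir) / "run_manifest.json")
    return manifest
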