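"""End-to-end orchestration: generate -> effects -> prioritize ->
time-machine validation -> pathways -> screen summary.

Stages communicate only through files under the run's output
directory, so any stage can be rerun from its inputs. A single global
seed fans out to per-stage seeds by stable hashing, and the run
manifest records every output with a checksum: identical config + seed
reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import effect_stats, io, synthetic_data, target_prioritization as tp
from . import pathway_dysregulation as pw
from . import time_machine as tm
from .datatypes import StudyBundle
from .errors import TargetscoutError

__all__ = ["RunConfig", "run_pipeline", "report_tables", "StageError"]

STAGES = ("generate", "effects", "prioritize", "timemachine", "pathways", "screen")


class StageError(TargetscoutError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    study: synthetic_data.StudyConfig | None = None
    filters: tp.FilterConfig = field(default_factory=tp.FilterConfig)
    criteria: pw.DysregulationCriteria = field(
        default_factory=pw.DysregulationCriteria
    )
    cutoff_year: int = 2015
    time_machine_k: int = 50
    similarity_threshold: float = 0.35
    similarity_coefficient: str = "jaccard"
    min_cluster: int = 4


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) by stable hashing."""
    digest = hashlib.sha256(f"{seed}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}

    study_cfg = cfg.study or synthetic_data.StudyConfig(
        seed=stage_seed(cfg.seed, "generate")
    )

    bundle: StudyBundle | None = None
    try:
        bundle = synthetic_data.generate_study(study_cfg)
        paths = io.write_bundle(bundle, outdir / "bundle")
        manifest["stages"]["generate"] = {"seed": study_cfg.seed, "outputs": paths}
    except Exception as exc:  # noqa: BLE001 - stage isolation boundary
        raise StageError("generate", exc) from exc

    try:
        eff_dir = outdir / "effects"
        eff_dir.mkdir(exist_ok=True)
        effects = []
        eff_paths = {}
        for i, comp in enumerate(bundle.comparisons):
            eff = effect_stats.compute_effects(comp)
            path = eff_dir / f"effects_{i:02d}.tsv"
            effect_stats.write_effects(eff, path)
            effects.append(eff)
            eff_paths[f"effects_{i:02d}"] = str(path)
        manifest["stages"]["effects"] = {"outputs": eff_paths}
    except Exception as exc:
        raise StageError("effects", exc) from exc

    try:
        pri_dir = outdir / "prioritize"
        pri_dir.mkdir(exist_ok=True)
        groups = tp.build_groups(bundle.comparisons)
        comp_index = {id(c): i for i, c in enumerate(bundle.comparisons)}
        for g in groups:
            g.effects = [effects[comp_index[id(c)]] for c in g.comparisons]
        top_lists = {}
        pri_paths = {}
        for g in groups:
            omics = tp.group_omics_scores(g)
            table = bundle.score_tables.join(omics, how="left").fillna(0.0)
            meta = tp.metascore(
                table, cfg.filters.enabled_families, weights=None
            )
            filtered = tp.apply_filters(meta, bundle.annotations, cfg.filters)
            top_lists[g.group_id] = filtered
            rank_path = pri_dir / f"ranking_{g.group_id}.tsv"
            meta.rename("metascore").to_frame().to_csv(
                rank_path, sep="\t", index_label="gene"
            )
            pri_paths[f"ranking_{g.group_id}"] = str(rank_path)
        candidates = tp.select_candidates(
            top_lists, groups, bundle.annotations, cfg.filters
        )
        cand_path = pri_dir / "candidates.tsv"
        tp.candidates_to_frame(candidates).to_csv(cand_path, sep="\t", index=False)
        pri_paths["candidates"] = str(cand_path)
        manifest["stages"]["prioritize"] = {
            "outputs": pri_paths,
            "n_groups": len(groups),
        }
    except Exception as exc:
        raise StageError("prioritize", exc) from exc

    try:
        _, novel = tm.split_chronology(bundle.chronology, cfg.cutoff_year)
        reports = {}
        for g in groups:
            omics = tp.group_omics_scores(g)
            ranking = list(omics.sort_values(ascending=False).index)
            k = min(cfg.time_machine_k, len(ranking))
            res = tm.evaluate_ranking(ranking, novel, k)
            reports[g.group_id] = {
                "cutoff": cfg.cutoff_year,
                "k": k,
                "counts": vars(res["counts"]),
                "elfc": res["elfc"],
                "hgpv": res["hgpv"],
            }
        tm_path = outdir / "timemachine.json"
        tm_path.write_text(json.dumps(reports, indent=2, sort_keys=True))
        manifest["stages"]["timemachine"] = {"outputs": {"report": str(tm_path)}}
    except Exception as exc:
        raise StageError("timemachine", exc) from exc

    try:
        pw_dir = outdir / "pathways"
        pw_dir.mkdir(exist_ok=True)
        pw_paths = {}
        all_calls = []
        for g in groups:
            eff_by_comp = {
                f"{g.group_id}_{j}": e for j, e in enumerate(g.effects)
            }
            scores = pw.score_pathways(eff_by_comp, bundle.pathway_db)
            calls = pw.call_dysregulated(scores, g.group_id, cfg.criteria)
            all_calls.extend(calls)
            calls_path = pw_dir / f"calls_{g.group_id}.tsv"
            pd.DataFrame(
                [(c.pathway, c.direction, c.group_id) for c in calls],
                columns=["pathway", "direction", "group"],
            ).to_csv(calls_path, sep="\t", index=False)
            pw_paths[f"calls_{g.group_id}"] = str(calls_path)
            if calls:
                report = pw.enrichment_report(calls, bundle.pathway_db)
                rep_path = pw_dir / f"enrichment_{g.group_id}.tsv"
                report.to_csv(rep_path, sep="\t", index=False)
                pw_paths[f"enrichment_{g.group_id}"] = str(rep_path)
        graph = pw.similarity_network(
            all_calls,
            bundle.pathway_db.pathways,
            threshold=cfg.similarity_threshold,
            coefficient=cfg.similarity_coefficient,
        )
        net_paths = io.write_network(graph, pw_dir / "network")
        pw_paths["network_graphml"] = str(net_paths[0])
        pw_paths["network_edges"] = str(net_paths[1])
        manifest["stages"]["pathways"] = {
            "outputs": pw_paths,
            "n_calls": len(all_calls),
            "n_reported_clusters": len(
                pw.reported_clusters(graph, cfg.min_cluster)
            ),
        }
    except Exception as exc:
        raise StageError("pathways", exc) from exc

    try:
        from .fly_screen import summarize

        cand_frame = pd.read_csv(cand_path, sep="\t")
        genes = sorted(set(cand_frame["gene"])) or sorted(
            {t.gene for t in study_cfg.planted_targets}
        )
        records = synthetic_data.generate_screen_table(
            genes, seed=stage_seed(cfg.seed, "screen")
        )
        summary = summarize(records)
        screen_path = outdir / "screen_summary.json"
        screen_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["stages"]["screen"] = {"outputs": {"summary": str(screen_path)}}
    except Exception as exc:
        raise StageError("screen", exc) from exc

    for stage, info in manifest["stages"].items():
        for name, path in info.get("outputs", {}).items():
            manifest["outputs"][f"{stage}/{name}"] = io.sha256_file(path)

    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def report_tables(manifest: dict, outdir=None) -> dict:
    """Render human-readable report tables from a completed run.

    Returns the candidate table, per-group enrichment tables and the
    screen summary; writes them under ``outdir`` when given.
    """
    cand_path = manifest["stages"]["prioritize"]["outputs"]["candidates"]
    candidates = pd.read_csv(cand_path, sep="\t")
    enrichment = {}
    for name, path in manifest["stages"]["pathways"]["outputs"].items():
        if name.startswith("enrichment_"):
            enrichment[name.removeprefix("enrichment_")] = pd.read_csv(path, sep="\t")
    screen = json.loads(
        Path(manifest["stages"]["screen"]["outputs"]["summary"]).read_text()
    )
    report = {
        "n_candidates": int(len(candidates)),
        "by_category": candidates["category"].value_counts().to_dict()
        if len(candidates)
        else {},
        "screen": screen,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        for gid, tab in enrichment.items():
            tab.to_csv(outdir / f"enrichment_{gid}.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return {"candidates": candidates, "enrichment": enrichment, "report": report}
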