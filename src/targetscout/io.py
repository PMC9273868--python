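"""Reading and writing the pipeline's on-disk formats.

Everything is plain text: expression matrices as TSV (genes as rows,
header of sample ids), sample sheets and metadata as TSV, gene sets as
GMT, networks as GraphML plus an edge-list TSV. Stages communicate
only through these files, so each stage can be rerun independently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import ComparisonDataset, GeneAnnotations, StudyBundle, TargetChronology
from .pathway_dysregulation import PathwayCollection, load_gmt, load_hierarchy

__all__ = [
    "write_bundle",
    "read_comparisons",
    "read_bundle",
    "write_network",
    "sha256_file",
]


def write_comparison(comp: ComparisonDataset, prefix: Path) -> list[Path]:
    matrix_path = prefix.with_suffix(".matrix.tsv")
    sheet_path = prefix.with_suffix(".samples.tsv")
    comp.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample_id": list(comp.matrix.columns),
         "group": [comp.labels[s] for s in comp.matrix.columns]}
    ).to_csv(sheet_path, sep="\t", index=False)
    return [matrix_path, sheet_path]


def write_bundle(bundle: StudyBundle, outdir) -> dict:
    """Write every bundle component under ``outdir``; returns a manifest
    fragment mapping logical names to paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    meta_rows = []
    for i, comp in enumerate(bundle.comparisons):
        prefix = outdir / f"comparison_{i:02d}"
        written = write_comparison(comp, prefix)
        paths[f"comparison_{i:02d}_matrix"] = str(written[0])
        paths[f"comparison_{i:02d}_samples"] = str(written[1])
        meta_rows.append(
            {
                "index": i,
                "group_id": comp.group_id,
                "subtype": comp.subtype,
                "modality": comp.modality,
                "source_name": comp.source_name,
                "n_case": len(comp.case_samples),
                "n_control": len(comp.control_samples),
            }
        )
    meta_path = outdir / "comparisons.tsv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    paths["comparisons_metadata"] = str(meta_path)

    ann_path = outdir / "annotations.tsv"
    bundle.annotations.table.to_csv(ann_path, sep="\t", index_label="gene")
    paths["annotations"] = str(ann_path)

    scores_path = outdir / "score_tables.tsv"
    bundle.score_tables.to_csv(scores_path, sep="\t", index_label="gene")
    paths["score_tables"] = str(scores_path)

    chron_path = outdir / "chronology.tsv"
    bundle.chronology.table.to_csv(chron_path, sep="\t", index=False)
    paths["chronology"] = str(chron_path)

    gmt_path = outdir / "pathways.gmt"
    with open(gmt_path, "w") as fh:
        for pid in sorted(bundle.pathway_db.pathways):
            genes = "\t".join(sorted(bundle.pathway_db.pathways[pid]))
            fh.write(f"{pid}\tsynthetic\t{genes}\n")
    paths["pathways_gmt"] = str(gmt_path)

    hier_path = outdir / "hierarchy.tsv"
    pd.DataFrame(
        sorted(bundle.pathway_db.hierarchy.items()),
        columns=["pathway_id", "process_name"],
    ).to_csv(hier_path, sep="\t", index=False)
    paths["hierarchy"] = str(hier_path)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    paths["truth"] = str(truth_path)
    return paths


def read_comparisons(bundle_dir) -> list[ComparisonDataset]:
    bundle_dir = Path(bundle_dir)
    meta = pd.read_csv(bundle_dir / "comparisons.tsv", sep="\t")
    comps = []
    for _, row in meta.iterrows():
        i = int(row["index"])
        matrix = pd.read_csv(
            bundle_dir / f"comparison_{i:02d}.matrix.tsv", sep="\t", index_col="gene"
        )
        sheet = pd.read_csv(bundle_dir / f"comparison_{i:02d}.samples.tsv", sep="\t")
        comps.append(
            ComparisonDataset(
                matrix=matrix,
                labels=dict(zip(sheet["sample_id"], sheet["group"])),
                subtype=row["subtype"],
                modality=row["modality"],
                group_id=row["group_id"],
                source_name=str(row["source_name"]),
            )
        )
    return comps


def read_bundle(bundle_dir) -> StudyBundle:
    bundle_dir = Path(bundle_dir)
    ann = pd.read_csv(bundle_dir / "annotations.tsv", sep="\t", index_col="gene")
    ann["druggable_class"] = ann["druggable_class"].fillna("")
    truth_path = bundle_dir / "truth.json"
    return StudyBundle(
        comparisons=read_comparisons(bundle_dir),
        annotations=GeneAnnotations(ann),
        score_tables=pd.read_csv(
            bundle_dir / "score_tables.tsv", sep="\t", index_col="gene"
        ),
        chronology=TargetChronology(
            pd.read_csv(bundle_dir / "chronology.tsv", sep="\t")
        ),
        pathway_db=PathwayCollection(
            pathways=load_gmt(bundle_dir / "pathways.gmt"),
            hierarchy=load_hierarchy(bundle_dir / "hierarchy.tsv"),
        ),
        truth=json.loads(truth_path.read_text()) if truth_path.exists() else {},
    )


def write_network(graph: nx.Graph, prefix: Path) -> list[Path]:
    """Write a similarity network as GraphML plus an edge-list TSV."""
    graphml = prefix.with_suffix(".graphml")
    edges = prefix.with_suffix(".edges.tsv")
    nx.write_graphml(graph, graphml)
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1.0)}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        edges, sep="\t", index=False
    )
    return [graphml, edges]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
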