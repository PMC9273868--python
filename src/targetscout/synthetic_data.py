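"""Synthetic study bundles with planted, recoverable truth.

The generator emulates the structure of the real study design — twelve
CNS case-control comparisons (five fALS, seven sALS) and four
patient-derived motor-neuron (diMN) comparisons (transcriptomic and
proteomic, each split by subtype), with the published per-comparison
arm sizes — without touching any real data. Expression values are
additive on the log2 scale: a per-gene baseline shared across
comparisons, plus a planted case-arm effect where a target is
penetrant, plus Gaussian noise. Planted pathways shift their member
genes coherently (direction x magnitude) in every comparison so the
dysregulation caller has a recoverable ground truth. Proteomic
matrices use the same generator; only the default noise level differs.

Everything is a pure function of the configuration (including its
seed): the same config yields byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import (
    ComparisonDataset,
    GeneAnnotations,
    StudyBundle,
    TargetChronology,
)
from .errors import ConfigurationError, DataError
from .pathway_dysregulation import PathwayCollection

__all__ = [
    "PlantedTarget",
    "PlantedPathway",
    "ComparisonSpec",
    "StudyConfig",
    "generate_study",
    "generate_chronology",
    "generate_screen_table",
    "default_comparison_specs",
    "load_paper_fixtures",
    "load_comparison_metadata",
    "load_candidate_table",
    "cohort_summary",
]

DRUGGABLE_CLASSES = (
    "GPCR",
    "Ion channel",
    "Kinase",
    "Nuclear receptor",
    "Enzyme",
    "Transporter",
)

#: Default log2-scale noise standard deviations per modality. SWATH-MS
#: abundances are a little noisier than transcript estimates.
DEFAULT_NOISE_SD = {"microarray": 0.5, "RNA-seq": 0.5, "SWATH-MS": 0.6}


@dataclass(frozen=True)
class PlantedTarget:
    gene: str
    direction: str  # up | down
    effect_size: float  # log2 units
    penetrance: float = 1.0  # fraction of comparisons carrying the effect

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigurationError(f"direction must be up/down: {self.direction!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigurationError("penetrance must lie in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ConfigurationError("effect size must be finite")


@dataclass(frozen=True)
class PlantedPathway:
    pathway: str
    direction: str  # up | down
    magnitude: float  # mean activation magnitude (log2 units per member gene)
    n_genes: int = 50

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ConfigurationError(f"direction must be up/down: {self.direction!r}")
        if self.magnitude <= 0 or self.n_genes < 1:
            raise ConfigurationError("magnitude and n_genes must be positive")


@dataclass(frozen=True)
class ComparisonSpec:
    group_id: str
    subtype: str
    modality: str
    source_name: str
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigurationError("arm sizes must be >= 1")


@dataclass
class StudyConfig:
    """Full specification of a synthetic study.

    The default comparison layout mirrors the real design (12 CNS + 4
    diMN comparisons with the published arm sizes); ``noise_sd``
    overrides the per-modality defaults when set.
    """

    comparisons: list[ComparisonSpec] = field(default_factory=list)
    n_genes: int = 2000
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    planted_pathways: list[PlantedPathway] = field(default_factory=list)
    n_background_pathways: int = 100
    pathway_size_range: tuple[int, int] = (10, 60)
    noise_sd: float | None = None
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.comparisons:
            self.comparisons = default_comparison_specs()
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


def _fixture(name: str):
    return resources.files("targetscout.data") / name


def _group_for_row(row) -> str:
    if row["source"] != "diMN":
        return f"CNS-{row['subtype']}"
    kind = "prot" if row["technology"] == "SWATH-MS" else "tx"
    return f"diMN-{kind}-{row['subtype']}"


def load_comparison_metadata(path=None) -> pd.DataFrame:
    """The bundled comparison-design table, with derived group ids.

    Transcribed from the published study-design table; adds
    ``group_id`` and ``compartment`` columns.
    """
    tab = pd.read_csv(path or _fixture("table1_comparisons.tsv"), sep="\t")
    required = {"subtype", "series", "technology", "source", "n_case", "n_control"}
    missing = required - set(tab.columns)
    if missing:
        raise DataError(f"comparison metadata missing columns {sorted(missing)}")
    tab["group_id"] = tab.apply(_group_for_row, axis=1)
    tab["compartment"] = np.where(tab["source"] == "diMN", "diMN", "CNS")
    return tab


def load_candidate_table(path=None) -> pd.DataFrame:
    """The bundled candidate-target table (28 rows)."""
    tab = pd.read_csv(path or _fixture("table2_candidates.tsv"), sep="\t")
    for col in ("aging_associated", "proteomic_source"):
        tab[col] = tab[col].astype(bool)
    return tab


def load_paper_fixtures():
    """Load the three transcribed fixture tables.

    Returns (comparison metadata DataFrame, candidate DataFrame, list
    of screen records).
    """
    from .fly_screen import load_screen_table

    return load_comparison_metadata(), load_candidate_table(), load_screen_table()


def cohort_summary(metadata: pd.DataFrame) -> dict:
    """Subject bookkeeping across the comparison design.

    CNS counts are sums over the twelve independent comparisons. The
    four diMN comparisons reuse one control pool and split one case
    cohort by subtype (the transcriptomic and proteomic comparisons
    profile the same subjects), so diMN subjects are counted once.
    """
    cns = metadata[metadata["compartment"] == "CNS"]
    dimn_tx = metadata[
        (metadata["compartment"] == "diMN") & (metadata["technology"] != "SWATH-MS")
    ]
    controls = dimn_tx["n_control"].unique()
    if len(controls) != 1:
        raise DataError("diMN comparisons should share one control pool")
    return {
        "cns_cases": int(cns["n_case"].sum()),
        "cns_controls": int(cns["n_control"].sum()),
        "dimn_cases": int(dimn_tx["n_case"].sum()),
        "dimn_controls": int(controls[0]),
        "n_comparisons": int(len(metadata)),
        "n_cns_comparisons": int(len(cns)),
    }


def default_comparison_specs() -> list[ComparisonSpec]:
    """Comparison layout mirroring the published study design."""
    meta = load_comparison_metadata()
    specs = []
    for _, row in meta.iterrows():
        specs.append(
            ComparisonSpec(
                group_id=row["group_id"],
                subtype=row["subtype"],
                modality=(
                    "SWATH-MS"
                    if row["technology"] == "SWATH-MS"
                    else ("RNA-seq" if row["technology"] == "RNA-seq" else "microarray")
                ),
                source_name=f"{row['series']}/{row['source']}",
                n_case=int(row["n_case"]),
                n_control=int(row["n_control"]),
            )
        )
    return specs


def _build_pathway_db(
    config: StudyConfig, genes: list[str], rng: np.random.Generator
) -> tuple[PathwayCollection, dict[str, set]]:
    processes = (
        (_fixture("top_level_processes.txt")).read_text().strip().splitlines()
    )
    pathways: dict[str, set] = {}
    hierarchy: dict[str, str] = {}
    planted_members: dict[str, set] = {}
    target_genes = {t.gene for t in config.planted_targets}
    pool = [g for g in genes if g not in target_genes]
    for i, pp in enumerate(config.planted_pathways):
        if pp.n_genes > len(pool):
            raise ConfigurationError("planted pathway larger than gene pool")
        members = set(rng.choice(pool, size=pp.n_genes, replace=False))
        pathways[pp.pathway] = members
        planted_members[pp.pathway] = members
        hierarchy[pp.pathway] = processes[i % len(processes)]
    lo, hi = config.pathway_size_range
    for i in range(config.n_background_pathways):
        pid = f"BG_PATH_{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        pathways[pid] = set(rng.choice(genes, size=min(size, len(genes)), replace=False))
        hierarchy[pid] = processes[int(rng.integers(0, len(processes)))]
    return PathwayCollection(pathways=pathways, hierarchy=hierarchy), planted_members


def generate_study(config: StudyConfig) -> StudyBundle:
    """Generate a complete synthetic study bundle.

    Deterministic for a fixed config: all randomness flows from one
    seeded generator consumed in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    for t in config.planted_targets:
        if t.gene not in gene_index:
            raise ConfigurationError(f"planted gene {t.gene!r} not in universe")

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    pathway_db, planted_members = _build_pathway_db(config, genes, rng)

    # Per-(target, comparison) penetrance draws, in fixed order.
    penetrant = {
        (t.gene, ci): bool(rng.random() < t.penetrance)
        for t in config.planted_targets
        for ci in range(len(config.comparisons))
    }

    comparisons: list[ComparisonDataset] = []
    for ci, spec in enumerate(config.comparisons):
        sd = config.noise_sd or DEFAULT_NOISE_SD[spec.modality]
        n = spec.n_case + spec.n_control
        mat = baseline[:, None] + rng.normal(0.0, sd, (config.n_genes, n))
        case_slice = slice(0, spec.n_case)
        for t in config.planted_targets:
            if penetrant[(t.gene, ci)]:
                sign = 1.0 if t.direction == "up" else -1.0
                mat[gene_index[t.gene], case_slice] += sign * t.effect_size
        for pp in config.planted_pathways:
            sign = 1.0 if pp.direction == "up" else -1.0
            rows = [gene_index[g] for g in planted_members[pp.pathway]]
            mat[np.array(rows)[:, None], case_slice] += sign * pp.magnitude
        samples = [f"c{ci:02d}_case{j:03d}" for j in range(spec.n_case)] + [
            f"c{ci:02d}_ctrl{j:03d}" for j in range(spec.n_control)
        ]
        labels = {
            s: ("case" if j < spec.n_case else "control")
            for j, s in enumerate(samples)
        }
        comparisons.append(
            ComparisonDataset(
                matrix=pd.DataFrame(mat, index=genes, columns=samples),
                labels=labels,
                subtype=spec.subtype,
                modality=spec.modality,
                group_id=spec.group_id,
                source_name=spec.source_name,
            )
        )

    # Annotations: planted targets are guaranteed druggable, small-molecule
    # accessible, non-essential and maximally novel so that recovery is a
    # test of the statistics, not of annotation luck.
    target_genes = {t.gene for t in config.planted_targets}
    n = config.n_genes
    classes = rng.choice(DRUGGABLE_CLASSES, size=n)
    has_class = rng.random(n) < 0.7
    ann = pd.DataFrame(
        {
            "druggable_class": np.where(has_class, classes, ""),
            "has_small_molecule": rng.random(n) < 0.5,
            "is_essential": rng.random(n) < 0.1,
            "aging_associated": rng.random(n) < 0.1,
            "novelty_level": rng.integers(0, 3, n),
        },
        index=pd.Index(genes, name="gene"),
    )
    for g in target_genes:
        ann.loc[g, ["druggable_class", "has_small_molecule"]] = ["GPCR", True]
        ann.loc[g, ["is_essential", "novelty_level"]] = [False, 2]

    # Stand-in literature/finance/KOL score tables: unit-normal noise with
    # a modest boost for planted targets, emulating external evidence.
    scores = pd.DataFrame(
        rng.normal(0.0, 1.0, (n, 3)),
        index=pd.Index(genes, name="gene"),
        columns=["text", "finance", "kol"],
    )
    scores.loc[sorted(target_genes)] += 2.0

    chronology = generate_chronology(
        n_genes=n, cutoff_density=0.2, seed=int(rng.integers(0, 2**31)), genes=genes
    )

    truth = {
        "planted_targets": [asdict(t) for t in config.planted_targets],
        "planted_pathways": [asdict(p) for p in config.planted_pathways],
        "planted_pathway_members": {
            k: sorted(v) for k, v in planted_members.items()
        },
        "seed": config.seed,
    }
    return StudyBundle(
        comparisons=comparisons,
        annotations=GeneAnnotations(ann),
        score_tables=scores,
        chronology=chronology,
        pathway_db=pathway_db,
        truth=truth,
    )


def generate_chronology(
    n_genes: int,
    cutoff_density: float,
    seed: int,
    cutoff_year: int = 2015,
    year_range: tuple[int, int] = (1995, 2021),
    genes: list[str] | None = None,
) -> TargetChronology:
    """Random trial-entry chronology: a pre/post-cutoff year mixture.

    Each gene falls after the cutoff with probability ``cutoff_density``;
    years are uniform on the respective side of the cutoff.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if not 0.0 <= cutoff_density <= 1.0:
        raise ConfigurationError("cutoff_density must lie in [0, 1]")
    lo, hi = year_range
    if not lo <= cutoff_year < hi:
        raise ConfigurationError("cutoff_year must lie inside year_range")
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = [f"G{i:05d}" for i in range(n_genes)]
    post = rng.random(n_genes) < cutoff_density
    years = np.where(
        post,
        rng.integers(cutoff_year + 1, hi + 1, n_genes),
        rng.integers(lo, cutoff_year + 1, n_genes),
    )
    return TargetChronology(pd.DataFrame({"gene": genes, "year": years}))


def generate_screen_table(
    genes: list[str], seed: int, p_lethal: float = 0.05, p_no_model: float = 0.1
):
    """Synthetic modifier-screen records for a candidate gene list.

    Each gene gets one fictitious fly ortholog; offspring scores are
    drawn from the integer scale with a rescue-leaning distribution, as
    modifier screens of pre-filtered candidates tend to show.
    """
    from .fly_screen import ScreenRecord

    rng = np.random.default_rng(seed)
    support = np.arange(-4, 3)
    weights = np.array([0.05, 0.15, 0.25, 0.15, 0.25, 0.1, 0.05])
    records = []
    for g in genes:
        fly = f"d{g}"
        if rng.random() < p_no_model:
            records.append(ScreenRecord(g, fly, model_available=False))
            continue
        if rng.random() < p_lethal:
            records.append(ScreenRecord(g, fly, model_available=True, lethal=True))
            continue
        n_off = int(rng.integers(1, 4))
        scores = list(rng.choice(support, size=n_off, p=weights / weights.sum()))
        records.append(
            ScreenRecord(g, fly, model_available=True, offspring_scores=[float(s) for s in scores])
        )
    return records


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2, sort_keys=True)
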