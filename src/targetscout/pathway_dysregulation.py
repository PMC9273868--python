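"""Pathway activation scoring, dysregulation calling, process enrichment
and gene-set similarity networks.

The pathway activation score here is a documented simplified stand-in
for topology-aware pathway activation scoring: a weighted mean of
member-gene log2 fold changes (optional per-gene topology weights,
uniform by default), with genes failing a significance gate
down-weighted rather than dropped. It is pluggable — any scorer
producing signed activation values per (pathway, comparison) can feed
the calling stage.

A pathway is called dysregulated for a subtype group when its
activation sign agrees in >= 80% of the group's comparisons and its
absolute score reaches 0.01 in at least one of them. Called pathways
are tested for overrepresentation in top-level processes with a
hypergeometric tail (Bonferroni-corrected), and assembled into a
similarity network in which pathways sharing gene content
(coefficient > 0.35) are connected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, UndefinedStatisticError

__all__ = [
    "PathwayCollection",
    "DysregulationCriteria",
    "DysregulationCall",
    "ProcessEnrichmentCounts",
    "activation_score",
    "score_pathways",
    "call_dysregulated",
    "process_enrichment",
    "bonferroni",
    "enrichment_report",
    "similarity_network",
    "reported_clusters",
]


@dataclass
class PathwayCollection:
    """Gene sets plus their mapping to top-level processes.

    ``pathways`` maps pathway id -> set of gene ids; ``hierarchy`` maps
    every pathway id to exactly one top-level process name (27 in the
    bundled Reactome-style hierarchy); ``topology`` optionally holds
    per-pathway gene weight dicts.
    """

    pathways: dict[str, set]
    hierarchy: dict[str, str]
    topology: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes:
                raise DataError(f"pathway {pid!r} has an empty gene set")
        missing = set(self.pathways) - set(self.hierarchy)
        if missing:
            raise DataError(
                f"pathways without a top-level process: {sorted(missing)[:3]}"
            )

    @property
    def processes(self) -> list[str]:
        return sorted(set(self.hierarchy.values()))

    def __len__(self) -> int:
        return len(self.pathways)


def load_gmt(path) -> dict[str, set]:
    """Parse a GMT file: name <tab> description <tab> gene..."""
    pathways: dict[str, set] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}: line {i}: GMT rows need >= 3 fields")
            pathways[parts[0]] = set(g for g in parts[2:] if g)
    return pathways


def load_hierarchy(path) -> dict[str, str]:
    """Parse a two-column TSV (pathway_id, process_name), with header."""
    tab = pd.read_csv(path, sep="\t")
    return dict(zip(tab.iloc[:, 0], tab.iloc[:, 1]))


@dataclass
class DysregulationCriteria:
    """The calling rule: sign agreement fraction and magnitude floor."""

    unidirectional_fraction: float = 0.80
    magnitude_threshold: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.unidirectional_fraction <= 1:
            raise ConfigurationError("unidirectional_fraction must be in (0, 1]")
        if self.magnitude_threshold <= 0:
            raise ConfigurationError("magnitude_threshold must be > 0")


@dataclass(frozen=True)
class DysregulationCall:
    pathway: str
    direction: str  # activated | inhibited
    group_id: str


def activation_score(
    effects: pd.DataFrame,
    pathway_genes: set,
    topology: dict | None = None,
    p_gate: float | None = 0.05,
    gate_factor: float = 0.5,
) -> float:
    """Signed activation score of one pathway in one comparison.

    Weighted mean of member-gene lfc values. Topology weights default
    to uniform; genes whose p-value misses the significance gate keep a
    ``gate_factor`` fraction of their weight (soft gating — dropping
    them outright would make small pathways unstable). ``p_gate=None``
    disables gating.
    """
    eff = effects[effects["gene"].isin(pathway_genes)]
    if eff.empty:
        raise UndefinedStatisticError("pathway has no genes in the effect universe")
    w = np.array(
        [1.0 if topology is None else float(topology.get(g, 1.0)) for g in eff["gene"]]
    )
    if p_gate is not None:
        w = w * np.where(eff["p_value"].to_numpy() < p_gate, 1.0, gate_factor)
    if w.sum() == 0:
        raise UndefinedStatisticError("all member weights are zero")
    return float(np.average(eff["lfc"].to_numpy(), weights=w))


def score_pathways(
    effects_by_comparison: dict[str, pd.DataFrame],
    collection: PathwayCollection,
    p_gate: float | None = 0.05,
) -> pd.DataFrame:
    """Activation scores for every (pathway, comparison) pair.

    Returns a pathways x comparisons DataFrame; pathways with no member
    gene in a comparison's universe get NaN there.
    """
    cols = {}
    for comp_id, eff in effects_by_comparison.items():
        universe = set(eff["gene"])
        vals = {}
        for pid, genes in collection.pathways.items():
            if genes & universe:
                topo = collection.topology.get(pid) if collection.topology else None
                vals[pid] = activation_score(eff, genes, topo, p_gate=p_gate)
            else:
                vals[pid] = np.nan
        cols[comp_id] = vals
    return pd.DataFrame(cols)


def call_dysregulated(
    scores: pd.DataFrame,
    group_id: str,
    criteria: DysregulationCriteria = DysregulationCriteria(),
) -> list[DysregulationCall]:
    """Apply the sign-agreement / magnitude rule to a group's scores.

    ``scores``: pathways x comparisons for one group. A score of
    exactly 0 counts toward neither direction; fractions are compared
    exactly (on 7 comparisons the 80% gate needs 6). The magnitude
    floor is met if any comparison's |score| reaches the threshold.
    """
    if scores.shape[1] < 1:
        raise DataError("need at least one comparison to call dysregulation")
    calls = []
    frac = criteria.unidirectional_fraction
    for pid, row in scores.iterrows():
        vals = row.dropna().to_numpy()
        if vals.size == 0:
            continue
        if np.abs(vals).max() < criteria.magnitude_threshold:
            continue
        pos = (vals > 0).sum() / vals.size
        neg = (vals < 0).sum() / vals.size
        if pos >= frac:
            calls.append(DysregulationCall(pid, "activated", group_id))
        elif neg >= frac:
            calls.append(DysregulationCall(pid, "inhibited", group_id))
    return calls


@dataclass(frozen=True)
class ProcessEnrichmentCounts:
    """Counts for the process-level hypergeometric test.

    N: total pathways in the database; K: dysregulated pathways in the
    process of interest; n: total dysregulated pathways in the group;
    r: pathways belonging to the process of interest.
    """

    N: int
    K: int
    n: int
    r: int

    def __post_init__(self) -> None:
        if min(self.N, self.K, self.n, self.r) < 0:
            raise DataError("counts must be nonnegative")
        if self.K > self.n:
            raise DataError("K (dysregulated in process) cannot exceed n")
        if self.n > self.N or self.r > self.N:
            raise DataError("n and r cannot exceed N")


def _comb(n: int, k: int) -> int:
    if k < 0 or k > n or n < 0:
        return 0
    return math.comb(n, k)


def process_enrichment(
    c: ProcessEnrichmentCounts, orientation: str = "as_printed"
) -> float:
    """Hypergeometric overrepresentation p-value for one process.

    ``as_printed`` evaluates p = 1 - sum_{i=0}^{r-1} C(K,i) C(N-K,n-i)
    / C(N,n), the published index convention (sum runs to the process
    size r, with K in the population-success slot). ``conventional``
    instead tests the observed overlap K against a population of r
    process pathways: P(X >= K) for X ~ Hypergeometric(N, r, n).
    Impossible binomial terms contribute zero.
    """
    denom = _comb(c.N, c.n)
    if denom == 0:
        raise DataError("C(N, n) is zero; invalid counts")
    if orientation == "as_printed":
        upper, pop_success = c.r, c.K
    elif orientation == "conventional":
        upper, pop_success = c.K, c.r
    else:
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    acc = 0
    for i in range(upper):
        acc += _comb(pop_success, i) * _comb(c.N - pop_success, c.n - i)
    return 1.0 - acc / denom


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def enrichment_report(
    calls: list[DysregulationCall],
    collection: PathwayCollection,
    orientation: str = "as_printed",
) -> pd.DataFrame:
    """Process-level enrichment of a group's dysregulated pathways.

    One row per top-level process containing at least one pathway, with
    the counts, raw p and Bonferroni-adjusted p (corrected for the
    number of processes tested).
    """
    called = {c.pathway for c in calls}
    unknown = called - set(collection.pathways)
    if unknown:
        raise DataError(f"calls reference unknown pathways: {sorted(unknown)[:3]}")
    N = len(collection)
    n = len(called)
    rows = []
    processes = collection.processes
    for proc in processes:
        members = {p for p, pr in collection.hierarchy.items() if pr == proc}
        r = len(members)
        K = len(called & members)
        counts = ProcessEnrichmentCounts(N=N, K=K, n=n, r=r)
        raw = process_enrichment(counts, orientation=orientation)
        rows.append(
            {"process": proc, "K": K, "n": n, "r": r, "N": N, "raw_p": raw}
        )
    rep = pd.DataFrame(rows)
    rep["adjusted_p"] = rep["raw_p"].map(lambda p: bonferroni(p, len(processes)))
    return rep


def _jaccard(a: set, b: set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _combined(a: set, b: set) -> float:
    inter = len(a & b)
    if not a or not b:
        return 0.0
    overlap = inter / min(len(a), len(b))
    return 0.5 * (_jaccard(a, b) + overlap)


SIMILARITY_COEFFICIENTS = {"jaccard": _jaccard, "combined": _combined}


def similarity_network(
    calls: list[DysregulationCall],
    gene_sets: dict[str, set],
    threshold: float = 0.35,
    coefficient: str = "jaccard",
) -> nx.Graph:
    """Build the similarity network of called pathways.

    Nodes are called pathways (direction and group stored as node
    attributes); an edge connects two pathways whose gene-content
    similarity strictly exceeds ``threshold``, with the coefficient as
    the edge weight. ``coefficient`` is ``jaccard`` (default) or
    ``combined`` (mean of Jaccard and overlap coefficients).
    """
    try:
        sim = SIMILARITY_COEFFICIENTS[coefficient]
    except KeyError:
        raise ConfigurationError(f"unknown similarity coefficient {coefficient!r}")
    missing = {c.pathway for c in calls} - set(gene_sets)
    if missing:
        raise DataError(f"called pathways without gene sets: {sorted(missing)[:3]}")
    g = nx.Graph()
    for c in calls:
        g.add_node(c.pathway, direction=c.direction, group_id=c.group_id)
    nodes = sorted(g.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            coef = sim(gene_sets[a], gene_sets[b])
            if coef > threshold:
                g.add_edge(a, b, weight=coef)
    return g


def reported_clusters(g: nx.Graph, min_cluster: int = 4) -> list[set]:
    """Connected components large enough to report (> 3 pathways by default)."""
    return [c for c in nx.connected_components(g) if len(c) >= min_cluster]
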