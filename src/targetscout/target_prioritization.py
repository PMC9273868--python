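"""Meta-analysis grouping, directional consistency, metascores and filters.

The study design pools case-control comparisons into six meta-analysis
groups (two CNS transcriptomic groups split by ALS subtype, four
patient-derived motor-neuron groups split by subtype and modality).
Within the CNS groups, a target's evidence is summarised as directional
consistency: the percentage of comparisons in which its log2 fold
change is strictly positive (or strictly negative, for downregulation),
rounded half-up to a whole percent. Candidate targets must be ranked in
a top-k list of at least one group and, for CNS targets, reach >= 80%
consistency in one direction for fALS, sALS, or both.

Score aggregation across heterogeneous families (omics, text, finance,
key-opinion-leader) is a weighted mean of per-family rank-normalized
scores; the omics family score for a group is the mean over its
comparisons of sign(lfc) * -log10(p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GROUP_IDS, ComparisonDataset, GeneAnnotations
from .errors import ConfigurationError, UndefinedStatisticError

__all__ = [
    "MetaGroup",
    "FilterConfig",
    "CandidateTarget",
    "build_groups",
    "consistency",
    "group_omics_scores",
    "metascore",
    "apply_filters",
    "select_candidates",
]

SCORE_FAMILIES = ("omics", "text", "finance", "kol")

CNS_GROUPS = ("CNS-fALS", "CNS-sALS")
DIMN_GROUPS = ("diMN-tx-fALS", "diMN-tx-sALS", "diMN-prot-fALS", "diMN-prot-sALS")


@dataclass
class MetaGroup:
    """A meta-analysis group: the comparisons sharing subtype/tissue/modality."""

    group_id: str
    comparisons: list[ComparisonDataset]
    effects: list[pd.DataFrame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.comparisons)


@dataclass
class FilterConfig:
    """Druggability / novelty filter cascade settings.

    ``novelty_mode='novel'`` mirrors the no-prior-knowledge setting:
    only the omics score family may be enabled, and genes must reach
    ``min_novelty``. ``'high_confidence'`` allows every family.
    """

    require_druggable_class: bool = True
    require_small_molecule: bool = True
    exclude_essential: bool = True
    novelty_mode: str = "high_confidence"
    min_novelty: int = 1
    enabled_families: tuple[str, ...] = SCORE_FAMILIES
    top_k: int = 50

    def __post_init__(self) -> None:
        if self.novelty_mode not in ("high_confidence", "novel"):
            raise ConfigurationError(f"unknown novelty mode {self.novelty_mode!r}")
        bad = set(self.enabled_families) - set(SCORE_FAMILIES)
        if bad:
            raise ConfigurationError(f"unknown score families {sorted(bad)}")
        if not self.enabled_families:
            raise ConfigurationError("at least one score family must be enabled")
        if self.novelty_mode == "novel" and tuple(self.enabled_families) != ("omics",):
            raise ConfigurationError(
                "novel mode requires exactly the omics family enabled"
            )
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")


@dataclass
class CandidateTarget:
    """One row of the candidate table."""

    gene: str
    category: str  # high_confidence | novel
    compartment: str  # CNS | diMN
    consistency_up_fals: int | None = None
    consistency_up_sals: int | None = None
    dimn_lfc: float | None = None
    dimn_p: float | None = None
    aging_flag: bool = False


def build_groups(comparisons: list[ComparisonDataset]) -> list[MetaGroup]:
    """Partition comparisons into meta-analysis groups by their group id.

    Every comparison lands in exactly one group; groups appear in the
    canonical order and only when non-empty.
    """
    by_id: dict[str, list[ComparisonDataset]] = {g: [] for g in GROUP_IDS}
    for comp in comparisons:
        by_id[comp.group_id].append(comp)
    return [MetaGroup(g, members) for g, members in by_id.items() if members]


def consistency(lfcs, direction: str) -> int:
    """Directional consistency as a whole percentage, rounded half-up.

    The share of comparisons whose log2 fold change is strictly
    positive (``direction='up'``) or strictly negative (``'down'``);
    an lfc of exactly 0 counts toward neither direction. 6 of 7
    positive yields 86 (85.71 rounded half-up).
    """
    lfcs = np.asarray(list(lfcs), dtype=float)
    if lfcs.size == 0:
        raise UndefinedStatisticError("consistency undefined for zero comparisons")
    if direction == "up":
        hits = int((lfcs > 0).sum())
    elif direction == "down":
        hits = int((lfcs < 0).sum())
    else:
        raise ConfigurationError(f"direction must be 'up' or 'down', got {direction!r}")
    return int(math.floor(100.0 * hits / lfcs.size + 0.5))


def group_omics_scores(group: MetaGroup, p_floor: float = 1e-300) -> pd.Series:
    """Per-gene omics evidence score for a meta-analysis group.

    Mean over the group's comparisons of sign(lfc) * -log10(p): genes
    consistently up with small p-values score high, consistently down
    genes score low (negative). Genes missing from a comparison
    contribute nothing to their own mean.
    """
    if not group.effects:
        raise UndefinedStatisticError(f"group {group.group_id} has no effects")
    per_comp = []
    for eff in group.effects:
        p = eff["p_value"].clip(lower=p_floor)
        signed = np.sign(eff["lfc"]) * (-np.log10(p))
        per_comp.append(pd.Series(signed.values, index=eff["gene"].values))
    return pd.concat(per_comp, axis=1).mean(axis=1).rename("omics")


def metascore(
    scores: pd.DataFrame,
    enabled_families=SCORE_FAMILIES,
    weights: dict[str, float] | None = None,
) -> pd.Series:
    """Aggregate score families into one ranking.

    Each enabled family is rank-normalized to (0, 1] (average ranks for
    ties) so heterogeneous scales are commensurable, then combined by a
    nonnegative-weighted mean. Returns the metascore sorted descending
    with ties broken lexicographically by gene id.
    """
    enabled = [f for f in enabled_families]
    missing = set(enabled) - set(scores.columns)
    if missing:
        raise ConfigurationError(f"score table lacks families {sorted(missing)}")
    if not enabled:
        raise ConfigurationError("no score families enabled")
    if weights is None:
        weights = {f: 1.0 for f in enabled}
    w = np.array([float(weights.get(f, 0.0)) for f in enabled])
    if (w < 0).any():
        raise ConfigurationError("weights must be nonnegative")
    if w.sum() == 0:
        raise ConfigurationError("all weights are zero")
    normed = scores[enabled].rank(method="average") / len(scores)
    meta = normed.mul(w, axis=1).sum(axis=1) / w.sum()
    order = sorted(meta.index, key=lambda g: (-meta[g], str(g)))
    return meta.loc[order]


def apply_filters(
    ranked: pd.Series | list[str],
    annotations: GeneAnnotations,
    cfg: FilterConfig,
) -> list[str]:
    """Order-preserving druggability/novelty filter, then a top-k cut.

    A gene with no annotation row fails any requirement that needs one.
    Idempotent: filtering a filtered list changes nothing (the top-k cut
    only truncates).
    """
    genes = list(ranked.index) if isinstance(ranked, pd.Series) else list(ranked)
    tab = annotations.table
    survivors = []
    for g in genes:
        if g in tab.index:
            row = tab.loc[g]
            dclass = str(row["druggable_class"]) if pd.notna(row["druggable_class"]) else ""
            has_sm = bool(row["has_small_molecule"])
            essential = bool(row["is_essential"])
            novelty = int(row["novelty_level"])
        else:
            dclass, has_sm, essential, novelty = "", False, False, 0
        if cfg.require_druggable_class and not dclass:
            continue
        if cfg.require_small_molecule and not has_sm:
            continue
        if cfg.exclude_essential and essential:
            continue
        if cfg.novelty_mode == "novel" and novelty < cfg.min_novelty:
            continue
        survivors.append(g)
    return survivors[: cfg.top_k]


def _group_consistencies(group: MetaGroup) -> pd.DataFrame:
    """Per-gene up/down consistency percentages over a group's effects."""
    lfc = pd.concat(
        [pd.Series(e["lfc"].values, index=e["gene"].values) for e in group.effects],
        axis=1,
    )
    n = lfc.notna().sum(axis=1)
    up = (lfc > 0).sum(axis=1)
    down = (lfc < 0).sum(axis=1)
    return pd.DataFrame(
        {
            "up": np.floor(100.0 * up / n + 0.5).astype(int),
            "down": np.floor(100.0 * down / n + 0.5).astype(int),
        }
    )


def select_candidates(
    top_lists: dict[str, list[str]],
    groups: list[MetaGroup],
    annotations: GeneAnnotations,
    cfg: FilterConfig,
    min_consistency: int = 80,
) -> list[CandidateTarget]:
    """Assemble the candidate table from per-group top lists.

    A gene qualifies only if it appears in at least one group's top
    list. CNS candidates must additionally reach ``min_consistency``
    percent in one direction (up or down) for fALS, sALS or both; the
    reported percentages are always the *up* consistencies, matching the
    convention of the candidate table. diMN candidates carry the group
    mean lfc and the smallest member p-value.
    """
    by_id = {g.group_id: g for g in groups}
    cons = {
        gid: _group_consistencies(by_id[gid]) for gid in CNS_GROUPS if gid in by_id
    }

    out: list[CandidateTarget] = []
    seen: set[tuple[str, str]] = set()
    for gid, top in top_lists.items():
        compartment = "CNS" if gid in CNS_GROUPS else "diMN"
        for gene in top:
            if (gene, compartment) in seen:
                continue
            aging = (
                bool(annotations.table.loc[gene, "aging_associated"])
                if gene in annotations.table.index
                else False
            )
            if compartment == "CNS":
                vals = {}
                eligible = False
                for sub, cgid in (("fALS", "CNS-fALS"), ("sALS", "CNS-sALS")):
                    if cgid in cons and gene in cons[cgid].index:
                        row = cons[cgid].loc[gene]
                        vals[sub] = int(row["up"])
                        if row["up"] >= min_consistency or row["down"] >= min_consistency:
                            eligible = True
                if not eligible:
                    continue
                out.append(
                    CandidateTarget(
                        gene=gene,
                        category=cfg.novelty_mode,
                        compartment="CNS",
                        consistency_up_fals=vals.get("fALS"),
                        consistency_up_sals=vals.get("sALS"),
                        aging_flag=aging,
                    )
                )
            else:
                grp = by_id[gid]
                lfcs, ps = [], []
                for eff in grp.effects:
                    hit = eff[eff["gene"] == gene]
                    if len(hit):
                        lfcs.append(float(hit["lfc"].iloc[0]))
                        ps.append(float(hit["p_value"].iloc[0]))
                if not lfcs:
                    continue
                out.append(
                    CandidateTarget(
                        gene=gene,
                        category=cfg.novelty_mode,
                        compartment="diMN",
                        dimn_lfc=float(np.mean(lfcs)),
                        dimn_p=float(min(ps)),
                        aging_flag=aging,
                    )
                )
            seen.add((gene, compartment))
    return out


def candidates_to_frame(candidates: list[CandidateTarget]) -> pd.DataFrame:
    """Render candidate records as a table mirroring the published layout."""
    return pd.DataFrame(
        {
            "gene": [c.gene for c in candidates],
            "category": [c.category for c in candidates],
            "compartment": [c.compartment for c in candidates],
            "fals_up_pct": [c.consistency_up_fals for c in candidates],
            "sals_up_pct": [c.consistency_up_sals for c in candidates],
            "dimn_lfc": [c.dimn_lfc for c in candidates],
            "dimn_p": [c.dimn_p for c in candidates],
            "aging_associated": [c.aging_flag for c in candidates],
        }
    )
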