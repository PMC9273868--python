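"""Retrospective "time machine" validation of a gene ranking.

A target chronology (gene, first clinical-trial year) is split at a
cutoff year; a ranking built from pre-cutoff information is then scored
on how strongly its top-k prefix is enriched for post-cutoff trial
entrants. Two metrics:

ELFC
    log2 of the enrichment fold change, log2((t_k / k) / (targets_N / N)),
    where t_k is the number of evaluated targets in the top-k, with 0.1
    substituted when the count is zero so the logarithm stays finite.
HGPV
    -log10 of the upper hypergeometric tail P(X > targets_k) for X ~
    Hypergeometric(N, targets_N, k). Higher values of either metric mean
    higher predictive power. A tail of exactly zero (the count is at the
    top of its support) is clamped to a configurable maximum rather than
    reported as infinity.

Both metrics are label-agnostic: the caller decides which set of
targets (post-cutoff "novel" entrants, or anything else) is evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .datatypes import TargetChronology
from .errors import DataError, UndefinedStatisticError

__all__ = [
    "EnrichmentCounts",
    "elfc",
    "hgpv",
    "split_chronology",
    "evaluate_ranking",
]

#: HGPV value reported when the hypergeometric tail is exactly zero.
HGPV_CLAMP = 300.0


@dataclass(frozen=True)
class EnrichmentCounts:
    """Counts entering the enrichment formulas.

    targets_k
        Evaluated targets found in the ranking's top-k prefix.
    k
        Prefix length.
    targets_N
        Evaluated targets among all N scored genes.
    N
        Total scored genes.
    """

    targets_k: int
    k: int
    targets_N: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.targets_k <= min(self.k, self.targets_N)):
            raise DataError(
                f"targets_k={self.targets_k} outside [0, min(k, targets_N)]"
            )
        if self.targets_N > self.N or self.k > self.N:
            raise DataError("targets_N and k must not exceed N")
        if self.k < 1 or self.N < 1:
            raise DataError("k and N must be >= 1")


def elfc(c: EnrichmentCounts) -> float:
    """Enrichment log2 fold change of the top-k target rate over background.

    Zero hits are replaced by 0.1 so the ratio stays defined; the
    substitution applies here only, never to the hypergeometric tail.
    """
    if c.targets_N == 0:
        raise UndefinedStatisticError("no evaluated targets among scored genes")
    t_k = c.targets_k if c.targets_k > 0 else 0.1
    return math.log2((t_k / c.k) * (c.N / c.targets_N))


def hgpv(
    c: EnrichmentCounts, inclusive: bool = False, clamp: float = HGPV_CLAMP
) -> float:
    """-log10 hypergeometric tail probability of the top-k target count.

    Default is the strict tail P(X > targets_k) = 1 - CDF(targets_k);
    ``inclusive=True`` gives P(X >= targets_k). Tails of exactly zero
    are clamped to ``clamp``.
    """
    observed = c.targets_k - 1 if inclusive else c.targets_k
    tail = stats.hypergeom.sf(observed, c.N, c.targets_N, c.k)
    if tail <= 0.0:
        return clamp
    return min(max(-math.log10(tail), 0.0), clamp)


def split_chronology(
    chronology: TargetChronology, cutoff_year: int
) -> tuple[set[str], set[str]]:
    """Split a chronology into (known, novel) gene sets at a cutoff year.

    A year equal to the cutoff counts as known (training side); the
    evaluated "novel" side is strictly after the cutoff.
    """
    if len(chronology) == 0:
        raise DataError("empty chronology")
    tab = chronology.table
    known = set(tab.loc[tab["year"] <= cutoff_year, "gene"])
    novel = set(tab.loc[tab["year"] > cutoff_year, "gene"])
    return known, novel


def evaluate_ranking(
    ranked_genes, evaluated: set[str], k: int, inclusive: bool = False
) -> dict:
    """Score a ranking's top-k enrichment for an evaluated target set.

    Returns a dict with the assembled counts and both metrics. The
    evaluated set is intersected with the ranked universe; an empty
    intersection is an error (no background rate exists).
    """
    ranked = list(ranked_genes)
    universe = set(ranked)
    if len(ranked) != len(universe):
        raise DataError("ranking contains duplicate genes")
    if not 1 <= k <= len(ranked):
        raise DataError(f"k={k} outside [1, {len(ranked)}]")
    in_universe = evaluated & universe
    if not in_universe:
        raise UndefinedStatisticError("no evaluated targets in the ranked universe")
    counts = EnrichmentCounts(
        targets_k=sum(1 for g in ranked[:k] if g in in_universe),
        k=k,
        targets_N=len(in_universe),
        N=len(ranked),
    )
    return {
        "counts": counts,
        "elfc": elfc(counts),
        "hgpv": hgpv(counts, inclusive=inclusive),
    }
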