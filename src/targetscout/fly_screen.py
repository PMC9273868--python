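"""Drosophila eye-degeneration modifier-screen scoring.

RNAi knockdown of a candidate gene's fly ortholog in a c9ALS model
(GGGGCC repeat expression in the eye) changes the severity of eye
degeneration. Severity change is graded on an integer scale from -4
(strongest rescue) to 2 (strongest enhancement); an ortholog's score is
the mean over scored offspring, so half-scores like -3.5 arise when
offspring split between -4 and -3. Lethal crosses yield no score and
are never imputed.

Classification thresholds (inclusive at the boundary):
  score <= -3            strong rescue
  score <= -2            moderate rescue
  score <= -1            mild rescue
  -1 < score < 1         no effect
  score >= 1             mild enhancement
  score >= 2             moderate enhancement

A human gene with several fly orthologs is represented by the score of
strongest modification (maximal absolute value; ties broken toward
rescue, i.e. the negative side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import DataError

__all__ = [
    "ScreenRecord",
    "ortholog_score",
    "classify",
    "gene_best_score",
    "summarize",
    "load_screen_table",
    "interpretation_label",
]

SCORE_MIN, SCORE_MAX = -4.0, 2.0

CATEGORY_LABELS = {
    "strong_rescue": "Strong rescue",
    "moderate_rescue": "Moderate rescue",
    "mild_rescue": "Mild rescue",
    "no_effect": "No modification",
    "mild_enhance": "Mild enhancement",
    "moderate_enhance": "Moderate enhancement",
}


@dataclass
class ScreenRecord:
    """One (human gene, fly ortholog) screen row."""

    human_gene: str
    fly_ortholog: str
    model_available: bool
    offspring_scores: list[float] = field(default_factory=list)
    lethal: bool = False
    prior_report: str | None = None

    def __post_init__(self) -> None:
        if not self.model_available and (self.offspring_scores or self.lethal):
            raise DataError(
                f"{self.human_gene}/{self.fly_ortholog}: scores recorded "
                "without an available fly model"
            )
        for s in self.offspring_scores:
            if not SCORE_MIN <= s <= SCORE_MAX:
                raise DataError(f"score {s} outside [{SCORE_MIN}, {SCORE_MAX}]")

    @property
    def score(self) -> float | None:
        """Mean offspring score, or None for lethal / no-model records."""
        if not self.offspring_scores:
            return None
        return ortholog_score(self.offspring_scores)


def ortholog_score(offspring_scores) -> float:
    """Aggregate offspring scores for one ortholog: the arithmetic mean.

    Offspring splitting between -4 and -3 therefore yield -3.5; lethal
    offspring must be excluded by the caller before aggregation.
    """
    scores = list(offspring_scores)
    if not scores:
        raise DataError("no non-lethal offspring scores to aggregate")
    for s in scores:
        if not SCORE_MIN <= s <= SCORE_MAX:
            raise DataError(f"score {s} outside [{SCORE_MIN}, {SCORE_MAX}]")
    return sum(scores) / len(scores)


def classify(score: float) -> str:
    """Map a modification score to its category (inclusive boundaries)."""
    if score is None:
        raise DataError("cannot classify a missing score")
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise DataError(f"score {score} outside [{SCORE_MIN}, {SCORE_MAX}]")
    if score <= -3:
        return "strong_rescue"
    if score <= -2:
        return "moderate_rescue"
    if score <= -1:
        return "mild_rescue"
    if score < 1:
        return "no_effect"
    if score < 2:
        return "mild_enhance"
    return "moderate_enhance"


def interpretation_label(score: float) -> str:
    """Human-readable interpretation string for a score."""
    return CATEGORY_LABELS[classify(score)]


def gene_best_score(records: list[ScreenRecord]) -> float | None:
    """Representative score for one human gene across its orthologs.

    The score of strongest modification (maximal |score|); on ties
    between a rescue and an enhancement of equal magnitude the rescue
    (negative) score wins. Returns None when no ortholog was scorable
    (lethal crosses or no fly model).
    """
    scored = [r.score for r in records if r.score is not None]
    if not scored:
        return None
    return min(scored, key=lambda s: (-abs(s), s > 0))


def summarize(records: list[ScreenRecord]) -> dict:
    """Screen-level bookkeeping over a set of records.

    Counts genes per best-score category, genes with at least one
    scorable ortholog, distinct fly orthologs, strong-or-moderate
    rescues, and strong rescues lacking any prior report.
    """
    by_gene: dict[str, list[ScreenRecord]] = {}
    for r in records:
        by_gene.setdefault(r.human_gene, []).append(r)

    category_counts = {c: 0 for c in CATEGORY_LABELS}
    genes_with_model = 0
    strong_or_moderate = 0
    unreported_strong = 0
    for gene, recs in by_gene.items():
        best = gene_best_score(recs)
        if best is None:
            continue
        genes_with_model += 1
        cat = classify(best)
        category_counts[cat] += 1
        if cat in ("strong_rescue", "moderate_rescue"):
            strong_or_moderate += 1
        if cat == "strong_rescue" and not any(r.prior_report for r in recs):
            unreported_strong += 1

    orthologs = {r.fly_ortholog for r in records if r.fly_ortholog}
    return {
        "n_genes": len(by_gene),
        "n_genes_with_model": genes_with_model,
        "n_distinct_orthologs": len(orthologs),
        "category_counts": category_counts,
        "n_strong_or_moderate_rescue": strong_or_moderate,
        "n_unreported_strong_rescue": unreported_strong,
    }


def load_screen_table(path=None) -> list[ScreenRecord]:
    """Load a screen table TSV into records.

    With no path, loads the bundled fixture transcribed from the c9ALS
    screen results. Expected columns: human_gene, fly_symbol,
    model_available (Yes/No), score (decimal, 'Lethal', or empty),
    interpretation, reference. The human_gene column repeats for genes
    with multiple orthologs.
    """
    if path is None:
        path = resources.files("targetscout.data") / "table3_screen.tsv"
    tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for i, row in tab.iterrows():
        available = row["model_available"].strip().lower() == "yes"
        raw_score = row.get("score", "").strip()
        lethal = raw_score.lower() == "lethal"
        scores: list[float] = []
        if available and raw_score and not lethal:
            try:
                mean = float(raw_score)
            except ValueError:
                raise DataError(f"{path}: row {i + 2}: bad score {raw_score!r}")
            # The published table stores the already-aggregated ortholog
            # mean; represent it as the two-offspring split that produces
            # it so aggregation round-trips (x.5 means a -4/-3 style split).
            if mean == int(mean):
                scores = [mean]
            else:
                scores = [mean - 0.5, mean + 0.5]
        records.append(
            ScreenRecord(
                human_gene=row["human_gene"],
                fly_ortholog=row["fly_symbol"],
                model_available=available,
                offspring_scores=scores,
                lethal=lethal,
                prior_report=row.get("reference", "").strip() or None,
            )
        )
    return records
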