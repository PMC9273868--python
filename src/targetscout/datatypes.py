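"""Shared container types for the analysis pipeline.

Expression data live in pandas objects (genes as the index, samples as
columns, already on the log2 scale); the dataclasses here carry the
metadata the pipeline needs to route a comparison into the right
meta-analysis group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError

#: The six meta-analysis groups: two CNS transcriptomic groups (split by
#: ALS subtype) and four patient-derived motor-neuron (diMN) groups
#: (transcriptomic and proteomic, each split by subtype).
GROUP_IDS = (
    "CNS-fALS",
    "CNS-sALS",
    "diMN-tx-fALS",
    "diMN-tx-sALS",
    "diMN-prot-fALS",
    "diMN-prot-sALS",
)

SUBTYPES = ("fALS", "sALS")
MODALITIES = ("microarray", "RNA-seq", "SWATH-MS")


@dataclass
class ComparisonDataset:
    """One case-control cohort on the log2 scale.

    Parameters
    ----------
    matrix
        Genes x samples expression/abundance values, log2 scale.
    labels
        Mapping of sample id to ``"case"`` or ``"control"``; must cover
        every column of ``matrix``.
    subtype
        ``"fALS"`` or ``"sALS"``.
    modality
        ``"microarray"``, ``"RNA-seq"`` or ``"SWATH-MS"``.
    group_id
        One of the six meta-analysis groups (:data:`GROUP_IDS`).
    source_name
        Free-text provenance (tissue, series id, ...).
    """

    matrix: pd.DataFrame
    labels: dict[str, str]
    subtype: str
    modality: str
    group_id: str
    source_name: str = ""

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise DataError(f"unknown subtype {self.subtype!r}")
        if self.modality not in MODALITIES:
            raise DataError(f"unknown modality {self.modality!r}")
        if self.group_id not in GROUP_IDS:
            raise DataError(f"unknown group id {self.group_id!r}")
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()][:3]
            raise DataError(f"duplicate gene ids in matrix: {list(dupes)}")
        missing = set(self.matrix.columns) - set(self.labels)
        if missing:
            raise DataError(f"samples without labels: {sorted(missing)[:3]}")
        bad = set(self.labels.values()) - {"case", "control"}
        if bad:
            raise DataError(f"labels must be case/control, got {sorted(bad)}")

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.labels[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.matrix.columns if self.labels[s] == "control"]

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index


@dataclass
class GeneAnnotations:
    """Per-gene annotation flags driving the druggability filter cascade.

    ``table`` is indexed by gene with columns ``druggable_class``
    (categorical string or empty for none), ``has_small_molecule``,
    ``is_essential``, ``aging_associated`` (booleans) and
    ``novelty_level`` (ordinal int, higher = more novel).
    """

    table: pd.DataFrame

    REQUIRED = (
        "druggable_class",
        "has_small_molecule",
        "is_essential",
        "aging_associated",
        "novelty_level",
    )

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise DataError(f"annotation table missing columns {sorted(missing)}")

    def covers(self, genes) -> bool:
        return set(genes) <= set(self.table.index)


@dataclass
class TargetChronology:
    """Year each target first entered a clinical trial, one row per gene.

    ``table`` has columns ``gene`` and ``year`` (integers).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.table.columns) < {"gene", "year"}:
            raise DataError("chronology needs 'gene' and 'year' columns")
        if self.table["gene"].duplicated().any():
            raise DataError("chronology has duplicate gene records")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class StudyBundle:
    """Everything a full pipeline run consumes, plus the planted truth."""

    comparisons: list[ComparisonDataset]
    annotations: GeneAnnotations
    score_tables: pd.DataFrame  # genes x score families
    chronology: TargetChronology
    pathway_db: "object"  # PathwayCollection; typed loosely to avoid a cycle
    truth: dict = field(default_factory=dict)
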