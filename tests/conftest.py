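import numpy as np
import pandas as pd
import pytest

from targetscout import synthetic_data as sd
from targetscout.datatypes import ComparisonDataset


def make_comparison(
    case: np.ndarray,
    control: np.ndarray,
    genes=None,
    group_id: str = "CNS-fALS",
    subtype: str = "fALS",
    modality: str = "RNA-seq",
) -> ComparisonDataset:
    """Assemble a ComparisonDataset from raw case/control arrays."""
    n_genes = case.shape[0]
    genes = genes or [f"G{i:05d}" for i in range(n_genes)]
    n_case, n_ctrl = case.shape[1], control.shape[1]
    cols = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_ctrl)]
    mat = pd.DataFrame(np.hstack([case, control]), index=genes, columns=cols)
    labels = {c: ("case" if c.startswith("case") else "control") for c in cols}
    return ComparisonDataset(
        matrix=mat,
        labels=labels,
        subtype=subtype,
        modality=modality,
        group_id=group_id,
        source_name="test",
    )


@pytest.fixture(scope="session")
def paper_fixtures():
    return sd.load_paper_fixtures()


@pytest.fixture(scope="session")
def screen_records(paper_fixtures):
    return paper_fixtures[2]


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic bundle with planted up/down targets."""
    cfg = sd.StudyConfig(
        n_genes=400,
        seed=11,
        planted_targets=[
            sd.PlantedTarget("G00003", "up", 1.5, 1.0),
            sd.PlantedTarget("G00007", "down", 1.5, 1.0),
        ],
        planted_pathways=[sd.PlantedPathway("PLANT_UP", "up", 0.05, n_genes=40)],
        n_background_pathways=25,
    )
    return cfg, sd.generate_study(cfg)
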