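"""Grouping, consistency, metascore and filter-cascade behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetscout import synthetic_data as sd
from targetscout import target_prioritization as tp
from targetscout.datatypes import GeneAnnotations
from targetscout.errors import ConfigurationError, UndefinedStatisticError


# ---------------------------------------------------------------- grouping
def test_build_groups_partitions_study_design():
    bundle = sd.generate_study(sd.StudyConfig(n_genes=10, n_background_pathways=2))
    groups = tp.build_groups(bundle.comparisons)
    sizes = sorted(len(g) for g in groups)
    assert len(groups) == 6
    assert sizes == [1, 1, 1, 1, 5, 7]
    seen = [id(c) for g in groups for c in g.comparisons]
    assert sorted(seen) == sorted(id(c) for c in bundle.comparisons)


def test_build_groups_empty_and_singletons():
    assert tp.build_groups([]) == []
    bundle = sd.generate_study(sd.StudyConfig(n_genes=10, n_background_pathways=2))
    one_per_group = {c.group_id: c for c in bundle.comparisons}
    groups = tp.build_groups(list(one_per_group.values()))
    assert len(groups) == 6 and all(len(g) == 1 for g in groups)


# ------------------------------------------------------------- consistency
@pytest.mark.parametrize(
    "lfcs,direction,expected",
    [
        ([0.5, 0.2, 0.9, 0.1, -0.3], "up", 80),
        ([0.5, 0.2, 0.9, 0.1, 0.4, 0.6, -0.3], "up", 86),  # 6/7 rounds half-up
        ([-1, -1, -1, -1, -1], "up", 0),
        ([0.2, -0.4, -0.1, -0.8, -0.2, -0.5, -0.6], "down", 86),
        ([0.0, 1.0], "up", 50),  # exact zero counts toward neither side
        ([0.0, 1.0], "down", 0),
    ],
)
def test_consistency_examples(lfcs, direction, expected):
    assert tp.consistency(lfcs, direction) == expected


def test_consistency_empty_errors():
    with pytest.raises(UndefinedStatisticError):
        tp.consistency([], "up")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=12))
def test_consistency_directions_sum_below_100_pre_rounding(lfcs):
    n = len(lfcs)
    up = sum(1 for x in lfcs if x > 0)
    down = sum(1 for x in lfcs if x < 0)
    assert up + down <= n
    assert (up + down == n) == all(x != 0 for x in lfcs)
    # rounded percentages never jointly exceed 100 by more than rounding slack
    assert tp.consistency(lfcs, "up") + tp.consistency(lfcs, "down") <= 101


# --------------------------------------------------------------- metascore
def test_metascore_single_family_preserves_order():
    scores = pd.DataFrame(
        {"omics": [3.0, 1.0, 2.0]}, index=["A", "B", "C"]
    )
    meta = tp.metascore(scores, ["omics"])
    assert list(meta.index) == ["A", "C", "B"]


def test_metascore_identical_families_weight_invariant():
    scores = pd.DataFrame(
        {"omics": [3.0, 1.0, 2.0], "text": [3.0, 1.0, 2.0]}, index=list("ABC")
    )
    m1 = tp.metascore(scores, ["omics", "text"], {"omics": 1, "text": 1})
    m2 = tp.metascore(scores, ["omics", "text"], {"omics": 5, "text": 0.1})
    assert list(m1.index) == list(m2.index) == ["A", "C", "B"]


def test_metascore_matches_brute_force_mean_ranks():
    """Five-gene table, equal weights over two families: the order must
    match exhaustive hand computation of mean ranks."""
    scores = pd.DataFrame(
        {"omics": [5.0, 4.0, 3.0, 2.0, 1.0], "text": [1.0, 5.0, 4.0, 3.0, 2.0]},
        index=list("ABCDE"),
    )
    # ranks (ascending): omics A5 B4 C3 D2 E1; text A1 B5 C4 D3 E2
    # mean ranks: A3.0 B4.5 C3.5 D2.5 E1.5 -> B, C, A, D, E
    meta = tp.metascore(scores, ["omics", "text"])
    assert list(meta.index) == ["B", "C", "A", "D", "E"]


def test_metascore_zero_weights_rejected():
    scores = pd.DataFrame({"omics": [1.0]}, index=["A"])
    with pytest.raises(ConfigurationError):
        tp.metascore(scores, ["omics"], {"omics": 0.0})


def test_metascore_tie_break_is_lexicographic():
    scores = pd.DataFrame({"omics": [1.0, 1.0, 1.0]}, index=["C", "A", "B"])
    assert list(tp.metascore(scores, ["omics"]).index) == ["A", "B", "C"]


# ----------------------------------------------------------------- filters
def _annotations(rows):
    tab = pd.DataFrame(rows).set_index("gene")
    return GeneAnnotations(tab)


@pytest.fixture()
def toy_annotations():
    return _annotations(
        [
            {"gene": f"G{i}", "druggable_class": "GPCR", "has_small_molecule": True,
             "is_essential": i == 1, "aging_associated": False, "novelty_level": 2}
            for i in range(60)
        ]
    )


def test_essential_gene_excluded(toy_annotations):
    cfg = tp.FilterConfig(top_k=50)
    out = tp.apply_filters([f"G{i}" for i in range(5)], toy_annotations, cfg)
    assert "G1" not in out and "G0" in out


def test_all_filters_off_truncates_only(toy_annotations):
    cfg = tp.FilterConfig(
        require_druggable_class=False,
        require_small_molecule=False,
        exclude_essential=False,
        top_k=3,
    )
    ranked = [f"G{i}" for i in range(10)]
    assert tp.apply_filters(ranked, toy_annotations, cfg) == ranked[:3]


def test_sixty_eligible_truncated_to_top_fifty(toy_annotations):
    cfg = tp.FilterConfig(exclude_essential=False, top_k=50)
    ranked = [f"G{i}" for i in range(60)]
    out = tp.apply_filters(ranked, toy_annotations, cfg)
    assert len(out) == 50
    assert out == ranked[:50]


def test_apply_filters_idempotent_and_order_preserving(toy_annotations):
    cfg = tp.FilterConfig(top_k=50)
    ranked = [f"G{i}" for i in range(60)]
    once = tp.apply_filters(ranked, toy_annotations, cfg)
    assert tp.apply_filters(once, toy_annotations, cfg) == once
    positions = [ranked.index(g) for g in once]
    assert positions == sorted(positions)


def test_novel_mode_requires_omics_only():
    with pytest.raises(ConfigurationError):
        tp.FilterConfig(novelty_mode="novel", enabled_families=("omics", "text"))
    cfg = tp.FilterConfig(novelty_mode="novel", enabled_families=("omics",))
    assert cfg.novelty_mode == "novel"


# ------------------------------------------------------------- candidates
def _group_with_lfcs(group_id, per_comp_lfcs, gene="TG"):
    effects = [
        pd.DataFrame({"gene": [gene], "lfc": [x], "p_value": [0.04]})
        for x in per_comp_lfcs
    ]
    g = tp.MetaGroup(group_id, comparisons=[None] * len(effects))
    g.effects = effects
    return g


def test_cns_candidate_requires_eighty_percent_one_direction():
    ann = _annotations(
        [{"gene": "TG", "druggable_class": "GPCR", "has_small_molecule": True,
          "is_essential": False, "aging_associated": False, "novelty_level": 2}]
    )
    cfg = tp.FilterConfig()
    fals = _group_with_lfcs("CNS-fALS", [1, 1, 1, 1, -1])  # 80% up
    sals = _group_with_lfcs("CNS-sALS", [1, -1, 1, -1, 1, -1, -1])
    picked = tp.select_candidates({"CNS-fALS": ["TG"]}, [fals, sals], ann, cfg)
    assert [c.gene for c in picked] == ["TG"]
    assert picked[0].consistency_up_fals == 80

    # 86% down (14% up) qualifies through the down direction
    sals_down = _group_with_lfcs("CNS-sALS", [0.2, -1, -1, -1, -1, -1, -1])
    fals_flat = _group_with_lfcs("CNS-fALS", [1, -1, 1, -1, 1])
    picked = tp.select_candidates(
        {"CNS-sALS": ["TG"]}, [fals_flat, sals_down], ann, cfg
    )
    assert picked and picked[0].consistency_up_sals == 14

    # below the gate in both directions -> rejected
    weak = _group_with_lfcs("CNS-fALS", [1, 1, 1, -1, -1])
    picked = tp.select_candidates({"CNS-fALS": ["TG"]}, [weak, sals], ann, cfg)
    assert picked == []


def test_gene_absent_from_every_top_list_rejected():
    ann = _annotations(
        [{"gene": "TG", "druggable_class": "GPCR", "has_small_molecule": True,
          "is_essential": False, "aging_associated": False, "novelty_level": 2}]
    )
    fals = _group_with_lfcs("CNS-fALS", [1, 1, 1, 1, 1])
    picked = tp.select_candidates({"CNS-fALS": []}, [fals], ann, tp.FilterConfig())
    assert picked == []


def test_dimn_candidate_carries_group_effect():
    ann = _annotations(
        [{"gene": "TG", "druggable_class": "GPCR", "has_small_molecule": True,
          "is_essential": False, "aging_associated": True, "novelty_level": 2}]
    )
    g = _group_with_lfcs("diMN-tx-fALS", [0.3])
    picked = tp.select_candidates({"diMN-tx-fALS": ["TG"]}, [g], ann, tp.FilterConfig())
    assert picked[0].compartment == "diMN"
    assert picked[0].dimn_lfc == pytest.approx(0.3)
    assert picked[0].aging_flag is True
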