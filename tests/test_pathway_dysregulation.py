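"""Pathway scoring, dysregulation calling, enrichment and networks."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetscout import pathway_dysregulation as pw
from targetscout.errors import ConfigurationError, DataError, UndefinedStatisticError


def _effects(lfcs, ps=None, genes=None):
    genes = genes or [f"g{i}" for i in range(len(lfcs))]
    ps = ps if ps is not None else [0.01] * len(lfcs)
    return pd.DataFrame({"gene": genes, "lfc": lfcs, "p_value": ps})


# --------------------------------------------------------- activation score
def test_activation_score_examples():
    eff = _effects([0.0, 0.0, 0.0])
    assert pw.activation_score(eff, {"g0", "g1", "g2"}) == 0.0

    eff = _effects([1.0, -1.0])
    assert pw.activation_score(eff, {"g0", "g1"}) == pytest.approx(0.0)

    eff = _effects([0.4, 0.2, 0.2, -0.2])
    assert pw.activation_score(
        eff, {"g0", "g1", "g2", "g3"}, p_gate=None
    ) == pytest.approx(0.15)


def test_activation_score_gating_downweights_insignificant_genes():
    eff = _effects([1.0, -1.0], ps=[0.01, 0.5])
    # significant +1 keeps weight 1, insignificant -1 drops to 0.5
    assert pw.activation_score(eff, {"g0", "g1"}) == pytest.approx(
        (1.0 - 0.5) / 1.5
    )


def test_activation_score_topology_weights():
    eff = _effects([1.0, 0.0])
    score = pw.activation_score(eff, {"g0", "g1"}, topology={"g0": 3.0, "g1": 1.0})
    assert score == pytest.approx(0.75)


def test_activation_score_no_overlap_errors():
    with pytest.raises(UndefinedStatisticError):
        pw.activation_score(_effects([1.0]), {"absent"})


# ------------------------------------------------------------------ calling
def _scores(rows, pathways=("P1",)):
    return pd.DataFrame(
        np.atleast_2d(rows), index=list(pathways),
        columns=[f"c{i}" for i in range(np.atleast_2d(rows).shape[1])],
    )


def test_call_requires_80pct_and_magnitude():
    crit = pw.DysregulationCriteria()
    calls = pw.call_dysregulated(
        _scores([0.02, 0.015, 0.012, 0.011, -0.005]), "CNS-fALS", crit
    )
    assert calls == [pw.DysregulationCall("P1", "activated", "CNS-fALS")]

    # all positive but below the 0.01 magnitude floor
    assert pw.call_dysregulated(_scores([0.005] * 5), "CNS-fALS", crit) == []

    # 3 of 5 positive: 60% < 80%
    assert (
        pw.call_dysregulated(_scores([0.02, 0.02, 0.02, -0.02, -0.02]), "g", crit)
        == []
    )


def test_call_inhibited_direction_and_exact_fraction():
    crit = pw.DysregulationCriteria()
    calls = pw.call_dysregulated(_scores([-0.02, -0.02, -0.02, -0.02, 0.01]), "g", crit)
    assert calls[0].direction == "inhibited"
    # on 7 comparisons the 80% gate needs 6 agreeing signs (no rounding)
    assert pw.call_dysregulated(_scores([0.02] * 5 + [-0.02] * 2), "g", crit) == []
    assert pw.call_dysregulated(_scores([0.02] * 6 + [-0.02]), "g", crit) != []


def test_call_zero_score_counts_neither_direction():
    crit = pw.DysregulationCriteria()
    # 4 positive, 1 exactly zero: 4/5 = 80% -> called
    assert pw.call_dysregulated(_scores([0.02, 0.02, 0.02, 0.02, 0.0]), "g", crit)


def test_call_monotone_in_agreeing_comparisons():
    """Appending a comparison whose score agrees in sign never removes an
    activation call."""
    crit = pw.DysregulationCriteria()
    base = [0.02, 0.02, 0.02, 0.02, -0.005]
    assert pw.call_dysregulated(_scores(base), "g", crit)
    assert pw.call_dysregulated(_scores(base + [0.03]), "g", crit)


# --------------------------------------------------------------- enrichment
def test_process_enrichment_examples():
    assert pw.process_enrichment(pw.ProcessEnrichmentCounts(N=10, K=2, n=3, r=0)) == 1.0
    assert pw.process_enrichment(
        pw.ProcessEnrichmentCounts(N=6, K=2, n=3, r=1)
    ) == pytest.approx(0.8, abs=1e-12)


def test_bonferroni():
    assert pw.bonferroni(0.001, 27) == pytest.approx(0.027)
    assert pw.bonferroni(0.2, 27) == 1.0
    with pytest.raises(ConfigurationError):
        pw.bonferroni(0.1, 0)


def test_process_enrichment_matches_enumeration_for_small_n():
    """The printed-index formula equals exhaustive enumeration of all
    n-subsets: p = P(at least r of the n drawn are among the K marked)."""
    for N in range(1, 13):
        for K in range(0, N + 1):
            for n in range(K, N + 1):
                hist = [0] * (n + 1)
                marked = set(range(K))
                for subset in itertools.combinations(range(N), n):
                    hist[len(marked.intersection(subset))] += 1
                total = sum(hist)
                for r in range(0, N + 1, max(1, N // 3)):
                    got = pw.process_enrichment(
                        pw.ProcessEnrichmentCounts(N=N, K=K, n=n, r=r)
                    )
                    exact = sum(hist[min(r, n + 1) :]) / total
                    assert got == pytest.approx(exact, abs=1e-12)


def test_conventional_orientation_swaps_roles():
    # conventional: P(X >= K) for X ~ HG(N, r, n)
    c = pw.ProcessEnrichmentCounts(N=6, K=1, n=3, r=2)
    got = pw.process_enrichment(c, orientation="conventional")
    # X ~ HG(6, 2, 3): P(X >= 1) = 1 - C(4,3)/C(6,3) = 1 - 4/20
    assert got == pytest.approx(0.8, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(1, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
def test_bonferroni_adjustment_bounds(N, K, n, r):
    K, n, r = min(K, N), min(n, N), min(r, N)
    K = min(K, n)
    raw = pw.process_enrichment(pw.ProcessEnrichmentCounts(N=N, K=K, n=n, r=r))
    adj = pw.bonferroni(raw, 27)
    assert raw - 1e-12 <= adj <= 1.0


# ------------------------------------------------------------------ network
def _call(p, direction="activated", group="CNS-fALS"):
    return pw.DysregulationCall(p, direction, group)


def test_similarity_network_identical_and_disjoint_sets():
    sets = {"A": {"x", "y"}, "B": {"x", "y"}, "C": {"z", "w"}}
    g = pw.similarity_network([_call(p) for p in "ABC"], sets)
    assert g.has_edge("A", "B") and g["A"]["B"]["weight"] == 1.0
    assert not g.has_edge("A", "C") and not g.has_edge("B", "C")


def test_combined_coefficient_option():
    a, b = {"a", "b", "c", "d"}, {"c", "d", "e", "f"}
    sets = {"A": a, "B": b}
    calls = [_call("A"), _call("B")]
    jac = pw.similarity_network(calls, sets, coefficient="jaccard")
    assert not jac.has_edge("A", "B")  # Jaccard 1/3 < 0.35
    comb = pw.similarity_network(calls, sets, coefficient="combined")
    assert comb.has_edge("A", "B")
    assert comb["A"]["B"]["weight"] == pytest.approx(0.5 * (1 / 3 + 1 / 2))


def test_network_symmetric_and_self_loop_free():
    rng = np.random.default_rng(2)
    sets = {
        f"P{i}": set(rng.choice(50, size=10, replace=False).tolist())
        for i in range(12)
    }
    g = pw.similarity_network([_call(p) for p in sets], sets)
    assert nx.number_of_selfloops(g) == 0
    assert g.number_of_nodes() == 12


def test_reported_clusters_threshold():
    g = nx.Graph()
    g.add_edges_from([(1, 2), (2, 3), (3, 4)])  # component of 4
    g.add_edges_from([(10, 11), (11, 12)])  # component of 3
    clusters = pw.reported_clusters(g, min_cluster=4)
    assert clusters == [{1, 2, 3, 4}]


def test_gmt_parse_error_reports_line(tmp_path):
    bad = tmp_path / "bad.gmt"
    bad.write_text("ok\tdesc\tg1\tg2\nshort\tdesc\n")
    with pytest.raises(DataError, match="line 2"):
        pw.load_gmt(bad)


def test_enrichment_report_counts(small_bundle):
    _, bundle = small_bundle
    db = bundle.pathway_db
    some = sorted(db.pathways)[:6]
    calls = [_call(p) for p in some]
    rep = pw.enrichment_report(calls, db)
    assert set(rep.columns) >= {"process", "K", "n", "r", "N", "raw_p", "adjusted_p"}
    assert (rep["n"] == 6).all()
    assert (rep["N"] == len(db)).all()
    assert (rep["adjusted_p"] >= rep["raw_p"] - 1e-12).all()
    assert rep["K"].sum() == 6  # every called pathway maps to exactly one process
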