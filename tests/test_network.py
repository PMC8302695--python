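"""Constraint construction, BIC scoring and structure search."""

import math

import numpy as np
import pandas as pd
import pytest

from syntrobn import (DAG, EdgeConstraintSet, SearchOptions, bic_score,
                      build_blacklist, enumerate_dags, exhaustive_search,
                      hill_climb)


def test_dag_rejects_cycles_self_loops_and_unknown_nodes():
    DAG(["a", "b"], [("a", "b")])
    with pytest.raises(ValueError, match="cycle"):
        DAG(["a", "b"], [("a", "b"), ("b", "a")])
    with pytest.raises(ValueError, match="self-loop"):
        DAG(["a"], [("a", "a")])
    with pytest.raises(ValueError, match="unknown node"):
        DAG(["a"], [("a", "b")])


def test_constraints_reject_overlap_and_cyclic_whitelist():
    with pytest.raises(ValueError, match="black- and whitelisted"):
        EdgeConstraintSet(blacklist={("a", "b")}, whitelist={("a", "b")})
    with pytest.raises(ValueError, match="cyclic"):
        EdgeConstraintSet(whitelist={("a", "b"), ("b", "a")})


# -- blacklist construction --------------------------------------------------


def test_blacklist_forbids_backward_edges_only():
    cons = build_blacklist({"a": "fermenter", "b": "methanogen"})
    assert ("b", "a") in cons.blacklist and ("a", "b") not in cons.blacklist


def test_blacklist_counts_match_pairwise_enumeration():
    tiers = {"f1": "fermenter", "f2": "fermenter",
             "m1": "methanogen", "m2": "methanogen", "out": "output"}
    cons = build_blacklist(tiers)
    # 2x2 methanogen->fermenter plus 1x4 output->everything
    assert len(cons.blacklist) == 8
    assert all(e[0] in ("m1", "m2", "out") for e in cons.blacklist)


def test_fermenter_and_geobacter_form_one_tier_class():
    cons = build_blacklist({"f": "fermenter", "g": "geobacter"})
    assert ("f", "g") not in cons.blacklist
    assert ("g", "f") not in cons.blacklist
    strict = build_blacklist({"f": "fermenter", "g": "geobacter"},
                             allow_within_tier=False)
    assert ("f", "g") in strict.blacklist and ("g", "f") in strict.blacklist


def test_environment_feeds_everything_but_output_feeds_nothing():
    tiers = {"e": "environment", "f": "fermenter", "out": "output"}
    cons = build_blacklist(tiers)
    assert ("e", "f") not in cons.blacklist
    assert ("e", "out") not in cons.blacklist
    assert ("out", "e") in cons.blacklist
    with pytest.raises(ValueError, match="tier"):
        build_blacklist({"x": "plant"})


# -- BIC ---------------------------------------------------------------------


def test_bic_single_node_matches_closed_form_gaussian_mle():
    data = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
    # variance 2/3; LL = -(3/2)(ln(2*pi*2/3)+1); penalty (2/2) ln 3
    expected = -1.5 * (math.log(2 * math.pi * 2 / 3) + 1) - math.log(3)
    assert bic_score(DAG(["x"]), data) == pytest.approx(expected, abs=1e-9)


def test_bic_decomposes_over_independent_blocks(rng):
    data = pd.DataFrame(rng.normal(size=(60, 4)),
                        columns=["a", "b", "c", "d"])
    dag = DAG(["a", "b", "c", "d"], [("a", "b"), ("c", "d")])
    left = bic_score(DAG(["a", "b"], [("a", "b")]), data[["a", "b"]])
    right = bic_score(DAG(["c", "d"], [("c", "d")]), data[["c", "d"]])
    assert bic_score(dag, data) == pytest.approx(left + right, rel=1e-12)


def test_bic_penalizes_an_irrelevant_parent_at_large_n(rng):
    n = 2000
    x = rng.normal(size=n)
    y = 0.9 * x + rng.normal(0, 0.2, n)
    z = rng.normal(size=n)  # no influence on y
    data = pd.DataFrame({"x": x, "y": y, "z": z})
    lean = DAG(["x", "y", "z"], [("x", "y")])
    padded = DAG(["x", "y", "z"], [("x", "y"), ("z", "y")])
    assert bic_score(lean, data) > bic_score(padded, data)


# -- hill climbing -----------------------------------------------------------


def test_independent_variables_yield_empty_graph(rng):
    data = pd.DataFrame(rng.normal(size=(500, 2)), columns=["A", "B"])
    assert hill_climb(data).edges == frozenset()
    assert exhaustive_search(data).edges == frozenset()


def test_strong_pairwise_signal_is_recovered_with_blacklist(rng):
    x = rng.normal(size=500)
    y = x + rng.normal(0, 0.1, 500)
    data = pd.DataFrame({"X": x, "Y": y})
    cons = EdgeConstraintSet(blacklist={("Y", "X")})
    assert hill_climb(data, cons).edges == frozenset({("X", "Y")})
    assert exhaustive_search(data, cons).edges == frozenset({("X", "Y")})


def test_whitelisted_edge_is_always_retained(rng):
    data = pd.DataFrame(rng.normal(size=(200, 3)), columns=["A", "B", "C"])
    cons = EdgeConstraintSet(whitelist={("A", "B")})
    assert ("A", "B") in hill_climb(data, cons).edges


def test_search_is_deterministic(rng):
    data = pd.DataFrame(rng.normal(size=(120, 5)),
                        columns=list("abcde"))
    data["b"] += 0.9 * data["a"]
    data["d"] += 0.8 * data["c"]
    first = hill_climb(data)
    second = hill_climb(data)
    assert first.edges == second.edges and first.nodes == second.nodes


def test_constraints_hold_across_many_random_scenarios():
    """Learned DAGs are acyclic and honor black/whitelists, and never
    score below the whitelist-only starting graph."""
    names = list("abcd")
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(80, 4))
        x[:, 1] += rng.uniform(-1, 1) * x[:, 0]
        x[:, 3] += rng.uniform(-1, 1) * x[:, 2]
        data = pd.DataFrame(x, columns=names)
        black, white = set(), set()
        pairs = [(a, b) for a in names for b in names if a != b]
        rng.shuffle(pairs)
        if rng.random() < 0.7:
            black.add(pairs[0])
        if rng.random() < 0.5 and pairs[1] != pairs[0][::-1]:
            white.add(pairs[1])
        black -= white
        cons = EdgeConstraintSet(blacklist=black, whitelist=white)
        dag = hill_climb(data, cons)  # DAG constructor asserts acyclicity
        assert not (dag.edges & cons.blacklist)
        assert cons.whitelist <= dag.edges
        start = DAG(names, white)
        assert bic_score(dag, data) >= bic_score(start, data) - 1e-9


def test_plain_greedy_mode_is_available(rng):
    data = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
    data["b"] += data["a"]
    options = SearchOptions(tabu_off=True)
    dag = hill_climb(data, options=options)
    assert {("a", "b"), ("b", "a")} & set(dag.edges)


def test_zero_variance_column_is_rejected_before_search():
    data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="zero-variance"):
        hill_climb(data)


# -- exhaustive enumeration --------------------------------------------------


def test_dag_enumeration_counts_are_exact():
    assert sum(1 for _ in enumerate_dags(["a"])) == 1
    assert sum(1 for _ in enumerate_dags(["a", "b"])) == 3
    assert sum(1 for _ in enumerate_dags(["a", "b", "c"])) == 25
    cons = EdgeConstraintSet(whitelist={("a", "b")})
    for dag in enumerate_dags(["a", "b", "c"], cons):
        assert ("a", "b") in dag.edges


def test_single_node_optimum_is_the_empty_graph():
    data = pd.DataFrame({"x": [1.0, 2.0, 4.0]})
    assert exhaustive_search(data).edges == frozenset()


def test_enumeration_refuses_large_node_sets():
    with pytest.raises(ValueError, match="at most 5"):
        exhaustive_search(pd.DataFrame(np.zeros((3, 6)),
                                       columns=list("abcdef")))
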