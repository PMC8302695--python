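"""Synthetic generators: template SEM, expression, community, counts."""

import itertools

import numpy as np
import pandas as pd
import pytest

import syntrobn as sb
from syntrobn.synthetic import GroundTruthSEM, SEMNode, _CORE_TAXA


def brute_force_path_weight(sem, sources, target):
    """Independent oracle: enumerate all simple directed paths and sum
    coefficient products (valid because the graph is acyclic)."""
    import networkx as nx

    g = nx.DiGraph()
    for p, c, w in sem.edges:
        g.add_edge(p, c, w=w)
    total = 0.0
    for s in set(sources):
        if s not in g or target not in g:
            continue
        for path in nx.all_simple_paths(g, s, target):
            prod = 1.0
            for a, b in itertools.pairwise(path):
                prod *= g.edges[a, b]["w"]
            total += prod
    return total


# -- scenario config ---------------------------------------------------------


def test_scenario_config_validates_and_round_trips_yaml(tmp_path):
    with pytest.raises(ValueError):
        sb.ScenarioConfig(n_samples=2)
    with pytest.raises(ValueError):
        sb.ScenarioConfig(noise_sd=0.0)
    with pytest.raises(ValueError):
        sb.ScenarioConfig(n_distractor_taxa=-1)
    config = sb.ScenarioConfig(n_samples=50, iht_effect=0.5, seed=9)
    path = tmp_path / "scenario.yaml"
    config.to_yaml(path)
    assert sb.ScenarioConfig.from_yaml(path) == config


# -- template SEM ------------------------------------------------------------


def test_template_sem_satisfies_tier_ordering_and_sizes(template_sem):
    tiers = {n.name: n.tier for n in template_sem.nodes}
    rank = {"fermenter": 0, "geobacter": 0, "methanogen": 1, "output": 2}
    for p, c, _ in template_sem.edges:
        assert rank[tiers[p]] <= rank[tiers[c]]
    assert len(template_sem.nodes_with(tier="fermenter")) >= 4
    assert len(template_sem.nodes_with(tier="geobacter")) >= 3
    assert len(template_sem.nodes_with(tier="methanogen")) >= 3
    assert template_sem.nodes_with(tier="output") == ["ch4_production"]
    # distractor genes are fully disconnected
    wired = {v for p, c, _ in template_sem.edges for v in (p, c)}
    for k in range(1, 4):
        assert f"dist_gene_{k}" not in wired


def test_sem_constructor_rejects_backward_tier_edges():
    nodes = (SEMNode("m", "methanogen", "other"),
             SEMNode("f", "fermenter", "other"))
    with pytest.raises(ValueError, match="tier"):
        GroundTruthSEM(nodes, (("m", "f", 0.5),))


def test_zero_iht_effect_annihilates_all_iht_paths():
    sem = sb.build_template_sem(sb.ScenarioConfig(iht_effect=0.0))
    iht = sem.nodes_with(mechanism="IHT")
    assert sem.total_path_weight(iht, "ch4_production") == 0.0
    assert brute_force_path_weight(sem, iht, "ch4_production") == 0.0


def test_iht_dominant_scenario_has_larger_path_weight(template_sem):
    iht = template_sem.nodes_with(mechanism="IHT")
    diet = template_sem.nodes_with(mechanism="DIET")
    w_iht = template_sem.total_path_weight(iht, "ch4_production")
    w_diet = template_sem.total_path_weight(diet, "ch4_production")
    assert w_iht == pytest.approx(
        brute_force_path_weight(template_sem, iht, "ch4_production"))
    assert w_diet == pytest.approx(
        brute_force_path_weight(template_sem, diet, "ch4_production"))
    assert w_iht > w_diet  # iht_effect=0.8 vs diet_effect=0.2


def test_sem_serialization_round_trip(template_sem, tmp_path):
    e, n = tmp_path / "edges.tsv", tmp_path / "nodes.tsv"
    template_sem.write(e, n)
    back = GroundTruthSEM.read(e, n)
    assert back == template_sem


# -- expression simulation ---------------------------------------------------


def test_expression_is_seeded_nonnegative_and_metadata_complete(template_sem):
    a = sb.simulate_expression(template_sem, 30, seed=5)
    b = sb.simulate_expression(template_sem, 30, seed=5)
    assert a.values.equals(b.values)
    assert (a.values.to_numpy() >= 0).all()
    assert not a.metadata[["role", "tier", "mechanism"]].isna().any().any()
    c = sb.simulate_expression(template_sem, 30, seed=6)
    assert not a.values.equals(c.values)


def test_vanishing_noise_makes_output_linear_in_ancestors():
    config = sb.ScenarioConfig(noise_sd=1e-9)
    sem = sb.build_template_sem(config)
    table = sb.simulate_expression(sem, 60, seed=3)
    y = table.values["ch4_production"].to_numpy()
    x = table.values[["mvhA_meth", "mvhB_meth", "hdrB_meth"]].to_numpy()
    design = np.column_stack([np.ones(len(y)), x])
    residual = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    assert float(np.abs(residual).max()) < 1e-6


def test_sample_covariance_matches_closed_form_sem_covariance(template_sem):
    """Monte-Carlo check against the path-tracing covariance oracle at
    n=10000: every pair within 3 standard errors."""
    n = 10_000
    table = sb.simulate_expression(template_sem, n, seed=11)
    _, implied = template_sem.implied_moments()
    names = template_sem.node_names
    sample = np.cov(table.values[names].to_numpy(), rowvar=False, ddof=0)
    s = implied.to_numpy()
    se = np.sqrt((np.outer(np.diag(s), np.diag(s)) + s ** 2) / n)
    assert (np.abs(sample - s) <= 3.0 * se + 1e-12).all()


def test_distractor_genes_decorrelate_from_output(template_sem):
    table = sb.simulate_expression(template_sem, 2000, seed=13)
    ch4 = table.values["ch4_production"]
    for k in range(1, 4):
        r = np.corrcoef(table.values[f"dist_gene_{k}"], ch4)[0, 1]
        assert abs(r) < 0.08


# -- community simulation ----------------------------------------------------


def test_community_is_compositional_and_core_rule_exact(default_config):
    dna, rna, env = sb.simulate_community(default_config)
    for table in (dna, rna):
        values = table.values.to_numpy()
        assert (values >= 0).all()
        assert (values.sum(axis=1) <= 1.0 + 1e-12).all()
    core = sb.select_core_taxa(dna, rna)
    assert sorted(core) == sorted(sb.core_taxon_names())
    assert len(core) == 22
    assert "ch4_production" in env.variables
    assert env.n_samples == default_config.n_samples


def test_community_generator_is_seed_deterministic(default_config):
    a = sb.simulate_community(default_config)
    b = sb.simulate_community(default_config)
    for x, y in zip(a, b):
        assert x.values.equals(y.values)


def test_single_weighted_taxon_dominates_ch4_correlation():
    config = sb.ScenarioConfig(n_samples=1000, seed=4)
    target = _CORE_TAXA[5][0]
    dna, rna, env = sb.simulate_community(
        config, ch4_weights={target: 10.0})
    ch4 = env.values["ch4_production"]
    corrs = {t: abs(np.corrcoef(rna.values[t], ch4)[0, 1])
             for t, _ in _CORE_TAXA}
    assert max(corrs, key=corrs.get) == target


def test_infeasible_distractor_count_is_rejected():
    with pytest.raises(ValueError, match="infeasib"):
        sb.simulate_community(sb.ScenarioConfig(n_distractor_taxa=1000))


# -- count simulation --------------------------------------------------------


def test_counts_are_bounded_by_library_and_reproducible():
    config = sb.ScenarioConfig(n_samples=10, seed=2)
    counts, lengths, libs = sb.simulate_counts(config)
    assert (counts.to_numpy() >= 0).all()
    assert np.issubdtype(counts.to_numpy().dtype, np.integer)
    assert (counts.sum(axis=1) <= libs[counts.index]).all()
    assert (lengths > 0).all()
    counts2, lengths2, libs2 = sb.simulate_counts(config)
    assert counts.equals(counts2)
    assert lengths.equals(lengths2) and libs.equals(libs2)


def test_rpkm_pipeline_tracks_simulated_expression():
    """End-to-end: RPKM computed from simulated counts correlates with the
    generating expression values for every gene."""
    config = sb.ScenarioConfig(n_samples=40, seed=8)
    counts, lengths, libs = sb.simulate_counts(config)
    rpkm = sb.compute_rpkm(counts, lengths, libs)
    sem = sb.build_template_sem(config)
    # the count generator's expression table (same internal seed spawn)
    root = np.random.SeedSequence(config.seed)
    ss_expr, _ = root.spawn(2)
    expr = sb.simulate_expression(
        sem, config.n_samples, int(ss_expr.generate_state(1)[0] % (2 ** 31)))
    shared = [g for g in rpkm.variables if expr.values[g].var() > 0]
    for gene in shared:
        r = np.corrcoef(rpkm.values[gene], expr.values[gene])[0, 1]
        assert r > 0.5, gene
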