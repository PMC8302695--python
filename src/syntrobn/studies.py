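"""Replication studies: the package's headline experiments across seeds.

Each function reruns one complete analysis under fresh seeds and returns a
tidy DataFrame, so the same code backs the example scripts, the test suite
and the reproduction script. Seeds are ``base_seed + k`` for replicate k.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .knockout import (KnockoutScenario, default_scenarios,
                       run_knockout_experiment)
from .model import fit_mle
from .network import (EdgeConstraintSet, build_blacklist, exhaustive_search,
                      hill_climb)
from .preprocess import (assemble_model_matrix, drop_zero_variance,
                         minmax_normalize, select_core_taxa)
from .synthetic import (ScenarioConfig, build_template_sem,
                        simulate_community, simulate_expression)
from .validation import (CVOptions, community_reconstruction_report, loo_cv,
                         null_model_predict)


def gene_knockout_study(n_seeds: int = 50, base_seed: int = 0,
                        iht_effect: float = 0.8, diet_effect: float = 0.2,
                        noise_sd: float = 0.2, n_samples: int = 200,
                        mode: str = "retrain",
                        include_distractor_scenario: bool = True,
                        scenarios_subset: list[str] | None = None
                        ) -> pd.DataFrame:
    """Repeat the in-silico knockout experiment across seeds.

    Per seed: simulate gene expression from the template SEM, normalize,
    build the tier blacklist, and run the knockout scenarios (complete,
    delta_IHT, delta_DIET, optionally delta_distractor silencing only the
    disconnected distractor genes). Returns one row per (seed, scenario)
    with R², relative RMSE and the R² drop versus the complete network.
    """
    rows = []
    for k in range(n_seeds):
        config = ScenarioConfig(n_samples=n_samples, iht_effect=iht_effect,
                                diet_effect=diet_effect, noise_sd=noise_sd,
                                seed=base_seed + k)
        sem = build_template_sem(config)
        expression = simulate_expression(sem, config.n_samples, config.seed)
        normalized, _ = minmax_normalize(expression)
        constraints = build_blacklist(dict(normalized.metadata["tier"]))
        scenarios = default_scenarios(normalized.metadata)
        if include_distractor_scenario:
            distractors = [v for v in normalized.variables
                           if v.startswith("dist_gene_")]
            scenarios.append(KnockoutScenario("delta_distractor", distractors))
        if scenarios_subset is not None:
            keep = set(scenarios_subset) | {"complete"}
            scenarios = [s for s in scenarios if s.name in keep]
        results = run_knockout_experiment(
            normalized, constraints, scenarios, "ch4_production", mode=mode)
        for r in results:
            rows.append((config.seed, r.scenario, r.r_squared,
                         r.relative_rmse, r.delta_r_squared))
    return pd.DataFrame(rows, columns=["seed", "scenario", "r_squared",
                                       "relative_rmse", "delta_r_squared"])


def community_null_study(n_seeds: int = 20, base_seed: int = 0,
                         independent_taxa: bool = False,
                         n_samples: int | None = None) -> pd.DataFrame:
    """Compare BN and mean-null community reconstruction across seeds.

    Per seed: simulate a community, select the core population, assemble
    the activity + environment matrix, run LOO-CV for the network and the
    null model, and record their mean Bray–Curtis similarities over the
    core taxa.
    """
    rows = []
    for k in range(n_seeds):
        kwargs = {"seed": base_seed + k}
        if n_samples is not None:
            kwargs["n_samples"] = n_samples
        config = ScenarioConfig(**kwargs)
        dna, rna, environment = simulate_community(
            config, independent_taxa=independent_taxa)
        core = select_core_taxa(dna, rna)
        matrix = assemble_model_matrix([rna.select(core), environment])
        matrix, _ = drop_zero_variance(matrix)
        normalized, _ = minmax_normalize(matrix)
        constraints = build_blacklist(dict(normalized.metadata["tier"]))
        taxa = [v for v in core if v in normalized.variables]
        cv = loo_cv(normalized, constraints, taxa, CVOptions())
        null = null_model_predict(normalized, taxa)
        report = community_reconstruction_report(cv, null)
        rows.append((config.seed, report.bray_curtis_mean,
                     report.null_bray_curtis_mean))
    return pd.DataFrame(rows, columns=["seed", "bray_curtis_bn",
                                       "bray_curtis_null"])


def structure_agreement_study(n_seeds: int = 100, base_seed: int = 0,
                              n_samples: int = 200) -> pd.DataFrame:
    """Hill climbing versus exhaustive enumeration on 3-node problems.

    Per seed: draw a random 3-node linear-Gaussian generating model with
    well-separated signal (|coefficient| in [0.8, 1.2], noise sd in
    [0.1, 0.3]), optionally a random single-edge blacklist, then learn a
    structure with both searches under identical constraints. Records the
    two BIC scores, whether they agree, and whether either result violates
    the constraints.
    """
    from .network import bic_score

    rows = []
    names = ["n0", "n1", "n2"]
    for k in range(n_seeds):
        seed = base_seed + k
        rng = np.random.default_rng(seed)
        order = rng.permutation(3)
        possible = [(int(order[i]), int(order[j]))
                    for i in range(3) for j in range(i + 1, 3)]
        edges = [e for e in possible if rng.random() < 0.6]
        coefs = {e: float(rng.uniform(0.8, 1.2) * rng.choice([-1, 1]))
                 for e in edges}
        x = np.zeros((n_samples, 3))
        for v in order:
            x[:, v] = rng.normal(0.0, rng.uniform(0.1, 0.3), size=n_samples)
            for (a, b), w in coefs.items():
                if b == v:
                    x[:, v] += w * x[:, a]
            if not any(b == v for _, b in edges):
                x[:, v] = rng.normal(0.0, 1.0, size=n_samples)
        data = pd.DataFrame(x, columns=names)
        blacklist = set()
        if rng.random() < 0.5:
            a, b = rng.choice(3, size=2, replace=False)
            blacklist.add((names[a], names[b]))
        constraints = EdgeConstraintSet(blacklist=blacklist)
        hc = hill_climb(data, constraints)
        ex = exhaustive_search(data, constraints)
        hc_score = bic_score(hc, data)
        ex_score = bic_score(ex, data)
        violated = any(e in constraints.blacklist for e in hc.edges | ex.edges)
        rows.append((seed, hc_score, ex_score,
                     bool(hc_score >= ex_score - 1e-6), violated))
    return pd.DataFrame(rows, columns=["seed", "hc_score", "exhaustive_score",
                                       "agree", "constraint_violated"])


def coefficient_recovery_study(n_seeds: int = 20, base_seed: int = 0,
                               n_samples: int = 1000) -> pd.DataFrame:
    """ML parameter recovery on the template SEM with known structure.

    Per seed: simulate expression at the given depth, fit the true DAG by
    maximum likelihood, and record every edge coefficient (estimate vs
    truth) and every residual variance (estimate vs truth).
    """
    rows = []
    for k in range(n_seeds):
        config = ScenarioConfig(seed=base_seed + k)
        sem = build_template_sem(config)
        expression = simulate_expression(sem, n_samples, config.seed)
        bn = fit_mle(sem.dag(), expression)
        for parent, child, true_coef in sem.edges:
            rows.append((config.seed, "coefficient", f"{parent}->{child}",
                         true_coef, bn.coefficients[child][parent]))
        for node in sem.nodes:
            rows.append((config.seed, "residual_variance", node.name,
                         node.noise_sd ** 2,
                         bn.residual_variances[node.name]))
    return pd.DataFrame(rows, columns=["seed", "quantity", "name", "truth",
                                       "estimate"])
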