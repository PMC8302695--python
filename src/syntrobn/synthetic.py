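"""Seeded synthetic data with the structure the network analysis assumes.

Two generators are provided:

* a linear-Gaussian structural equation model (SEM) over a
  fermenter → *Geobacter* → methanogen → CH₄ gene network, with separately
  tunable path weights for the interspecies-hydrogen-transfer (IHT) route
  (H₂-evolution genes in fermenters, hydrogenase genes in *Geobacter*, the
  H₂-uptake ``mvhA``-like gene in the methanogen) and the direct-electron-
  transfer (DIET) route (``omc``/``pilA``-like genes in *Geobacter*, the
  polyferredoxin ``mvhB``-like gene in the methanogen);
* a compositional community generator producing 16S "DNA" (abundance) and
  "RNA" (activity) tables with a designated core population satisfying the
  >0.5% mean abundance / >50% occurrence rule, plus environmental and
  performance variables driven linearly by designated taxa activities.

Everything is driven by one integer seed through a spawned seed hierarchy,
so regenerating one table never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import LinearGaussianBN
from .network import DAG, _TIER_RANK
from .table import FeatureTable, default_metadata

#: Fixed weight of edges that belong to neither competing mechanism
#: (substrate-driven coupling inside the fermenter/Geobacter tiers).
BACKGROUND_WEIGHT = 0.7
#: Weight of the core-methanogenesis (hdr-like) contribution to CH4.
HDR_WEIGHT = 0.3


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-condition knobs for the synthetic generators.

    Defaults mirror the contrast the knockout analysis is built around: a
    dominant hydrogen-transfer route (``iht_effect=0.8``) with a weaker
    direct-electron-transfer route (``diet_effect=0.2``), moderate
    observation noise, and a sampling depth comparable to a three-batch
    triplicate reactor study (36 samples).
    """

    n_samples: int = 36
    iht_effect: float = 0.8
    diet_effect: float = 0.2
    noise_sd: float = 0.2
    seed: int = 0
    n_distractor_taxa: int = 3

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be at least 3")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_distractor_taxa < 0:
            raise ValueError("n_distractor_taxa must be non-negative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass(frozen=True)
class SEMNode:
    name: str
    tier: str
    mechanism: str
    intercept: float = 0.0
    noise_sd: float = 1.0


@dataclass(frozen=True)
class GroundTruthSEM:
    """Generating model: DAG, true edge coefficients, per-node noise."""

    nodes: tuple[SEMNode, ...]
    edges: tuple[tuple[str, str, float], ...]  # (parent, child, coefficient)

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        tiers = {n.name: n.tier for n in self.nodes}
        DAG(names, [(p, c) for p, c, _ in self.edges])  # acyclicity + names
        for n in self.nodes:
            if n.noise_sd <= 0:
                raise ValueError(f"non-positive noise_sd at {n.name!r}")
        for p, c, _ in self.edges:
            if not _tier_edge_allowed(tiers[p], tiers[c]):
                raise ValueError(
                    f"edge {p!r} ({tiers[p]}) -> {c!r} ({tiers[c]}) violates "
                    "the tier ordering")

    # -- views ---------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def dag(self) -> DAG:
        return DAG(self.node_names, [(p, c) for p, c, _ in self.edges])

    def metadata(self) -> pd.DataFrame:
        meta = default_metadata(self.node_names, role="gene")
        for n in self.nodes:
            meta.at[n.name, "tier"] = n.tier
            meta.at[n.name, "mechanism"] = n.mechanism
            if n.tier == "output":
                meta.at[n.name, "role"] = "output"
        return meta

    def nodes_with(self, *, tier: str | None = None,
                   mechanism: str | None = None) -> list[str]:
        out = []
        for n in self.nodes:
            if tier is not None and n.tier != tier:
                continue
            if mechanism is not None and n.mechanism != mechanism:
                continue
            out.append(n.name)
        return out

    def to_lgbn(self) -> LinearGaussianBN:
        """The SEM as a fitted-model object (variance = noise_sd²)."""
        coefficients: dict[str, dict[str, float]] = {n.name: {}
                                                     for n in self.nodes}
        for p, c, w in self.edges:
            coefficients[c][p] = w
        return LinearGaussianBN(
            dag=self.dag(),
            intercepts={n.name: n.intercept for n in self.nodes},
            coefficients=coefficients,
            residual_variances={n.name: n.noise_sd ** 2 for n in self.nodes},
        )

    def implied_moments(self):
        """Closed-form mean/covariance of the linear-Gaussian SEM."""
        return self.to_lgbn().implied_moments()

    def total_path_weight(self, sources, target: str) -> float:
        """Sum over all directed source→target paths of coefficient products."""
        children: dict[str, list[tuple[str, float]]] = {
            n.name: [] for n in self.nodes}
        for p, c, w in self.edges:
            children[p].append((c, w))
        memo: dict[str, float] = {}

        def weight_to_target(v: str) -> float:
            if v == target:
                return 1.0
            if v in memo:
                return memo[v]
            memo[v] = sum(w * weight_to_target(c) for c, w in children[v])
            return memo[v]

        return float(sum(weight_to_target(s) for s in set(sources)))

    # -- serialization -------------------------------------------------

    def write(self, edges_path: str | Path, nodes_path: str | Path) -> None:
        pd.DataFrame(list(self.edges),
                     columns=["parent", "child", "coefficient"]).to_csv(
            edges_path, sep="\t", index=False, float_format="%.17g")
        pd.DataFrame(
            [(n.name, n.intercept, n.noise_sd, n.tier, n.mechanism)
             for n in self.nodes],
            columns=["node", "intercept", "noise_sd", "tier", "mechanism"],
        ).to_csv(nodes_path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, edges_path: str | Path,
             nodes_path: str | Path) -> "GroundTruthSEM":
        e = pd.read_csv(edges_path, sep="\t", float_precision="round_trip")
        v = pd.read_csv(nodes_path, sep="\t", float_precision="round_trip")
        return cls(
            nodes=tuple(SEMNode(r.node, r.tier, r.mechanism,
                                float(r.intercept), float(r.noise_sd))
                        for r in v.itertuples()),
            edges=tuple((r.parent, r.child, float(r.coefficient))
                        for r in e.itertuples()),
        )


def _tier_edge_allowed(parent_tier: str, child_tier: str) -> bool:
    if parent_tier == "output":
        return False
    if parent_tier == "environment":
        return child_tier != "fermenter"
    if child_tier == "environment":
        return True
    return _TIER_RANK[parent_tier] <= _TIER_RANK[child_tier]


# ---------------------------------------------------------------------------
# Template gene-network SEM
# ---------------------------------------------------------------------------


def build_template_sem(config: ScenarioConfig) -> GroundTruthSEM:
    """Fixed-topology gene network with competing IHT and DIET routes.

    Fermenters express alcohol-metabolism genes (adhE-, dhaT-like) that
    drive H₂-evolving hydrogenases (hndC-, hyaB-like) and the *Geobacter*
    EET machinery (omcF-, pilA-like). Hydrogen flows to the methanogen's
    H₂-uptake complex (mvhA-like) through *Geobacter* hydrogenases (hox-,
    ech-like) with every IHT edge weighted ``iht_effect``; electrons flow
    directly to the polyferredoxin (mvhB-like) node with every DIET edge
    weighted ``diet_effect``. CH₄ production is a linear readout of the two
    methanogen entry points plus a core heterodisulfide-reductase
    (hdrB-like) term. Distractor genes are disconnected.
    """
    ferm_sd = 1.0  # exogenous nodes are standard Gaussians before rescaling
    sd = config.noise_sd
    iht, diet = config.iht_effect, config.diet_effect
    bg = BACKGROUND_WEIGHT
    nodes = [
        SEMNode("adhE_ferm", "fermenter", "other", 0.0, ferm_sd),
        SEMNode("dhaT_ferm", "fermenter", "other", 0.0, ferm_sd),
        SEMNode("hndC_ferm", "fermenter", "IHT", 0.0, sd),
        SEMNode("hyaB_ferm", "fermenter", "IHT", 0.0, sd),
        SEMNode("hox_geo", "geobacter", "IHT", 0.0, sd),
        SEMNode("ech_geo", "geobacter", "IHT", 0.0, sd),
        SEMNode("omcF_geo", "geobacter", "DIET", 0.0, sd),
        SEMNode("pilA_geo", "geobacter", "DIET", 0.0, sd),
        SEMNode("mvhA_meth", "methanogen", "IHT", 0.0, sd),
        SEMNode("mvhB_meth", "methanogen", "DIET", 0.0, sd),
        SEMNode("hdrB_meth", "methanogen", "other", 0.0, ferm_sd),
        SEMNode("ch4_production", "output", "other", 0.0, sd),
    ]
    nodes += [SEMNode(f"dist_gene_{k + 1}", "fermenter", "other", 0.0, ferm_sd)
              for k in range(config.n_distractor_taxa)]
    edges = [
        ("adhE_ferm", "hndC_ferm", bg),
        ("dhaT_ferm", "hyaB_ferm", bg),
        ("adhE_ferm", "omcF_geo", bg),
        ("omcF_geo", "pilA_geo", bg),
        ("hndC_ferm", "hox_geo", iht),
        ("hyaB_ferm", "ech_geo", iht),
        ("hox_geo", "mvhA_meth", iht),
        ("ech_geo", "mvhA_meth", iht),
        ("hndC_ferm", "mvhA_meth", iht),
        ("omcF_geo", "mvhB_meth", diet),
        ("pilA_geo", "mvhB_meth", diet),
        ("mvhA_meth", "ch4_production", iht),
        ("mvhB_meth", "ch4_production", diet),
        ("hdrB_meth", "ch4_production", HDR_WEIGHT),
    ]
    return GroundTruthSEM(tuple(nodes), tuple(edges))


def simulate_expression(sem: GroundTruthSEM, n: int, seed: int) -> FeatureTable:
    """Sample an expression-like table from the SEM.

    Nodes are drawn in topological order as
    ``intercept + Σ coef·parent + N(0, noise_sd)``; each column is then
    shifted (not truncated) to be non-negative, which preserves the
    linear-Gaussian covariance structure exactly.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    names = sem.node_names
    idx = {v: i for i, v in enumerate(names)}
    parents: dict[str, list[tuple[int, float]]] = {v: [] for v in names}
    for p, c, w in sem.edges:
        parents[c].append((idx[p], w))
    noise_sd = {node.name: node.noise_sd for node in sem.nodes}
    intercept = {node.name: node.intercept for node in sem.nodes}
    x = np.zeros((n, len(names)))
    for v in sem.dag().topological_order():
        j = idx[v]
        x[:, j] = intercept[v] + rng.normal(0.0, noise_sd[v], size=n)
        for pj, w in parents[v]:
            x[:, j] += w * x[:, pj]
    shift = np.maximum(0.0, -x.min(axis=0))
    x = x + shift
    values = pd.DataFrame(x, columns=names,
                          index=[f"S{i + 1}" for i in range(n)])
    return FeatureTable(values, sem.metadata())


# ---------------------------------------------------------------------------
# Community generator
# ---------------------------------------------------------------------------

_CORE_TAXA = (
    ("Ethanoligenens_OTU682", "fermenter"),
    ("Clostridium_OTU92", "fermenter"),
    ("Rhodocyclaceae_OTU196", "fermenter"),
    ("Desulfovibrio_OTU66", "fermenter"),
    ("Geobacter_OTU650", "geobacter"),
    ("Geobacter_OTU28", "geobacter"),
    ("Geobacter_OTU268", "geobacter"),
    ("Methanobacterium_OTU36", "methanogen"),
    ("Methanobacterium_OTU104", "methanogen"),
    ("Methanobacterium_OTU577", "methanogen"),
) + tuple((f"Bacteria_OTU{700 + k}", "fermenter") for k in range(12))

_ENV_VARS = ("biogas_rate", "cod_removal", "coulombic_efficiency",
             "acetate", "propionate", "ethanol", "ph", "effluent_toc")


def simulate_community(config: ScenarioConfig, *,
                       independent_taxa: bool = False,
                       ch4_weights: dict[str, float] | None = None
                       ) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """(dna, rna, environment) tables for a synthetic reactor community.

    Twenty-two core taxa carry latent log-abundances with (optionally)
    chained linear-Gaussian dependencies; ``n_distractor_taxa`` rare taxa
    are sporadic and fail the core rule. Abundances are closed by a
    softmax-style renormalization against a remainder bucket, so every row
    sums to at most 1. Environmental variables — a CH₄-production column
    plus eight reactor performance/chemistry variables — are linear
    functions of designated taxon activities (RNA relative abundance) plus
    Gaussian noise; ``ch4_weights`` overrides the per-taxon generating
    weights of the CH₄ column.
    """
    core = list(_CORE_TAXA)
    n_core = len(core)
    if config.n_distractor_taxa > 5 * n_core:
        raise ValueError("n_distractor_taxa infeasibly large vs core size")
    rare = [(f"rare_OTU{900 + k}", "fermenter")
            for k in range(config.n_distractor_taxa)]
    taxa = [t for t, _ in core] + [t for t, _ in rare]
    tiers = dict(core + rare)
    n = config.n_samples
    root = np.random.SeedSequence(config.seed)
    ss_dna, ss_rna, ss_env, ss_struct = root.spawn(4)
    rng_s = np.random.default_rng(ss_struct)

    # latent log-abundance baselines and (optional) dependency structure
    mu = rng_s.uniform(np.log(0.008), np.log(0.04), size=n_core)
    parent_of = np.full(n_core, -1)
    if not independent_taxa:
        for j in range(1, n_core):
            if rng_s.random() < 0.7:
                parent_of[j] = rng_s.integers(0, j)

    def latent(rng: np.random.Generator):
        z = np.empty((n, n_core))
        for j in range(n_core):
            own_sd = 0.5 if parent_of[j] < 0 else 0.25
            z[:, j] = mu[j] + rng.normal(0.0, own_sd, size=n)
            if parent_of[j] >= 0:
                # strong partner-tracking: latent correlation ~0.85
                z[:, j] += 0.9 * (z[:, parent_of[j]] - mu[parent_of[j]])
        return z

    rng_dna = np.random.default_rng(ss_dna)
    rng_rna = np.random.default_rng(ss_rna)
    z_dna = latent(rng_dna)
    # activity tracks the abundance realization: a per-taxon ribosomal
    # activity offset plus sample-level noise, not an independent community
    activity_offset = rng_s.normal(0.0, 0.3, size=n_core)
    z_rna = z_dna + activity_offset + rng_rna.normal(0.0, 0.2,
                                                     size=z_dna.shape)

    def close(z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mass = np.exp(z)
        if rare:
            rare_mass = np.exp(rng.normal(np.log(5e-4), 0.3,
                                          size=(n, len(rare))))
            present = rng.random((n, len(rare))) < 0.2
            rare_mass *= present
            mass = np.hstack([mass, rare_mass])
        # the bucket aggregates the long tail of rare taxa, so its mass is
        # large and statistically stable relative to any single core taxon
        remainder = np.exp(rng.normal(np.log(0.6), 0.05, size=(n, 1)))
        return mass / (mass.sum(axis=1, keepdims=True) + remainder[:, 0:1])

    samples = [f"S{i + 1}" for i in range(n)]
    dna_ab = pd.DataFrame(close(z_dna, rng_dna), index=samples, columns=taxa)
    rna_ab = pd.DataFrame(close(z_rna, rng_rna), index=samples, columns=taxa)

    def taxon_meta(role: str) -> pd.DataFrame:
        meta = default_metadata(taxa, role=role)
        for t in taxa:
            meta.at[t, "tier"] = tiers[t]
        return meta

    dna = FeatureTable(dna_ab, taxon_meta("taxon_dna"))
    rna = FeatureTable(rna_ab, taxon_meta("taxon_rna"))

    # environment/performance variables driven by designated taxa activities
    rng_env = np.random.default_rng(ss_env)
    if ch4_weights is None:
        ch4_weights = {"Methanobacterium_OTU36": 12.0,
                       "Geobacter_OTU650": 8.0,
                       "Geobacter_OTU268": -4.0}
    env = pd.DataFrame(index=samples)
    signal = np.zeros(n)
    for taxon, w in ch4_weights.items():
        signal += w * rna_ab[taxon].to_numpy()
    scale = max(float(np.std(signal)), 1e-9)
    env["ch4_production"] = 0.3 + signal + rng_env.normal(
        0.0, config.noise_sd * scale, size=n)
    for k, name in enumerate(_ENV_VARS):
        drivers = rng_env.choice(n_core, size=2, replace=False)
        w = rng_env.uniform(4.0, 12.0, size=2) * rng_env.choice([-1, 1], 2)
        sig = rna_ab.iloc[:, drivers].to_numpy() @ w
        s = max(float(np.std(sig)), 1e-9)
        env[name] = 1.0 + sig + rng_env.normal(0.0, config.noise_sd * s,
                                               size=n)
    env_meta = default_metadata(list(env.columns), role="environment",
                                tier="environment")
    env_meta.loc["ch4_production", ["role", "tier"]] = ["output", "output"]
    environment = FeatureTable(env, env_meta)
    return dna, rna, environment


def core_taxon_names() -> list[str]:
    """Names of the designated 22-member core population."""
    return [t for t, _ in _CORE_TAXA]


# ---------------------------------------------------------------------------
# Read-count generator (RPKM fixture)
# ---------------------------------------------------------------------------


def simulate_counts(config: ScenarioConfig
                    ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """(counts, gene_lengths_bp, library_sizes) for RPKM testing.

    Gene expression comes from the template SEM; per sample, reads are
    multinomially allocated to genes with probabilities proportional to
    expression × length, reserving a slice of the library for unassigned
    reads so per-sample totals never exceed the library size.
    """
    root = np.random.SeedSequence(config.seed)
    ss_expr, ss_counts = root.spawn(2)
    sem = build_template_sem(config)
    expr = simulate_expression(sem, config.n_samples,
                               int(ss_expr.generate_state(1)[0] % (2 ** 31)))
    genes = [v for v in expr.variables
             if expr.metadata.at[v, "role"] == "gene"]
    rng = np.random.default_rng(ss_counts)
    lengths = pd.Series(rng.integers(300, 3001, size=len(genes)),
                        index=genes, name="length_bp")
    libs = pd.Series(rng.integers(800_000, 1_200_001,
                                  size=config.n_samples),
                     index=expr.sample_ids, name="library_size")
    counts = np.zeros((config.n_samples, len(genes)), dtype=int)
    weights = (expr.values[genes].to_numpy() + 0.05) * lengths.to_numpy()
    for i in range(config.n_samples):
        p = 0.9 * weights[i] / weights[i].sum()
        p_full = np.append(p, 1.0 - p.sum())  # unassigned remainder
        draw = rng.multinomial(int(libs.iloc[i]), p_full)
        counts[i] = draw[:-1]
    return (pd.DataFrame(counts, index=expr.sample_ids, columns=genes),
            lengths, libs)
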