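"""Linear-Gaussian Bayesian network parameterization and prediction.

Each node is modeled as ``x_v = intercept_v + Σ_p coef_vp · x_p + ε_v`` with
``ε_v ~ N(0, σ²_v)``; the joint distribution over all nodes is multivariate
normal. Parameters are maximum-likelihood estimates: ordinary least squares
per family with the residual variance divided by n (not n − k) and floored
at 1e-12 so interpolating fits keep a finite likelihood.

Prediction supports two regimes:

``parents``
    Plug the observed parent values into the node equation — the local
    regression forecast. Requires every parent of a target to be observed.
``joint``
    Assemble the implied multivariate normal and return the exact
    conditional mean of the targets given whatever evidence is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .network import DAG, FamilyScorer, VARIANCE_FLOOR, _as_frame


@dataclass(frozen=True)
class LinearGaussianBN:
    """Fitted network: DAG plus per-node intercept, coefficients, variance."""

    dag: DAG
    intercepts: dict[str, float]
    coefficients: dict[str, dict[str, float]]
    residual_variances: dict[str, float]

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if set(self.coefficients.get(node, {})) != set(self.dag.parents(node)):
                raise ValueError(f"coefficient keys of {node!r} != its parents")
            if self.residual_variances[node] <= 0:
                raise ValueError(f"non-positive residual variance at {node!r}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    # -- implied joint distribution ------------------------------------

    def implied_moments(self) -> tuple[pd.Series, pd.DataFrame]:
        """Mean vector and covariance of the implied multivariate normal.

        With coefficient matrix B (B[child, parent]), intercept vector c and
        noise covariance Ω = diag(σ²): x = (I − B)⁻¹ c has the means and
        Σ = (I − B)⁻¹ Ω (I − B)⁻ᵀ the covariance (standard path-tracing
        result for linear SEMs).
        """
        names = list(self.nodes)
        idx = {v: i for i, v in enumerate(names)}
        p = len(names)
        b = np.zeros((p, p))
        c = np.array([self.intercepts[v] for v in names])
        omega = np.diag([self.residual_variances[v] for v in names])
        for child in names:
            for parent, w in self.coefficients[child].items():
                b[idx[child], idx[parent]] = w
        inv = np.linalg.inv(np.eye(p) - b)
        mean = inv @ c
        cov = inv @ omega @ inv.T
        cov = (cov + cov.T) / 2.0  # symmetrize round-off
        return (pd.Series(mean, index=names),
                pd.DataFrame(cov, index=names, columns=names))

    # -- serialization -------------------------------------------------

    def to_frames(self, metadata: pd.DataFrame | None = None):
        """(edge frame, node frame) representation used by the TSV export."""
        edges = pd.DataFrame(
            [(p, ch, self.coefficients[ch][p]) for p, ch in sorted(self.dag.edges)],
            columns=["parent", "child", "coefficient"],
        )
        rows = []
        for v in self.nodes:
            tier = mech = ""
            if metadata is not None and v in metadata.index:
                tier = str(metadata.at[v, "tier"])
                mech = str(metadata.at[v, "mechanism"])
            rows.append((v, self.intercepts[v], self.residual_variances[v],
                         tier, mech))
        nodes = pd.DataFrame(
            rows, columns=["node", "intercept", "residual_variance",
                           "tier", "mechanism"])
        return edges, nodes

    def write(self, edges_path: str | Path, nodes_path: str | Path,
              metadata: pd.DataFrame | None = None) -> None:
        edges, nodes = self.to_frames(metadata)
        edges.to_csv(edges_path, sep="\t", index=False, float_format="%.17g")
        nodes.to_csv(nodes_path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, edges_path: str | Path,
             nodes_path: str | Path) -> "LinearGaussianBN":
        edges = pd.read_csv(edges_path, sep="\t", float_precision="round_trip")
        nodes = pd.read_csv(nodes_path, sep="\t", float_precision="round_trip")
        dag = DAG(list(nodes["node"]),
                  [(r.parent, r.child) for r in edges.itertuples()])
        coefficients: dict[str, dict[str, float]] = {v: {} for v in dag.nodes}
        for r in edges.itertuples():
            coefficients[r.child][r.parent] = float(r.coefficient)
        return cls(
            dag=dag,
            intercepts={r.node: float(r.intercept) for r in nodes.itertuples()},
            coefficients=coefficients,
            residual_variances={r.node: float(r.residual_variance)
                                for r in nodes.itertuples()},
        )

    def write_graphml(self, path: str | Path,
                      metadata: pd.DataFrame | None = None) -> None:
        g = nx.DiGraph()
        for v in self.nodes:
            attrs = {"intercept": self.intercepts[v],
                     "residual_variance": self.residual_variances[v]}
            if metadata is not None and v in metadata.index:
                attrs["tier"] = str(metadata.at[v, "tier"])
                attrs["mechanism"] = str(metadata.at[v, "mechanism"])
            g.add_node(v, **attrs)
        for p, c in sorted(self.dag.edges):
            g.add_edge(p, c, coefficient=self.coefficients[c][p])
        nx.write_graphml(g, path)

    def write_dot(self, path: str | Path) -> None:
        """Minimal DOT export for graphviz rendering of the network."""
        lines = ["digraph bayesian_network {"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for p, c in sorted(self.dag.edges):
            w = self.coefficients[c][p]
            lines.append(f'  "{p}" -> "{c}" [label="{w:.3f}"];')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")


def fit_mle(dag: DAG, data) -> LinearGaussianBN:
    """Maximum-likelihood parameters of ``dag`` on ``data``.

    Per node: OLS of the node on its parents (intercept and coefficients),
    residual variance RSS/n floored at 1e-12. Collinear parents raise an
    error naming the offending family.
    """
    frame = _as_frame(data)
    missing = set(dag.nodes) - set(frame.columns)
    if missing:
        raise ValueError(f"data lacks column(s) {sorted(missing)}")
    scorer = FamilyScorer(frame[list(dag.nodes)])
    largest = max((len(dag.parents(v)) for v in dag.nodes), default=0) + 1
    if scorer.n <= largest:
        raise ValueError(
            f"n={scorer.n} too small for largest family size {largest}")
    intercepts: dict[str, float] = {}
    coefficients: dict[str, dict[str, float]] = {}
    variances: dict[str, float] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        pidx = [scorer.index[q] for q in parents]
        try:
            intercept, beta, sigma2 = scorer.coefficients(
                scorer.index[node], pidx)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"collinear parents in family {node!r} <- {parents}") from exc
        intercepts[node] = intercept
        coefficients[node] = {q: float(b) for q, b in zip(parents, beta)}
        variances[node] = max(sigma2, VARIANCE_FLOOR)
    return LinearGaussianBN(dag, intercepts, coefficients, variances)


def predict_nodes(bn: LinearGaussianBN, evidence: dict[str, float] | pd.Series,
                  targets: list[str], method: str = "parents") -> pd.Series:
    """Predict target nodes from observed evidence.

    ``method='parents'`` evaluates each target's node equation on the
    observed parent values; ``method='joint'`` conditions the implied
    multivariate normal on all evidence (targets excluded) and returns the
    conditional mean.
    """
    if isinstance(evidence, pd.Series):
        evidence = dict(evidence)
    unknown = [t for t in targets if t not in bn.nodes]
    if unknown:
        raise ValueError(f"unknown target(s): {unknown}")
    if method == "parents":
        out = {}
        for t in targets:
            parents = bn.dag.parents(t)
            missing = [q for q in parents if q not in evidence]
            if missing:
                raise ValueError(
                    f"evidence lacks parent(s) {missing} of target {t!r}")
            out[t] = bn.intercepts[t] + sum(
                bn.coefficients[t][q] * float(evidence[q]) for q in parents)
        return pd.Series(out, dtype=float)[targets]
    if method != "joint":
        raise ValueError(f"unknown prediction method {method!r}")
    mean, cov = bn.implied_moments()
    observed = [v for v in bn.nodes if v in evidence and v not in targets]
    if not observed:
        return mean[targets]
    s_oo = cov.loc[observed, observed].to_numpy()
    s_to = cov.loc[targets, observed].to_numpy()
    dev = np.array([float(evidence[v]) - mean[v] for v in observed])
    # solve with a tiny ridge fallback for singular observed blocks
    try:
        adj = s_to @ np.linalg.solve(s_oo, dev)
    except np.linalg.LinAlgError:
        adj = s_to @ np.linalg.lstsq(s_oo, dev, rcond=None)[0]
    return pd.Series(mean[targets].to_numpy() + adj, index=targets)
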