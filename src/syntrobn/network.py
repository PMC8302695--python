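"""Constrained structure learning for linear-Gaussian Bayesian networks.

The search problem mirrors the study design it supports: expression of
fermenter and *Geobacter* genes may influence methanogen genes, which may
influence methane production, but never the other way round. That prior
knowledge enters as an :class:`EdgeConstraintSet` (blacklist of forbidden
edges, whitelist of required ones) built from tier labels by
:func:`build_blacklist`.

Structure is scored with the Gaussian BIC (maximized log-likelihood of each
node given its parents minus ``(k/2)·ln n`` with ``k = |parents| + 2`` for
intercept, coefficients and residual variance) and searched with greedy
hill climbing over add/delete/reverse edge operators.  For small problems
:func:`exhaustive_search` enumerates every DAG honoring the constraints and
serves as the exact reference the greedy search is checked against.

Scores are computed from the sample mean vector and MLE covariance matrix
via the normal equations, so a family evaluation costs ``O(k^3)``
independent of sample count; evaluations are cached per (child, parent-set).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .table import FeatureTable

#: Residual-variance floor keeping log-likelihoods finite on interpolating fits.
VARIANCE_FLOOR = 1e-12

#: Minimum BIC gain for a hill-climbing move to count as an improvement.
SCORE_EPS = 1e-10

# Tier ranks defining the inference direction. Fermentative bacteria and
# Geobacter form one class (either may feed the other); environment is
# unranked and may connect in both directions with every non-output tier.
_TIER_RANK = {"fermenter": 0, "geobacter": 0, "methanogen": 1, "output": 2}


# ---------------------------------------------------------------------------
# DAG and constraints
# ---------------------------------------------------------------------------

Edge = tuple[str, str]


@dataclass(frozen=True)
class DAG:
    """Directed acyclic graph over named variables."""

    nodes: tuple[str, ...]
    edges: frozenset[Edge]

    def __init__(self, nodes, edges=()):  # noqa: D107 - convenience coercion
        nodes = tuple(nodes)
        edges = frozenset((str(p), str(c)) for p, c in edges)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)
        node_set = set(nodes)
        if len(node_set) != len(nodes):
            raise ValueError("duplicate node names")
        for p, c in edges:
            if p == c:
                raise ValueError(f"self-loop on {p!r}")
            if p not in node_set or c not in node_set:
                raise ValueError(f"edge ({p!r}, {c!r}) references unknown node")
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge set contains a cycle")

    def parents(self, node: str) -> list[str]:
        return sorted(p for p, c in self.edges if c == node)

    def children(self, node: str) -> list[str]:
        return sorted(c for p, c in self.edges if p == node)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))


@dataclass(frozen=True)
class EdgeConstraintSet:
    """Forbidden (blacklist) and required (whitelist) directed edges."""

    blacklist: frozenset[Edge] = field(default_factory=frozenset)
    whitelist: frozenset[Edge] = field(default_factory=frozenset)

    def __init__(self, blacklist=(), whitelist=()):  # noqa: D107
        blacklist = frozenset((str(p), str(c)) for p, c in blacklist)
        whitelist = frozenset((str(p), str(c)) for p, c in whitelist)
        object.__setattr__(self, "blacklist", blacklist)
        object.__setattr__(self, "whitelist", whitelist)
        clash = blacklist & whitelist
        if clash:
            raise ValueError(f"edges both black- and whitelisted: {sorted(clash)}")
        g = nx.DiGraph(list(whitelist))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("whitelist alone is cyclic")

    def restrict(self, nodes) -> "EdgeConstraintSet":
        """Constraints restricted to edges among the given nodes."""
        keep = set(nodes)
        return EdgeConstraintSet(
            blacklist={e for e in self.blacklist if e[0] in keep and e[1] in keep},
            whitelist={e for e in self.whitelist if e[0] in keep and e[1] in keep},
        )


def build_blacklist(tiers: dict[str, str] | pd.Series,
                    allow_within_tier: bool = True) -> EdgeConstraintSet:
    """Forbid edges running against the tier ordering.

    The ordering is {fermenter, geobacter} -> methanogen -> output; any edge
    from a strictly later rank to a strictly earlier rank is blacklisted, as
    is every edge leaving the output node. Environment variables are
    unranked: they may feed and be fed by any tier except that nothing
    leaves the output. With ``allow_within_tier=False`` edges inside one
    tier class (fermenter/geobacter count as one class) are forbidden too.
    """
    if isinstance(tiers, pd.Series):
        tiers = dict(tiers)
    unknown = sorted({t for t in tiers.values()}
                     - set(_TIER_RANK) - {"environment"})
    if unknown:
        raise ValueError(f"unknown tier label(s): {unknown}")
    names = list(tiers)
    black: set[Edge] = set()
    for a, b in itertools.permutations(names, 2):
        ta, tb = tiers[a], tiers[b]
        if ta == "output":
            black.add((a, b))
            continue
        ra = _TIER_RANK.get(ta)
        rb = _TIER_RANK.get(tb)
        if ra is not None and rb is not None and ra > rb:
            black.add((a, b))
        elif not allow_within_tier:
            same_class = (ra is not None and ra == rb) or (
                ta == "environment" and tb == "environment")
            if same_class:
                black.add((a, b))
    return EdgeConstraintSet(blacklist=black)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _as_frame(data) -> pd.DataFrame:
    return data.values if isinstance(data, FeatureTable) else data


class FamilyScorer:
    """Cached per-node Gaussian BIC family scores for one dataset.

    Works off the sample means and MLE covariance, so each evaluation is a
    small linear solve regardless of n. A singular parent covariance makes
    the family unscorable (-inf), which effectively forbids the edge set.
    """

    def __init__(self, data: pd.DataFrame):
        x = np.ascontiguousarray(data.to_numpy(dtype=float))
        self.columns = list(data.columns)
        self.index = {c: i for i, c in enumerate(self.columns)}
        self.n = x.shape[0]
        if self.n < 1:
            raise ValueError("need at least one sample")
        self.mean = x.mean(axis=0)
        xc = x - self.mean
        self.cov = (xc.T @ xc) / self.n  # MLE covariance
        self._covl = self.cov.tolist()   # scalar access for small families
        self._cache: dict[tuple[int, int], float] = {}
        self._log2pi = math.log(2.0 * math.pi)

    def family_score(self, child: int, parents) -> float:
        mask = 0
        for q in parents:
            mask |= 1 << q
        return self.family_score_mask(child, mask)

    def family_score_mask(self, child: int, mask: int) -> float:
        """Family score with the parent set given as a bitmask (hot path)."""
        key = (child, mask)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if mask.bit_count() + 2 > self.n:
            # more parameters than samples: family not estimable
            self._cache[key] = -math.inf
            return -math.inf
        parents = _mask_to_frozenset(mask)
        sigma2 = self._residual_variance(child, parents)
        if sigma2 is None:
            score = -math.inf
        else:
            n = self.n
            loglik = -0.5 * n * (self._log2pi + math.log(sigma2) + 1.0)
            k = len(parents) + 2  # intercept + coefficients + variance
            score = loglik - 0.5 * k * math.log(n)
        self._cache[key] = score
        return score

    def _residual_variance(self, child: int, parents: frozenset[int]):
        """RSS/n of the child regressed on its parents; None if singular.

        Small parent sets (the overwhelming majority during search) are
        solved in closed form; larger ones go through a Cholesky solve. A
        (near-)singular parent covariance marks the family unscorable.
        """
        s = self._covl
        k = len(parents)
        if k == 0:
            sigma2 = s[child][child]
        elif k == 1:
            (a,) = parents
            saa = s[a][a]
            if saa <= 1e-12 * max(saa, 1.0):
                return None
            sigma2 = s[child][child] - s[a][child] ** 2 / saa
        elif k == 2:
            a, b = parents
            saa, sbb, sab = s[a][a], s[b][b], s[a][b]
            det = saa * sbb - sab * sab
            if det <= 1e-12 * max(saa * sbb, 1e-30):
                return None
            sac, sbc = s[a][child], s[b][child]
            beta_a = (sbb * sac - sab * sbc) / det
            beta_b = (saa * sbc - sab * sac) / det
            sigma2 = s[child][child] - beta_a * sac - beta_b * sbc
        else:
            p = sorted(parents)
            spp = self.cov[np.ix_(p, p)]
            spc = self.cov[p, child]
            try:
                chol = np.linalg.cholesky(spp)
            except np.linalg.LinAlgError:
                return None
            diag = np.diag(chol)
            if np.min(diag) ** 2 <= 1e-12 * float(np.max(diag)) ** 2:
                return None
            half = np.linalg.solve(chol, spc)
            sigma2 = self.cov[child, child] - float(half @ half)
        return max(float(sigma2), VARIANCE_FLOOR)

    def coefficients(self, child: int, parents: list[int]):
        """OLS intercept/coefficients/ML residual variance for one family."""
        s = self.cov
        if parents:
            spp = s[np.ix_(parents, parents)]
            spc = s[parents, child]
            chol = np.linalg.cholesky(spp)  # raises if not PD (collinear)
            diag = np.diag(chol)
            if np.min(diag) ** 2 <= 1e-12 * float(np.max(diag)) ** 2:
                raise np.linalg.LinAlgError("collinear parents")
            beta = np.linalg.solve(spp, spc)
            sigma2 = float(s[child, child] - spc @ beta)
        else:
            beta = np.zeros(0)
            sigma2 = float(s[child, child])
        intercept = float(self.mean[child] - beta @ self.mean[parents])
        return intercept, beta, max(sigma2, VARIANCE_FLOOR)


def bic_score(dag: DAG, data) -> float:
    """Gaussian BIC of ``dag`` on ``data`` (higher is better).

    Decomposes over nodes: each family contributes its maximized Gaussian
    log-likelihood minus ``((|parents| + 2)/2)·ln n``.
    """
    frame = _as_frame(data)
    missing = set(dag.nodes) - set(frame.columns)
    if missing:
        raise ValueError(f"data lacks column(s) {sorted(missing)}")
    scorer = FamilyScorer(frame[list(dag.nodes)])
    largest = max((len(dag.parents(v)) for v in dag.nodes), default=0) + 2
    if scorer.n < largest:
        raise ValueError(
            f"n={scorer.n} below parameter count {largest} of largest family")
    total = 0.0
    for node in dag.nodes:
        child = scorer.index[node]
        parents = frozenset(scorer.index[p] for p in dag.parents(node))
        total += scorer.family_score(child, parents)
    return total


# ---------------------------------------------------------------------------
# Greedy search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchOptions:
    """Hill-climbing options.

    By default the greedy ascent is followed by a short deterministic tabu
    walk: when no operator improves the score, the best non-recently-
    visited operator is applied anyway (for at most ``patience``
    non-improving steps, banning the last ``tabu_length`` graphs), and the
    best graph seen overall is returned. This lets the search step across
    score plateaus created by equivalence-class ties (e.g. re-orienting
    edges into a collider) without sacrificing determinism. ``tabu_off``
    reduces the search to plain greedy hill climbing. ``restarts`` adds
    seeded random starting graphs; the best final score wins.
    """

    max_iter: int = 500
    tabu_off: bool = False
    tabu_length: int = 10
    patience: int = 5
    restarts: int = 0
    seed: int = 0


_OP_RANK = {"add": 0, "delete": 1, "reverse": 2}


class _SearchState:
    """Bitmask adjacency for fast cycle checks during search."""

    def __init__(self, p: int, edges: set[tuple[int, int]]):
        self.p = p
        self.parents = [0] * p
        self.children = [0] * p
        for a, b in edges:
            self.parents[b] |= 1 << a
            self.children[a] |= 1 << b

    def edge_set(self) -> set[tuple[int, int]]:
        return {(a, b) for b in range(self.p)
                for a in range(self.p) if self.parents[b] >> a & 1}

    def has_path(self, src: int, dst: int, skip_edge=None) -> bool:
        """Directed path src -> dst (optionally ignoring one edge)."""
        seen = 1 << src
        stack = [src]
        while stack:
            v = stack.pop()
            kids = self.children[v]
            if skip_edge is not None and v == skip_edge[0]:
                kids &= ~(1 << skip_edge[1])
            new = kids & ~seen
            if new >> dst & 1:
                return True
            seen |= new
            while new:
                low = new & -new
                stack.append(low.bit_length() - 1)
                new &= new - 1
        return False

    def descendants(self) -> list[int]:
        """Bitmask of (proper) descendants per node, via DFS."""
        reach = [0] * self.p
        for v in range(self.p):
            seen = 0
            stack = [v]
            while stack:
                u = stack.pop()
                new = self.children[u] & ~seen
                seen |= new
                while new:
                    low = new & -new
                    stack.append(low.bit_length() - 1)
                    new &= new - 1
            reach[v] = seen
        return reach

    def apply(self, op: str, a: int, b: int) -> None:
        if op == "add":
            self.parents[b] |= 1 << a
            self.children[a] |= 1 << b
        elif op == "delete":
            self.parents[b] &= ~(1 << a)
            self.children[a] &= ~(1 << b)
        else:  # reverse a->b to b->a
            self.apply("delete", a, b)
            self.apply("add", b, a)


def _mask_to_frozenset(mask: int) -> frozenset[int]:
    out = []
    while mask:
        low = mask & -mask
        out.append(low.bit_length() - 1)
        mask &= mask - 1
    return frozenset(out)


def hill_climb(data, constraints: EdgeConstraintSet | None = None,
               options: SearchOptions | None = None) -> DAG:
    """Greedy BIC hill climbing over DAGs honoring the constraints.

    Starts from the whitelist-only graph and repeatedly applies the single
    best-scoring legal operator (add, delete or reverse an edge) until no
    operator improves the score. Legality: the result stays acyclic,
    contains no blacklisted edge and keeps every whitelisted edge. Ties are
    broken lexicographically on (operator kind: add < delete < reverse,
    parent name, child name), so the search is fully deterministic; with
    ``restarts > 0`` additional seeded random starting graphs are tried and
    the best final score wins (same tie-break on equal scores).
    """
    frame = _as_frame(data)
    constraints = constraints or EdgeConstraintSet()
    options = options or SearchOptions()
    names = list(frame.columns)
    index = {c: i for i, c in enumerate(names)}
    p = len(names)

    for a, b in constraints.whitelist | constraints.blacklist:
        if a not in index or b not in index:
            raise ValueError(f"constraint edge ({a!r}, {b!r}) not in data")
    black = {(index[a], index[b]) for a, b in constraints.blacklist}
    white = {(index[a], index[b]) for a, b in constraints.whitelist}

    scorer = FamilyScorer(frame)
    variances = np.diag(scorer.cov)
    zero_var = [names[i] for i in range(p) if variances[i] <= 0]
    if zero_var:
        raise ValueError(f"zero-variance column(s): {zero_var}")

    # legal parents per child (not self, not blacklisted as parent->child)
    allowed_parents = [0] * p
    for a in range(p):
        for b in range(p):
            if a != b and (a, b) not in black:
                allowed_parents[b] |= 1 << a

    score_mask = scorer.family_score_mask

    def climb(start_edges: set[tuple[int, int]]):
        state = _SearchState(p, start_edges)
        parents = state.parents
        node_score = [score_mask(b, parents[b]) for b in range(p)]
        total = float(sum(node_score))
        best_edges, best_total = state.edge_set(), total
        current_key = frozenset(best_edges)
        tabu: list[frozenset] = [current_key]
        non_improving = 0
        for _ in range(options.max_iter):
            reach = state.descendants()
            cands = []  # (-delta, rank, parent_name, child_name, op, a, b)
            for b in range(p):
                pmask = parents[b]
                base = node_score[b]
                # additions: legal new parents that do not create a cycle
                cand_mask = allowed_parents[b] & ~pmask & ~reach[b]
                while cand_mask:
                    low = cand_mask & -cand_mask
                    a = low.bit_length() - 1
                    cand_mask &= cand_mask - 1
                    delta = score_mask(b, pmask | low) - base
                    cands.append((-delta, 0, names[a], names[b], "add", a, b))
                # deletions and reversals over current non-whitelist edges
                m = pmask
                while m:
                    low = m & -m
                    a = low.bit_length() - 1
                    m &= m - 1
                    if (a, b) in white:
                        continue
                    del_delta = score_mask(b, pmask & ~low) - base
                    cands.append((-del_delta, 1, names[a], names[b],
                                  "delete", a, b))
                    if (b, a) not in black and not state.has_path(
                            a, b, skip_edge=(a, b)):
                        d = del_delta + score_mask(
                            a, parents[a] | 1 << b) - node_score[a]
                        cands.append((-d, 2, names[a], names[b],
                                      "reverse", a, b))
            cands.sort()
            # take the best operator whose resulting graph was not just seen
            chosen = None
            for neg_delta, _, _, _, op, a, b in cands:
                if neg_delta >= math.inf:
                    break
                key = _result_key(current_key, op, a, b)
                if key not in tabu:
                    chosen = (-neg_delta, op, a, b, key)
                    break
            if chosen is None:
                break
            delta, op, a, b, current_key = chosen
            if delta <= SCORE_EPS:
                if options.tabu_off or non_improving >= options.patience:
                    break
                non_improving += 1
            state.apply(op, a, b)
            node_score[b] = score_mask(b, parents[b])
            if op == "reverse":
                node_score[a] = score_mask(a, parents[a])
            total += delta
            tabu.append(current_key)
            if len(tabu) > options.tabu_length:
                tabu.pop(0)
            if total > best_total + SCORE_EPS:
                best_edges, best_total = state.edge_set(), total
                non_improving = 0
        return best_edges, best_total

    starts = [set(white)]
    if options.restarts > 0:
        rng = np.random.default_rng(options.seed)
        allowed = [e for e in itertools.permutations(range(p), 2)
                   if e not in black]
        for _ in range(options.restarts):
            edges = set(white)
            state = _SearchState(p, edges)
            order = rng.permutation(len(allowed))
            for k in order:
                a, b = allowed[k]
                if rng.random() < 0.25 and not (
                        state.parents[b] >> a & 1) and not state.has_path(b, a):
                    state.apply("add", a, b)
                    edges.add((a, b))
            starts.append(edges)

    best_edges, best_score = None, -math.inf
    for start in starts:
        edges, score = climb(start)
        key = tuple(sorted((names[a], names[b]) for a, b in edges))
        if best_edges is None or score > best_score + SCORE_EPS or (
                abs(score - best_score) <= SCORE_EPS and key < best_key):
            best_edges, best_score, best_key = edges, score, key
    return DAG(names, {(names[a], names[b]) for a, b in best_edges})


def _result_key(current: frozenset, op: str, a: int, b: int) -> frozenset:
    """Edge set resulting from applying an operator (for the tabu list)."""
    if op == "add":
        return current | {(a, b)}
    if op == "delete":
        return current - {(a, b)}
    return (current - {(a, b)}) | {(b, a)}


# ---------------------------------------------------------------------------
# Exhaustive reference search
# ---------------------------------------------------------------------------


def enumerate_dags(nodes, constraints: EdgeConstraintSet | None = None):
    """Yield every labeled DAG over ``nodes`` honoring the constraints.

    Only feasible for very small node sets (the count for n unconstrained
    labeled nodes is 1, 1, 3, 25, 543, 29281 for n = 0..5).
    """
    names = list(nodes)
    p = len(names)
    if p > 5:
        raise ValueError("enumeration limited to at most 5 nodes")
    constraints = constraints or EdgeConstraintSet()
    index = {c: i for i, c in enumerate(names)}
    black = {(index[a], index[b]) for a, b in constraints.blacklist}
    white = {(index[a], index[b]) for a, b in constraints.whitelist}
    optional = [e for e in itertools.permutations(range(p), 2)
                if e not in black and e not in white]
    for r in range(len(optional) + 1):
        for combo in itertools.combinations(optional, r):
            edges = white | set(combo)
            if _acyclic(p, edges):
                yield DAG(names, {(names[a], names[b]) for a, b in edges})


def _acyclic(p: int, edges: set[tuple[int, int]]) -> bool:
    parents = [0] * p
    for a, b in edges:
        parents[b] |= 1 << a
    remaining = (1 << p) - 1
    while remaining:
        progressed = False
        m = remaining
        while m:
            low = m & -m
            v = low.bit_length() - 1
            if parents[v] & remaining == 0:
                remaining &= ~low
                progressed = True
            m &= m - 1
        if not progressed:
            return False
    return True


def exhaustive_search(data, constraints: EdgeConstraintSet | None = None) -> DAG:
    """Globally BIC-optimal DAG by enumeration (≤5 nodes).

    Serves as the exact oracle against which :func:`hill_climb` is checked.
    Ties are broken by the lexicographically smallest sorted edge list.
    """
    frame = _as_frame(data)
    names = list(frame.columns)
    if len(names) > 5:
        raise ValueError("exhaustive search limited to at most 5 nodes")
    scorer = FamilyScorer(frame)
    index = scorer.index
    best = None
    for dag in enumerate_dags(names, constraints):
        total = sum(
            scorer.family_score(index[v],
                                frozenset(index[q] for q in dag.parents(v)))
            for v in names)
        key = tuple(sorted(dag.edges))
        if best is None or total > best[0] + 1e-12 or (
                total >= best[0] - 1e-12 and key < best[1]):
            best = (total, key, dag)
    return best[2]
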