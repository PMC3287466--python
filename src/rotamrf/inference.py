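"""Marginal inference on the rotamer MRF.

Four sum-product algorithms — loopy belief propagation (LBP), mean-field
(MF), tree-reweighted BP (TRBP) and a generalized BP (GBP) variant on
merged-triangle regions — plus an exact enumeration oracle for small state
spaces.  All of them return per-vertex probability vectors over the
vertex's candidate rotamers together with convergence metadata.

Messages are normalized to sum to 1 after every update (pure rescaling,
prevents underflow).  Convergence is declared when the L∞ change of all
beliefs between successive asynchronous sweeps drops below the tolerance;
non-convergence within the iteration cap is a reported state, never an
error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .potentials import MarkovRandomField


@dataclass
class InferenceConfig:
    max_iterations: int = 100
    tolerance: float = 1e-6
    damping: float = 0.0      # 0 = plain updates
    schedule: str = "input"   # or "random"
    init: str = "uniform"     # or "random"
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1 or self.tolerance <= 0:
            raise ValueError("invalid inference configuration")
        if not (0 <= self.damping < 1):
            raise ValueError("damping must lie in [0, 1)")


@dataclass
class MarginalSet:
    beliefs: Dict[int, np.ndarray]
    converged: bool
    iterations_used: int
    max_residual: float
    algorithm: str = ""
    #: per-sweep L∞ residuals, for convergence diagnostics
    residual_trace: List[float] = field(default_factory=list)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.beliefs[i]


@dataclass
class EdgeAppearance:
    """Spanning-tree edge-appearance probabilities ρ_ij ∈ (0, 1]."""

    rho: Dict[Tuple[int, int], float]

    def get(self, i: int, j: int) -> float:
        return self.rho[(i, j) if i < j else (j, i)]


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def _directed_edges(mrf: MarkovRandomField) -> List[Tuple[int, int]]:
    out = []
    for i, j in mrf.graph.edge_list():
        out.append((i, j))
        out.append((j, i))
    return out


def _init_messages(
    mrf: MarkovRandomField, config: InferenceConfig
) -> Dict[Tuple[int, int], np.ndarray]:
    rng = np.random.default_rng(config.seed)
    msgs = {}
    for i, j in _directed_edges(mrf):
        n = mrf.n_states(j)
        if config.init == "random":
            msgs[(i, j)] = _normalize(rng.uniform(0.5, 1.5, size=n))
        else:
            msgs[(i, j)] = np.full(n, 1.0 / n)
    return msgs


def _sweep_order(items: list, config: InferenceConfig, rng) -> list:
    if config.schedule == "random":
        return [items[k] for k in rng.permutation(len(items))]
    return items


# ---------------------------------------------------------------------------
# exact enumeration oracle

MAX_EXACT_STATES = 10_000_000


def exact_marginals(mrf: MarkovRandomField, cap: int = MAX_EXACT_STATES) -> MarginalSet:
    """Exact marginals by materializing the normalized joint tensor.

    Refuses state spaces above ``cap`` configurations.  Also the only place
    the normalizer Z is ever computed.
    """
    order = sorted(mrf.vertex_potentials)
    shape = [mrf.n_states(i) for i in order]
    total = int(np.prod([float(s) for s in shape]))
    if np.prod([float(s) for s in shape]) > cap:
        raise ValueError(f"state space {total} exceeds enumeration cap {cap}")
    axis = {v: k for k, v in enumerate(order)}
    joint = np.ones(shape)
    for i in order:
        sh = [1] * len(order)
        sh[axis[i]] = shape[axis[i]]
        joint = joint * mrf.vertex_potentials[i].reshape(sh)
    for (i, j), mat in mrf.edge_potentials.items():
        # edge keys are sorted pairs and `order` is ascending, so axis[i] < axis[j]
        sh = [1] * len(order)
        sh[axis[i]], sh[axis[j]] = mat.shape
        joint = joint * mat.reshape(sh)
    z = joint.sum()
    beliefs = {
        i: np.asarray(joint.sum(axis=tuple(k for k in range(len(order)) if k != axis[i])))
        / z
        for i in order
    }
    return MarginalSet(beliefs, True, 1, 0.0, algorithm="exact")


# ---------------------------------------------------------------------------
# loopy belief propagation


def _beliefs_from_messages(
    mrf: MarkovRandomField,
    msgs: Dict[Tuple[int, int], np.ndarray],
    rho: Optional[EdgeAppearance] = None,
) -> Dict[int, np.ndarray]:
    out = {}
    for i in mrf.vertex_potentials:
        b = mrf.vertex_potentials[i].copy()
        for k in mrf.graph.neighbors(i):
            m = msgs[(k, i)]
            b = b * (m ** rho.get(k, i) if rho is not None else m)
        out[i] = _normalize(b)
    return out


def _residual(a: Dict[int, np.ndarray], b: Dict[int, np.ndarray]) -> float:
    return max(float(np.max(np.abs(a[i] - b[i]))) for i in a)


def lbp(mrf: MarkovRandomField, config: Optional[InferenceConfig] = None) -> MarginalSet:
    """Sum-product loopy belief propagation with asynchronous sweeps.

    Message i→j: Σ_xi φ_i(xi) ψ_ij(xi,xj) Π_{k∈N(i)∖j} m_ki(xi).
    Belief: φ_i Π_k m_ki, normalized.  Exact on acyclic graphs.
    """
    config = config or InferenceConfig()
    rng = np.random.default_rng(config.seed)
    msgs = _init_messages(mrf, config)
    edges = _directed_edges(mrf)
    beliefs = _beliefs_from_messages(mrf, msgs)
    converged, it, res = False, 0, np.inf
    trace: List[float] = []
    for it in range(1, config.max_iterations + 1):
        for i, j in _sweep_order(edges, config, rng):
            pre = mrf.vertex_potentials[i].copy()
            for k in mrf.graph.neighbors(i):
                if k != j:
                    pre = pre * msgs[(k, i)]
            new = _normalize(pre @ mrf.edge_matrix(i, j))
            if config.damping > 0:
                new = _normalize((1 - config.damping) * new + config.damping * msgs[(i, j)])
            msgs[(i, j)] = new
        new_beliefs = _beliefs_from_messages(mrf, msgs)
        res = _residual(new_beliefs, beliefs) if beliefs else 0.0
        trace.append(res)
        beliefs = new_beliefs
        if res < config.tolerance:
            converged = True
            break
    return MarginalSet(beliefs, converged, it, res, "lbp", trace)


# ---------------------------------------------------------------------------
# mean field


def mean_field(mrf: MarkovRandomField, config: Optional[InferenceConfig] = None) -> MarginalSet:
    """Naive mean-field coordinate ascent.

    b_i ∝ φ_i(xi)·exp(Σ_{j∈N(i)} Σ_xj b_j(xj)·ln ψ_ij(xi,xj)), updated
    asynchronously until the beliefs stop moving.  Exact when the graph has
    no edges (the product form is then the true joint).
    """
    config = config or InferenceConfig()
    rng = np.random.default_rng(config.seed)
    order = sorted(mrf.vertex_potentials)
    if config.init == "random":
        beliefs = {i: _normalize(rng.uniform(0.5, 1.5, mrf.n_states(i))) for i in order}
    else:
        beliefs = {i: np.full(mrf.n_states(i), 1.0 / mrf.n_states(i)) for i in order}
    log_psi = {e: np.log(m) for e, m in mrf.edge_potentials.items()}

    def log_edge(i, j):
        if i < j:
            return log_psi[(i, j)]
        return log_psi[(j, i)].T

    converged, it, res = False, 0, np.inf
    trace: List[float] = []
    for it in range(1, config.max_iterations + 1):
        old = {i: b.copy() for i, b in beliefs.items()}
        for i in _sweep_order(order, config, rng):
            logb = np.log(mrf.vertex_potentials[i])
            for j in mrf.graph.neighbors(i):
                logb = logb + log_edge(i, j) @ beliefs[j]
            logb -= logb.max()
            beliefs[i] = _normalize(np.exp(logb))
        res = _residual(beliefs, old)
        trace.append(res)
        if res < config.tolerance:
            converged = True
            break
    return MarginalSet(beliefs, converged, it, res, "mf", trace)


# ---------------------------------------------------------------------------
# tree-reweighted BP


def compute_edge_appearance(graph) -> EdgeAppearance:
    """Exact spanning-tree edge-appearance probabilities.

    By the matrix-tree theorem, the fraction of spanning trees containing
    edge (i,j) equals the effective resistance between i and j in the
    unit-conductance network, computed here from the Laplacian pseudoinverse
    per connected component.  Bridges and tree edges get exactly 1.
    """
    g = graph.to_networkx() if hasattr(graph, "to_networkx") else nx.Graph(graph)
    rho: Dict[Tuple[int, int], float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nodes = sorted(sub.nodes)
        idx = {v: k for k, v in enumerate(nodes)}
        lap = nx.laplacian_matrix(sub, nodelist=nodes).toarray().astype(float)
        lplus = np.linalg.pinv(lap)
        for u, v in sub.edges:
            r = lplus[idx[u], idx[u]] + lplus[idx[v], idx[v]] - 2 * lplus[idx[u], idx[v]]
            r = min(max(r, 0.0), 1.0)
            if r > 1.0 - 1e-9:
                r = 1.0
            rho[(u, v) if u < v else (v, u)] = r
    return EdgeAppearance(rho)


def uniform_edge_appearance(graph, value: float = 1.0) -> EdgeAppearance:
    g = graph.to_networkx() if hasattr(graph, "to_networkx") else nx.Graph(graph)
    return EdgeAppearance({(min(u, v), max(u, v)): value for u, v in g.edges})


def trbp(
    mrf: MarkovRandomField,
    rho: Optional[EdgeAppearance] = None,
    config: Optional[InferenceConfig] = None,
) -> MarginalSet:
    """Tree-reweighted sum-product BP.

    Message i→j: Σ_xi φ_i ψ_ij^{1/ρ_ij} Π_{k∈N(i)∖j} m_ki^{ρ_ki} / m_ji^{1−ρ_ij};
    belief: φ_i Π_k m_ki^{ρ_ki}.  With all ρ = 1 the update reduces
    algebraically to plain LBP.
    """
    config = config or InferenceConfig()
    if rho is None:
        rho = compute_edge_appearance(mrf.graph)
    rng = np.random.default_rng(config.seed)
    msgs = _init_messages(mrf, config)
    edges = _directed_edges(mrf)
    beliefs = _beliefs_from_messages(mrf, msgs, rho)
    converged, it, res = False, 0, np.inf
    trace: List[float] = []
    for it in range(1, config.max_iterations + 1):
        for i, j in _sweep_order(edges, config, rng):
            r_ij = rho.get(i, j)
            pre = mrf.vertex_potentials[i].copy()
            for k in mrf.graph.neighbors(i):
                if k != j:
                    pre = pre * msgs[(k, i)] ** rho.get(k, i)
            pre = pre / msgs[(j, i)] ** (1.0 - r_ij)
            new = _normalize(pre @ mrf.edge_matrix(i, j) ** (1.0 / r_ij))
            if config.damping > 0:
                new = _normalize((1 - config.damping) * new + config.damping * msgs[(i, j)])
            msgs[(i, j)] = new
        new_beliefs = _beliefs_from_messages(mrf, msgs, rho)
        res = _residual(new_beliefs, beliefs)
        trace.append(res)
        beliefs = new_beliefs
        if res < config.tolerance:
            converged = True
            break
    return MarginalSet(beliefs, converged, it, res, "trbp", trace)


# ---------------------------------------------------------------------------
# generalized BP (merged-triangle region factors)


def _build_factors(mrf: MarkovRandomField):
    """Group edge potentials into clique factors.

    Every triangle of the interaction graph becomes one factor over its
    three vertices, holding the product of those of its edges not already
    claimed by an earlier triangle; each remaining edge becomes a pairwise
    factor.  Each edge potential enters exactly one factor, so the
    factorization is an exact rewrite of the pairwise model.  On
    triangle-free graphs this is precisely the Bethe factor graph.
    """
    g = mrf.graph.to_networkx()
    claimed: set = set()
    factors: List[Tuple[Tuple[int, ...], np.ndarray]] = []
    triangles = sorted(
        {tuple(sorted(t)) for t in (c for c in nx.enumerate_all_cliques(g) if len(c) == 3)}
    )
    for a, b, c in triangles:
        tri_edges = [e for e in ((a, b), (a, c), (b, c)) if frozenset(e) not in claimed]
        if not tri_edges:
            continue
        tensor = np.ones((mrf.n_states(a), mrf.n_states(b), mrf.n_states(c)))
        pos = {a: 0, b: 1, c: 2}
        for u, v in tri_edges:  # u < v, so pos[u] < pos[v]
            claimed.add(frozenset((u, v)))
            mat = mrf.edge_matrix(u, v)
            sh = [1, 1, 1]
            sh[pos[u]], sh[pos[v]] = mat.shape
            tensor = tensor * mat.reshape(sh)
        factors.append(((a, b, c), tensor))
    for i, j in mrf.graph.edge_list():
        if frozenset((i, j)) not in claimed:
            factors.append(((i, j), mrf.edge_matrix(i, j)))
    return factors


def gbp(mrf: MarkovRandomField, config: Optional[InferenceConfig] = None) -> MarginalSet:
    """Generalized BP: sum-product on the merged-triangle factor graph.

    Outer regions are the graph's triangles (plus leftover edges); counting
    is exact because each edge potential is assigned to exactly one factor.
    Reduces to the Bethe/LBP factorization on triangle-free graphs and is
    exact whenever the factor graph is acyclic (e.g., a single triangle).
    """
    config = config or InferenceConfig()
    rng = np.random.default_rng(config.seed)
    factors = _build_factors(mrf)
    # messages factor->var and var->factor
    f2v: Dict[Tuple[int, int], np.ndarray] = {}
    v2f: Dict[Tuple[int, int], np.ndarray] = {}
    var_factors: Dict[int, List[int]] = {i: [] for i in mrf.vertex_potentials}
    for fi, (scope, _) in enumerate(factors):
        for v in scope:
            var_factors[v].append(fi)
            n = mrf.n_states(v)
            f2v[(fi, v)] = np.full(n, 1.0 / n)
            if config.init == "random":
                v2f[(v, fi)] = _normalize(rng.uniform(0.5, 1.5, n))
            else:
                v2f[(v, fi)] = np.full(n, 1.0 / n)

    def beliefs_now() -> Dict[int, np.ndarray]:
        out = {}
        for i in mrf.vertex_potentials:
            b = mrf.vertex_potentials[i].copy()
            for fi in var_factors[i]:
                b = b * f2v[(fi, i)]
            out[i] = _normalize(b)
        return out

    beliefs = beliefs_now()
    converged, it, res = False, 0, np.inf
    trace: List[float] = []
    schedule = list(range(len(factors)))
    for it in range(1, config.max_iterations + 1):
        for fi in _sweep_order(schedule, config, rng):
            scope, tensor = factors[fi]
            # refresh incoming var->factor messages
            for v in scope:
                m = mrf.vertex_potentials[v].copy()
                for fj in var_factors[v]:
                    if fj != fi:
                        m = m * f2v[(fj, v)]
                v2f[(v, fi)] = _normalize(m)
            for pos, v in enumerate(scope):
                t = tensor
                for qos, u in enumerate(scope):
                    if u == v:
                        continue
                    sh = [1] * t.ndim
                    sh[qos] = len(v2f[(u, fi)])
                    t = t * v2f[(u, fi)].reshape(sh)
                axes = tuple(q for q in range(t.ndim) if q != pos)
                new = _normalize(t.sum(axis=axes))
                if config.damping > 0:
                    new = _normalize(
                        (1 - config.damping) * new + config.damping * f2v[(fi, v)]
                    )
                f2v[(fi, v)] = new
        new_beliefs = beliefs_now()
        res = _residual(new_beliefs, beliefs)
        trace.append(res)
        beliefs = new_beliefs
        if res < config.tolerance:
            converged = True
            break
    return MarginalSet(beliefs, converged, it, res, "gbp", trace)


ALGORITHMS = {
    "lbp": lambda mrf, config: lbp(mrf, config),
    "mf": lambda mrf, config: mean_field(mrf, config),
    "trbp": lambda mrf, config: trbp(mrf, None, config),
    "gbp": lambda mrf, config: gbp(mrf, config),
}


def run_inference(
    mrf: MarkovRandomField,
    algorithm: str = "lbp",
    config: Optional[InferenceConfig] = None,
    rho: Optional[EdgeAppearance] = None,
) -> MarginalSet:
    """Dispatch to one of the four algorithms by name."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    if algorithm == "trbp" and rho is not None:
        return trbp(mrf, rho, config)
    return ALGORITHMS[algorithm](mrf, config)
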