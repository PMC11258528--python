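"""Constraint-based Bayesian-network structure learning for feature selection.

The learner follows the Markov-blanket route: IAMB (incremental association
Markov blanket) discovers each node's blanket with a conditional
mutual-information G-test; blankets are symmetrized into a skeleton
(AND rule), candidate neighbours are confirmed by searching for a
separating subset inside the smaller blanket, v-structures are oriented,
and the orientation rules propagate. Edge confidence comes from a
nonparametric bootstrap — *strength* is the fraction of replicates
containing an edge between two nodes, *direction* the fraction of a given
orientation among those — and the averaged network keeps edges with
strength ≥ 50 % oriented with the bootstrap majority. A final marginal
independence sweep removes edges whose pairwise G-test is not significant.

The two feature sets the screening study compares are read off the final
graph: the outcome's Markov blanket, and every feature connected to the
outcome by a path in the undirected skeleton ("all-path features").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# discrete data holder
# ---------------------------------------------------------------------------

class DiscreteData:
    """Integer-coded view of a discrete data frame, cheap to resample.

    Columns are factorized once; bootstrap replicates reuse the codes and
    the observed level counts (degrees of freedom are defined by the levels
    observed in the data the learner was given).
    """

    def __init__(self, frame: pd.DataFrame | None = None, *, codes=None, cards=None, columns=None):
        if frame is not None:
            if len(frame) == 0:
                raise ValueError("empty data")
            self.columns = list(frame.columns)
            self.codes = {}
            self.cards = {}
            for c in self.columns:
                vals = frame[c].to_numpy()
                uniq, inv = np.unique(vals, return_inverse=True)
                self.codes[c] = inv.astype(np.int64)
                self.cards[c] = len(uniq)
        else:
            self.columns, self.codes, self.cards = columns, codes, cards
        self.n = len(next(iter(self.codes.values())))

    def resample(self, idx: np.ndarray) -> "DiscreteData":
        codes = {c: v[idx] for c, v in self.codes.items()}
        return DiscreteData(codes=codes, cards=self.cards, columns=self.columns)


@dataclass
class CITestResult:
    """G-test of conditional independence X ⟂ Y | Z from a contingency table."""

    g: float
    dof: int
    p_value: float


def _g_from_codes(xc, yc, rx, ry, zc=None, nz=1):
    """G = 2·N·MI(X;Y|Z) in nats from integer codes; zero cells contribute 0."""
    if zc is None:
        idx = yc * rx + xc
    else:
        idx = (zc * ry + yc) * rx + xc
    counts = np.bincount(idx, minlength=nz * ry * rx).reshape(nz, ry, rx).astype(float)
    n_z = counts.sum(axis=(1, 2), keepdims=True)
    n_xz = counts.sum(axis=1, keepdims=True)
    n_yz = counts.sum(axis=2, keepdims=True)
    mask = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(counts * n_z) - np.log(n_xz * n_yz)
    return float(2.0 * np.sum(counts[mask] * log_ratio[mask]))


def _ci_codes(data: DiscreteData, x: str, y: str, z: tuple) -> CITestResult:
    rx, ry = data.cards[x], data.cards[y]
    dof = (rx - 1) * (ry - 1) * int(np.prod([data.cards[v] for v in z], dtype=np.int64))
    if dof <= 0:
        return CITestResult(0.0, max(dof, 0), 1.0)
    if z:
        zc = data.codes[z[0]].copy()
        nz = data.cards[z[0]]
        for v in z[1:]:
            zc = zc * data.cards[v] + data.codes[v]
            nz *= data.cards[v]
        if nz * rx * ry > max(400_000, 8 * data.n):
            _, zc = np.unique(zc, return_inverse=True)
            nz = int(zc.max()) + 1
        g = _g_from_codes(data.codes[x], data.codes[y], rx, ry, zc, nz)
    else:
        g = _g_from_codes(data.codes[x], data.codes[y], rx, ry)
    return CITestResult(g, dof, float(chi2.sf(g, dof)))


def ci_test(data, x: str, y: str, z=()) -> CITestResult:
    """Conditional mutual-information G-test between columns ``x`` and ``y``.

    ``G = 2·N·MI(X;Y|Z)`` with MI in nats from empirical frequencies;
    degrees of freedom ``(r_x−1)(r_y−1)·∏ r_z`` over observed levels; the
    p-value is the upper chi-square tail.
    """
    if not isinstance(data, DiscreteData):
        data = DiscreteData(pd.DataFrame(data))
    return _ci_codes(data, x, y, tuple(z))


# ---------------------------------------------------------------------------
# graph container
# ---------------------------------------------------------------------------

@dataclass
class BNGraph:
    """Partially directed graph: directed edges plus undirected leftovers."""

    nodes: list[str]
    directed: set = field(default_factory=set)
    undirected: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.directed = {tuple(e) for e in self.directed}
        self.undirected = {frozenset(e) for e in self.undirected}
        for a, b in self.directed:
            if a == b:
                raise ValueError("self-loop")
            if frozenset((a, b)) in self.undirected or (b, a) in self.directed:
                raise ValueError(f"duplicate edge between {a} and {b}")
        dg = self.to_networkx()
        if not nx.is_directed_acyclic_graph(dg):
            raise ValueError("directed part contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.nodes)
        dg.add_edges_from(self.directed)
        return dg

    def skeleton(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((a, b) for a, b in self.directed)
        g.add_edges_from(tuple(e) for e in self.undirected)
        return g

    def parents(self, v: str) -> set:
        return {a for a, b in self.directed if b == v}

    def children(self, v: str) -> set:
        return {b for a, b in self.directed if a == v}

    def neighbors(self, v: str) -> set:
        out = self.parents(v) | self.children(v)
        for e in self.undirected:
            if v in e:
                out |= e - {v}
        return out

    def has_undirected_incident(self, v: str) -> bool:
        return any(v in e for e in self.undirected)

    def skeleton_edges(self) -> set:
        return {frozenset((a, b)) for a, b in self.directed} | set(self.undirected)


@dataclass
class MarkovBlanket:
    parents: set
    children: set
    spouses: set

    def all(self) -> set:
        return self.parents | self.children | self.spouses


@dataclass
class EdgeConfidence:
    """Bootstrap edge support: per unordered pair, strength and direction."""

    nodes: list[str]
    n_boot: int
    #: frozenset pair -> replicates containing the edge in either direction
    presence: dict = field(default_factory=dict)
    #: ordered pair -> (possibly fractional) count of that orientation
    orientation: dict = field(default_factory=dict)

    def strength(self, a: str, b: str) -> float:
        return self.presence.get(frozenset((a, b)), 0) / self.n_boot

    def direction(self, a: str, b: str) -> float:
        present = self.presence.get(frozenset((a, b)), 0)
        if present == 0:
            return 0.0
        return self.orientation.get((a, b), 0.0) / present

    def pairs(self):
        return sorted(self.presence, key=lambda e: tuple(sorted(e)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.pairs():
            a, b = sorted(e)
            rows.append(
                {"from": a, "to": b, "strength": self.strength(a, b), "direction": self.direction(a, b)}
            )
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])


# ---------------------------------------------------------------------------
# IAMB
# ---------------------------------------------------------------------------

def iamb_markov_blanket(target: str, data, alpha: float = DEFAULT_ALPHA, candidates=None) -> set:
    """IAMB blanket discovery: greedy grow by maximal conditional association,
    then shrink members that lost significance, iterated to a fixpoint."""
    if not isinstance(data, DiscreteData):
        data = DiscreteData(pd.DataFrame(data))
    candidates = [c for c in (candidates or data.columns) if c != target]
    if len(data.columns) < 2:
        raise ValueError("need at least 2 columns")
    mb: list[str] = []
    while True:
        changed = False
        # grow: admit the most associated significant candidate, repeatedly
        while True:
            best, best_g = None, -np.inf
            for c in candidates:
                if c in mb:
                    continue
                res = _ci_codes(data, c, target, tuple(mb))
                if res.p_value < alpha and res.g > best_g:
                    best, best_g = c, res.g
            if best is None:
                break
            mb.append(best)
            changed = True
        # shrink: drop members no longer significant given the rest
        shrunk = True
        while shrunk:
            shrunk = False
            for c in list(mb):
                rest = tuple(v for v in mb if v != c)
                res = _ci_codes(data, c, target, rest)
                if res.p_value >= alpha:
                    mb.remove(c)
                    shrunk = changed = True
        if not changed:
            break
    return set(mb)


# ---------------------------------------------------------------------------
# full structure learning
# ---------------------------------------------------------------------------

def _find_sepset(data, x, y, mbs, alpha, max_subset=None):
    """Search for a separating subset of the smaller blanket (minus x, y)."""
    cand_x = sorted(mbs[x] - {y})
    cand_y = sorted(mbs[y] - {x})
    pool = cand_x if len(cand_x) <= len(cand_y) else cand_y
    if max_subset is None:
        max_subset = len(pool)
    for size in range(0, max_subset + 1):
        for sub in itertools.combinations(pool, size):
            if _ci_codes(data, x, y, sub).p_value >= alpha:
                return set(sub)
    return None


def learn_structure(data, alpha: float = DEFAULT_ALPHA) -> BNGraph:
    """Learn a partially directed network from discrete data.

    Blankets for every node (IAMB) → AND-rule adjacency candidates →
    neighbour confirmation by separating-subset search → v-structure
    orientation (common neighbour absent from the separating set) → Meek
    orientation propagation. Deterministic for fixed data and alpha.
    """
    if not isinstance(data, DiscreteData):
        data = DiscreteData(pd.DataFrame(data))
    cols = data.columns
    mbs = {v: iamb_markov_blanket(v, data, alpha) for v in cols}

    sepsets: dict = {}
    adjacent: set = set()
    for x, y in itertools.combinations(cols, 2):
        if y in mbs[x] and x in mbs[y]:  # AND symmetry rule
            sep = _find_sepset(data, x, y, mbs, alpha)
            if sep is None:
                adjacent.add(frozenset((x, y)))
            else:
                sepsets[frozenset((x, y))] = sep

    nbrs = {v: set() for v in cols}
    for e in adjacent:
        a, b = tuple(e)
        nbrs[a].add(b)
        nbrs[b].add(a)

    directed: set = set()
    undirected = set(adjacent)

    def orient(a, b) -> bool:
        """Direct a→b if possible without duplicating or cycling."""
        e = frozenset((a, b))
        if (a, b) in directed:
            return False
        if (b, a) in directed or e not in undirected:
            return False
        dg = nx.DiGraph(list(directed) + [(a, b)])
        if not nx.is_directed_acyclic_graph(dg):
            return False
        undirected.discard(e)
        directed.add((a, b))
        return True

    # v-structures x→y←z for non-adjacent x, z with y outside their sepset
    for y in cols:
        for x, z in itertools.combinations(sorted(nbrs[y]), 2):
            if z in nbrs[x]:
                continue
            key = frozenset((x, z))
            sep = sepsets.get(key)
            if sep is None:
                sep = _find_sepset(data, x, z, mbs, alpha)
                if sep is not None:
                    sepsets[key] = sep
            if sep is not None and y not in sep:
                orient(x, y)
                orient(z, y)

    # Meek propagation (rules 1-3; sufficient without background knowledge)
    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # R1: w→x, x–y, w not adjacent to y  =>  x→y
                if any(w != y and y not in nbrs[w] for w in (p for p, q in directed if q == x)):
                    if orient(x, y):
                        changed = True
                        break
                # R2: x→w→y and x–y  =>  x→y
                if any((x, w) in directed and (w, y) in directed for w in nbrs[x] & nbrs[y]):
                    if orient(x, y):
                        changed = True
                        break
                # R3: x–w, x–v, w→y, v→y, w not adjacent to v  =>  x→y
                half = [w for w in nbrs[x] if frozenset((x, w)) in undirected and (w, y) in directed]
                if any(v not in nbrs[w] and v != w for w, v in itertools.permutations(half, 2)):
                    if orient(x, y):
                        changed = True
                        break
            if changed:
                break
    return BNGraph(list(cols), directed, undirected)


# ---------------------------------------------------------------------------
# bootstrap confidence and averaging
# ---------------------------------------------------------------------------

def bootstrap_confidence(data, B: int = 1000, alpha: float = DEFAULT_ALPHA, seed: int = 0) -> EdgeConfidence:
    """Edge strength and direction over ``B`` full-size bootstrap replicates.

    Undirected edges in a replicate count half toward each orientation.
    """
    if B < 1:
        raise ValueError("B must be ≥ 1")
    if not isinstance(data, DiscreteData):
        data = DiscreteData(pd.DataFrame(data))
    rng = np.random.default_rng(seed)
    conf = EdgeConfidence(nodes=list(data.columns), n_boot=B)
    for _ in range(B):
        idx = rng.integers(0, data.n, size=data.n)
        g = learn_structure(data.resample(idx), alpha)
        for a, b in g.directed:
            e = frozenset((a, b))
            conf.presence[e] = conf.presence.get(e, 0) + 1
            conf.orientation[(a, b)] = conf.orientation.get((a, b), 0.0) + 1.0
        for e in g.undirected:
            a, b = tuple(e)
            conf.presence[e] = conf.presence.get(e, 0) + 1
            conf.orientation[(a, b)] = conf.orientation.get((a, b), 0.0) + 0.5
            conf.orientation[(b, a)] = conf.orientation.get((b, a), 0.0) + 0.5
    return conf


def average_network(conf: EdgeConfidence, strength_threshold: float = 0.5):
    """Model-averaged network: keep strength ≥ threshold, majority direction.

    Exact 50/50 direction ties go to the lexicographically smaller source
    (logged in the returned notes); if the majority orientations form a
    directed cycle, the weakest-strength edge in the cycle is dropped
    (also logged). Returns ``(BNGraph, notes)``.
    """
    notes: list[str] = []
    edges = []
    for e in conf.pairs():
        a, b = sorted(e)
        s = conf.strength(a, b)
        if s < strength_threshold:
            continue
        d_ab = conf.direction(a, b)
        if d_ab > 0.5:
            edges.append((a, b, s))
        elif d_ab < 0.5:
            edges.append((b, a, s))
        else:
            notes.append(f"direction tie for {a}–{b}: oriented {a}→{b} by node order")
            edges.append((a, b, s))
    dg = nx.DiGraph()
    dg.add_nodes_from(conf.nodes)
    for a, b, s in edges:
        dg.add_edge(a, b, strength=s)
    while not nx.is_directed_acyclic_graph(dg):
        cycle = nx.find_cycle(dg)
        weakest = min(cycle, key=lambda e: dg.edges[e]["strength"])
        notes.append(f"cycle broken by dropping {weakest[0]}→{weakest[1]}")
        dg.remove_edge(*weakest[:2])
    return BNGraph(list(conf.nodes), set(dg.edges()), set()), notes


def prune_by_independence(graph: BNGraph, data, alpha: float = DEFAULT_ALPHA, conditional: bool = False) -> BNGraph:
    """Remove edges whose pairwise mutual-information test is not significant.

    The default is the marginal test between the two endpoints; with
    ``conditional=True`` directed edges are tested given the child's other
    parents instead.
    """
    if not isinstance(data, DiscreteData):
        data = DiscreteData(pd.DataFrame(data))
    directed = set()
    for a, b in graph.directed:
        z = tuple(sorted(graph.parents(b) - {a})) if conditional else ()
        if _ci_codes(data, a, b, z).p_value < alpha:
            directed.add((a, b))
    undirected = set()
    for e in graph.undirected:
        a, b = tuple(e)
        if _ci_codes(data, a, b, ()).p_value < alpha:
            undirected.add(e)
    return BNGraph(list(graph.nodes), directed, undirected)


# ---------------------------------------------------------------------------
# feature-set extraction
# ---------------------------------------------------------------------------

def markov_blanket_of(graph: BNGraph, node: str) -> MarkovBlanket:
    """Parents, children and spouses of ``node`` read off a directed graph.

    Spouses are co-parents of the node's children that are not themselves
    linked to the node. Any undirected edge touching the node is an error:
    the blanket is only defined once those edges are oriented.
    """
    if node not in graph.nodes:
        raise KeyError(node)
    if graph.has_undirected_incident(node):
        raise ValueError(f"undirected edge incident to {node!r}; orient it first")
    parents = graph.parents(node)
    children = graph.children(node)
    linked = parents | children | {node}
    spouses = set()
    for c in children:
        spouses |= graph.parents(c) - linked
    return MarkovBlanket(parents=parents, children=children, spouses=spouses - {node})


def all_path_features(graph: BNGraph, node: str) -> set:
    """Every node reachable from ``node`` in the undirected skeleton."""
    if node not in graph.nodes:
        raise KeyError(node)
    return nx.node_connected_component(graph.skeleton(), node) - {node}
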