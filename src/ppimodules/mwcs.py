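"""Maximum-weight connected subgraph (MWCS) search on node-weighted networks.

Given a network whose nodes carry additive scores (positive for genes below
the significance threshold, negative above it), the MWCS is the connected
node subset maximising the summed score — the functional module with the
strongest cumulative association.  Two solvers are provided:

* :func:`solve_exact` — exhaustive enumeration of connected induced
  subgraphs with branch-and-bound pruning; feasible for small graphs and
  used as the ground-truth oracle in tests.
* :func:`solve_heuristic` — a contraction + Steiner-tree-style greedy search
  that scales to genome-sized interaction networks.

The heuristic pipeline: (1) contract each connected component of
positive-score nodes into a super-node weighing the component sum; (2) route
shortest paths between super-nodes where traversing a negative node costs
its |score|; (3) greedily connect super-nodes to the growing tree whenever
the super-node's gain exceeds the connection cost; (4) expand back to
original nodes and prune non-positive leaves to a fixpoint.  A feasible
solution is always returned, so the heuristic score never exceeds the exact
optimum.
"""

from __future__ import annotations

import dataclasses
import heapq
import itertools
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .bum import NodeScores
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleResult",
    "MwcsSizeError",
    "align_inputs",
    "solve_exact",
    "solve_heuristic",
    "solve",
    "module_report",
]

_SCORE_ATOL = 1e-9


class MwcsSizeError(ValueError):
    """Graph too large for exhaustive search; use the heuristic solver."""


@dataclasses.dataclass(frozen=True)
class ModuleResult:
    """A connected node set with its cumulative score."""

    members: frozenset[str]
    total_score: float
    solver: str
    node_scores: dict[str, float]

    def __post_init__(self):
        if not self.members:
            raise ValueError("a module must be non-empty")
        total = sum(self.node_scores[m] for m in self.members)
        if abs(total - self.total_score) > 1e-9 * max(1.0, abs(total)):
            raise ValueError("total_score does not match the sum of member scores")

    @property
    def n_positive_members(self) -> int:
        return sum(1 for m in self.members if self.node_scores[m] > 0)

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.members)
        return pd.DataFrame(
            {"gene": rows, "score": [self.node_scores[g] for g in rows]}
        )

    def to_dict(self) -> dict:
        return {
            "members": sorted(self.members),
            "total_score": self.total_score,
            "solver": self.solver,
            "n_members": len(self.members),
            "n_positive_members": self.n_positive_members,
            "node_scores": {g: self.node_scores[g] for g in sorted(self.members)},
        }

    def to_graph(self, network: nx.Graph | None = None) -> nx.Graph:
        """Induced subgraph of the members with scores as node attributes."""
        if network is not None:
            G = network.subgraph(self.members).copy()
            G.graph.clear()  # inherited attrs (e.g. load reports) are not exportable
        else:
            G = nx.Graph()
            G.add_nodes_from(self.members)
        nx.set_node_attributes(G, {m: float(self.node_scores[m]) for m in self.members}, "score")
        G.graph["total_score"] = float(self.total_score)
        G.graph["solver"] = self.solver
        return G


# ---------------------------------------------------------------------------
# Input alignment
# ---------------------------------------------------------------------------

def align_inputs(
    network: nx.Graph,
    scores: NodeScores,
    missing_policy: str = "drop",
) -> tuple[nx.Graph, NodeScores]:
    """Reconcile the network's nodes with the scored genes.

    ``drop`` restricts the search graph to nodes that have a score;
    ``impute_zero`` keeps unscored network nodes with score 0 (warned).
    Genes scored but absent from the network are excluded from the search
    (they cannot join a connected module) and logged.
    """
    if missing_policy not in ("drop", "impute_zero"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    net_nodes = set(network.nodes)
    scored = set(scores.scores)
    off_network = scored - net_nodes
    if off_network:
        logger.info("%d scored gene(s) absent from the network; excluded", len(off_network))
    unscored = net_nodes - scored
    if missing_policy == "drop":
        keep = net_nodes & scored
        if not keep:
            raise ValueError("no overlap between network nodes and scored genes")
        sub = network.subgraph(keep).copy()
        new_scores = {g: scores.scores[g] for g in keep}
    else:
        if unscored:
            warnings.warn(
                f"{len(unscored)} network node(s) without scores imputed to 0", stacklevel=2
            )
        if not net_nodes & scored:
            raise ValueError("no overlap between network nodes and scored genes")
        sub = network.copy()
        new_scores = {g: scores.scores.get(g, 0.0) for g in net_nodes}
    return sub, NodeScores(tau=scores.tau, alpha_used=scores.alpha_used, scores=new_scores)


# ---------------------------------------------------------------------------
# Exact solver
# ---------------------------------------------------------------------------

def _better(score, size, members, best):
    """Tie-break: higher score, then fewer nodes, then lexicographic members."""
    if best is None:
        return True
    b_score, b_size, b_members = best
    if score != b_score:
        return score > b_score
    if size != b_size:
        return size < b_size
    return members < b_members


def solve_exact(network: nx.Graph, scores: NodeScores, max_nodes: int = 20) -> ModuleResult:
    """Enumerate every connected induced subgraph and return the best.

    Enumeration is connectivity-aware (subsets grow only through edges) with
    a branch-and-bound cut: a branch is abandoned when its current score plus
    all still-reachable positive score cannot strictly beat the incumbent.
    Ties are broken by (fewer nodes, then lexicographically smallest sorted
    member list), so the output is byte-stable.

    Raises :class:`MwcsSizeError` above ``max_nodes`` nodes.
    """
    nodes = sorted(network.nodes)
    if not nodes:
        raise ValueError("empty network")
    if len(nodes) > max_nodes:
        raise MwcsSizeError(
            f"{len(nodes)} nodes exceeds max_nodes={max_nodes}; use solve_heuristic"
        )
    s = {v: float(scores.scores[v]) for v in nodes}
    adj = {v: sorted(set(network.neighbors(v)) - {v}) for v in nodes}

    best: tuple | None = None  # (score, size, sorted member tuple)

    def consider(members: frozenset, score: float):
        nonlocal best
        key = (score, len(members), tuple(sorted(members)))
        if _better(*key, best):
            best = key

    # Enumerate connected sets whose smallest (sorted-order) node is `root`.
    for i, root in enumerate(nodes):
        banned_root = set(nodes[:i])

        def grow(members: frozenset, score: float, ext: list, banned: set, pos_avail: float):
            consider(members, score)
            # prune: even taking all reachable positive weight cannot win
            local_banned = set(banned)
            for u in ext:
                if u in local_banned:
                    continue
                gain_bound = score + pos_avail
                if best is not None and gain_bound < best[0]:
                    return
                new_ext = [w for w in ext if w != u and w not in local_banned]
                for w in adj[u]:
                    if w not in members and w != u and w not in local_banned and w not in new_ext:
                        new_ext.append(w)
                grow(
                    members | {u},
                    score + s[u],
                    new_ext,
                    local_banned,
                    pos_avail - max(s[u], 0.0),
                )
                local_banned.add(u)
                pos_avail -= max(s[u], 0.0)

        pos_total = sum(max(s[v], 0.0) for v in nodes if v not in banned_root and v != root)
        ext0 = [w for w in adj[root] if w not in banned_root]
        grow(frozenset([root]), s[root], ext0, banned_root, pos_total)

    score, _, members = best
    if score <= 0:
        warnings.warn("optimal module has non-positive total score", stacklevel=2)
    member_set = frozenset(members)
    return ModuleResult(
        members=member_set,
        total_score=score,
        solver="exact",
        node_scores={m: s[m] for m in member_set},
    )


# ---------------------------------------------------------------------------
# Heuristic solver
# ---------------------------------------------------------------------------

def _dijkstra_from(sources, cadj, entry_cost):
    """Multi-source Dijkstra over the contracted graph with node entry costs."""
    dist = {k: 0.0 for k in sources}
    parent: dict = {}
    heap = [(0.0, k) for k in sorted(sources)]
    heapq.heapify(heap)
    seen = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in seen:
            continue
        seen.add(u)
        for w in sorted(cadj[u]):
            nd = d + entry_cost(w)
            if w not in dist or nd < dist[w] - 1e-15:
                dist[w] = nd
                parent[w] = u
                heapq.heappush(heap, (nd, w))
    return dist, parent


def _greedy_tree(members_of, weight, cadj, entry_cost):
    """Grow a tree of super-nodes, accepting only net-positive connections."""
    start = max(members_of, key=lambda sid: (weight[sid], sid))
    tree: set = {start}
    remaining = set(members_of) - tree
    while remaining:
        dist, parent = _dijkstra_from(tree, cadj, entry_cost)
        cand = [(weight[t] - dist[t], t) for t in remaining if t in dist]
        if not cand:
            break
        gain, target = max(cand, key=lambda gt: (gt[0], gt[1]))
        if gain <= 0:
            break
        k = target
        while k not in tree:
            tree.add(k)
            remaining.discard(k)
            k = parent[k]
    return tree


def _steiner_pruned_tree(members_of, weight, cadj, entry_cost, node_value):
    """Steiner tree over all super-nodes, then strong pruning.

    Per-target greedy growth cannot see that several super-nodes may share a
    connecting trunk, so it under-collects in star-like configurations.  This
    stage spans ALL super-nodes with a minimum-cost Steiner approximation
    (MST of the metric closure) and removes unprofitable branches with the
    classic strong-pruning dynamic program: a child subtree is kept iff its
    net value is positive.
    """
    supers = sorted(members_of)
    # metric closure between super-nodes
    closure = {}
    paths = {}
    for sid in supers:
        dist, parent = _dijkstra_from([sid], cadj, entry_cost)
        for t in supers:
            if t > sid and t in dist:
                closure[(sid, t)] = dist[t]
                chain = [t]
                while chain[-1] != sid:
                    chain.append(parent[chain[-1]])
                paths[(sid, t)] = chain
    # Kruskal MST per metric-closure component (deterministic tie-break)
    parent_dsu = {sid: sid for sid in supers}

    def find(x):
        while parent_dsu[x] != x:
            parent_dsu[x] = parent_dsu[parent_dsu[x]]
            x = parent_dsu[x]
        return x

    expanded = nx.Graph()
    expanded.add_nodes_from(supers)
    for (a, b), cost in sorted(closure.items(), key=lambda kv: (kv[1], kv[0])):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_dsu[ra] = rb
            chain = paths[(a, b)]
            nx.add_path(expanded, chain)
    # spanning tree of the expansion (path unions may create cycles)
    root = max(supers, key=lambda sid: (weight[sid], sid))
    tree = nx.bfs_tree(expanded.subgraph(nx.node_connected_component(expanded, root)), root)

    # strong pruning: keep a child subtree iff its net value is positive
    keep = set()
    net = {}
    for v in reversed(list(nx.topological_sort(tree))):
        value = node_value(v)
        kept_children = []
        for c in tree.successors(v):
            if net[c] > 0:
                value += net[c]
                kept_children.append(c)
        net[v] = value
        tree.nodes[v]["kept_children"] = kept_children
    stack = [root]
    while stack:
        v = stack.pop()
        keep.add(v)
        stack.extend(tree.nodes[v]["kept_children"])
    return keep


def solve_heuristic(network: nx.Graph, scores: NodeScores, seed=None) -> ModuleResult:
    """Contraction + Steiner-style MWCS heuristic.

    Connected components of positive-score nodes are contracted into
    super-nodes, which are then joined across negative territory by two
    complementary constructions — per-target greedy growth and an MST-based
    Steiner tree with strong pruning — and the higher-scoring result is
    kept, with non-positive leaves pruned to a fixpoint.

    Guarantees: the result is connected; its score is at least the best
    single-node score and never exceeds the exact optimum; no leaf with
    score <= 0 remains; and every connected component of positive nodes is
    wholly inside or wholly outside the module.  Fully deterministic (ties
    broken by node identifiers); ``seed`` is accepted for interface symmetry
    with the stochastic stages.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    s = {v: float(scores.scores[v]) for v in network.nodes}

    positives = [v for v in network.nodes if s[v] > 0]
    if not positives:
        best_node = max(sorted(s), key=lambda v: s[v])
        warnings.warn(
            "all node scores are non-positive; returning the single best node", stacklevel=2
        )
        return ModuleResult(
            members=frozenset([best_node]),
            total_score=s[best_node],
            solver="heuristic",
            node_scores={best_node: s[best_node]},
        )

    # (1) contract positive components into super-nodes
    pos_comps = [sorted(c) for c in nx.connected_components(network.subgraph(positives))]
    pos_comps.sort()  # stable super-node indexing
    super_of = {}
    weight = {}
    members_of = {}
    for idx, comp in enumerate(pos_comps):
        sid = ("S", idx)
        members_of[sid] = comp
        weight[sid] = sum(s[v] for v in comp)
        for v in comp:
            super_of[v] = sid

    def vkey(v):
        # contracted-graph vertex for an original node
        return super_of.get(v, ("n", v))

    # (2) contracted adjacency; entry cost: 0 for super-nodes, -score else
    cadj: dict = {}
    for a, b in network.edges:
        ka, kb = vkey(a), vkey(b)
        if ka == kb:
            continue
        cadj.setdefault(ka, set()).add(kb)
        cadj.setdefault(kb, set()).add(ka)
    for v in network.nodes:
        cadj.setdefault(vkey(v), set())

    def entry_cost(k):
        return 0.0 if k[0] == "S" else -s[k[1]]

    def node_value(k):
        return weight[k] if k[0] == "S" else s[k[1]]

    def expand_and_prune(tree_keys) -> tuple[set, float]:
        module = set()
        for k in tree_keys:
            if k[0] == "S":
                module.update(members_of[k])
            else:
                module.add(k[1])
        sub = network.subgraph(module).copy()
        while sub.number_of_nodes() > 1:
            leaves = sorted(v for v in sub.nodes if sub.degree(v) <= 1 and s[v] <= 0)
            if not leaves:
                break
            sub.remove_node(leaves[0])
        module = set(sub.nodes)
        return module, sum(s[v] for v in module)

    # (3) two constructions; keep the better module
    candidates = [
        expand_and_prune(_greedy_tree(members_of, weight, cadj, entry_cost)),
        expand_and_prune(
            _steiner_pruned_tree(members_of, weight, cadj, entry_cost, node_value)
        ),
    ]
    module, total = candidates[0]
    for cand_module, cand_total in candidates[1:]:
        if _better(cand_total, len(cand_module), tuple(sorted(cand_module)),
                   (total, len(module), tuple(sorted(module)))):
            module, total = cand_module, cand_total

    return ModuleResult(
        members=frozenset(module),
        total_score=total,
        solver="heuristic",
        node_scores={m: s[m] for m in module},
    )


def solve(network: nx.Graph, scores: NodeScores, solver: str = "heuristic", **kw) -> ModuleResult:
    """Dispatch to :func:`solve_exact` or :func:`solve_heuristic`."""
    if solver == "exact":
        return solve_exact(network, scores, **kw)
    if solver == "heuristic":
        return solve_heuristic(network, scores, **kw)
    raise ValueError(f"unknown solver: {solver!r}")


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def module_report(
    result: ModuleResult,
    network: nx.Graph,
    gene_sets: GeneSetCollection | None = None,
) -> dict:
    """Summary counts for a module: size, positive members, per-set overlap."""
    report = {
        "n_members": len(result.members),
        "n_positive_members": result.n_positive_members,
        "total_score": result.total_score,
        "n_edges": network.subgraph(result.members).number_of_edges(),
        "per_set": {},
    }
    if gene_sets is not None:
        for name, members in gene_sets.items():
            report["per_set"][name] = len(result.members & members)
    return report


# ---------------------------------------------------------------------------
# Independent brute-force oracle (test/reference use)
# ---------------------------------------------------------------------------

def brute_force_optimum(network: nx.Graph, scores: NodeScores) -> float:
    """Optimal MWCS score by naive enumeration of ALL node subsets.

    Deliberately shares no code with :func:`solve_exact`: subsets come from
    ``itertools.combinations`` and connectivity is checked by breadth-first
    search.  Exponential — reference/oracle use only.
    """
    nodes = sorted(network.nodes)
    adj = {v: set(network.neighbors(v)) for v in nodes}
    s = scores.scores
    best = -np.inf
    for r in range(1, len(nodes) + 1):
        for combo in itertools.combinations(nodes, r):
            subset = set(combo)
            # BFS connectivity
            stack = [combo[0]]
            seen = {combo[0]}
            while stack:
                u = stack.pop()
                for w in adj[u] & subset:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if len(seen) == len(subset):
                total = sum(s[v] for v in combo)
                if total > best:
                    best = total
    return float(best)
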