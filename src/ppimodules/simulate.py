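"""Synthetic networks, planted modules and mixture-distributed p-values.

Everything the analysis consumes — a reference interaction network, a
per-gene statistics table and disease gene sets — can be generated here with
known ground truth, so the whole pipeline is testable without any external
data.  The generator plants a sharp-null mixture: a connected module of
genes whose p-values come from the Beta(alpha_signal, 1) signal law, against
a uniform background, which makes module-recovery truth unambiguous.  Mean
expression is drawn log-normally, independent of the p-values by default;
``expression_correlation`` couples the two to stress expression matching.

What this emulates: the shape of differential-expression p-value
distributions and the scale-free-ish topology of curated interaction maps.
What it does not: read-count noise, library-size effects, correlated genes
within pathways, or literature bias in interaction coverage.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import as_rng, seed_int, spawn_seeds
from .io import GeneTable

__all__ = [
    "SyntheticInstance",
    "generate_network",
    "plant_module",
    "generate_pvalues",
    "plant_cross_connectivity",
    "make_instance",
]


@dataclasses.dataclass(frozen=True)
class SyntheticInstance:
    """A generated dataset plus the ground truth that produced it."""

    network: nx.Graph
    planted_module: frozenset[str]
    table: GeneTable
    disease_set: frozenset[str] | None
    truth: dict
    seed: object = None


def _gene_labels(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_network(
    n_nodes: int,
    model: str = "preferential_attachment",
    params: dict | None = None,
    seed=None,
) -> nx.Graph:
    """Generate a simple undirected network with string gene-id labels.

    Models: ``erdos_renyi`` (param ``p``), ``preferential_attachment``
    (param ``m``), ``configuration`` (param ``degree_sequence``; sampling is
    rejected until the realisation is simple).  Deterministic given ``seed``.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    params = dict(params or {})
    s = seed_int(seed)
    if model == "erdos_renyi":
        G = nx.gnp_random_graph(n_nodes, params.get("p", 0.1), seed=s)
    elif model == "preferential_attachment":
        G = nx.barabasi_albert_graph(n_nodes, params.get("m", 3), seed=s)
    elif model == "configuration":
        seq = params.get("degree_sequence")
        if seq is None:
            raise ValueError("configuration model needs params={'degree_sequence': [...]}")
        try:
            G = nx.random_degree_sequence_graph(seq, seed=s, tries=100)
        except (nx.NetworkXUnfeasible, nx.NetworkXError) as err:
            raise ValueError(f"infeasible degree sequence: {err}") from err
    else:
        raise ValueError(f"unknown network model: {model!r}")
    labels = _gene_labels(n_nodes)
    return nx.relabel_nodes(G, dict(zip(range(n_nodes), labels)))


def plant_module(network: nx.Graph, module_size: int, seed=None) -> frozenset[str]:
    """Pick a random connected subgraph of the requested size.

    Grows by random-walk frontier expansion from a random start node inside
    a sufficiently large connected component, so the planted set always
    induces a connected subgraph.
    """
    if module_size < 1:
        raise ValueError("module_size must be >= 1")
    rng = as_rng(seed)
    comps = [sorted(c) for c in nx.connected_components(network) if len(c) >= module_size]
    if not comps:
        raise ValueError(f"no connected component of size >= {module_size}")
    comps.sort()
    comp = comps[int(rng.integers(len(comps)))]
    start = comp[int(rng.integers(len(comp)))]
    module = {start}
    frontier = sorted(set(network.neighbors(start)) - module)
    while len(module) < module_size:
        u = frontier[int(rng.integers(len(frontier)))]
        module.add(u)
        frontier = sorted(
            (set(frontier) | set(network.neighbors(u))) - module
        )
    return frozenset(module)


def generate_pvalues(
    network: nx.Graph,
    planted,
    alpha_signal: float,
    seed=None,
    expression_log_mean: float = 2.0,
    expression_log_sd: float = 1.0,
    expression_correlation: float = 0.0,
) -> GeneTable:
    """Draw per-gene p-values: Beta(alpha_signal, 1) for planted genes, else uniform.

    The Beta(a, 1) draw uses inverse-CDF sampling, p = u**(1/a).  Mean
    expression is log-normal; with ``expression_correlation`` > 0 its
    log-scale value is shifted downward in proportion to log10(p), coupling
    expression to significance to stress decile matching.
    """
    if not (0 < alpha_signal < 1):
        raise ValueError("alpha_signal must lie in (0, 1)")
    rng = as_rng(seed)
    planted = set(planted)
    genes = sorted(network.nodes)
    u = 1.0 - rng.random(len(genes))  # in (0, 1]
    is_planted = np.array([g in planted for g in genes])
    p = np.where(is_planted, u ** (1.0 / alpha_signal), u)
    p = np.clip(p, 1e-300, 1.0)
    log_expr = rng.normal(expression_log_mean, expression_log_sd, size=len(genes))
    if expression_correlation:
        log_expr = log_expr + expression_correlation * (-np.log10(p) - 1.0)
    return GeneTable(
        pd.DataFrame(
            {
                "gene": genes,
                "p_value": p,
                "mean_expression": np.exp(log_expr),
            }
        )
    )


def plant_cross_connectivity(
    network: nx.Graph, disease_set, de_set, extra_edges: int, seed=None
) -> nx.Graph:
    """Add exactly ``extra_edges`` new edges between two gene sets.

    Candidate pairs are non-adjacent (disease, DE) node pairs with distinct
    endpoints; the requested count above the number of candidates is an
    error.  Returns a new graph; the input is untouched.
    """
    if extra_edges < 0:
        raise ValueError("extra_edges must be >= 0")
    H = network.copy()
    if extra_edges == 0:
        return H
    rng = as_rng(seed)
    disease = sorted(set(disease_set) & set(network.nodes))
    de = sorted(set(de_set) & set(network.nodes))
    candidates = [
        (d, e) for d in disease for e in de if d != e and not network.has_edge(d, e)
    ]
    if extra_edges > len(candidates):
        raise ValueError(
            f"requested {extra_edges} cross edges but only {len(candidates)} non-edges available"
        )
    idx = rng.choice(len(candidates), size=extra_edges, replace=False)
    H.add_edges_from(candidates[i] for i in idx)
    return H


def make_instance(
    n_nodes: int = 500,
    model: str = "preferential_attachment",
    params: dict | None = None,
    module_size: int = 20,
    alpha_signal: float = 0.1,
    disease_size: int | None = None,
    cross_edge_excess: int = 0,
    de_quantile: float = 0.05,
    seed=None,
    **pvalue_kw,
) -> SyntheticInstance:
    """Compose a full synthetic dataset with planted structure.

    Defaults generate the reference benchmark: a 500-node preferential-
    attachment network (m=3) with a connected 20-gene planted module whose
    p-values follow Beta(0.1, 1).  Optionally draws a disease set of
    ``disease_size`` random genes and adds ``cross_edge_excess`` extra edges
    between it and the most significant ``de_quantile`` fraction of genes.
    """
    params = dict(params or {})
    if model == "preferential_attachment":
        params.setdefault("m", 3)
    s_net, s_mod, s_pv, s_dis, s_cross = spawn_seeds(seed, 5)
    network = generate_network(n_nodes, model, params, seed=s_net)
    planted = plant_module(network, module_size, seed=as_rng(s_mod))
    table = generate_pvalues(network, planted, alpha_signal, seed=as_rng(s_pv), **pvalue_kw)

    disease = None
    if disease_size is not None:
        rng = as_rng(s_dis)
        genes = sorted(network.nodes)
        disease = frozenset(
            genes[i] for i in rng.choice(len(genes), size=disease_size, replace=False)
        )
        if cross_edge_excess:
            pv = table.p_value_of()
            n_de = max(1, int(round(de_quantile * len(genes))))
            de = frozenset(pv.sort_values().index[:n_de])
            network = plant_cross_connectivity(
                network, disease, de, cross_edge_excess, seed=as_rng(s_cross)
            )
    truth = {
        "lambda_mix": 1.0 - module_size / n_nodes,
        "alpha_signal": alpha_signal,
        "module_size": module_size,
        "cross_edge_excess": cross_edge_excess,
        "model": model,
        "params": params,
    }
    return SyntheticInstance(
        network=network,
        planted_module=planted,
        table=table,
        disease_set=disease,
        truth=truth,
        seed=seed,
    )
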