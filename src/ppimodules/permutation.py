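"""Empirical significance of module membership by joint permutation.

The MWCS is a selected object: every gene in it was chosen partly because of
its p-value and partly because of where it sits in the network, so no
analytic null exists for "gene g belongs to the module".  Significance is
therefore assessed empirically: the search is repeated B times under a joint
null that (a) randomly permutes the p-values across genes and (b) rewires
the network with degree-preserving double-edge swaps, and the frequency with
which each observed-module gene reappears in null modules estimates how
often it would be picked by chance alone.

Per gene, the raw null frequency k/B is reported alongside the pseudocounted
empirical p-value (k+1)/(B+1) (never exactly zero) and a Bonferroni
adjustment over the genes of the observed module.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from . import bum, mwcs
from ._rng import as_rng, spawn_seeds
from .io import GeneTable

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationSummary",
    "rewire_preserving_degrees",
    "permute_scores",
    "null_mwcs_frequencies",
    "flag_significant",
]


@dataclasses.dataclass(frozen=True)
class PermutationSummary:
    """Per-gene null frequencies and empirical p-values for an observed module."""

    B: int
    null_counts: dict[str, int]
    observed_module: mwcs.ModuleResult
    seed: object = None

    def frequency(self, gene: str) -> float:
        """Raw null frequency k/B."""
        return self.null_counts.get(gene, 0) / self.B

    def empirical_p(self, gene: str) -> float:
        """Pseudocounted estimator (k+1)/(B+1); minimum attainable 1/(B+1)."""
        return (self.null_counts.get(gene, 0) + 1) / (self.B + 1)

    def adjusted_p(self, gene: str) -> float:
        """Bonferroni over the m genes of the observed module."""
        m = len(self.observed_module.members)
        return min(1.0, self.empirical_p(gene) * m)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.observed_module.members)
        return pd.DataFrame(
            {
                "gene": genes,
                "score": [self.observed_module.node_scores[g] for g in genes],
                "null_count": [self.null_counts.get(g, 0) for g in genes],
                "frequency": [self.frequency(g) for g in genes],
                "empirical_p": [self.empirical_p(g) for g in genes],
                "adjusted_p": [self.adjusted_p(g) for g in genes],
            }
        )

    def to_dict(self) -> dict:
        return {
            "B": self.B,
            "observed_module": self.observed_module.to_dict(),
            "genes": self.to_frame().to_dict(orient="records"),
        }


def rewire_preserving_degrees(
    network: nx.Graph, n_swaps: int | None = None, seed=None
) -> nx.Graph:
    """Randomise a graph by double-edge swaps that preserve every degree.

    ``n_swaps`` proposals are drawn (default ``10 * |edges|``); a proposal
    replacing edges (a, b) and (c, d) with (a, d) and (c, b) is rejected if
    it would introduce a self-loop or a duplicate edge, so the output is
    always simple and has exactly the input's degree sequence.  Deterministic
    given ``seed``.  If not a single proposal is accepted, the input graph is
    returned unchanged with a warning.
    """
    m = network.number_of_edges()
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    if n_swaps is None:
        n_swaps = 10 * m
    rng = as_rng(seed)
    H = network.copy()
    edges = [tuple(e) for e in H.edges]
    accepted = 0
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if H.has_edge(a, d) or H.has_edge(c, b):
            continue
        H.remove_edge(a, b)
        H.remove_edge(c, d)
        H.add_edge(a, d)
        H.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    if accepted == 0:
        warnings.warn("no valid degree-preserving swap found; returning input", stacklevel=2)
        return network.copy()
    return H


def permute_scores(table: GeneTable, seed=None) -> GeneTable:
    """Randomly reassign p-values across gene ids (uniform permutation).

    The multiset of p-values is exactly preserved; only the gene labels move.
    """
    if len(table) == 0:
        raise ValueError("empty gene table")
    rng = as_rng(seed)
    perm = rng.permutation(len(table))
    return table.with_permuted_pvalues(perm)


def null_mwcs_frequencies(
    network: nx.Graph,
    table: GeneTable,
    B: int = 1000,
    solver: str = "heuristic",
    seed=None,
    fit: bum.BumFit | None = None,
    tau: float | None = None,
    n_swaps: int | None = None,
    refit: bool = False,
    missing_policy: str = "drop",
    observed: mwcs.ModuleResult | None = None,
) -> PermutationSummary:
    """Estimate how often each observed-module gene appears in null modules.

    Each of the B iterations applies BOTH null operations — a p-value
    permutation and a fresh degree-preserving rewiring — with independent
    substream seeds, rescoring the permuted p-values with the observed fit's
    (alpha, tau) so the score multiset is exactly preserved and only the
    assignment and topology vary.  Set ``refit=True`` to refit the mixture
    per permutation instead.

    Returns a :class:`PermutationSummary` keyed to the observed module.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    seeds = spawn_seeds(seed, B + 1)
    if fit is None:
        fit = bum.fit_bum(table.p_values, seed=seeds[0])
    if tau is None:
        tau = bum.bonferroni_threshold(len(table))

    if observed is None:
        scores = bum.score_nodes(table, fit, tau)
        net_o, scores_o = mwcs.align_inputs(network, scores, missing_policy)
        observed = mwcs.solve(net_o, scores_o, solver=solver)

    counts: dict[str, int] = {}
    for b in range(B):
        sub = seeds[b + 1].spawn(3)
        t_b = permute_scores(table, seed=as_rng(sub[0]))
        net_b = rewire_preserving_degrees(network, n_swaps=n_swaps, seed=as_rng(sub[1]))
        fit_b = bum.fit_bum(t_b.p_values, seed=sub[2]) if refit else fit
        scores_b = bum.score_nodes(t_b, fit_b, tau)
        net_ab, scores_ab = mwcs.align_inputs(net_b, scores_b, missing_policy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_module = mwcs.solve(net_ab, scores_ab, solver=solver)
        for g in null_module.members:
            counts[g] = counts.get(g, 0) + 1

    return PermutationSummary(B=B, null_counts=counts, observed_module=observed, seed=seed)


def flag_significant(summary: PermutationSummary, level: float = 0.05) -> set[str]:
    """Genes of the observed module with Bonferroni-adjusted empirical p < level."""
    return {
        g for g in summary.observed_module.members if summary.adjusted_p(g) < level
    }
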