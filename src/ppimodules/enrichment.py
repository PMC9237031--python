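"""Connectivity enrichment between gene sets and expression-matched nulls.

Tests whether a disease gene set (e.g. curated neurodevelopmental-disorder
genes) is excessively connected on the interaction network to a set of
differentially expressed genes.  Because co-expressed genes are better
connected than random gene pairs, the null distribution is built from random
gene sets matched to the disease set's expression profile — either by
decile bins of mean expression or by a per-gene +/-10% expression window —
rather than from unconstrained random draws.

Also provides plain overlap tests (hypergeometric and binomial) for gene-set
over-representation.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._rng import as_rng, spawn_seeds
from .io import GeneSetCollection, GeneTable

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionBins",
    "ConnectivityEnrichment",
    "assign_expression_deciles",
    "sample_matched_set",
    "connectivity_statistic",
    "connectivity_enrichment",
    "overlap_test",
]


@dataclasses.dataclass(frozen=True)
class ExpressionBins:
    """Rank-based expression bins (deciles by default)."""

    n_bins: int
    bin_edges: tuple[float, ...]
    assignment: dict[str, int]  # gene -> bin index in [1, n_bins]

    def members(self, bin_index: int) -> list[str]:
        return sorted(g for g, b in self.assignment.items() if b == bin_index)

    def histogram(self, genes) -> np.ndarray:
        """Per-bin counts of ``genes`` (genes without a bin are ignored)."""
        h = np.zeros(self.n_bins, dtype=int)
        for g in genes:
            b = self.assignment.get(g)
            if b is not None:
                h[b - 1] += 1
        return h


@dataclasses.dataclass(frozen=True)
class ConnectivityEnrichment:
    """Observed vs expression-matched-null connectivity for one disease set."""

    disease_set_name: str
    observed_stat: float
    null_stats: np.ndarray
    empirical_p: float
    adjusted_p: float
    matching: str
    B: int
    seed: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "disease_set": self.disease_set_name,
                    "observed_stat": self.observed_stat,
                    "null_mean": float(np.mean(self.null_stats)),
                    "null_sd": float(np.std(self.null_stats)),
                    "empirical_p": self.empirical_p,
                    "adjusted_p": self.adjusted_p,
                    "matching": self.matching,
                    "B": self.B,
                }
            ]
        )

    def to_dict(self) -> dict:
        rec = self.to_frame().to_dict(orient="records")[0]
        return rec


def assign_expression_deciles(table: GeneTable, n_bins: int = 10) -> ExpressionBins:
    """Bin genes into expression deciles by rank of mean expression.

    Genes are ranked by mean expression (ties broken by gene id so the
    assignment is deterministic) and split into ``n_bins`` near-equal rank
    bins; the assignment is invariant under monotone relabeling of the
    expression values.
    """
    expr = table.mean_expression.dropna()
    if len(expr) < n_bins:
        raise ValueError(f"need at least {n_bins} genes with expression, got {len(expr)}")
    order = sorted(expr.index, key=lambda g: (expr[g], g))
    chunks = np.array_split(np.arange(len(order)), n_bins)
    assignment = {}
    edges = []
    for b, idx in enumerate(chunks, start=1):
        for i in idx:
            assignment[order[i]] = b
        edges.append(float(expr[order[idx[-1]]]))
    return ExpressionBins(n_bins=n_bins, bin_edges=tuple(edges), assignment=assignment)


def sample_matched_set(
    bins_or_table,
    target_set,
    universe,
    strategy: str = "decile",
    n_sets: int = 1,
    seed=None,
    table: GeneTable | None = None,
) -> list[frozenset[str]]:
    """Draw random gene sets matched to a target set's expression profile.

    ``decile``: each sampled set reproduces the target's per-bin decile
    counts exactly, drawing without replacement from ``universe`` minus the
    target.  ``pct10``: each target gene is replaced by a random gene whose
    mean expression lies within +/-10% of it.

    Target genes outside the universe or without expression are dropped with
    a warning; an exhausted bin or window is an error naming it.
    """
    rng = as_rng(seed)
    universe = set(universe)
    if strategy == "decile":
        if isinstance(bins_or_table, GeneTable):
            bins = assign_expression_deciles(bins_or_table)
        else:
            bins = bins_or_table
        target = set(target_set) & universe & set(bins.assignment)
        dropped = len(set(target_set)) - len(target)
        if dropped:
            warnings.warn(
                f"{dropped} target gene(s) outside the universe or without expression dropped",
                stacklevel=2,
            )
        if not target:
            raise ValueError("target set is empty after restriction to the universe")
        need = bins.histogram(target)
        pool = {
            b: [g for g in bins.members(b) if g in universe and g not in target]
            for b in range(1, bins.n_bins + 1)
        }
        for b in range(1, bins.n_bins + 1):
            if need[b - 1] > len(pool[b]):
                raise ValueError(
                    f"bin {b}: need {need[b-1]} matched genes but only {len(pool[b])} candidates"
                )
        out = []
        for _ in range(n_sets):
            picked: list[str] = []
            for b in range(1, bins.n_bins + 1):
                k = int(need[b - 1])
                if k:
                    idx = rng.choice(len(pool[b]), size=k, replace=False)
                    picked.extend(pool[b][i] for i in idx)
            out.append(frozenset(picked))
        return out

    if strategy == "pct10":
        tbl = table if table is not None else bins_or_table
        if not isinstance(tbl, GeneTable):
            raise TypeError("pct10 matching requires a GeneTable with mean expression")
        expr = tbl.mean_expression.dropna()
        target = set(target_set) & universe & set(expr.index)
        dropped = len(set(target_set)) - len(target)
        if dropped:
            warnings.warn(
                f"{dropped} target gene(s) outside the universe or without expression dropped",
                stacklevel=2,
            )
        if not target:
            raise ValueError("target set is empty after restriction to the universe")
        candidates = {
            g: [
                u
                for u in sorted(universe & set(expr.index) - target)
                if 0.9 * expr[g] <= expr[u] <= 1.1 * expr[g]
            ]
            for g in sorted(target)
        }
        for g, cand in candidates.items():
            if not cand:
                raise ValueError(f"no candidate within +/-10% expression of gene {g!r}")
        out = []
        for _ in range(n_sets):
            picked: set[str] = set()
            for g in sorted(target):
                avail = [u for u in candidates[g] if u not in picked]
                if not avail:
                    raise ValueError(f"candidates within +/-10% of gene {g!r} exhausted")
                picked.add(avail[int(rng.integers(len(avail)))])
            out.append(frozenset(picked))
        return out

    raise ValueError(f"unknown matching strategy: {strategy!r}")


def connectivity_statistic(network: nx.Graph, set_a, set_b) -> float:
    """Proportion of connections linking two gene sets.

    Returns (# edges with one endpoint in each set) / (# edges incident to
    the union of both sets).  Genes appearing in both sets are removed from
    ``set_b`` with a warning so overlap cannot inflate the cross-count; a
    zero denominator returns 0 with a warning.
    """
    nodes = set(network.nodes)
    A = set(set_a) & nodes
    B = set(set_b) & nodes
    overlap = A & B
    if overlap:
        warnings.warn(
            f"{len(overlap)} gene(s) in both sets assigned to the first set only", stacklevel=2
        )
        B -= overlap
    if not A and not B:
        raise ValueError("both sets are empty after restriction to the network")
    union = A | B
    adj = network.adj
    cross = sum(1 for a in A for v in adj[a] if v in B)
    degree_sum = sum(len(adj[u]) for u in union)
    internal = sum(1 for u in union for v in adj[u] if v in union) // 2
    incident = degree_sum - internal
    if incident == 0:
        warnings.warn("no edges incident to either set; statistic set to 0", stacklevel=2)
        return 0.0
    return cross / incident


def connectivity_enrichment(
    network: nx.Graph,
    disease_sets: GeneSetCollection,
    de_set,
    table: GeneTable,
    B: int = 1000,
    matching: str = "decile",
    seed=None,
) -> list[ConnectivityEnrichment]:
    """Connectivity of each disease set to the DE set vs matched random sets.

    For each disease set the observed statistic is compared with B random
    sets matched to the disease set's expression profile (the DE set is held
    fixed).  Empirical p-values use the one-sided >= rule with a +1
    pseudocount and are Bonferroni-adjusted over the number of disease sets
    tested.
    """
    expr = table.mean_expression.dropna()
    universe = set(expr.index)
    bins = assign_expression_deciles(table) if matching == "decile" else None
    de = frozenset(de_set)
    results = []
    n_tests = len(disease_sets)
    child_seeds = spawn_seeds(seed, n_tests)
    for child, (name, dset) in zip(child_seeds, sorted(disease_sets.items())):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            observed = connectivity_statistic(network, dset, de)
            nulls = sample_matched_set(
                bins if matching == "decile" else table,
                dset,
                universe,
                strategy=matching,
                n_sets=B,
                seed=as_rng(child),
                table=table,
            )
            null_stats = np.array(
                [connectivity_statistic(network, s, de) for s in nulls], dtype=float
            )
        emp = (1 + int((null_stats >= observed).sum())) / (B + 1)
        results.append(
            ConnectivityEnrichment(
                disease_set_name=name,
                observed_stat=observed,
                null_stats=null_stats,
                empirical_p=emp,
                adjusted_p=min(1.0, emp * n_tests),
                matching=matching,
                B=B,
                seed=seed,
            )
        )
    return results


def overlap_test(query_set, reference_set, universe, binom_prob: float | None = None) -> dict:
    """Over-representation of a query set in a reference set.

    Both sets are restricted to the universe.  Reports the overlap count,
    the odds ratio from the 2x2 table (Haldane 0.5 correction when any cell
    is zero), the hypergeometric upper-tail p-value and a binomial
    upper-tail p-value whose success probability defaults to
    |reference| / |universe| (override with ``binom_prob``).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    Q = set(query_set) & universe
    R = set(reference_set) & universe
    N, K, n = len(universe), len(R), len(Q)
    k = len(Q & R)
    hyper_p = float(stats.hypergeom.sf(k - 1, N, K, n))
    prob = K / N if binom_prob is None else binom_prob
    if n > 0 and 0 < prob < 1:
        binom_p = float(stats.binomtest(k, n, prob, alternative="greater").pvalue)
    else:
        binom_p = 1.0
    a, b = k, n - k
    c, d = K - k, N - K - (n - k)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return {
        "overlap_count": k,
        "odds_ratio": float(odds_ratio),
        "hypergeom_p": hyper_p,
        "binomial_p": binom_p,
        "n_query": n,
        "n_reference": K,
        "n_universe": N,
    }
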