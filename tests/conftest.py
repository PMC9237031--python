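import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ppimodules import GeneTable, NodeScores, simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def draw_bum_sample(n: int, lam: float, alpha: float, rng) -> np.ndarray:
    """Independent oracle for the mixture: draw from it directly."""
    noise = rng.random(n) < lam
    u = 1.0 - rng.random(n)  # in (0, 1]
    return np.where(noise, u, u ** (1.0 / alpha))


def random_scored_graph(seed: int, n_lo: int = 6, n_hi: int = 14, p: float = 0.3):
    """Erdos-Renyi graph with Normal(0,1) node scores, for solver tests."""
    rg = np.random.default_rng(seed)
    n = int(rg.integers(n_lo, n_hi + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rg.integers(2**31)))
    g = nx.relabel_nodes(g, {j: f"N{j:02d}" for j in g.nodes})
    scores = NodeScores(
        tau=0.05, alpha_used=0.5, scores={v: float(rg.normal()) for v in g.nodes}
    )
    return g, scores


def toy_table(p_values: dict[str, float], expression: dict[str, float] | None = None) -> GeneTable:
    genes = sorted(p_values)
    data = {"gene": genes, "p_value": [p_values[g] for g in genes]}
    if expression is not None:
        data["mean_expression"] = [expression[g] for g in genes]
    return GeneTable(pd.DataFrame(data))


@pytest.fixture(scope="session")
def synthetic_instance():
    """Reference planted-module instance shared across tests (read-only)."""
    return simulate.make_instance(seed=11)


@pytest.fixture
def path_graph_scores():
    """Path A(-1)-B(+2)-C(-0.5)-D(+1); optimum is {B,C,D} with score 2.5."""
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
    scores = NodeScores(
        tau=0.05, alpha_used=0.5, scores={"A": -1.0, "B": 2.0, "C": -0.5, "D": 1.0}
    )
    return g, scores
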