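"""Readers and writers for networks, gene tables, gene sets and results.

All downstream analysis consumes the types defined here:

* a network is a simple undirected :class:`networkx.Graph` whose nodes are
  gene identifiers (exact, case-sensitive strings);
* a :class:`GeneTable` holds per-gene differential-expression statistics
  (p-value, optional log fold-change and mean expression);
* a :class:`GeneSetCollection` holds named gene sets read from GMT.

Identifier matching throughout the package is exact string match; symbol
aliasing and identifier-mapping services are out of scope.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTable",
    "GeneSetCollection",
    "NetworkLoadReport",
    "read_network",
    "write_network",
    "read_gene_table",
    "write_gene_table",
    "read_gmt",
    "write_gmt",
    "write_results",
    "write_manifest",
    "file_digest",
]


# ---------------------------------------------------------------------------
# Gene table
# ---------------------------------------------------------------------------

class GeneTable:
    """Per-gene statistics: p-values plus optional covariates.

    Parameters
    ----------
    data
        DataFrame with columns ``gene`` (unique strings), ``p_value``
        (floats strictly in (0, 1]), and optionally ``log_fc`` and
        ``mean_expression`` (non-negative).
    """

    REQUIRED = ("gene", "p_value")
    OPTIONAL = ("log_fc", "mean_expression")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"gene table is missing required column(s): {missing}")
        data = data.reset_index(drop=True).copy()
        data["gene"] = data["gene"].astype(str)
        if data["gene"].duplicated().any():
            dups = data.loc[data["gene"].duplicated(), "gene"].unique()[:5]
            raise ValueError(f"duplicate gene ids in table: {list(dups)} ...")
        p = pd.to_numeric(data["p_value"], errors="raise").astype(float)
        if p.isna().any():
            raise ValueError("gene table contains missing p-values")
        if (p <= 0).any() or (p > 1).any():
            bad = data.loc[(p <= 0) | (p > 1), "gene"].tolist()[:5]
            raise ValueError(f"p-values must lie in (0, 1]; offending genes: {bad}")
        data["p_value"] = p
        if "mean_expression" in data.columns:
            expr = pd.to_numeric(data["mean_expression"], errors="raise").astype(float)
            if (expr.dropna() < 0).any():
                raise ValueError("mean_expression must be non-negative")
            data["mean_expression"] = expr
        self.data = data

    # -- accessors ----------------------------------------------------------

    @property
    def gene_ids(self) -> np.ndarray:
        return self.data["gene"].to_numpy()

    @property
    def p_values(self) -> np.ndarray:
        return self.data["p_value"].to_numpy()

    @property
    def mean_expression(self) -> pd.Series:
        """Mean expression indexed by gene (NaN when absent)."""
        if "mean_expression" in self.data.columns:
            return self.data.set_index("gene")["mean_expression"]
        return pd.Series(np.nan, index=self.data["gene"], name="mean_expression")

    def p_value_of(self) -> pd.Series:
        return self.data.set_index("gene")["p_value"]

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneTable({len(self)} genes)"

    def subset(self, genes: Iterable[str]) -> "GeneTable":
        genes = set(genes)
        return GeneTable(self.data[self.data["gene"].isin(genes)])

    def with_permuted_pvalues(self, permutation: np.ndarray) -> "GeneTable":
        """Return a copy with p-values reassigned by an index permutation."""
        out = self.data.copy()
        out["p_value"] = out["p_value"].to_numpy()[permutation]
        return GeneTable(out)


# ---------------------------------------------------------------------------
# Gene set collections (GMT)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Network input
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NetworkLoadReport:
    """What was kept and dropped while loading an edge list."""

    n_nodes: int = 0
    n_edges: int = 0
    n_self_loops_removed: int = 0
    n_duplicate_edges_removed: int = 0


def read_network(path, fmt: str = "edge_list") -> nx.Graph:
    """Read a simple undirected network from an edge list or SIF file.

    Edge direction in the input is ignored (interactions are treated as
    undirected), self-loops are dropped, and reversed duplicates collapse to
    a single edge.  A confidence/weight third column in edge lists is parsed
    and ignored.  The counts of dropped records are stored on the returned
    graph as ``G.graph["load_report"]`` (a :class:`NetworkLoadReport`).

    Parameters
    ----------
    path
        File with one interaction per non-comment line.
    fmt
        ``"edge_list"``: ``nodeA nodeB [weight]`` (whitespace/tab separated).
        ``"sif"``: ``nodeA <tab> relation <tab> nodeB`` (relation ignored).
    """
    if fmt not in ("edge_list", "sif"):
        raise ValueError(f"unknown network format: {fmt!r}")
    path = Path(path)
    report = NetworkLoadReport()
    G = nx.Graph()
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fmt == "sif":
                if len(fields) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF lines need exactly 3 fields, got {len(fields)}"
                    )
                a, b = fields[0], fields[2]
            else:
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: edge-list lines need >=2 fields, got {len(fields)}"
                    )
                a, b = fields[0], fields[1]
            n_lines += 1
            if a == b:
                report.n_self_loops_removed += 1
                continue
            if G.has_edge(a, b):
                report.n_duplicate_edges_removed += 1
                continue
            G.add_edge(a, b)
    if n_lines == 0:
        raise ValueError(f"{path}: no interactions found")
    report.n_nodes = G.number_of_nodes()
    report.n_edges = G.number_of_edges()
    G.graph["load_report"] = report
    return G


def write_network(G: nx.Graph, path, fmt: str = "edge_list") -> None:
    """Write a network as a 2-column edge list or SIF (relation ``pp``)."""
    lines = []
    for a, b in sorted((tuple(sorted(e)) for e in G.edges()), key=lambda e: e):
        lines.append(f"{a}\tpp\t{b}" if fmt == "sif" else f"{a}\t{b}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene table input
# ---------------------------------------------------------------------------

_P_COLUMN_ALIASES = ("p_value", "pvalue", "p", "pval", "p.value")
_GENE_COLUMN_ALIASES = ("gene", "gene_id", "geneid", "symbol")


def read_gene_table(path, clamp_floor: float = 1e-300) -> GeneTable:
    """Read a per-gene statistics TSV into a :class:`GeneTable`.

    The header must name a gene column and a p-value column (common aliases
    are recognised).  p-values of exactly 0 are clamped to ``clamp_floor``
    with a warning: the downstream mixture-model log-likelihood requires
    log p to be finite.  Negative p-values or p > 1 raise.
    """
    if clamp_floor <= 0:
        raise ValueError("clamp_floor must be positive")
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    gene_col = next((lower[a] for a in _GENE_COLUMN_ALIASES if a in lower), None)
    p_col = next((lower[a] for a in _P_COLUMN_ALIASES if a in lower), None)
    if gene_col is None or p_col is None:
        raise ValueError(
            f"{path}: header must contain a gene column and a p-value column; got {list(df.columns)}"
        )
    rename = {gene_col: "gene", p_col: "p_value"}
    for opt in ("log_fc", "logfc", "log2fc"):
        if opt in lower:
            rename[lower[opt]] = "log_fc"
    if "mean_expression" in lower:
        rename[lower["mean_expression"]] = "mean_expression"
    elif "mean_counts" in lower:
        rename[lower["mean_counts"]] = "mean_expression"
    df = df.rename(columns=rename)
    p = pd.to_numeric(df["p_value"], errors="raise").astype(float)
    if p.isna().any():
        raise ValueError(f"{path}: rows with missing p-values are rejected")
    n_zero = int((p == 0).sum())
    if n_zero:
        logger.warning("%s: clamped %d zero p-value(s) to %.3g", path, n_zero, clamp_floor)
        p = p.where(p != 0, clamp_floor)
    df["p_value"] = p
    return GeneTable(df)


def write_gene_table(table: GeneTable, path) -> None:
    _atomic_write_text(path, table.data.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members, tab-separated).

    Duplicate members within a set are deduplicated; a repeated set name or
    an empty member list is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need >=3 tab-separated fields")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m.strip()]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for name in sorted(collection.sets):
        desc = collection.descriptions.get(name, "")
        members = "\t".join(sorted(collection.sets[name]))
        lines.append(f"{name}\t{desc}\t{members}")
    _atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------

def write_results(result, path, fmt: str = "tsv") -> None:
    """Write a result artifact (module, permutation summary, enrichment).

    ``tsv`` writes the tabular form via the object's ``to_frame()``;
    ``json`` writes ``to_dict()``; ``graphml`` is available for module
    results and embeds each member's score as a node attribute.
    """
    if fmt == "tsv":
        frame = result.to_frame()
        _atomic_write_text(path, frame.to_csv(sep="\t", index=False))
    elif fmt == "json":
        _atomic_write_text(path, json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n")
    elif fmt == "graphml":
        graph = getattr(result, "to_graph", None)
        if graph is None:
            raise ValueError(f"{type(result).__name__} has no graph representation")
        _atomic_write_graphml(graph(), path)
    else:
        raise ValueError(f"unknown result format: {fmt!r}")


def file_digest(path) -> str:
    """SHA-256 hex digest of a file, for run manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, config: Mapping, seed, inputs: Mapping[str, str] | None = None) -> None:
    """Write a JSON run manifest: resolved config, seed, versions, input digests."""
    import networkx
    import scipy

    from . import __version__

    manifest = {
        "config": dict(config),
        "seed": seed,
        "versions": {
            "ppimodules": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
        "input_digests": {
            name: file_digest(p) for name, p in (inputs or {}).items() if p is not None
        },
    }
    _atomic_write_text(path, json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Atomic file output
# ---------------------------------------------------------------------------

def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_graphml(G: nx.Graph, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        nx.write_graphml(G, tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
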