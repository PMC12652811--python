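"""Weighted protein-network filtering, hub statistics and Markov Clustering.

Consumes STRING-export-style edge tables (both the 0–1 float and 0–1000
integer score dialects), applies the confidence thresholds used for the
interaction network around the candidate ABA-biosynthesis enzymes
(combined score >= 0.700, optionally co-expression >= 0.400), reports
degree/clustering statistics, and clusters the filtered graph with a
from-scratch Markov Clustering (MCL) implementation at inflation 3.

MCL alternates *expansion* (matrix power, random-walk spreading) and
*inflation* (elementwise power + column renormalization, favouring strong
walks) on the column-stochastic transition matrix until the iterate is
stationary; the nonzero rows of the limit are attractors and each
attractor's support is one cluster.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .proteome_io import TableError, _open_read, _open_write

#: STRING evidence channels recognised in edge tables.
CHANNELS = (
    "coexpression",
    "experiments",
    "database",
    "textmining",
    "neighborhood",
    "fusion",
    "cooccurrence",
)

_NODE_COLUMN_ALIASES = (
    ("node1", "node2"),
    ("node_a", "node_b"),
    ("protein1", "protein2"),
    ("item_id_a", "item_id_b"),
)
_COMBINED_ALIASES = ("combined_score", "combined", "score")


@dataclass(frozen=True)
class Edge:
    """Undirected weighted edge; nodes stored in lexicographic order."""

    node_a: str
    node_b: str
    combined: float
    channel_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"self-edge on {self.node_a!r}")
        if self.node_a > self.node_b:
            a, b = self.node_b, self.node_a
            object.__setattr__(self, "node_a", a)
            object.__setattr__(self, "node_b", b)
        for name, score in {"combined": self.combined, **self.channel_scores}.items():
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"{name} score {score} outside [0, 1]")


@dataclass(frozen=True)
class NetworkConfig:
    """Thresholds and MCL parameters.

    ``min_combined`` and ``min_coexpression`` are the high-confidence and
    co-expression-view thresholds; set ``min_coexpression`` to ``None`` to
    filter on the combined score alone.  The MCL numerical parameters
    (pruning, convergence tolerance, iteration cap) are fixed for
    determinism.
    """

    min_combined: float = 0.700
    min_coexpression: float | None = 0.400
    mcl_inflation: float = 3.0
    mcl_expansion: int = 2
    prune_threshold: float = 1e-6
    convergence_tol: float = 1e-9
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_combined <= 1.0):
            raise ValueError("min_combined must be in [0, 1]")
        if self.min_coexpression is not None and not (0.0 <= self.min_coexpression <= 1.0):
            raise ValueError("min_coexpression must be in [0, 1] or None")
        if self.mcl_inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.mcl_expansion < 2:
            raise ValueError("expansion must be >= 2")


@dataclass(frozen=True)
class DegreeStats:
    """Weighted degrees, unweighted average degree and mean local
    clustering coefficient; ``top_hub`` is the node of maximal weighted
    degree (lexicographic tie-break)."""

    weighted_degree: Mapping[str, float]
    average_node_degree: float
    clustering_coefficient: float
    top_hub: str


@dataclass(frozen=True)
class ClusterAssignment:
    """MCL output: clusters sorted by (size desc, smallest member), the
    node -> cluster-id membership map (overlap permitted), and convergence
    diagnostics."""

    clusters: tuple[tuple[str, ...], ...]
    membership: Mapping[str, frozenset[int]]
    converged: bool
    n_iterations: int
    max_column_deviation: float


def _normalize_score(value: float) -> float:
    # STRING web exports print integer scores on a 0-1000 scale
    return value / 1000.0 if value > 1.0 else float(value)


def read_edge_tsv(source) -> list[Edge]:
    """Read a STRING-export-style TSV into merged, normalized edges.

    Node columns and the combined-score column are located by common header
    aliases (a leading ``#`` is ignored); channel columns are matched by
    substring against the known channel names.  Scores above 1 are taken on
    the 0–1000 scale and divided by 1000.  Reciprocal duplicate rows are
    merged keeping the row with the maximum combined score.
    """
    with _open_read(source) as fh:
        df = pd.read_csv(fh, sep="\t")
    canon = {c: c.lstrip("#").strip().lower() for c in df.columns}
    by_canon = {v: k for k, v in canon.items()}
    node_cols = None
    for a, b in _NODE_COLUMN_ALIASES:
        if a in by_canon and b in by_canon:
            node_cols = (by_canon[a], by_canon[b])
            break
    if node_cols is None:
        raise TableError(f"no recognised node columns in {list(df.columns)}")
    combined_col = next((by_canon[a] for a in _COMBINED_ALIASES if a in by_canon), None)
    if combined_col is None:
        raise TableError(f"no combined-score column in {list(df.columns)}")
    channel_cols = {
        ch: col
        for col in df.columns
        for ch in CHANNELS
        if ch in canon[col] and col != combined_col
    }
    best: dict[tuple[str, str], Edge] = {}
    for values in df.itertuples(index=False, name=None):
        row = dict(zip(df.columns, values))
        a, b = str(row[node_cols[0]]), str(row[node_cols[1]])
        channels = {
            ch: _normalize_score(float(row[col]))
            for ch, col in channel_cols.items()
            if not pd.isna(row[col])
        }
        edge = Edge(a, b, _normalize_score(float(row[combined_col])), channels)
        key = (edge.node_a, edge.node_b)
        if key not in best or edge.combined > best[key].combined:
            best[key] = edge
    return [best[k] for k in sorted(best)]


def filter_edges(edges: Iterable[Edge], config: NetworkConfig | None = None) -> list[Edge]:
    """Keep edges with combined >= ``min_combined`` and, when the
    co-expression filter is active, a co-expression channel score >=
    ``min_coexpression`` (edges lacking the channel fail the criterion)."""
    config = config or NetworkConfig()
    kept = []
    for e in edges:
        if e.combined < config.min_combined:
            continue
        if config.min_coexpression is not None:
            coex = e.channel_scores.get("coexpression")
            if coex is None or coex < config.min_coexpression:
                continue
        kept.append(e)
    return kept


def degree_stats(edges: Sequence[Edge], nodes: Iterable[str] = ()) -> DegreeStats:
    """Hub and degree statistics of the (filtered) graph.

    Weighted degree sums the combined score over incident edges; average
    node degree is the unweighted 2E/V; the clustering coefficient is the
    mean local transitivity with degree-<2 nodes contributing 0.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        g.add_edge(e.node_a, e.node_b, weight=e.combined)
    if g.number_of_nodes() == 0:
        raise ValueError("degree_stats: empty graph")
    wdeg = {n: float(d) for n, d in g.degree(weight="weight")}
    top_hub = min(wdeg, key=lambda n: (-wdeg[n], n))
    return DegreeStats(
        weighted_degree=wdeg,
        average_node_degree=2.0 * g.number_of_edges() / g.number_of_nodes(),
        clustering_coefficient=float(nx.average_clustering(g, count_zeros=True)),
        top_hub=top_hub,
    )


def mcl_cluster(
    edges: Sequence[Edge],
    config: NetworkConfig | None = None,
    nodes: Iterable[str] = (),
) -> ClusterAssignment:
    """Markov Clustering of the weighted graph.

    The adjacency gets self-loops of weight equal to each node's maximum
    incident edge weight (1.0 for isolated nodes), is column-normalized,
    and is iterated with expansion ``e`` and inflation ``r`` (entries below
    ``prune_threshold`` zeroed and columns renormalized each round) until
    the maximum absolute entry change falls below ``convergence_tol``.
    Rows of the limit with residual mass are attractors; each attractor's
    nonzero-support columns form one cluster (overlaps permitted,
    identical clusters deduplicated).  Non-convergence returns the partial
    clustering with ``converged=False``.
    """
    config = config or NetworkConfig()
    labels = sorted({n for e in edges for n in (e.node_a, e.node_b)} | set(nodes))
    if not labels:
        raise ValueError("mcl_cluster: empty graph")
    index = {n: i for i, n in enumerate(labels)}
    n = len(labels)
    adj = np.zeros((n, n))
    for e in edges:
        i, j = index[e.node_a], index[e.node_b]
        adj[i, j] = adj[j, i] = max(adj[i, j], e.combined)
    loop = adj.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(adj, loop)

    m = adj / adj.sum(axis=0, keepdims=True)
    converged = False
    iterations = 0
    max_col_dev = 0.0
    for iterations in range(1, config.max_iterations + 1):
        prev = m
        m = np.linalg.matrix_power(m, config.mcl_expansion)
        m = m ** config.mcl_inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < config.prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        max_col_dev = max(max_col_dev, float(np.abs(m.sum(axis=0) - 1.0).max()))
        if float(np.abs(m - prev).max()) < config.convergence_tol:
            converged = True
            break

    attractor_rows = np.flatnonzero(m.sum(axis=1) > config.prune_threshold)
    raw = {frozenset(np.flatnonzero(m[i] > 0.0)) for i in attractor_rows}
    clusters = [c for c in raw if c]
    # numerical safety net: attach any column not covered by an attractor
    covered = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in covered:
            i = int(np.argmax(m[:, j]))
            target = next((c for c in clusters if i in c), None)
            if target is not None:
                clusters.remove(target)
                clusters.append(target | {j})
            else:
                clusters.append(frozenset({j}))
            covered.add(j)
    named = sorted(
        (tuple(sorted(labels[i] for i in c)) for c in clusters),
        key=lambda c: (-len(c), c[0]),
    )
    membership: dict[str, set[int]] = {lab: set() for lab in labels}
    for cid, cluster in enumerate(named):
        for lab in cluster:
            membership[lab].add(cid)
    return ClusterAssignment(
        clusters=tuple(named),
        membership={k: frozenset(v) for k, v in membership.items()},
        converged=converged,
        n_iterations=iterations,
        max_column_deviation=max_col_dev,
    )


def write_cluster_tsv(assignment: ClusterAssignment, dest) -> None:
    """Write ``node<TAB>cluster_id`` rows, sorted by (node, cluster_id)."""
    with _open_write(dest) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["node", "cluster_id"])
        for node in sorted(assignment.membership):
            for cid in sorted(assignment.membership[node]):
                writer.writerow([node, cid])


def write_stats_tsv(stats: DegreeStats, dest) -> None:
    """Write summary statistics plus per-node weighted degrees as TSV."""
    with _open_write(dest) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["statistic", "value"])
        writer.writerow(["top_hub", stats.top_hub])
        writer.writerow(["average_node_degree", f"{stats.average_node_degree:.6g}"])
        writer.writerow(["clustering_coefficient", f"{stats.clustering_coefficient:.6g}"])
        for node in sorted(stats.weighted_degree):
            writer.writerow([f"weighted_degree:{node}", f"{stats.weighted_degree[node]:.6g}"])
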