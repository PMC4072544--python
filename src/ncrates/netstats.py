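"""Protein-interaction-network metrics and group-comparison statistics.

Networks are undirected, unweighted simple graphs (duplicate edges collapsed,
self-loops dropped).  Per-node metrics are degree, unnormalized shortest-path
betweenness centrality, and — given a cross-species ortholog map — the number
of neighbors lacking an ortholog in the other species.  From these, three
node classes are selected by decile:

* hubs: top decile of degree (non-hubs: bottom decile);
* bottlenecks: top decile of betweenness *excluding hubs* (non-bottlenecks:
  bottom decile of betweenness);
* re-wired consensus: nodes in the top decile of non-orthologous-neighbor
  counts in *both* networks, matched through the ortholog map.

Group comparisons use the two-sided Wilcoxon rank-sum test for distributions
(with Cohen's-d standardized mean difference as effect size) and Fisher's
exact test for 2x2 contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.stats

__all__ = [
    "NetworkMetrics",
    "GroupComparison",
    "build_graph",
    "compute_metrics",
    "select_hubs",
    "select_bottlenecks",
    "rewired_consensus",
    "smd",
    "group_tests",
    "read_edge_list",
    "read_ortholog_map",
]


@dataclass(frozen=True)
class NetworkMetrics:
    """Per-node metrics of one interaction network."""

    degree: dict[str, int]
    betweenness: dict[str, float]
    nonortholog_neighbors: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.degree)


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group statistical comparison."""

    statistic_name: str
    statistic: float
    p_value: float
    smd: float | None
    n_per_group: tuple[int, int]


def build_graph(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Simple undirected graph: duplicate edges collapsed, self-loops dropped."""
    g = nx.Graph()
    for u, v in edges:
        if u != v:
            g.add_edge(u, v)
    return g


def compute_metrics(
    edges: Iterable[tuple[str, str]] | nx.Graph,
    ortholog_map: Mapping[str, str] | None = None,
) -> NetworkMetrics:
    """Degree, exact betweenness and non-orthologous-neighbor counts.

    Betweenness is Brandes' exact shortest-path betweenness, unnormalized
    (only rank deciles are consumed downstream).  With an ortholog map, a
    node's ``nonortholog_neighbors`` is the number of its neighbors absent
    from the map (species-specific partners).
    """
    g = edges if isinstance(edges, nx.Graph) else build_graph(edges)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    degree = {n: d for n, d in g.degree()}
    betweenness = nx.betweenness_centrality(g, normalized=False)
    nonorth: dict[str, int] = {}
    if ortholog_map is not None:
        mapped = set(ortholog_map)
        nonorth = {n: sum(1 for nb in g.neighbors(n) if nb not in mapped) for n in g}
    return NetworkMetrics(
        degree=degree, betweenness=betweenness, nonortholog_neighbors=nonorth
    )


def _decile_split(
    values: Mapping[str, float], top_fraction: float, bottom_fraction: float
) -> tuple[set[str], set[str], bool]:
    """Top/bottom sets by quantile threshold, ties included on the qualifying
    side.  Returns (top, bottom, degenerate)."""
    arr = np.array(list(values.values()), dtype=float)
    degenerate = bool(np.all(arr == arr[0]))
    hi = float(np.quantile(arr, 1.0 - top_fraction))
    lo = float(np.quantile(arr, bottom_fraction))
    top = {n for n, v in values.items() if v >= hi}
    bottom = {n for n, v in values.items() if v <= lo}
    return top, bottom, degenerate


def select_hubs(
    metrics: NetworkMetrics,
    top_fraction: float = 0.10,
    bottom_fraction: float = 0.10,
) -> tuple[set[str], set[str], bool]:
    """Hubs (top decile of degree) and non-hubs (bottom decile).

    Returns (hubs, non_hubs, degenerate); ``degenerate`` is True when all
    degrees are equal, in which case both sets cover all nodes.  Isolated
    nodes are retained with degree 0.
    """
    if len(metrics.degree) < 10:
        raise ValueError("hub selection needs >= 10 nodes")
    return _decile_split(metrics.degree, top_fraction, bottom_fraction)


def select_bottlenecks(
    metrics: NetworkMetrics,
    hubs: set[str],
    top_fraction: float = 0.10,
    bottom_fraction: float = 0.10,
) -> tuple[set[str], set[str], bool]:
    """Bottlenecks: top decile of betweenness minus hubs; non-bottlenecks:
    bottom decile of betweenness."""
    top, bottom, degenerate = _decile_split(
        metrics.betweenness, top_fraction, bottom_fraction
    )
    return top - set(hubs), bottom, degenerate


def rewired_consensus(
    metrics_a: NetworkMetrics,
    metrics_b: NetworkMetrics,
    ortholog_map: Mapping[str, str],
    top_fraction: float = 0.10,
) -> set[str]:
    """Consensus most-re-wired nodes across two networks.

    A node qualifies in a network when its non-orthologous-neighbor count is
    in the top decile *and* positive (a node with no species-specific
    partners is never re-wired, even in a degenerate all-zero network).  The
    consensus is the set of ortholog pairs qualifying in both networks,
    reported as first-network node names.
    """
    def qualifying(metrics: NetworkMetrics) -> set[str]:
        counts = metrics.nonortholog_neighbors
        if not counts:
            return set()
        arr = np.array(list(counts.values()), dtype=float)
        hi = float(np.quantile(arr, 1.0 - top_fraction))
        return {n for n, v in counts.items() if v >= hi and v > 0}

    top_a = qualifying(metrics_a)
    top_b = qualifying(metrics_b)
    return {a for a in top_a if ortholog_map.get(a) in top_b}


# --------------------------------------------------------------------------
# Statistics
# --------------------------------------------------------------------------


def smd(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized mean difference (Cohen's d with pooled SD).

    (mean(x) - mean(y)) / s_pooled, with s_pooled from n-1 variances.  Scale
    invariant and antisymmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("smd requires >= 2 values per sample")
    nx_, ny_ = len(x), len(y)
    pooled_var = ((nx_ - 1) * x.var(ddof=1) + (ny_ - 1) * y.var(ddof=1)) / (nx_ + ny_ - 2)
    if pooled_var == 0:
        if x.mean() == y.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation with unequal means")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def group_tests(
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
    table: Sequence[Sequence[int]] | None = None,
) -> GroupComparison:
    """Two-group comparison: Wilcoxon rank-sum for distributions, Fisher's
    exact test for 2x2 tables.

    With samples ``x`` and ``y``, runs the two-sided Wilcoxon rank-sum test
    and attaches the standardized mean difference.  With ``table``, runs the
    two-sided Fisher's exact test (no SMD).  Identical constant samples give
    p = 1 by the rank-sum normal approximation.
    """
    if table is not None:
        table = np.asarray(table, dtype=int)
        if table.shape != (2, 2):
            raise ValueError(f"Fisher's exact test needs a 2x2 table, got {table.shape}")
        odds, p = scipy.stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison(
            statistic_name="fisher_exact",
            statistic=float(odds),
            p_value=float(p),
            smd=None,
            n_per_group=(int(table[0].sum()), int(table[1].sum())),
        )
    if x is None or y is None or len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    stat, p = scipy.stats.ranksums(x, y)
    try:
        effect = smd(x, y)
    except ValueError:
        effect = None
    return GroupComparison(
        statistic_name="wilcoxon_rank_sum",
        statistic=float(stat),
        p_value=float(p),
        smd=effect,
        n_per_group=(len(x), len(y)),
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column tab-separated edge list; lines starting with '#' skipped."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"bad edge line: {line!r}")
            edges.append((parts[0], parts[1]))
    return edges


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column tab-separated ortholog map (species1 node -> species2 node)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"bad ortholog-map line: {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def write_ortholog_map(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in mapping.items():
            fh.write(f"{a}\t{b}\n")
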