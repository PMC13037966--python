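"""Per-scenario co-expression networks: components, degrees, hubs, exports.

Networks are undirected and unweighted: an edge is present iff the gene pair
passed a differential scenario (and, normally, the phenotype filter), and
absent otherwise. |r| is deliberately not used as an edge weight — at n = 5
it is too noisy to rank edges. Clusters are simply connected components,
which avoids imposing artificial partitions on a sparse graph; hubs are nodes
with degree >= 10 by default.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from ._util import round_half_up
from .scenarios import DS1, DS2, DS3, NO_SCENARIO

#: how an edge of each scenario reads biologically
EDGE_KIND = {DS1: "formed", DS2: "dissolved", DS3: "changed"}

DEFAULT_HUB_DEGREE = 10


def build_network(
    calls: pd.DataFrame, scenario: str, require_filter: bool = True
) -> nx.Graph:
    """Graph over the passing pairs of one scenario.

    Nodes are the union of pair members; each passing pair contributes exactly
    one edge (duplicates collapse; self-pairs cannot arise from unordered pair
    enumeration). Every edge carries ``edge_kind`` (formed / dissolved /
    changed for DS1 / DS2 / DS3).
    """
    if scenario not in EDGE_KIND:
        raise ValueError(f"unknown scenario {scenario!r}")
    sub = calls[calls["scenario"] == scenario]
    if require_filter and "passes_filter" in sub.columns:
        sub = sub[sub["passes_filter"]]
    g = nx.Graph(scenario=scenario)
    kind = EDGE_KIND[scenario]
    for a, b in zip(sub["gene_a"], sub["gene_b"]):
        if a != b:
            g.add_edge(str(a), str(b), edge_kind=kind)
    return g


def components(net: nx.Graph) -> list[list[str]]:
    """Connected components ("clusters"), each as a sorted member list,
    ordered by size descending with ties broken by the lexicographically
    smallest member id — a deterministic, platform-independent order."""
    comps = [sorted(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


@dataclass
class DegreeSummary:
    """Degree histogram plus the hub set of one network."""

    n_nodes: int
    n_edges: int
    histogram: dict[int, int]  # degree -> node count
    hubs: list[tuple[str, int]]  # (gene, degree), degree desc then id
    min_degree: int = DEFAULT_HUB_DEGREE

    @property
    def hub_ids(self) -> list[str]:
        return [g for g, _ in self.hubs]

    def hub_share(self, digits: int = 1) -> float | None:
        """Hubs as a percent of all nodes (one decimal by default)."""
        if self.n_nodes == 0:
            return None
        return round_half_up(100.0 * len(self.hubs) / self.n_nodes, digits)


def degree_summary(net: nx.Graph, min_degree: int = DEFAULT_HUB_DEGREE) -> DegreeSummary:
    """Exact degree counts and the hub set (degree >= min_degree)."""
    degrees = dict(net.degree())
    hubs = sorted(
        ((g, d) for g, d in degrees.items() if d >= min_degree),
        key=lambda gd: (-gd[1], gd[0]),
    )
    return DegreeSummary(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        histogram=dict(sorted(Counter(degrees.values()).items())),
        hubs=hubs,
        min_degree=min_degree,
    )


def top_clusters(
    clusters: list[list[str]], k: int = 10, tie_inclusive: bool = True
) -> list[list[str]]:
    """The k largest clusters; with ``tie_inclusive`` every cluster whose size
    equals the k-th size is kept, so more than k may be returned."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(clusters) <= k:
        return list(clusters)
    if not tie_inclusive:
        return clusters[:k]
    cutoff = len(clusters[k - 1])
    return [c for c in clusters if len(c) >= cutoff]


def small_cluster_share(clusters: list[list[str]], digits: int = 1) -> float | None:
    """Percent of clusters containing only 2-3 members."""
    if not clusters:
        return None
    small = sum(1 for c in clusters if 2 <= len(c) <= 3)
    return round_half_up(100.0 * small / len(clusters), digits)


def hub_overlap(
    hubs_a: DegreeSummary | list[str], hubs_b: DegreeSummary | list[str]
) -> tuple[list[str], int]:
    """Shared hub ids (sorted) and the size of the hub union."""
    set_a = set(hubs_a.hub_ids if isinstance(hubs_a, DegreeSummary) else hubs_a)
    set_b = set(hubs_b.hub_ids if isinstance(hubs_b, DegreeSummary) else hubs_b)
    return (sorted(set_a & set_b), len(set_a | set_b))


def _annotate(net: nx.Graph, clusters: list[list[str]], min_degree: int) -> nx.Graph:
    g = net.copy()
    member_of = {gene: i + 1 for i, c in enumerate(clusters) for gene in c}
    for gene in g.nodes:
        d = g.degree(gene)
        g.nodes[gene]["degree"] = int(d)
        g.nodes[gene]["is_hub"] = bool(d >= min_degree)
        g.nodes[gene]["cluster_id"] = int(member_of.get(gene, 0))
    return g


def export_graph(
    net: nx.Graph,
    clusters: list[list[str]],
    path: str | Path,
    fmt: str = "graphml",
    min_degree: int = DEFAULT_HUB_DEGREE,
) -> None:
    """Write the network with node attributes (cluster id, degree, hub flag)
    and per-edge ``edge_kind``, as GraphML or a TSV edge list."""
    g = _annotate(net, clusters, min_degree)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "tsv":
        rows = [
            {
                "gene_a": a,
                "gene_b": b,
                "edge_kind": data.get("edge_kind", ""),
                "cluster_id": g.nodes[a]["cluster_id"],
            }
            for a, b, data in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "edge_kind", "cluster_id"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'graphml' or 'tsv'")
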