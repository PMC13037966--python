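"""Interaction-table expansion and hypergeometric over-representation analysis.

Top clusters are expanded with high-confidence first neighbors from a
STRING-format interaction table (protein1, protein2, combined_score in
0-1000; records kept when combined_score > 950, i.e. confidence > 0.95).
Enrichment runs on three gene groupings — cluster genes alone, their
interactors alone, and the combination — against GMT gene-set collections,
using the one-sided hypergeometric tail with Benjamini-Hochberg FDR control.
Two FDR tiers are conventional: 0.05 for breadth, 1e-5 to single out highly
significant terms shared between scenarios.

Identifiers in the interaction table are assumed pre-mapped to the expression
gene-id namespace; an optional two-column mapping file can be applied first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUPING_CLUSTER = "cluster_genes"
GROUPING_INTERACTORS = "interactors_only"
GROUPING_COMBINED = "combined"
GROUPINGS = (GROUPING_CLUSTER, GROUPING_INTERACTORS, GROUPING_COMBINED)

ENRICHMENT_COLUMNS = ["term", "description", "k", "K", "n", "N", "p", "q"]


class InteractionFormatError(ValueError):
    """Raised for malformed interaction-table records."""


@dataclass
class InteractionTable:
    """Symmetric high-confidence interaction lookup."""

    neighbors: dict[str, set[str]]
    min_score: int = 950

    def partners(self, gene: str) -> set[str]:
        return set(self.neighbors.get(gene, ()))

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.neighbors.values()) // 2


def load_interactions(
    path: str | Path,
    min_score: int = 950,
    id_map: Mapping[str, str] | None = None,
) -> InteractionTable:
    """Read a STRING-style TSV (protein1, protein2, combined_score).

    Records are retained when combined_score is *strictly* greater than
    ``min_score`` and stored symmetrically. A malformed score is a hard error
    naming the line. ``id_map`` optionally translates identifiers into the
    expression gene-id namespace before filtering.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise InteractionFormatError(
            f"{path}: expected 3 columns (protein1, protein2, combined_score)"
        )
    scores = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    bad = np.nonzero(scores.isna().to_numpy())[0]
    if bad.size:
        # +2: one for the header, one for 1-based line numbers
        raise InteractionFormatError(
            f"{path}: malformed combined_score {df.iloc[bad[0], 2]!r} on line {bad[0] + 2}"
        )
    neighbors: dict[str, set[str]] = {}
    keep = scores.to_numpy() > min_score
    for a, b in zip(df.iloc[:, 0][keep], df.iloc[:, 1][keep]):
        a, b = str(a), str(b)
        if id_map is not None:
            a = id_map.get(a, a)
            b = id_map.get(b, b)
        if a == b:
            continue
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    return InteractionTable(neighbors=neighbors, min_score=min_score)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping interaction-table ids to expression gene ids."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


@dataclass
class GeneSetCollection:
    """Named gene sets (GO-BP-like or KEGG-like) with descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty gene set(s): {empty}")

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: per line, tab-separated name, description, members.

    Duplicate set names are a hard error; lines without members are rejected.
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
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, members")
            name, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=source)


def expand_cluster(cluster: Iterable[str], table: InteractionTable) -> set[str]:
    """First-neighbor interactors of the cluster members, minus the members
    themselves; genes absent from the table contribute nothing."""
    members = set(cluster)
    out: set[str] = set()
    for gene in members:
        out |= table.partners(gene)
    return out - members


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis.

    For each set, p = P(X >= k) with X ~ Hypergeom(N, K, n) where N is the
    universe size, K the universe genes in the set, n the (universe-restricted)
    query size and k the query genes in the set. q is the Benjamini-Hochberg
    FDR over all tested sets. Rows sorted by (q, p, term). Query genes outside
    the universe are dropped with a logged count; an empty effective query
    yields an empty result.
    """
    universe_set = set(universe)
    query_set = set(query)
    dropped = query_set - universe_set
    if dropped:
        logger.warning("ora: dropped %d query gene(s) outside the universe", len(dropped))
    query_set &= universe_set
    if not query_set:
        logger.warning("ora: empty effective query")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    N = len(universe_set)
    n = len(query_set)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & universe_set
        K = len(in_universe)
        k = len(in_universe & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term": name,
                "description": collection.descriptions.get(name, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["q", "p", "term"], kind="mergesort").reset_index(drop=True)
    return out[ENRICHMENT_COLUMNS]


def run_groupings(
    top_clusters_ds1: list[list[str]],
    top_clusters_ds2: list[list[str]],
    table: InteractionTable,
    collection: GeneSetCollection,
    universe: Iterable[str],
    fdr: float = 0.05,
) -> dict:
    """Six enrichment runs (2 scenarios x 3 groupings) plus overlap summaries.

    Returns ``{"results": {(scenario, grouping): DataFrame}, "gene_groups":
    {...}, "overlap": {...}}`` where overlap holds, per scenario, the
    Venn-style exclusive/shared significant-term counts across the three
    groupings at the given FDR, and per grouping the DS1/DS2 shared count.
    """
    universe = set(universe)
    gene_groups: dict[tuple[str, str], set[str]] = {}
    for scen, clusters in (("DS1", top_clusters_ds1), ("DS2", top_clusters_ds2)):
        members: set[str] = set().union(*clusters) if clusters else set()
        interactors = expand_cluster(members, table)
        gene_groups[(scen, GROUPING_CLUSTER)] = members
        gene_groups[(scen, GROUPING_INTERACTORS)] = interactors
        gene_groups[(scen, GROUPING_COMBINED)] = members | interactors

    results = {
        key: ora(genes, collection, universe) for key, genes in gene_groups.items()
    }

    def significant(df: pd.DataFrame) -> set[str]:
        return set(df.loc[df["q"] < fdr, "term"])

    overlap: dict = {}
    for scen in ("DS1", "DS2"):
        sig = {g: significant(results[(scen, g)]) for g in GROUPINGS}
        c, i, m = sig[GROUPING_CLUSTER], sig[GROUPING_INTERACTORS], sig[GROUPING_COMBINED]
        overlap[scen] = {
            "cluster_only": len(c - i - m),
            "interactors_only": len(i - c - m),
            "combined_only": len(m - c - i),
            "cluster_and_interactors": len((c & i) - m),
            "cluster_and_combined": len((c & m) - i),
            "interactors_and_combined": len((i & m) - c),
            "all_three": len(c & i & m),
            "union": len(c | i | m),
        }
    overlap["ds1_ds2_shared"] = {
        g: len(significant(results[("DS1", g)]) & significant(results[("DS2", g)]))
        for g in GROUPINGS
    }
    return {"results": results, "gene_groups": gene_groups, "overlap": overlap}


def intersect_terms(
    res_ds1: pd.DataFrame, res_ds2: pd.DataFrame, fdr: float = 0.05
) -> pd.DataFrame:
    """Terms significant (q < fdr) in both scenarios, ranked by the worse of
    the two q values (then term id)."""
    a = res_ds1[res_ds1["q"] < fdr][["term", "description", "q"]].rename(columns={"q": "q_ds1"})
    b = res_ds2[res_ds2["q"] < fdr][["term", "q"]].rename(columns={"q": "q_ds2"})
    merged = a.merge(b, on="term", how="inner")
    merged["q_max"] = merged[["q_ds1", "q_ds2"]].max(axis=1)
    return (
        merged.sort_values(["q_max", "term"], kind="mergesort")
        .reset_index(drop=True)[["term", "description", "q_ds1", "q_ds2", "q_max"]]
    )
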