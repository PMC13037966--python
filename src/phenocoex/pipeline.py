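"""End-to-end orchestration: classify -> scenarios -> filter -> network -> enrichment.

The pipeline is deterministic given (inputs, seed): a single master seed fans
out into per-pair permutation sub-seeds through a stable hash of the gene ids,
so results do not depend on evaluation order. Every summary number is a view
over the stage dump files written alongside it and can be recounted from them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._util import round_half_up
from . import annotation as anno
from . import network as net
from . import scenarios as scen
from .coexpression import Thresholds, classify_group
from .expression_data import (
    ExpressionMatrix,
    GroupKey,
    StudyDesign,
    read_design,
    read_tpm_matrix,
    subset_group,
)
from .synthetic import GroundTruth

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and knobs for one pipeline run."""

    matrix_path: str
    design_path: str
    out_dir: str
    interactions_path: str | None = None
    gene_sets_path: str | None = None
    id_map_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    strength_alpha: float = 0.05
    lenient_nondiff: bool = False
    hub_min_degree: int = 10
    top_k: int = 10
    tie_inclusive: bool = True
    fdr: float = 0.05
    fdr_strict: float = 1e-5
    min_string_score: int = 950
    seed: int = 0
    percent_digits: int = 1
    log_transform: bool = False
    exact_perm: bool = False
    mean_tpm_filter: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        th = cfg.pop("thresholds", None)
        config = cls(**cfg)
        if th:
            config.thresholds = Thresholds(**th)
        return config


def report_share(numerator: int, denominator: int, digits: int = 1) -> float | None:
    """100 * numerator / denominator rounded half-up to ``digits`` decimals;
    None (rendered as an em dash in reports) for a zero denominator."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, digits)


def classify_study(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
    exact_perm: bool = False,
    log_transform: bool = False,
) -> dict[GroupKey, pd.DataFrame]:
    """Pair-classification tables for every group in the design."""
    out: dict[GroupKey, pd.DataFrame] = {}
    for key in design.groups:
        group = subset_group(matrix, design, key)
        out[key] = classify_group(
            group,
            thresholds,
            seed=seed,
            exact=exact_perm,
            log_transform=log_transform,
        )
    return out


@dataclass
class RunSummary:
    """Headline quantities of one run; a view, not a source."""

    n_genes: int
    n_pairs: int
    label_counts: dict[str, dict[str, int]]  # "line/treatment" -> label -> count
    scenario_pair_counts: dict[str, int]
    scenario_gene_counts: dict[str, int]
    filter_effect: dict
    condition_tally: list[dict]
    network_stats: dict[str, dict]
    enrichment: dict | None
    parameters: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _group_tag(key: GroupKey) -> str:
    return f"{key[0]}/{key[1]}"


def _network_stage(
    calls: pd.DataFrame, config: PipelineConfig, out_dir: Path | None
) -> tuple[dict, dict[str, list[list[str]]], dict[str, net.DegreeSummary]]:
    stats: dict[str, dict] = {}
    clusters_by: dict[str, list[list[str]]] = {}
    degrees_by: dict[str, net.DegreeSummary] = {}
    for ds in scen.SCENARIOS:
        g = net.build_network(calls, ds)
        clusters = net.components(g)
        summary = net.degree_summary(g, config.hub_min_degree)
        top = net.top_clusters(clusters, config.top_k, config.tie_inclusive)
        clusters_by[ds] = clusters
        degrees_by[ds] = summary
        top_nodes = sum(len(c) for c in top)
        stats[ds] = {
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "n_clusters": len(clusters),
            "largest_cluster": len(clusters[0]) if clusters else 0,
            "n_hubs": len(summary.hubs),
            "hub_share_pct": summary.hub_share(config.percent_digits),
            "n_top_clusters": len(top),
            "top_cluster_nodes": top_nodes,
            "top_cluster_node_share_pct": report_share(
                top_nodes, summary.n_nodes, config.percent_digits
            ),
            "small_cluster_share_pct": net.small_cluster_share(
                clusters, config.percent_digits
            ),
        }
        if out_dir is not None and g.number_of_nodes() > 0:
            net.export_graph(g, clusters, out_dir / f"network_{ds}.graphml", "graphml",
                             config.hub_min_degree)
            net.export_graph(g, clusters, out_dir / f"network_{ds}_edges.tsv", "tsv",
                             config.hub_min_degree)
            pd.DataFrame(
                [
                    {"cluster_id": i + 1, "size": len(c), "members": ",".join(c)}
                    for i, c in enumerate(clusters)
                ]
            ).to_csv(out_dir / f"clusters_{ds}.tsv", sep="\t", index=False)
    return stats, clusters_by, degrees_by


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    design: StudyDesign | None = None,
) -> RunSummary:
    """Run the full analysis and write stage artifacts under ``out_dir``.

    ``matrix``/``design`` may be passed directly (e.g. from the synthetic
    generator) to skip re-reading the files named in the config.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if matrix is None:
        matrix = read_tpm_matrix(config.matrix_path)
    if design is None:
        design = read_design(config.design_path)

    if config.mean_tpm_filter is not None:
        keep = matrix.values.mean(axis=1) >= config.mean_tpm_filter
        matrix = ExpressionMatrix(matrix.values.loc[keep])

    group_stats = classify_study(
        matrix,
        design,
        config.thresholds,
        seed=config.seed,
        exact_perm=config.exact_perm,
        log_transform=config.log_transform,
    )
    dump = []
    label_counts: dict[str, dict[str, int]] = {}
    for key, df in group_stats.items():
        tagged = df.copy()
        tagged.insert(0, "treatment", key[1])
        tagged.insert(0, "cell_line", key[0])
        dump.append(tagged)
        label_counts[_group_tag(key)] = df["label"].value_counts().to_dict()
    pd.concat(dump, ignore_index=True).to_csv(
        out_dir / "pair_stats.tsv", sep="\t", index=False
    )

    test = scen.StrengthChangeTest(alpha=config.strength_alpha)
    calls = scen.call_scenarios_table(
        group_stats, design, test=test, lenient_nondiff=config.lenient_nondiff
    )
    calls.to_csv(out_dir / "scenario_calls.tsv", sep="\t", index=False)
    tally = scen.tally_combinations(calls, design)
    tally.to_csv(out_dir / "condition_tally.tsv", sep="\t", index=False)
    effect = scen.apply_filter_toggle(calls)

    passing = calls[calls["passes_filter"]]
    scenario_pair_counts = {
        ds: int((passing["scenario"] == ds).sum()) for ds in scen.SCENARIOS
    }
    scenario_gene_counts = {
        ds: len(
            set(passing.loc[passing["scenario"] == ds, "gene_a"])
            | set(passing.loc[passing["scenario"] == ds, "gene_b"])
        )
        for ds in scen.SCENARIOS
    }

    network_stats, clusters_by, degrees_by = _network_stage(calls, config, out_dir)

    enrichment_summary = None
    if config.interactions_path and config.gene_sets_path:
        id_map = anno.read_id_map(config.id_map_path) if config.id_map_path else None
        table = anno.load_interactions(
            config.interactions_path, config.min_string_score, id_map
        )
        collection = anno.read_gmt(config.gene_sets_path)
        universe = sorted(set(matrix.gene_ids) & set(collection.all_genes))
        top1 = net.top_clusters(clusters_by[scen.DS1], config.top_k, config.tie_inclusive)
        top2 = net.top_clusters(clusters_by[scen.DS2], config.top_k, config.tie_inclusive)
        runs = anno.run_groupings(top1, top2, table, collection, universe, config.fdr)
        for (ds, grouping), df in runs["results"].items():
            df.to_csv(out_dir / f"enrichment_{ds}_{grouping}.tsv", sep="\t", index=False)
        shared = anno.intersect_terms(
            runs["results"][("DS1", anno.GROUPING_COMBINED)],
            runs["results"][("DS2", anno.GROUPING_COMBINED)],
            config.fdr_strict,
        )
        shared.to_csv(out_dir / "shared_terms_strict.tsv", sep="\t", index=False)
        enrichment_summary = {
            "overlap": runs["overlap"],
            "n_shared_strict": int(shared.shape[0]),
            "universe_size": len(universe),
        }

    summary = RunSummary(
        n_genes=matrix.shape[0],
        n_pairs=int(calls.shape[0]),
        label_counts=label_counts,
        scenario_pair_counts=scenario_pair_counts,
        scenario_gene_counts=scenario_gene_counts,
        filter_effect={
            "n_with": effect.n_with,
            "n_without": effect.n_without,
            "n_extra": effect.n_extra,
            "pct_increase": effect.pct_increase,
        },
        condition_tally=tally.to_dict("records"),
        network_stats=network_stats,
        enrichment=enrichment_summary,
        parameters={
            "thresholds": asdict(config.thresholds),
            "strength_alpha": config.strength_alpha,
            "lenient_nondiff": config.lenient_nondiff,
            "hub_min_degree": config.hub_min_degree,
            "top_k": config.top_k,
            "tie_inclusive": config.tie_inclusive,
            "min_string_score": config.min_string_score,
            "fdr": config.fdr,
            "fdr_strict": config.fdr_strict,
            "seed": config.seed,
            "log_transform": config.log_transform,
            "exact_perm": config.exact_perm,
            "mean_tpm_filter": config.mean_tpm_filter,
        },
    )
    summary.to_json(out_dir / "summary.json")
    return summary


def _canonical(pairs: Mapping | pd.DataFrame) -> set[tuple[str, str]]:
    return {
        tuple(sorted((str(a), str(b))))
        for a, b in zip(pairs["gene_a"], pairs["gene_b"])
    }


def score_against_truth(
    calls: pd.DataFrame,
    clusters_by_scenario: Mapping[str, list[list[str]]],
    hubs_by_scenario: Mapping[str, list[str]],
    truth: GroundTruth,
) -> dict:
    """Pair-level precision/recall per scenario, cluster recovery, hub hit.

    Precision counts *any* planted structure of the scenario (explicit pairs,
    within-cluster pairs, hub spokes and leaf-leaf pairs) as a true positive;
    recall is taken over the guaranteed plants only, whose construction
    certifies every per-group label. An empty call set yields precision None
    with a warning.
    """
    known = set(calls["gene_a"]) | set(calls["gene_b"])
    truth_genes = set(truth.pairs["gene_a"]) | set(truth.pairs["gene_b"]) - {""}
    unknown = truth_genes - known
    if unknown:
        raise ValueError(
            f"truth manifest references genes absent from the calls: {sorted(unknown)[:5]}"
        )
    out: dict = {}
    passing = calls[calls["passes_filter"]]
    for ds in ("DS1", "DS2", "DS3"):
        called = _canonical(passing[passing["scenario"] == ds])
        planted_any = truth.scenario_pairs(ds)
        planted_sure = truth.scenario_pairs(ds, guaranteed_only=True)
        tp = len(called & planted_any)
        if called:
            precision = tp / len(called)
        else:
            precision = None
            if planted_sure:
                logger.warning("no %s calls although %d pairs were planted", ds, len(planted_sure))
        recall = (
            len(called & planted_sure) / len(planted_sure) if planted_sure else None
        )
        out[ds] = {
            "n_called": len(called),
            "n_planted": len(planted_any),
            "n_planted_guaranteed": len(planted_sure),
            "true_positives": tp,
            "precision": precision,
            "recall": recall,
        }
    cluster_scores = {}
    for cid, members in truth.clusters.items():
        mem = set(members)
        best_j, container = 0.0, False
        for comp in clusters_by_scenario.get("DS1", []):
            cset = set(comp)
            inter = len(mem & cset)
            if inter:
                best_j = max(best_j, inter / len(mem | cset))
                if mem <= cset:
                    container = True
        cluster_scores[cid] = {
            "size": len(members),
            "recovered_in_one_component": container,
            "best_jaccard": best_j,
        }
    out["clusters"] = cluster_scores
    out["hub"] = {
        "planted": truth.hub_center,
        "detected": bool(
            truth.hub_center and truth.hub_center in set(hubs_by_scenario.get("DS1", []))
        ),
    }
    return out
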