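"""Umbrella pipeline: simulate → filter → defe → hardy → network → pca → report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defe as defe_mod
from . import io as io_mod
from .deg import DegThresholds, call_table, union_deg_set
from .design import StudyDesign
from .hardiness import ANTI_HARDY, HARDY, classify_all
from .network import (
    association_strength,
    cluster,
    cluster_trait_correlation,
    condition_indicator_traits,
    neighborhood,
    soft_adjacency,
    subnetwork,
    threshold_top,
    tom,
)
from .pca import run_pca, separation
from .simulate import PlantedTruth, StudyBundle, generate_study

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; round-trips through YAML."""

    seed: int = 0
    n_genes: int = 3000
    n_lipids: int = 224
    effect_size_log2: float = 4.0
    noise_sd_log2: float = 0.3
    lfc_min: float = 2.0
    padj_max: float = 0.01
    tpm_min: float = 2.0
    alpha: float = 0.05
    beta: int = 6
    signed: bool = False
    quantile: float = 0.99
    n_clusters: int = 50
    as_denominator: str = "connected"
    include_lipids_in_network: bool = True

    def __post_init__(self) -> None:
        for name in ("lfc_min", "padj_max", "tpm_min", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig, out_dir: Path | str | None = None
) -> tuple[dict, StudyBundle]:
    """Run every stage on a synthetic study and return (summary, bundle).

    When ``out_dir`` is given, all stage outputs (TSVs, gene lists, network
    exports, summary JSON) are written there.
    """
    design = StudyDesign()
    truth = PlantedTruth(
        n_genes=config.n_genes,
        n_lipids=config.n_lipids,
        effect_size_log2=config.effect_size_log2,
        noise_sd_log2=config.noise_sd_log2,
        seed=config.seed,
    )
    bundle = generate_study(design, truth)

    thresholds = DegThresholds(
        lfc_min=config.lfc_min, padj_max=config.padj_max, tpm_min=config.tpm_min
    )
    stage = "deg_filter"
    try:
        calls = call_table(bundle.contrasts, bundle.expression, thresholds)
        degs = union_deg_set(calls)

        stage = "defe"
        series = defe_mod.default_series(design)
        codes = {p: defe_mod.encode(calls, s) for p, s in series.items()}
        freq = {p: defe_mod.frequency_table(c) for p, c in codes.items()}
        groups = {
            name: defe_mod.named_group(codes, series, name)
            for name in defe_mod.NAMED_GROUPS
        }

        stage = "hardiness"
        contrast_tables = {c.name: c.table for c in bundle.contrasts}
        hardy_calls = classify_all(
            bundle.expression,
            contrast_tables,
            calls,
            design,
            genes=sorted(degs),
            alpha=config.alpha,
        )
        hardy_set = set(hardy_calls.index[hardy_calls["label"] == HARDY])
        anti_set = set(hardy_calls.index[hardy_calls["label"] == ANTI_HARDY])

        stage = "network"
        log_expr = bundle.expression.log2().loc[sorted(degs)]
        node_data = (
            pd.concat([log_expr, bundle.lipids])
            if config.include_lipids_in_network
            else log_expr
        )
        adjacency = soft_adjacency(node_data, beta=config.beta, signed=config.signed)
        tom_m = tom(adjacency)
        net = threshold_top(tom_m, quantile=config.quantile)
        clusters = cluster(tom_m, n_clusters=min(config.n_clusters, len(tom_m)))
        net.cluster_of_node = clusters.to_dict()
        indicators = condition_indicator_traits(
            bundle.expression.samples, design
        ).astype(float)
        traits = pd.concat([bundle.lipids, indicators])
        gene_clusters = clusters.loc[clusters.index.intersection(log_expr.index)]
        cluster_r, cluster_p = cluster_trait_correlation(
            gene_clusters, log_expr, traits
        )
        subnets = {}
        for name, members in (
            ("WHG", groups["WHG"]),
            ("SHG", groups["SHG"]),
            ("hardy", hardy_set),
            ("anti_hardy", anti_set),
        ):
            if members:
                sub = subnetwork(net, members)
                subnets[name] = {
                    "n_members": sub.n_members,
                    "n_connected": len(sub.connected_members),
                    "avg_degree": sub.avg_degree,
                    "AS": association_strength(sub, config.as_denominator),
                }
            else:
                subnets[name] = {
                    "n_members": 0, "n_connected": 0, "avg_degree": 0.0, "AS": 0.0,
                }
        whg_reach = (
            neighborhood(net, groups["WHG"], "immediate")
            | neighborhood(net, groups["WHG"], "secondary")
            if groups["WHG"]
            else set()
        )
        shared_with_shg = sorted(whg_reach & groups["SHG"])

        stage = "pca"
        pca = run_pca(log_expr)
        separations = {}
        if len(groups["WHG"]) >= 2 and len(groups["SHG"]) >= 2:
            rep = separation(
                pca, groups["WHG"], groups["SHG"], [1, 2, 3], names=("WHG", "SHG")
            )
            separations["WHG_vs_SHG_pc123"] = rep.silhouette
        if len(hardy_set) >= 2 and len(anti_set) >= 2:
            rep = separation(
                pca, hardy_set, anti_set, [1, 2], names=("hardy", "anti_hardy")
            )
            separations["hardy_vs_anti_pc12"] = rep.silhouette
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_degs": len(degs),
        "pattern_counts": {
            p: dict(zip(f["pattern"].head(10), f["count"].head(10).astype(int)))
            for p, f in freq.items()
        },
        "group_sizes": {name: len(g) for name, g in groups.items()},
        "n_hardy": len(hardy_set),
        "n_anti_hardy": len(anti_set),
        "subnetworks": subnets,
        "whg_shg_shared_neighbors": shared_with_shg,
        "pca_variance_explained": [float(v) for v in pca.variance_explained[:3]],
        "separation": separations,
        "network": {
            "n_nodes": len(net.nodes),
            "n_edges": net.graph.number_of_edges(),
            "cutoff": net.cutoff,
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_mod.write_expression(
            bundle.expression, out / "expression.tsv", out / "samples.tsv"
        )
        io_mod.write_design(design, out / "design.yaml")
        for c in bundle.contrasts:
            io_mod.write_contrast(c, out / f"contrast_{c.name}.tsv")
        io_mod.write_tsv(calls, out / "degcalls.tsv", index_label="gene")
        for p, f in freq.items():
            io_mod.write_tsv(f.set_index("pattern"), out / f"defe_{p}_frequency.tsv")
        for name, members in groups.items():
            io_mod.write_gene_list(members, out / f"group_{name}.txt")
        io_mod.write_tsv(hardy_calls, out / "hardy_calls.tsv", index_label="gene")
        io_mod.write_network(net, out / "edges.tsv", out / "network.graphml")
        io_mod.write_tsv(
            clusters.to_frame(), out / "clusters.tsv", index_label="node"
        )
        io_mod.write_tsv(cluster_r, out / "cluster_trait_r.tsv", index_label="cluster")
        io_mod.write_tsv(cluster_p, out / "cluster_trait_p.tsv", index_label="cluster")
        io_mod.write_tsv(pca.scores, out / "pca_scores.tsv", index_label="gene")
        io_mod.write_tsv(pca.loadings, out / "pca_loadings.tsv", index_label="sample")
        config.to_yaml(out / "config.yaml")
        io_mod.write_json(summary, out / "summary.json")

    return summary, bundle
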