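"""End-to-end orchestration: filter -> networks -> modules -> preservation
-> topology -> enrichment, with every parameter logged to a run-metadata
sidecar and all outputs as headered TSV.

The defaults are the canonical workflow parameters: presence fraction
0.5, SAM delta 0.296, soft-threshold criterion R^2 > 0.8 over powers
1-20, average-linkage TOM clustering cut with deep_split 1, cut height
0.99, minimum module size 27, preservation over 200 permutations with
weak-module cutoff z_summary < 5, and enrichment filters q < 0.05 with
overlap >= 2.  The soft-threshold power is selected on the reference
condition and shared with the test condition unless overridden.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import enrichment_frame, hypergeometric_enrichment, read_gmt
from .filtering import presence_filter, sam_select
from .io import (
    read_expression_table,
    read_flags_table,
    read_groups_table,
    validate_expression,
    validate_groups,
    write_expression_table,
)
from .modules import ModulePartition, assign_colors, kme, merge_similar_modules, module_eigengenes
from .network import build_network
from .preservation import module_preservation, select_weak_modules
from .topology import (
    betweenness,
    build_module_graph,
    density_threshold,
    differential_bc,
    write_edge_list,
    write_graphml,
)
from .treecut import average_linkage, hybrid_dynamic_cut
from .network import tom_dissimilarity

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration for the whole workflow (YAML-loadable)."""

    expression: str | None = None
    groups: str | None = None
    flags: str | None = None          # optional presence-call matrix
    gmt: str | None = None            # optional gene-set collection
    reference_condition: str | None = None  # default: lexicographically first
    sample_subset: list[str] | None = None

    # filtering
    min_fraction: float = 0.5
    sam_delta: float = 0.296
    sam_n_perm: int = 100
    skip_sam: bool = False

    # network
    candidate_betas: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_cut: float = 0.8
    shared_beta: bool = True
    beta: int | None = None

    # module detection
    deep_split: int = 1
    cut_height: float = 0.99
    min_module_size: int = 27
    pam_stage: bool = True
    merge_threshold: float = 0.0      # 0 disables eigengene merging

    # preservation
    preservation_n_perm: int = 200
    preservation_cutoff: float = 5.0

    # topology
    graph_source: str = "tom"
    graph_threshold: float | None = None   # None -> per-module density policy
    graph_max_density: float = 0.15

    # enrichment
    min_overlap: int = 2
    q_cut: float = 0.05

    seed: int = 0
    outdir: str = "coexdiff_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_meta(outdir: Path, config: PipelineConfig, extra: dict) -> None:
    meta = {"version": __version__, "config": config.to_dict(), **extra}
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def run_full_pipeline(
    config: PipelineConfig,
    expr: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
    flags: pd.DataFrame | None = None,
) -> Path:
    """Run the complete differential co-expression workflow.

    Inputs may be passed in memory (``expr``/``groups``/``flags``) or read
    from the paths in ``config``.  Writes all stage outputs plus a
    run-metadata file into ``config.outdir`` and returns that path.
    Deterministic for a fixed seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if expr is None:
            expr = read_expression_table(config.expression)
        if groups is None:
            groups = read_groups_table(config.groups)
        if flags is None and config.flags:
            flags = read_flags_table(config.flags)
        validate_expression(expr)
        if config.sample_subset:
            expr = expr[[s for s in expr.columns if s in set(config.sample_subset)]]
        groups = validate_groups(expr, groups, min_per_group=3)
        conds = sorted(groups.unique())
        if len(conds) != 2:
            raise ValueError(f"need exactly 2 conditions, got {conds}")
        ref_cond = config.reference_condition or conds[0]
        test_cond = next(c for c in conds if c != ref_cond)

        stage = "filter"
        if flags is not None:
            expr = presence_filter(expr, flags, groups, config.min_fraction)
        sam_meta = {}
        if not config.skip_sam:
            sam = sam_select(
                expr, groups, config.sam_delta, n_perm=config.sam_n_perm, seed=config.seed
            )
            pd.DataFrame(
                {"d": sam.d, "expected_d": sam.expected, "selected": sam.selected}
            ).to_csv(outdir / "sam_statistics.tsv", sep="\t", index_label="gene_id")
            expr = expr.loc[sam.selected.index[sam.selected]]
            sam_meta = {"sam_s0": sam.s0, "sam_selected": int(sam.selected.sum())}
        write_expression_table(expr, outdir / "filtered_expression.tsv")

        stage = "network"
        expr_ref = expr[groups.index[groups == ref_cond]]
        expr_test = expr[groups.index[groups == test_cond]]
        net_ref, scan = build_network(
            expr_ref, beta=config.beta, candidate_betas=config.candidate_betas, r2_cut=config.r2_cut
        )
        if scan is not None:
            scan.to_frame().to_csv(outdir / "soft_threshold_scan.tsv", sep="\t", index=False)
        test_beta = net_ref.beta if config.shared_beta else None
        net_test, _ = build_network(
            expr_test, beta=test_beta, candidate_betas=config.candidate_betas, r2_cut=config.r2_cut
        )

        stage = "modules"
        diss = tom_dissimilarity(net_ref.tom)
        dend = average_linkage(diss, gene_ids=list(expr.index))
        labels = hybrid_dynamic_cut(
            dend,
            diss,
            deep_split=config.deep_split,
            cut_height=config.cut_height,
            min_size=config.min_module_size,
            pam_stage=config.pam_stage,
        )
        partition = assign_colors(
            ModulePartition(
                list(expr.index),
                labels,
                params={
                    "deep_split": config.deep_split,
                    "cut_height": config.cut_height,
                    "min_size": config.min_module_size,
                    "pam_stage": config.pam_stage,
                },
            )
        )
        if config.merge_threshold > 0:
            partition = merge_similar_modules(expr_ref, partition, config.merge_threshold)
        eig = module_eigengenes(expr_ref, partition)
        kme_tab = kme(expr_ref, eig)
        part_tab = partition.to_frame()
        own_kme = [
            kme_tab.loc[g, m] if m != 0 else np.nan
            for g, m in zip(part_tab.index, part_tab["module"])
        ]
        part_tab["kme_own_module"] = own_kme
        part_tab.to_csv(outdir / "module_partition.tsv", sep="\t")

        stage = "preservation"
        report = module_preservation(
            net_ref,
            net_test,
            expr_test,
            partition,
            n_perm=config.preservation_n_perm,
            seed=config.seed,
        )
        report.to_frame().to_csv(outdir / "module_preservation.tsv", sep="\t", index=False)
        weak = select_weak_modules(report, cutoff=config.preservation_cutoff)
        (outdir / "selected_modules.tsv").write_text(
            "module\tcolor\n" + "".join(f"{m}\t{partition.color_of(m)}\n" for m in weak)
        )

        stage = "topology"
        for m in weak:
            genes = partition.genes_in(m)
            if len(genes) < 3:
                continue
            color = partition.color_of(m)
            tabs = {}
            for label, net in (("reference", net_ref), ("test", net_test)):
                t = config.graph_threshold or density_threshold(
                    net, genes, source=config.graph_source, max_density=config.graph_max_density
                )
                mg = build_module_graph(net, genes, source=config.graph_source, threshold=t)
                write_graphml(mg, outdir / f"module_{color}_{label}.graphml")
                write_edge_list(mg, outdir / f"module_{color}_{label}.edges.tsv")
                tabs[label] = betweenness(mg)
            table = differential_bc(tabs["reference"], tabs["test"])
            table.round(2).to_csv(outdir / f"centrality_{color}.tsv", sep="\t")

        stage = "enrichment"
        if config.gmt:
            gmt = read_gmt(config.gmt)
            background = set(expr.index)
            for m in weak:
                res = hypergeometric_enrichment(
                    partition.genes_in(m),
                    background,
                    gmt,
                    min_overlap=config.min_overlap,
                    q_cut=config.q_cut,
                )
                enrichment_frame(res).to_csv(
                    outdir / f"enrichment_{partition.color_of(m)}.tsv", sep="\t", index=False
                )
        else:
            logger.warning("WARN no GMT collection configured; enrichment stage skipped")

        _write_meta(
            outdir,
            config,
            {
                "reference_condition": ref_cond,
                "test_condition": test_cond,
                "beta_reference": net_ref.beta,
                "beta_test": net_test.beta,
                "n_genes_analyzed": int(expr.shape[0]),
                "n_modules": len(partition.module_ids),
                "selected_modules": [partition.color_of(m) for m in weak],
                "graph_threshold_policy": (
                    f"absolute {config.graph_threshold}"
                    if config.graph_threshold
                    else f"per-module density <= {config.graph_max_density} "
                    "(NOTE: export threshold is the least reproducible choice in this "
                    "workflow; record it when comparing runs)"
                ),
                **sam_meta,
            },
        )
        return outdir
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
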