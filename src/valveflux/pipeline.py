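"""End-to-end orchestration: nine-condition (or any-condition) runs.

One wild-type reference is computed per model; every condition is compared
against it.  Per condition the stages are: differential expression →
gene-to-reaction fold-change mapping → valve constraints → FBA growth and
carrying-flux counts → FVA capacity comparison → pFBA six-way gene
classification and single-gene deletions (restricted summaries over the
condition's down-regulated genes) → targeted reaction objectives →
centrality top-k membership of the down-regulated genes.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .cbm import (
    compare_capacity,
    count_carrying_flux,
    fba,
    fva,
    classify_genes_pfba,
    maximize_reaction_objective,
    single_gene_deletion,
    PFBA_CATEGORIES,
)
from .expression import (
    assign_reaction_fold_changes,
    differential_expression,
    read_expression_tsv,
    results_frame,
    significant_down,
)
from .model_core import read_sbml
from .topology import (
    CentralityConfig,
    build_enzyme_network,
    compute_centralities,
    rank_and_flag,
    write_centrality_tsv,
    write_edge_list,
)
from .valve import apply_valve_constraints, compute_reference_fluxes

logger = logging.getLogger(__name__)


@dataclass
class ConditionSpec:
    label: str
    expression_path: str
    samples_path: str


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; loadable from YAML/JSON."""

    model_path: str
    conditions: list[ConditionSpec]
    out_dir: str
    alpha: float = 0.01
    valve_mode: str = "cap"
    fva_fraction: float = 1.0
    essentiality_cutoff: float = 0.01
    objective_targets: list[str] = field(default_factory=list)
    centrality_top_k: int = 100
    epc_realizations: int = 1000
    epc_retention_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["conditions"] = [ConditionSpec(**c) for c in raw.get("conditions", [])]
        return cls(**raw)


@dataclass
class ConditionReport:
    """Machine-readable twin of the study's per-condition result shapes."""

    label: str
    n_significant_down: int
    n_constrained_reactions: int
    growth: float
    growth_ratio: float
    carrying_total: int
    carrying_positive: int
    carrying_negative: int
    increased_subsystems: dict[str, list[str]]
    decreased_subsystems: dict[str, list[str]]
    category_percentages: dict[str, float]
    percent_growth_reducing: float
    percent_essential: float
    objective_values: dict[str, float]
    centrality_top_flags: dict[str, list[str]]
    down_genes_in_model: list[str]


def run_pipeline(cfg: RunConfig) -> tuple[list[ConditionReport], dict]:
    """Execute every stage for every condition against one WT reference.

    Returns the per-condition reports and a manifest (versions, seeds,
    tolerances, warnings).  All intermediate artifacts are written under
    ``cfg.out_dir``.  Any stage failure aborts with the stage name and the
    offending condition label.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    warnings: list[str] = []
    t0 = time.monotonic()

    model = read_sbml(cfg.model_path)
    ref = compute_reference_fluxes(model)
    wt_sol = fba(model)
    wt_counts = count_carrying_flux(wt_sol)
    wt_fva = fva(model, cfg.fva_fraction)
    logger.info("WT reference: growth %.6g (%.1fs)", ref.f_wt, time.monotonic() - t0)

    net = build_enzyme_network(model)
    cent_cfg = CentralityConfig(
        epc_realizations=cfg.epc_realizations,
        epc_retention_probability=cfg.epc_retention_probability,
        seed=cfg.seed,
    )
    table = compute_centralities(net, cent_cfg)
    write_centrality_tsv(table, os.path.join(cfg.out_dir, "centrality.tsv"))
    write_edge_list(net, os.path.join(cfg.out_dir, "enzyme_network.tsv"))

    reports: list[ConditionReport] = []
    for cond in cfg.conditions:
        stage = "differential expression"
        try:
            cdir = os.path.join(cfg.out_dir, cond.label)
            os.makedirs(cdir, exist_ok=True)
            matrix = read_expression_tsv(cond.expression_path, cond.samples_path)
            de = differential_expression(matrix, alpha=cfg.alpha)
            results_frame(de).to_csv(os.path.join(cdir, "de_results.tsv"), sep="\t")
            down = significant_down(de, cfg.alpha)
            down_in_model = sorted(down & set(model.genes))
            if down - set(model.genes):
                warnings.append(
                    f"{cond.label}: {len(down - set(model.genes))} down genes not in model GPRs"
                )

            stage = "valve integration"
            fc_map = assign_reaction_fold_changes(model, de, cfg.alpha)
            constrained = apply_valve_constraints(model, ref, fc_map, mode=cfg.valve_mode)
            constrained.provenance_frame().to_csv(
                os.path.join(cdir, "valve_provenance.tsv"), sep="\t", index=False
            )

            stage = "FBA"
            sol = fba(constrained.model)
            counts = count_carrying_flux(sol) if sol.optimal else (0, 0, 0)
            growth = sol.f if sol.optimal else 0.0

            stage = "FVA capacity comparison"
            mut_fva = fva(constrained.model, cfg.fva_fraction)
            cap = compare_capacity(wt_fva, mut_fva, model)

            stage = "pFBA classification"
            classification = classify_genes_pfba(
                constrained.model, essentiality_cutoff=cfg.essentiality_cutoff
            )
            classification.details.to_csv(os.path.join(cdir, "gene_categories.tsv"), sep="\t")
            deletions = single_gene_deletion(
                constrained.model, cfg.essentiality_cutoff, genes=down_in_model or None
            )

            cats = classification.category.reindex(down_in_model)
            n_down = len(down_in_model)
            category_pct = {
                c: (100.0 * (cats == c).sum() / n_down if n_down else 0.0)
                for c in PFBA_CATEGORIES
            }
            reduce_tol = 1e-6
            pct_reducing = (
                100.0 * (deletions.ratio.reindex(down_in_model) < 1 - reduce_tol).sum() / n_down
                if n_down
                else 0.0
            )
            pct_essential = (
                100.0 * deletions.essential.reindex(down_in_model).sum() / n_down if n_down else 0.0
            )

            stage = "targeted objectives"
            objective_values = {}
            for rid in cfg.objective_targets:
                osol = maximize_reaction_objective(constrained.model, rid)
                objective_values[rid] = osol.f if osol.optimal else 0.0

            stage = "centrality flags"
            flags = rank_and_flag(table, down_in_model, k=cfg.centrality_top_k)

            reports.append(
                ConditionReport(
                    label=cond.label,
                    n_significant_down=len(down),
                    n_constrained_reactions=len(fc_map),
                    growth=growth,
                    growth_ratio=growth / ref.f_wt if ref.f_wt else float("nan"),
                    carrying_total=counts[0],
                    carrying_positive=counts[1],
                    carrying_negative=counts[2],
                    increased_subsystems=cap.increased_subsystems,
                    decreased_subsystems=cap.decreased_subsystems,
                    category_percentages=category_pct,
                    percent_growth_reducing=pct_reducing,
                    percent_essential=pct_essential,
                    objective_values=objective_values,
                    centrality_top_flags=flags,
                    down_genes_in_model=down_in_model,
                )
            )
            logger.info("condition %s done (growth ratio %.3f)", cond.label, reports[-1].growth_ratio)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed for condition {cond.label!r}: {exc}") from exc

    manifest = {
        "valveflux_version": __version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "valve_mode": cfg.valve_mode,
        "fva_fraction": cfg.fva_fraction,
        "essentiality_cutoff": cfg.essentiality_cutoff,
        "epc": {
            "realizations": cfg.epc_realizations,
            "retention_probability": cfg.epc_retention_probability,
            "seed": cfg.seed,
        },
        "wt": {
            "growth": ref.f_wt,
            "carrying_total": wt_counts[0],
            "carrying_positive": wt_counts[1],
            "carrying_negative": wt_counts[2],
        },
        "warnings": warnings,
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump([asdict(r) for r in reports], fh, indent=1, sort_keys=True)
    render_tables(reports, cfg.out_dir)
    return reports, manifest


def render_tables(reports: list[ConditionReport], out_dir: str) -> None:
    """Write the study-shaped summary tables as TSV.

    ``growth.tsv`` (growth-rate bar data), ``carrying_flux.tsv``,
    ``subsystems_increased.tsv`` / ``subsystems_decreased.tsv`` (subsystem ×
    condition membership), ``gene_category_percentages.tsv`` (one decimal)
    and ``objective_swaps.tsv``.
    """
    os.makedirs(out_dir, exist_ok=True)
    labels = [r.label for r in reports]

    pd.DataFrame(
        {
            "condition": labels,
            "growth": [r.growth for r in reports],
            "growth_ratio": [r.growth_ratio for r in reports],
        }
    ).to_csv(os.path.join(out_dir, "growth.tsv"), sep="\t", index=False)

    pd.DataFrame(
        {
            "condition": labels,
            "total": [r.carrying_total for r in reports],
            "positive": [r.carrying_positive for r in reports],
            "negative": [r.carrying_negative for r in reports],
        }
    ).to_csv(os.path.join(out_dir, "carrying_flux.tsv"), sep="\t", index=False)

    for attr, fname in (
        ("increased_subsystems", "subsystems_increased.tsv"),
        ("decreased_subsystems", "subsystems_decreased.tsv"),
    ):
        rows = {}
        for r in reports:
            for ss in getattr(r, attr):
                rows.setdefault(ss, []).append(r.label)
        frame = pd.DataFrame(
            {"subsystem": sorted(rows), "conditions": ["- ".join(rows[s]) for s in sorted(rows)]}
        )
        frame.to_csv(os.path.join(out_dir, fname), sep="\t", index=False)

    cat_rows = []
    for r in reports:
        row = {"condition": r.label}
        row["single_gene_deletion"] = f"{r.percent_growth_reducing:.1f}"
        row["essential_genes"] = f"{r.percent_essential:.1f}"
        for c in PFBA_CATEGORIES:
            row[c] = f"{r.category_percentages[c]:.1f}"
        cat_rows.append(row)
    pd.DataFrame(cat_rows).to_csv(
        os.path.join(out_dir, "gene_category_percentages.tsv"), sep="\t", index=False
    )

    obj_rows = []
    for r in reports:
        row = {"condition": r.label}
        row.update(r.objective_values)
        obj_rows.append(row)
    pd.DataFrame(obj_rows).to_csv(os.path.join(out_dir, "objective_swaps.tsv"), sep="\t", index=False)
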