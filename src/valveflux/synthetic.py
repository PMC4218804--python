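"""Toy metabolic models and planted expression matrices.

Every downstream stage is testable without downloads: the named fixtures
(`toy_linear`, `toy_parallel`, `toy_shortlong`, `toy_class`) carry analytic
optima worked out by hand at design time, the random generator produces
small feasible branched networks for solver cross-checks, and
`simulate_expression` plants down-regulated genes at stated log2 fold
changes in Gaussian log2 noise — emulating the WT-vs-mutant two-group
structure of a microarray comparison, not probe- or read-level detail.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import MUT, WT, ExpressionMatrix, write_expression_tsv
from .model_core import MetabolicModel, Metabolite, Reaction, parse_gpr, write_sbml

UPTAKE_CAP = 10.0
WIDE = 1000.0


def _rxn(rid, stoich, lb=0.0, ub=WIDE, gpr="", subsystem="", obj=0.0, name=""):
    return Reaction(
        id=rid,
        name=name or rid,
        stoichiometry=stoich,
        lower_bound=lb,
        upper_bound=ub,
        gpr=parse_gpr(gpr),
        subsystem=subsystem,
        objective_coefficient=obj,
    )


def _mets(*ids):
    return [Metabolite(id=i, name=i, compartment="c") for i in ids]


# ---------------------------------------------------------------------------
# Named analytic fixtures (optima stored at design time, by hand LP)
# ---------------------------------------------------------------------------


def toy_linear(uptake_cap: float = UPTAKE_CAP) -> tuple[MetabolicModel, dict]:
    """A -> B chain: unique optimum = uptake cap; every flux equals it."""
    model = MetabolicModel(
        id="TOY_LIN",
        metabolites=_mets("A", "B"),
        reactions=[
            _rxn("EX_A", {"A": 1}, 0, uptake_cap, gpr="gA", subsystem="exchange"),
            _rxn("R_AB", {"A": -1, "B": 1}, 0, WIDE, gpr="gB", subsystem="conversion"),
            _rxn("BIO", {"B": -1}, 0, WIDE, gpr="gBIO", subsystem="biomass", obj=1.0),
        ],
    )
    analytic = {
        "optimum": uptake_cap,
        "fluxes": {"EX_A": uptake_cap, "R_AB": uptake_cap, "BIO": uptake_cap},
        "essential_genes": ["gA", "gB", "gBIO"],
    }
    return model, analytic


def toy_parallel(uptake_cap: float = UPTAKE_CAP) -> tuple[MetabolicModel, dict]:
    """Two redundant A -> B routes; either alone sustains the optimum."""
    model = MetabolicModel(
        id="TOY_PAR",
        metabolites=_mets("A", "B"),
        reactions=[
            _rxn("EX_A", {"A": 1}, 0, uptake_cap, subsystem="exchange"),
            _rxn("R1", {"A": -1, "B": 1}, 0, WIDE, gpr="g1", subsystem="conversion"),
            _rxn("R2", {"A": -1, "B": 1}, 0, WIDE, gpr="g2", subsystem="conversion"),
            _rxn("BIO", {"B": -1}, 0, WIDE, subsystem="biomass", obj=1.0),
        ],
    )
    analytic = {
        "optimum": uptake_cap,
        "fva_at_optimum": {"R1": (0.0, uptake_cap), "R2": (0.0, uptake_cap)},
        "essential_genes": [],
    }
    return model, analytic


def toy_shortlong(uptake_cap: float = UPTAKE_CAP) -> tuple[MetabolicModel, dict]:
    """One-step vs two-step A -> B route; parsimony picks the short one."""
    model = MetabolicModel(
        id="TOY_SHORTLONG",
        metabolites=_mets("A", "B", "C"),
        reactions=[
            _rxn("EX_A", {"A": 1}, 0, uptake_cap, subsystem="exchange"),
            _rxn("S1", {"A": -1, "B": 1}, 0, WIDE, gpr="gs", subsystem="short route"),
            _rxn("L1", {"A": -1, "C": 1}, 0, WIDE, gpr="gl1", subsystem="long route"),
            _rxn("L2", {"C": -1, "B": 1}, 0, WIDE, gpr="gl2", subsystem="long route"),
            _rxn("BIO", {"B": -1}, 0, WIDE, subsystem="biomass", obj=1.0),
        ],
    )
    analytic = {
        "optimum": uptake_cap,
        "pfba_fluxes": {"S1": uptake_cap, "L1": 0.0, "L2": 0.0},
    }
    return model, analytic


def toy_class(uptake_cap: float = UPTAKE_CAP) -> tuple[MetabolicModel, dict]:
    """Short/long routes plus a wasteful bypass and a dead end: one planted
    gene per parsimonious-FBA category.

    gu gates the only uptake (essential); gs carries the parsimonious
    optimum; gl1/gl2 form a usable-at-optimum alternative (ELE); gm's bypass
    wastes substrate so it can only run below optimal growth (MLE); gd's
    reaction feeds a dead-end metabolite (blocked).
    """
    model = MetabolicModel(
        id="TOY_CLASS",
        metabolites=_mets("A", "B", "C", "D", "E"),
        reactions=[
            _rxn("EX_A", {"A": 1}, 0, uptake_cap, gpr="gu", subsystem="exchange"),
            _rxn("S1", {"A": -1, "B": 1}, 0, WIDE, gpr="gs", subsystem="short route"),
            _rxn("L1", {"A": -1, "C": 1}, 0, WIDE, gpr="gl1", subsystem="long route"),
            _rxn("L2", {"C": -1, "B": 1}, 0, WIDE, gpr="gl2", subsystem="long route"),
            _rxn("W1", {"A": -1, "D": 1}, 0, WIDE, gpr="gm", subsystem="overflow"),
            _rxn("EX_D", {"D": -1}, 0, WIDE, subsystem="exchange"),
            _rxn("R_DEAD", {"A": -1, "E": 1}, 0, WIDE, gpr="gd", subsystem="dead end"),
            _rxn("BIO", {"B": -1}, 0, WIDE, subsystem="biomass", obj=1.0),
        ],
    )
    analytic = {
        "optimum": uptake_cap,
        "categories": {
            "gu": "essential",
            "gs": "pFBA optima",
            "gl1": "ELE",
            "gl2": "ELE",
            "gm": "MLE",
            "gd": "blocked",
        },
    }
    return model, analytic


def core_model(uptake_cap: float = UPTAKE_CAP) -> tuple[MetabolicModel, dict]:
    """A branched ten-reaction network with subsystems, an isozyme pair and
    an enzyme complex — the substrate for the synthetic multi-condition
    study.

    Biomass draws equally on two precursor pools.  B1 has a single route
    (U1 then A1), so throttling those steps caps growth proportionally; B2
    has two parallel routes (Bx1, Bx2), so throttling either alone leaves
    growth untouched — reaction-level redundancy.  The overflow reaction OV
    carries no flux at the optimum and DEAD feeds a dead-end metabolite.

    At the WT optimum (growth = uptake cap): EX_G and BIO carry the cap,
    U1 = A1 = U2 = Bx1+Bx2 = cap/2, OV = DEAD = 0.
    """
    model = MetabolicModel(
        id="TOY_CORE",
        metabolites=_mets("G", "P1", "P2", "B1", "B2", "W", "D"),
        reactions=[
            _rxn("EX_G", {"G": 1}, 0, uptake_cap, subsystem="exchange"),
            _rxn("U1", {"G": -1, "P1": 1}, 0, WIDE, gpr="gU1", subsystem="upper glycolysis"),
            _rxn("U2", {"G": -1, "P2": 1}, 0, WIDE, gpr="gU2", subsystem="upper glycolysis"),
            _rxn("A1", {"P1": -1, "B1": 1}, 0, WIDE, gpr="gA1 or gA1b", subsystem="precursor A"),
            _rxn("Bx1", {"P2": -1, "B2": 1}, 0, WIDE, gpr="gB1 and gB1b", subsystem="precursor B"),
            _rxn("Bx2", {"P2": -1, "B2": 1}, 0, WIDE, gpr="gB2", subsystem="precursor B"),
            _rxn("OV", {"P2": -1, "W": 1}, 0, WIDE, gpr="gW", subsystem="overflow"),
            _rxn("EX_W", {"W": -1}, 0, WIDE, subsystem="exchange"),
            _rxn("DEAD", {"G": -1, "D": 1}, 0, WIDE, gpr="gD", subsystem="dead end"),
            _rxn("BIO", {"B1": -0.5, "B2": -0.5}, 0, WIDE, subsystem="biomass", obj=1.0),
        ],
    )
    analytic = {"optimum": uptake_cap}
    return model, analytic


@dataclass
class ToySpec:
    """Parameterized request for a toy model."""

    topology: str = "linear"  # linear | parallel | shortlong | classify | core | random
    uptake_cap: float = UPTAKE_CAP
    n_reactions: int = 8
    seed: int = 0


def make_toy_model(spec: ToySpec) -> tuple[MetabolicModel, dict]:
    """Dispatch on topology; returns (model, analytic-truth record)."""
    builders = {
        "linear": toy_linear,
        "parallel": toy_parallel,
        "shortlong": toy_shortlong,
        "classify": toy_class,
        "core": core_model,
    }
    if spec.topology in builders:
        if spec.uptake_cap <= 0:
            raise ValueError("uptake cap must be positive")
        return builders[spec.topology](spec.uptake_cap)
    if spec.topology == "random":
        if spec.n_reactions < 3:
            raise ValueError("random model needs >= 3 reactions (uptake, conversion, biomass)")
        return random_model(spec.seed, n_reactions=spec.n_reactions, uptake_cap=spec.uptake_cap)
    raise ValueError(f"unknown topology {spec.topology!r}")


def random_model(
    seed: int, n_reactions: int = 10, uptake_cap: float = UPTAKE_CAP
) -> tuple[MetabolicModel, dict]:
    """A seeded random branched network, feasible with growth > 0.

    A backbone chain (uptake -> M1 -> ... -> Mk -> biomass) guarantees a
    growth route; extra reactions connect random metabolite pairs with
    random caps, reversibility, stoichiometric coefficients and GPRs.
    """
    rng = np.random.default_rng(seed)
    n_extra = max(0, n_reactions - 3)
    k = int(rng.integers(2, 5))  # backbone metabolites
    mets = [f"M{i}" for i in range(1, k + 1)]
    reactions = [
        _rxn("EX_up", {"M1": 1}, 0, float(rng.uniform(1, uptake_cap)), subsystem="exchange")
    ]
    gene_counter = 0

    def _gpr():
        nonlocal gene_counter
        style = rng.random()
        gene_counter += 1
        if style < 0.4:
            return f"rg{gene_counter}"
        gene_counter += 1
        op = "or" if style < 0.7 else "and"
        return f"rg{gene_counter - 1} {op} rg{gene_counter}"

    for i in range(1, k):
        reactions.append(
            _rxn(
                f"C{i}",
                {f"M{i}": -1, f"M{i + 1}": 1},
                0,
                float(rng.uniform(uptake_cap, 3 * uptake_cap)),
                gpr=_gpr(),
                subsystem=f"ss{int(rng.integers(1, 4))}",
            )
        )
    for e in range(n_extra - (k - 1)):
        i, j = rng.choice(k, size=2, replace=False) + 1
        coef = float(rng.integers(1, 3))
        ub = float(rng.uniform(0.5, 2 * uptake_cap))
        lb = -float(rng.uniform(0.5, 2 * uptake_cap)) if rng.random() < 0.3 else 0.0
        reactions.append(
            _rxn(
                f"X{e}",
                {f"M{i}": -coef, f"M{j}": 1.0},
                lb,
                ub,
                gpr=_gpr() if rng.random() < 0.8 else "",
                subsystem=f"ss{int(rng.integers(1, 4))}",
            )
        )
    reactions.append(_rxn("BIO", {f"M{k}": -1}, 0, WIDE, subsystem="biomass", obj=1.0))
    model = MetabolicModel(id=f"TOY_RND_{seed}", metabolites=_mets(*mets), reactions=reactions)
    return model, {"seed": seed}


# ---------------------------------------------------------------------------
# Planted expression matrices
# ---------------------------------------------------------------------------


@dataclass
class PlantedExpressionSpec:
    """Two-group log2 expression simulation with planted down-regulation.

    Defaults mirror a small microarray comparison: 200 genes, 4 WT vs 4
    mutant arrays, per-gene baselines around 8 log2 units, measurement noise
    sd 0.5, and a planted set shifted by -2 log2 units in the mutant group.
    """

    n_genes: int = 200
    n_wt: int = 4
    n_mut: int = 4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.5
    planted_fc: float = -2.0
    planted_genes: tuple[str, ...] = ()
    n_planted: int = 20
    gene_ids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be positive")
        if self.gene_ids and len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length must equal n_genes")
        if self.planted_genes:
            ids = self.gene_ids or tuple(_default_gene_ids(self.n_genes))
            unknown = set(self.planted_genes) - set(ids)
            if unknown:
                raise ValueError(f"planted genes not in gene ids: {sorted(unknown)}")


def _default_gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def simulate_expression(spec: PlantedExpressionSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw the planted two-group matrix; returns (matrix, truth table).

    WT values are Normal(baseline_g, noise_sd) per gene; mutant values of
    planted genes are shifted by the planted log2 fold change.  The truth
    table lists every gene with its true fold change and planted flag.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_ids) if spec.gene_ids else _default_gene_ids(spec.n_genes)
    if spec.planted_genes:
        planted = list(spec.planted_genes)
    else:
        planted = list(rng.choice(genes, size=min(spec.n_planted, len(genes)), replace=False))
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    true_fc = np.array([spec.planted_fc if g in set(planted) else 0.0 for g in genes])
    wt = baseline[:, None] + rng.normal(0, spec.noise_sd, size=(len(genes), spec.n_wt))
    mut = (
        baseline[:, None]
        + true_fc[:, None]
        + rng.normal(0, spec.noise_sd, size=(len(genes), spec.n_mut))
    )
    samples = [f"WT_{i + 1}" for i in range(spec.n_wt)] + [f"MUT_{i + 1}" for i in range(spec.n_mut)]
    values = pd.DataFrame(np.hstack([wt, mut]), index=genes, columns=samples)
    groups = pd.Series([WT] * spec.n_wt + [MUT] * spec.n_mut, index=samples)
    truth = pd.DataFrame(
        {"gene": genes, "true_log2FC": true_fc, "planted": [g in set(planted) for g in genes]}
    ).set_index("gene")
    return ExpressionMatrix(values=values, groups=groups), truth


# ---------------------------------------------------------------------------
# End-to-end fixture bundles
# ---------------------------------------------------------------------------


def end_to_end_fixture(
    out_dir: str,
    model_spec: ToySpec = None,
    expression_spec: PlantedExpressionSpec = None,
) -> dict:
    """Write a pipeline-ready bundle: model.xml, expression.tsv, samples.tsv,
    truth.json.  The truth record carries the planted fold changes, the
    expected valve-constrained reactions and the expected growth where the
    fixture has an analytic answer."""
    model_spec = model_spec or ToySpec(topology="linear")
    model, analytic = make_toy_model(model_spec)
    if expression_spec is None:
        expression_spec = PlantedExpressionSpec(
            gene_ids=tuple(sorted(model.genes)), n_genes=len(model.genes), n_planted=1
        )
    if expression_spec.gene_ids and expression_spec.planted_genes:
        if not set(expression_spec.gene_ids) & set(model.genes):
            raise ValueError("expression gene ids share no genes with the model")
    matrix, truth = simulate_expression(expression_spec)
    os.makedirs(out_dir, exist_ok=True)
    write_sbml(model, os.path.join(out_dir, "model.xml"))
    write_expression_tsv(
        matrix, os.path.join(out_dir, "expression.tsv"), os.path.join(out_dir, "samples.tsv")
    )
    planted = sorted(truth.index[truth["planted"]])
    constrained = sorted({r.id for r in model.reactions if set(planted) & r.gene_set})
    # analytic expected growth: on the linear chain every flux equals the
    # optimum, so one valve at factor 2**FC caps growth at that fraction
    expected_growth = None
    if model_spec.topology == "linear":
        expected_growth = analytic["optimum"] * (
            2.0 ** expression_spec.planted_fc if constrained else 1.0
        )
    record = {
        "model_id": model.id,
        "analytic": analytic,
        "planted_genes": planted,
        "planted_fc": expression_spec.planted_fc,
        "expected_constrained_reactions": constrained,
        "expected_growth": expected_growth,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
    return record


# ---------------------------------------------------------------------------
# The synthetic multi-condition study
# ---------------------------------------------------------------------------

#: Nine planted conditions over the core model, emulating the structure of a
#: WT-vs-mutant histone-tail expression panel: varying numbers of
#: down-regulated metabolic genes at moderate-to-strong log2 fold changes,
#: redundant parallel steps (gB1, gB2), an unused-at-optimum overflow enzyme
#: (gW), and one condition with no affected metabolic gene at all (growth
#: must stay at the WT value).  Each condition also plants two non-metabolic
#: filler genes, which the mapping stage must skip.  The last field is the
#: growth ratio expected if the planted fold change were recovered exactly:
#: 2**FC where a unique-route step is throttled, 1.0 where the constrained
#: reaction is redundant or unused (the estimated fold change carries
#: sampling noise, so realized unique-route ratios scatter around 2**FC).
STUDY_CONDITIONS: tuple[tuple[str, tuple[str, ...], float, float], ...] = (
    ("cond1_upper_single", ("gU1",), -2.0, 0.25),
    ("cond2_upper_both", ("gU1", "gU2"), -1.0, 0.5),
    ("cond3_committed_step", ("gA1",), -1.5, 2.0**-1.5),
    ("cond4_parallel_a", ("gB2",), -1.5, 1.0),
    ("cond5_parallel_b", ("gB1",), -2.0, 1.0),
    ("cond6_overflow", ("gW",), -2.0, 1.0),
    ("cond7_upper_weak", ("gU2",), -1.0, 0.5),
    ("cond8_unaffected", (), -2.0, 1.0),
    ("cond9_combined", ("gU1", "gA1", "gB2"), -2.5, 2.0**-2.5),
)

STUDY_NOISE_SD = 0.25
STUDY_N_FILLER_GENES = 40


def make_study(out_dir: str, seed: int = 0, conditions=STUDY_CONDITIONS) -> dict:
    """Write the core model plus one expression bundle per condition.

    Returns a record with the model path and per-condition expression and
    sample-sheet paths, ready to drive the full pipeline.
    """
    model, analytic = core_model()
    os.makedirs(out_dir, exist_ok=True)
    model_path = os.path.join(out_dir, "model.xml")
    write_sbml(model, model_path)
    gene_ids = sorted(model.genes) + [f"nm{i:03d}" for i in range(1, STUDY_N_FILLER_GENES + 1)]
    record = {"model_path": model_path, "wt_optimum": analytic["optimum"], "conditions": []}
    rng = np.random.default_rng(seed)
    for label, planted_model_genes, fc, expected_ratio in conditions:
        filler = tuple(rng.choice(gene_ids[len(model.genes):], size=2, replace=False))
        planted = tuple(planted_model_genes) + (filler if planted_model_genes else ())
        spec = PlantedExpressionSpec(
            n_genes=len(gene_ids),
            gene_ids=tuple(gene_ids),
            planted_genes=planted,
            n_planted=len(planted),
            planted_fc=fc,
            noise_sd=STUDY_NOISE_SD,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        matrix, truth = simulate_expression(spec)
        expr_path = os.path.join(out_dir, f"{label}_expression.tsv")
        samples_path = os.path.join(out_dir, f"{label}_samples.tsv")
        write_expression_tsv(matrix, expr_path, samples_path)
        record["conditions"].append(
            {
                "label": label,
                "expression_path": expr_path,
                "samples_path": samples_path,
                "planted_model_genes": sorted(planted_model_genes),
                "planted_fc": fc,
                "expected_growth_ratio": expected_ratio,
            }
        )
    with open(os.path.join(out_dir, "study.json"), "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
    return record
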