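"""Linear-programming analyses over a metabolic model.

All solves go through a single deterministic HiGHS backend
(``scipy.optimize.linprog``): flux balance analysis (FBA) maximizing the
linear objective ``c·v`` subject to steady state ``S·v = 0`` and bounds
``lb <= v <= ub``; flux variability analysis (FVA); parsimonious FBA (pFBA)
with the six-way gene classification; single-gene deletions driven by GPR
evaluation; and targeted single-reaction objectives (metabolite-turnover
proxies such as acetyl-CoA synthetase / carboxylase flux).

Sign conventions: shadow prices ``y`` (per metabolite) and reduced costs
``w`` (per reaction) are reported for the *maximization* problem, i.e. the
negated duals of the minimization LP actually solved.  They are exposed, not
interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model_core import MetabolicModel, evaluate_gpr

logger = logging.getLogger(__name__)

FLUX_TOL = 1e-9
FEAS_TOL = 1e-6


class SolverError(RuntimeError):
    """An LP terminated in a status the caller cannot proceed from."""


@dataclass
class FluxSolution:
    """One LP solve: objective ``f``, fluxes ``x``, duals ``y``/``w``."""

    f: float
    x: pd.Series
    y: pd.Series
    w: pd.Series
    status: str
    duality_residual: float = float("nan")

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(
    S: np.ndarray,
    c_max: np.ndarray,
    bounds: list[tuple[float, float]],
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
) -> tuple:
    """Maximize c_max·v s.t. S v = 0, A_ub v <= b_ub, bounds.  Returns the
    raw scipy result of the equivalent minimization."""
    b_eq = np.zeros(S.shape[0])
    return linprog(
        -c_max,
        A_eq=S,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )


def _model_arrays(model: MetabolicModel):
    S = model.stoichiometric_matrix()
    c = np.array([r.objective_coefficient for r in model.reactions], dtype=float)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, c, bounds


def fba(model: MetabolicModel) -> FluxSolution:
    """Flux balance analysis: maximize the model objective.

    Infeasibility or unboundedness is reported in ``status`` (with NaN
    objective), never silently.
    """
    if not model.objective_reactions:
        raise SolverError(f"model {model.id!r} has no objective reaction")
    S, c, bounds = _model_arrays(model)
    res = _solve(S, c, bounds)
    status = _STATUS.get(res.status, "failed")
    rids = model.reaction_ids
    mids = model.metabolite_ids
    if status != "optimal":
        nanr = pd.Series(np.nan, index=rids)
        return FluxSolution(float("nan"), nanr, pd.Series(np.nan, index=mids), nanr.copy(), status)
    x = np.asarray(res.x)
    # duals of the min problem; negate for the maximization convention
    y_min = np.asarray(res.eqlin.marginals)
    w_min = np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    residual = abs(
        float(-c @ x)
        - float(np.asarray(res.lower.marginals) @ lb + np.asarray(res.upper.marginals) @ ub)
    )
    return FluxSolution(
        f=float(c @ x),
        x=pd.Series(x, index=rids),
        y=pd.Series(-y_min, index=mids),
        w=pd.Series(-w_min, index=rids),
        status="optimal",
        duality_residual=residual,
    )


def count_carrying_flux(sol: FluxSolution, tol: float = FLUX_TOL) -> tuple[int, int, int]:
    """(total, positive, negative) counts of reactions with |flux| > tol."""
    if not sol.optimal:
        raise SolverError(f"cannot count carrying flux on a {sol.status} solution")
    pos = int((sol.x > tol).sum())
    neg = int((sol.x < -tol).sum())
    return pos + neg, pos, neg


@dataclass
class FVAResult:
    """Per-reaction attainable [min, max] flux at a fraction of the optimum."""

    minimum: pd.Series
    maximum: pd.Series
    fraction_of_optimum: float

    @property
    def capacity(self) -> pd.Series:
        return self.maximum - self.minimum


def fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reactions: list[str] | None = None,
) -> FVAResult:
    """Flux variability analysis.

    The objective is first maximized, then constrained to at least
    ``fraction_of_optimum`` of its optimum while each reaction's flux is
    minimized and maximized in turn.  ``fraction_of_optimum=None`` drops the
    objective requirement entirely (used for blocked-reaction detection).
    """
    S, c, bounds = _model_arrays(model)
    A_ub = b_ub = None
    if fraction_of_optimum is not None:
        if not 0 <= fraction_of_optimum <= 1:
            raise ValueError(f"fraction_of_optimum must be in [0, 1], got {fraction_of_optimum}")
        base = fba(model)
        if not base.optimal:
            raise SolverError(f"FVA on a {base.status} model {model.id!r}")
        A_ub = -c.reshape(1, -1)
        b_ub = np.array([-fraction_of_optimum * base.f])
    rids = model.reaction_ids
    targets = rids if reactions is None else list(reactions)
    idx = {rid: j for j, rid in enumerate(rids)}
    mins, maxs = {}, {}
    for rid in targets:
        j = idx[rid]
        e = np.zeros(len(rids))
        e[j] = 1.0
        res_max = _solve(S, e, bounds, A_ub, b_ub)  # maximize v_j
        res_min = _solve(S, -e, bounds, A_ub, b_ub)  # maximize -v_j == minimize v_j
        if res_max.status != 0 or res_min.status != 0:
            raise SolverError(
                f"FVA subproblem for {rid!r} ended {_STATUS.get(res_max.status, 'failed')}"
            )
        maxs[rid] = float(res_max.x[j])
        mins[rid] = float(res_min.x[j])
    return FVAResult(
        minimum=pd.Series(mins),
        maximum=pd.Series(maxs),
        fraction_of_optimum=fraction_of_optimum if fraction_of_optimum is not None else float("nan"),
    )


@dataclass
class CapacityComparison:
    """Mutant-vs-WT flux-capacity shift, per reaction and per subsystem.

    Positive ``delta`` means the mutant model gained flux capacity on that
    reaction.  A subsystem is listed as increased (decreased) if at least one
    member reaction gained (lost) capacity beyond the tolerance; a subsystem
    may legitimately appear in both lists.
    """

    delta: pd.Series
    increased_subsystems: dict[str, list[str]]
    decreased_subsystems: dict[str, list[str]]


def compare_capacity(
    wt: FVAResult,
    mut: FVAResult,
    model: MetabolicModel,
    tol: float = FEAS_TOL,
) -> CapacityComparison:
    if set(wt.minimum.index) != set(mut.minimum.index):
        raise ValueError("FVA results cover different reaction sets")
    delta = (mut.capacity - wt.capacity).reindex(wt.minimum.index)
    inc: dict[str, list[str]] = {}
    dec: dict[str, list[str]] = {}
    for rid, d in delta.items():
        ss = model.reaction(rid).subsystem or "(none)"
        if d > tol:
            inc.setdefault(ss, []).append(rid)
        elif d < -tol:
            dec.setdefault(ss, []).append(rid)
    return CapacityComparison(delta=delta, increased_subsystems=inc, decreased_subsystems=dec)


# ---------------------------------------------------------------------------
# Gene deletions
# ---------------------------------------------------------------------------


@dataclass
class DeletionResult:
    """Per-gene knockout growth, ratio to the wild type, essential flag."""

    wt_growth: float
    growth: pd.Series
    ratio: pd.Series
    essential: pd.Series  # boolean
    cutoff: float


def _disabled_reactions(model: MetabolicModel, removed_genes: set[str]) -> list[int]:
    present = set(model.genes) - removed_genes
    return [
        j
        for j, r in enumerate(model.reactions)
        if r.gpr is not None and not evaluate_gpr(r.gpr, present)
    ]


def single_gene_deletion(
    model: MetabolicModel,
    essentiality_cutoff: float = 0.01,
    genes: list[str] | None = None,
) -> DeletionResult:
    """Knock out each gene in turn: zero the bounds of every reaction whose
    GPR evaluates false without it, re-solve FBA, and compare growth.

    A gene is essential iff its growth ratio falls below
    ``essentiality_cutoff`` (an infeasible knockout counts as zero growth).
    """
    base = fba(model)
    if not base.optimal or base.f <= 0:
        raise SolverError(f"deletion analysis requires a growing base model, got {base.status}")
    S, c, bounds = _model_arrays(model)
    targets = sorted(model.genes) if genes is None else list(genes)
    growth = {}
    for g in targets:
        off = _disabled_reactions(model, {g})
        if not off:
            growth[g] = base.f
            continue
        b2 = list(bounds)
        for j in off:
            b2[j] = (0.0, 0.0)
        res = _solve(S, c, b2)
        growth[g] = float(c @ res.x) if res.status == 0 else 0.0
    gser = pd.Series(growth)
    ratio = (gser / base.f).clip(lower=0.0, upper=1.0)
    return DeletionResult(
        wt_growth=base.f,
        growth=gser,
        ratio=ratio,
        essential=ratio < essentiality_cutoff,
        cutoff=essentiality_cutoff,
    )


# ---------------------------------------------------------------------------
# Parsimonious FBA and six-way gene classification
# ---------------------------------------------------------------------------

PFBA_RELATIVE_TOL = 1e-6


def pfba(model: MetabolicModel) -> FluxSolution:
    """Parsimonious FBA: fix growth at its FBA optimum (relative tolerance
    1e-6), then minimize total absolute flux through gene-associated
    reactions via the standard positive/negative flux split.

    When no reaction is gene-associated the minimization covers all
    reactions, which also serves as the deterministic reference-flux
    refinement for degenerate FBA optima.
    """
    return _pfba_impl(model, gene_associated_only=True)


def parsimonious_fba_all(model: MetabolicModel) -> FluxSolution:
    """pFBA variant minimizing total absolute flux over *all* reactions with
    the objective pinned exactly at its optimum; yields a unique,
    reproducible representative of the optimal face (the WT reference)."""
    return _pfba_impl(model, gene_associated_only=False, exact_fix=True)


def _pfba_impl(
    model: MetabolicModel, gene_associated_only: bool, exact_fix: bool = False
) -> FluxSolution:
    base = fba(model)
    if not base.optimal:
        raise SolverError(f"pFBA on a {base.status} model {model.id!r}")
    S, c, bounds = _model_arrays(model)
    n = len(model.reactions)
    minimized = [
        j
        for j, r in enumerate(model.reactions)
        if (not gene_associated_only) or r.gpr is not None
    ]
    if not minimized:
        minimized = list(range(n))
    # variables: v = p - n with p, n >= 0
    p_bounds, n_bounds = [], []
    for lb, ub in bounds:
        if lb >= 0:
            p_bounds.append((lb, ub))
            n_bounds.append((0.0, 0.0))
        elif ub <= 0:
            p_bounds.append((0.0, 0.0))
            n_bounds.append((-ub, -lb))
        else:
            p_bounds.append((0.0, ub))
            n_bounds.append((0.0, -lb))
    S2 = np.hstack([S, -S])
    cost = np.zeros(2 * n)
    for j in minimized:
        cost[j] = 1.0
        cost[n + j] = 1.0
    if exact_fix:
        A_eq = np.vstack([S2, np.hstack([c, -c])])
        b_eq = np.concatenate([np.zeros(S2.shape[0]), [base.f]])
        A_ub = b_ub = None
    else:
        floor = base.f * (1 - np.sign(base.f) * PFBA_RELATIVE_TOL) if base.f != 0 else 0.0
        A_eq, b_eq = S2, np.zeros(S2.shape[0])
        A_ub = np.hstack([-c, c]).reshape(1, -1)
        b_ub = np.array([-floor])
    res = linprog(
        cost,
        A_eq=A_eq,
        b_eq=b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=p_bounds + n_bounds,
        method="highs",
    )
    if res.status != 0:
        raise SolverError(f"pFBA stage 2 ended {_STATUS.get(res.status, 'failed')}")
    v = np.asarray(res.x[:n]) - np.asarray(res.x[n:])
    rids = model.reaction_ids
    return FluxSolution(
        f=float(c @ v),
        x=pd.Series(v, index=rids),
        y=pd.Series(np.nan, index=model.metabolite_ids),
        w=pd.Series(np.nan, index=rids),
        status="optimal",
    )


PFBA_CATEGORIES = ("essential", "pFBA optima", "ELE", "MLE", "pFBA no-flux", "blocked")


@dataclass
class PFBAClassification:
    """Six-way importance classes for gene-associated genes.

    Priority order: essential > blocked > pFBA optima > ELE (enzymatically
    less efficient: usable at optimal growth but unused by the parsimonious
    optimum) > MLE (metabolically less efficient: usable only below optimal
    growth) > pFBA no-flux.
    """

    category: pd.Series  # gene -> category string
    details: pd.DataFrame = field(default=None)

    def genes_in(self, category: str) -> list[str]:
        return sorted(self.category.index[self.category == category])


def classify_genes_pfba(
    model: MetabolicModel,
    essentiality_cutoff: float = 0.01,
    tol: float = FLUX_TOL,
) -> PFBAClassification:
    """Classify every gene-associated gene by its role in parsimonious
    optimal growth (see :class:`PFBAClassification` for the priority order).
    """
    genes = sorted(model.genes)
    if not genes:
        return PFBAClassification(category=pd.Series(dtype=object))
    g2r = {g: [r.id for r in model.reactions if g in r.gene_set] for g in genes}
    deletions = single_gene_deletion(model, essentiality_cutoff)
    sol_pfba = pfba(model)
    fva_opt = fva(model, fraction_of_optimum=1.0)
    fva_free = fva(model, fraction_of_optimum=None)

    flux_tol = max(tol, 1e-7)
    cats = {}
    rows = []
    for g in genes:
        rxns = g2r[g]
        abs_pfba = max(abs(sol_pfba.x[r]) for r in rxns)
        range_opt = max(fva_opt.maximum[r] - fva_opt.minimum[r] for r in rxns)
        extreme_opt = max(max(abs(fva_opt.maximum[r]), abs(fva_opt.minimum[r])) for r in rxns)
        extreme_free = max(max(abs(fva_free.maximum[r]), abs(fva_free.minimum[r])) for r in rxns)
        if deletions.essential[g]:
            cat = "essential"
        elif extreme_free <= flux_tol:
            cat = "blocked"
        elif abs_pfba > flux_tol:
            cat = "pFBA optima"
        elif range_opt > flux_tol or extreme_opt > flux_tol:
            cat = "ELE"
        elif extreme_free > flux_tol:
            cat = "MLE"
        else:
            cat = "pFBA no-flux"
        cats[g] = cat
        rows.append(
            {
                "gene": g,
                "category": cat,
                "deletion_ratio": deletions.ratio[g],
                "max_abs_pfba_flux": abs_pfba,
                "max_range_at_optimum": range_opt,
                "max_abs_flux_unconstrained": extreme_free,
            }
        )
    return PFBAClassification(
        category=pd.Series(cats), details=pd.DataFrame(rows).set_index("gene")
    )


# ---------------------------------------------------------------------------
# Targeted reaction objectives (metabolite-turnover proxies)
# ---------------------------------------------------------------------------


def maximize_reaction_objective(model: MetabolicModel, reaction_id: str) -> FluxSolution:
    """Maximize the flux of one reaction as the sole objective.

    The target's lower bound is set to 0 (the turnover reactions this is used
    for are irreversible), all other objective coefficients are zeroed, and
    FBA is run on a copy — the input model is untouched.
    """
    work = model.copy()
    found = False
    for r in work.reactions:
        r.objective_coefficient = 0.0
        if r.id == reaction_id:
            r.objective_coefficient = 1.0
            r.lower_bound = 0.0
            if r.upper_bound < 0:
                r.upper_bound = 0.0
            found = True
    if not found:
        raise KeyError(f"no reaction {reaction_id!r} in model {model.id!r}")
    return fba(work)
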