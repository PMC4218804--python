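"""Valve-based integration of expression fold changes into flux bounds.

Switch-style methods zero out the reactions of lowly expressed genes; the
valve approach instead *throttles* them.  Each down-regulated reaction keeps
a fraction ``2**FC`` of its wild-type reference flux, where ``FC`` is the
(negative) log2 fold change — an FC of −2 leaves one quarter of the WT flux
available.  Constraints can only shrink the solution space, so mutant growth
never exceeds the wild-type optimum.

The WT reference flux vector comes from a parsimonious refinement of the
base model's FBA optimum: FBA optima are generically degenerate, and the
minimal-total-flux representative makes the reference (and everything built
on it) reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cbm import FEAS_TOL, SolverError, parsimonious_fba_all
from .model_core import MetabolicModel

logger = logging.getLogger(__name__)


@dataclass
class ReferenceFluxState:
    """Deterministic optimal flux vector of the base model plus its growth."""

    fluxes: pd.Series
    f_wt: float


def compute_reference_fluxes(model: MetabolicModel) -> ReferenceFluxState:
    """Solve FBA, then minimize total absolute flux at the fixed optimum.

    Raises :class:`~valveflux.cbm.SolverError` if the base model is
    infeasible or unbounded.
    """
    sol = parsimonious_fba_all(model)
    S = model.stoichiometric_matrix()
    imbalance = np.abs(S @ sol.x.to_numpy()).max() if len(model.metabolites) else 0.0
    if imbalance > 10 * FEAS_TOL:
        raise SolverError(f"reference fluxes violate steady state (max imbalance {imbalance:g})")
    return ReferenceFluxState(fluxes=sol.x, f_wt=sol.f)


def scaling_factor(fold_change: float) -> float:
    """Bound-scaling factor for a (non-positive) log2 fold change.

    ``2**FC``: an FC of −2 keeps one quarter of the WT flux, 0 keeps all of
    it.  Positive fold changes are rejected — widening bounds cannot change
    an FBA optimum and up-regulated genes are excluded from the analysis.
    """
    if fold_change > 0:
        raise ValueError(f"fold change must be <= 0 for valve scaling, got {fold_change}")
    return float(2.0**fold_change)


@dataclass
class ValveProvenance:
    reaction_id: str
    reference_flux: float
    fold_change: float
    factor: float
    old_bounds: tuple[float, float]
    new_bounds: tuple[float, float]


@dataclass
class ConstrainedModel:
    """A condition-specific model: base model plus valve-scaled bounds.

    ``provenance`` records, per constrained reaction, the WT reference flux,
    the fold change, the scaling factor and the before/after bounds.
    """

    model: MetabolicModel
    provenance: dict[str, ValveProvenance]
    mode: str

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reaction": p.reaction_id,
                    "reference_flux": p.reference_flux,
                    "fold_change": p.fold_change,
                    "factor": p.factor,
                    "old_lb": p.old_bounds[0],
                    "old_ub": p.old_bounds[1],
                    "new_lb": p.new_bounds[0],
                    "new_ub": p.new_bounds[1],
                }
                for p in self.provenance.values()
            ]
        )


def apply_valve_constraints(
    model: MetabolicModel,
    ref: ReferenceFluxState,
    fc_map: dict[str, float],
    mode: str = "cap",
) -> ConstrainedModel:
    """Build a condition-specific model by throttling down-regulated reactions.

    For each reaction in ``fc_map`` with factor ``phi = 2**FC`` and reference
    flux ``v``:

    * ``mode="cap"`` (default): the flux interval becomes ``[0, phi*v]`` for
      ``v > 0`` and ``[phi*v, 0]`` for ``v < 0``; a reaction the WT optimum
      does not use (``v = 0``) has both original bounds multiplied by
      ``phi``, keeping the valve meaningful without forcing a flux.
    * ``mode="fixed"``: both bounds are set to ``phi*v`` exactly.  Fixing
      many fluxes simultaneously is generically infeasible; this literal
      reading is retained for fidelity experiments only.

    All other reactions keep their bounds.  Positive fold changes are
    rejected.
    """
    if mode not in ("cap", "fixed"):
        raise ValueError(f"mode must be 'cap' or 'fixed', got {mode!r}")
    missing = set(fc_map) - set(model.reaction_ids)
    if missing:
        raise KeyError(f"fc_map references unknown reactions: {sorted(missing)}")
    derived = model.copy()
    provenance: dict[str, ValveProvenance] = {}
    zero_tol = FEAS_TOL
    for rid, fc in sorted(fc_map.items()):
        phi = scaling_factor(fc)  # rejects fc > 0
        r = derived.reaction(rid)
        v = float(ref.fluxes[rid])
        old = r.bounds
        if mode == "fixed":
            new = (phi * v, phi * v)
        elif abs(v) <= zero_tol:
            new = (phi * old[0], phi * old[1])
        elif v > 0:
            new = (0.0, phi * v)
        else:
            new = (phi * v, 0.0)
        r.lower_bound, r.upper_bound = new
        provenance[rid] = ValveProvenance(
            reaction_id=rid,
            reference_flux=v,
            fold_change=fc,
            factor=phi,
            old_bounds=old,
            new_bounds=new,
        )
        if abs(v) <= zero_tol:
            logger.info("reaction %r has zero reference flux; scaled original bounds", rid)
    derived.validate()
    return ConstrainedModel(model=derived, provenance=provenance, mode=mode)
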