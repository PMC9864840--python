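"""Enzyme-constrained model assembly and linear-programming solutions.

The enzyme constraint is a single linear row added to an irreversible,
isozyme-split stoichiometric model:

    sum_i  v_i * MW_i / (sigma_i * kcat_i)  <=  E = ptot * f

with v_i in mmol/gDW/h, MW_i in kDa (= g/mmol), kcat_i converted from
1/s to 1/h, sigma_i the saturation coefficient, ptot the total protein
content (g/gDW) and f the enzyme mass fraction. Only reactions with
both a kcat and an MW enter the row. The same expression evaluated at a
flux solution is the per-reaction enzyme cost (g enzyme/gDW).

FBA maximizes an objective flux subject to steady state, bounds and the
budget row; pFBA is the two-stage variant that afterwards minimizes the
total flux while holding the optimum, and is the canonical reported
solution throughout. LPs are solved with scipy's HiGHS interface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .enzyme_data import (
    CoverageStats,
    KcatTable,
    ProteinTable,
    assign_kcat,
    complex_mw,
)
from .exceptions import EmptyConstraintError, LookupError_, SolverError
from .model_core import (
    MetabolicModel,
    _read_json,
    _write_json,
    base_reaction_id,
    split_isozymes,
    split_reversible,
)

__all__ = [
    "EnzymeConstrainedModel",
    "FluxSolution",
    "build_ec_model",
    "solve_fba",
    "solve_pfba",
    "enzyme_cost",
    "read_ec_model",
    "write_ec_model",
]

SECONDS_PER_HOUR = 3600.0
FEASIBILITY_TOL = 1e-9
PFBA_RELAX = 1e-7
BINDING_TOL = 1e-6

_LP_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EnzymeConstrainedModel:
    """An irreversible, isozyme-split model plus one enzyme-budget row."""

    base: MetabolicModel
    kcat: dict[str, float]              # reaction id -> 1/s
    mw: dict[str, float]                # reaction id -> kDa (g/mmol)
    sigma: dict[str, float]             # reaction id -> (0, 1]
    ptot: float                         # g protein / gDW
    f: float                            # enzyme mass fraction
    kcat_provenance: dict[str, str] = field(default_factory=dict)
    coverage: CoverageStats | None = None

    @property
    def enzyme_budget(self) -> float:
        """E = ptot * f in g enzyme / gDW."""
        return self.ptot * self.f

    @property
    def constrained_reactions(self) -> list[str]:
        """Reactions entering the budget row (both kcat and MW known)."""
        return [r.id for r in self.base.reactions
                if r.id in self.kcat and r.id in self.mw]

    def budget_coefficient(self, rxn_id: str) -> float:
        """g enzyme per unit flux: MW / (sigma * kcat[1/h])."""
        return self.mw[rxn_id] / (
            self.sigma.get(rxn_id, 1.0) * self.kcat[rxn_id] * SECONDS_PER_HOUR
        )

    def copy(self) -> "EnzymeConstrainedModel":
        return EnzymeConstrainedModel(
            base=self.base.copy(),
            kcat=dict(self.kcat),
            mw=dict(self.mw),
            sigma=dict(self.sigma),
            ptot=self.ptot,
            f=self.f,
            kcat_provenance=dict(self.kcat_provenance),
            coverage=self.coverage,
        )

    def with_kcat(self, rxn_id: str, kcat_per_s: float) -> "EnzymeConstrainedModel":
        out = self.copy()
        out.kcat[rxn_id] = kcat_per_s
        return out


@dataclass
class FluxSolution:
    """Optimal fluxes, enzyme costs and budget usage of one LP solve."""

    status: str                         # {"optimal", "infeasible", "unbounded"}
    objective_value: float
    fluxes: pd.Series
    enzyme_cost: pd.Series              # g/gDW per constrained reaction
    total_enzyme_used: float
    enzyme_budget: float
    objective_id: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    @property
    def budget_binding(self) -> bool:
        if not math.isfinite(self.enzyme_budget):
            return False
        return self.enzyme_budget - self.total_enzyme_used <= BINDING_TOL

    @property
    def budget_slack(self) -> float:
        return self.enzyme_budget - self.total_enzyme_used

    def summary(self, top: int = 10) -> str:
        lines = [
            f"status:            {self.status}",
            f"objective ({self.objective_id}): {self.objective_value:.6g}",
            f"enzyme used:       {self.total_enzyme_used:.6g} g/gDW "
            f"(budget {self.enzyme_budget:.6g}, "
            f"{'binding' if self.budget_binding else 'slack'})",
            "",
            f"top {top} enzyme costs (g/gDW):",
        ]
        for rxn_id, cost in self.enzyme_cost.sort_values(ascending=False).head(top).items():
            lines.append(f"  {rxn_id:<24s} {cost:.6g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_ec_model(
    model: MetabolicModel,
    kcats: KcatTable,
    proteins: ProteinTable,
    ptot: float,
    f: float,
    sigma_policy: float | dict[str, float] = 1.0,
    fill_policy: str | None = "median",
) -> EnzymeConstrainedModel:
    """Assemble an enzyme-constrained model from a GEM and evidence tables.

    Pipeline: split reversible reactions, split isozymes, compute the
    complex MW behind each reaction's (now OR-free) GPR, assign kcats,
    and store the budget E = ptot * f. Reactions whose genes lack
    protein data, or that receive no kcat, simply stay outside the
    budget row; an entirely empty row raises
    :class:`EmptyConstraintError`.
    """
    if not 0 < f <= 1:
        raise ValueError(f"f must be in (0, 1], got {f}")
    if ptot <= 0:
        raise ValueError(f"ptot must be > 0, got {ptot}")
    split_model, _ = split_reversible(model)
    split_model, _ = split_isozymes(split_model)
    mw: dict[str, float] = {}
    for r in split_model.reactions:
        if r.gpr.is_empty:
            continue
        try:
            mw[r.id] = complex_mw(r.gpr, proteins)
        except LookupError_:
            continue  # no protein data: reaction stays unconstrained
    assignments, coverage = assign_kcat(split_model, kcats, fill_policy)
    kcat = {rxn_id: value for rxn_id, (value, _) in assignments.items()}
    provenance = {rxn_id: prov for rxn_id, (_, prov) in assignments.items()}
    if isinstance(sigma_policy, dict):
        sigma = {r.id: float(sigma_policy.get(r.id, 1.0)) for r in split_model.reactions}
    else:
        sigma = {r.id: float(sigma_policy) for r in split_model.reactions}
    ecm = EnzymeConstrainedModel(
        base=split_model, kcat=kcat, mw=mw, sigma=sigma,
        ptot=ptot, f=f, kcat_provenance=provenance, coverage=coverage,
    )
    if not ecm.constrained_reactions:
        raise EmptyConstraintError("no reaction carries both a kcat and an MW")
    return ecm


# ---------------------------------------------------------------------------
# Bound overrides
# ---------------------------------------------------------------------------

def _resolve_overrides(
    model: MetabolicModel,
    overrides: dict[str, float | tuple[float, float]] | None,
) -> dict[str, tuple[float, float]]:
    """Translate user overrides (stated on original reaction ids, net-flux
    convention: uptake = negative lower bound on an exchange) into bounds
    on the possibly split model's reactions."""
    resolved: dict[str, tuple[float, float]] = {}
    if not overrides:
        return resolved
    by_base: dict[str, list] = {}
    for r in model.reactions:
        by_base.setdefault(base_reaction_id(r.id), []).append(r)
    for rxn_id, value in overrides.items():
        has_reverse_partner = model.has_reaction(rxn_id + "_reverse")
        if model.has_reaction(rxn_id) and not has_reverse_partner:
            r = model.reaction(rxn_id)
            lb, ub = (value if isinstance(value, tuple) else (float(value), r.upper_bound))
            resolved[rxn_id] = (lb, ub)
            continue
        members = (
            [model.reaction(rxn_id), model.reaction(rxn_id + "_reverse")]
            if has_reverse_partner
            else by_base.get(rxn_id)
        )
        if not members:
            raise LookupError_(f"override target {rxn_id!r} not in model")
        forward = [r for r in members if "_reverse" not in r.id]
        reverse = [r for r in members if "_reverse" in r.id]
        if len(forward) != 1 or len(reverse) > 1:
            raise ValueError(
                f"override target {rxn_id!r} maps to multiple split reactions; "
                f"override the split ids directly"
            )
        net_ub = forward[0].upper_bound
        lb, ub = (value if isinstance(value, tuple) else (float(value), net_ub))
        resolved[forward[0].id] = (max(lb, 0.0), max(ub, 0.0))
        if reverse:
            resolved[reverse[0].id] = (max(-ub, 0.0), max(-lb, 0.0))
    return resolved


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------

def _assemble(model: MetabolicModel,
              overrides: dict[str, tuple[float, float]]):
    n = len(model.reactions)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = lil_matrix((len(model.metabolites), n))
    bounds = []
    for j, r in enumerate(model.reactions):
        for met_id, coef in r.stoichiometry.items():
            S[met_index[met_id], j] = coef
        bounds.append(overrides.get(r.id, (r.lower_bound, r.upper_bound)))
    return S.tocsr(), bounds


def _lp(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs", options=_LP_OPTIONS)
    return res


def _budget_row(model: MetabolicModel, ecm: EnzymeConstrainedModel | None):
    if ecm is None:
        return None
    row = np.zeros(len(model.reactions))
    for j, r in enumerate(model.reactions):
        if r.id in ecm.kcat and r.id in ecm.mw:
            row[j] = ecm.budget_coefficient(r.id)
    return row


def _costs(model: MetabolicModel, ecm: EnzymeConstrainedModel | None,
           fluxes: np.ndarray) -> pd.Series:
    if ecm is None:
        return pd.Series(dtype=float)
    data = {
        r.id: ecm.budget_coefficient(r.id) * fluxes[j]
        for j, r in enumerate(model.reactions)
        if r.id in ecm.kcat and r.id in ecm.mw
    }
    return pd.Series(data, dtype=float)


def _solution(model: MetabolicModel, ecm, res, objective_id: str,
              budget: float) -> FluxSolution:
    if res.status == 2:
        status = "infeasible"
    elif res.status == 3:
        status = "unbounded"
    elif res.status == 0:
        status = "optimal"
    else:  # pragma: no cover - solver pathology
        raise SolverError(f"LP solver failed: {res.message}")
    if status != "optimal":
        return FluxSolution(
            status=status, objective_value=float("nan"),
            fluxes=pd.Series(dtype=float), enzyme_cost=pd.Series(dtype=float),
            total_enzyme_used=float("nan"), enzyme_budget=budget,
            objective_id=objective_id,
        )
    fluxes = pd.Series(res.x, index=model.reaction_ids)
    costs = _costs(model, ecm, res.x)
    return FluxSolution(
        status="optimal",
        objective_value=float(fluxes[objective_id]),
        fluxes=fluxes,
        enzyme_cost=costs,
        total_enzyme_used=float(costs.sum()),
        enzyme_budget=budget,
        objective_id=objective_id,
    )


def _prepare(model_or_ecm, objective_id, bound_overrides, enzyme_budget):
    if isinstance(model_or_ecm, EnzymeConstrainedModel):
        ecm = model_or_ecm
        model = ecm.base
        budget = ecm.enzyme_budget if enzyme_budget is None else enzyme_budget
    else:
        ecm = None
        model = model_or_ecm
        budget = math.inf if enzyme_budget is None else enzyme_budget
    objective_id = objective_id or model.objective_reaction_id
    if not objective_id or not model.has_reaction(objective_id):
        raise LookupError_(f"objective reaction {objective_id!r} not in model")
    overrides = _resolve_overrides(model, bound_overrides)
    return model, ecm, objective_id, overrides, budget


def solve_fba(
    model_or_ecm: MetabolicModel | EnzymeConstrainedModel,
    objective_id: str | None = None,
    bound_overrides: dict | None = None,
    enzyme_budget: float | None = None,
) -> FluxSolution:
    """Maximize an objective flux under steady state, bounds and (for an
    enzyme-constrained model) the enzyme-budget row.

    ``enzyme_budget`` overrides E (``math.inf`` relaxes the constraint
    entirely). Infeasibility is reported in the solution status, not
    raised.
    """
    model, ecm, objective_id, overrides, budget = _prepare(
        model_or_ecm, objective_id, bound_overrides, enzyme_budget
    )
    S, bounds = _assemble(model, overrides)
    n = len(model.reactions)
    c = np.zeros(n)
    c[model.reaction_ids.index(objective_id)] = -1.0
    A_ub, b_ub = None, None
    row = _budget_row(model, ecm)
    if row is not None and math.isfinite(budget):
        A_ub, b_ub = row.reshape(1, -1), [budget]
    res = _lp(c, A_ub, b_ub, S, np.zeros(S.shape[0]), bounds)
    return _solution(model, ecm, res, objective_id, budget)


def solve_pfba(
    model_or_ecm: MetabolicModel | EnzymeConstrainedModel,
    objective_id: str | None = None,
    bound_overrides: dict | None = None,
    enzyme_budget: float | None = None,
    objective_fraction: float = 1.0,
) -> FluxSolution:
    """Parsimonious FBA: fix the objective at (a fraction of) its FBA
    optimum, then minimize the total flux.

    Total-flux minimization requires non-negative fluxes; a plain model
    with reversible reactions is split internally and net fluxes are
    mapped back onto the original reactions. The objective is fixed via
    ``>= fraction * opt * (1 - 1e-7)`` to absorb solver round-off.
    """
    if isinstance(model_or_ecm, MetabolicModel) and any(
        r.lower_bound < 0 for r in model_or_ecm.reactions
    ):
        return _pfba_on_reversible(model_or_ecm, objective_id, bound_overrides,
                                   enzyme_budget, objective_fraction)
    model, ecm, objective_id, overrides, budget = _prepare(
        model_or_ecm, objective_id, bound_overrides, enzyme_budget
    )
    S, bounds = _assemble(model, overrides)
    n = len(model.reactions)
    obj_idx = model.reaction_ids.index(objective_id)
    c1 = np.zeros(n)
    c1[obj_idx] = -1.0
    ub_rows, ub_vals = [], []
    row = _budget_row(model, ecm)
    if row is not None and math.isfinite(budget):
        ub_rows.append(row)
        ub_vals.append(budget)
    A_ub1 = np.vstack(ub_rows) if ub_rows else None
    res1 = _lp(c1, A_ub1, ub_vals or None, S, np.zeros(S.shape[0]), bounds)
    if res1.status != 0:
        return _solution(model, ecm, res1, objective_id, budget)
    opt = -res1.fun
    target = objective_fraction * opt
    target -= abs(target) * PFBA_RELAX
    fix_row = np.zeros(n)
    fix_row[obj_idx] = -1.0  # -v_obj <= -target
    A_ub2 = np.vstack(ub_rows + [fix_row]) if ub_rows else fix_row.reshape(1, -1)
    b_ub2 = list(ub_vals) + [-target]
    c2 = np.ones(n)
    res2 = _lp(c2, A_ub2, b_ub2, S, np.zeros(S.shape[0]), bounds)
    if res2.status != 0:
        raise SolverError(
            "pFBA stage 2 infeasible at the fixed optimum; retry with "
            "objective_fraction = 1 - 1e-6"
        )
    return _solution(model, ecm, res2, objective_id, budget)


def _pfba_on_reversible(model, objective_id, bound_overrides, enzyme_budget,
                        objective_fraction):
    split_model, mapping = split_reversible(model)
    sol = solve_pfba(split_model, objective_id or model.objective_reaction_id,
                     bound_overrides, enzyme_budget, objective_fraction)
    if not sol.optimal:
        return sol
    net = {}
    for old_id, new_ids in mapping.items():
        net[old_id] = sol.fluxes[new_ids[0]]
        if len(new_ids) == 2:
            net[old_id] -= sol.fluxes[new_ids[1]]
        elif new_ids[0].endswith("_reverse"):
            net[old_id] = -sol.fluxes[new_ids[0]]
    sol.fluxes = pd.Series(net)
    return sol


# ---------------------------------------------------------------------------
# Enzyme cost accounting
# ---------------------------------------------------------------------------

def enzyme_cost(ecm: EnzymeConstrainedModel, solution: FluxSolution) -> pd.DataFrame:
    """Per-reaction enzyme cost table, sorted by cost descending.

    cost_i = v_i * MW_i / (sigma_i * kcat_i[1/h]); cost share is the
    fraction of the total enzyme used.
    """
    if not solution.optimal:
        raise ValueError("enzyme_cost requires an optimal solution")
    rows = []
    total = solution.total_enzyme_used
    for rxn_id in ecm.constrained_reactions:
        flux = float(solution.fluxes.get(rxn_id, 0.0))
        cost = ecm.budget_coefficient(rxn_id) * flux
        rows.append(
            {
                "reaction": rxn_id,
                "flux": flux,
                "kcat_per_s": ecm.kcat[rxn_id],
                "mw_kda": ecm.mw[rxn_id],
                "sigma": ecm.sigma.get(rxn_id, 1.0),
                "cost": cost,
                "cost_share": cost / total if total > 0 else 0.0,
                "genes": " and ".join(sorted(ecm.base.reaction(rxn_id).gpr.genes)),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["cost", "reaction"], ascending=[False, True],
                          ignore_index=True)


# ---------------------------------------------------------------------------
# EC model JSON I/O (native dialect with enzyme annotations)
# ---------------------------------------------------------------------------

def write_ec_model(ecm: EnzymeConstrainedModel, path: str | Path) -> None:
    extras = {}
    for r in ecm.base.reactions:
        entry = {}
        if r.id in ecm.kcat:
            entry["kcat_per_s"] = ecm.kcat[r.id]
            entry["kcat_provenance"] = ecm.kcat_provenance.get(r.id, "")
        if r.id in ecm.mw:
            entry["enzyme_mw_kda"] = ecm.mw[r.id]
        sigma = ecm.sigma.get(r.id, 1.0)
        if entry or sigma != 1.0:
            entry["sigma"] = sigma
        if entry:
            extras[r.id] = entry
    _write_json(
        ecm.base, path, reaction_extras=extras,
        document_extras={"ec_model": {"ptot": ecm.ptot, "f": ecm.f,
                                      "enzyme_budget": ecm.enzyme_budget}},
    )


def read_ec_model(path: str | Path) -> EnzymeConstrainedModel:
    base = _read_json(path)
    base.validate()
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    meta = doc.get("ec_model", {})
    kcat, mw, sigma, provenance = {}, {}, {}, {}
    for entry in doc.get("reactions", []):
        rxn_id = entry["id"]
        if "kcat_per_s" in entry:
            kcat[rxn_id] = float(entry["kcat_per_s"])
            if entry.get("kcat_provenance"):
                provenance[rxn_id] = entry["kcat_provenance"]
        if "enzyme_mw_kda" in entry:
            mw[rxn_id] = float(entry["enzyme_mw_kda"])
        if "sigma" in entry:
            sigma[rxn_id] = float(entry["sigma"])
    return EnzymeConstrainedModel(
        base=base, kcat=kcat, mw=mw, sigma=sigma,
        ptot=float(meta.get("ptot", 1.0)),
        f=float(meta.get("f", 1.0)),
        kcat_provenance=provenance,
    )
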