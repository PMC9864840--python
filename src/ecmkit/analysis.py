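"""Simulation studies on (enzyme-constrained) metabolic models.

Four workflows, all built on pFBA solutions:

* phenotype phase planes — optimal growth over a substrate x oxygen
  uptake grid;
* growth prediction on defined carbon sources, with error metrics
  against experimental tables;
* substrate sweeps — growth, secretion, biomass yield, enzyme usage
  efficiency and the oxidative-phosphorylation ratio along an uptake
  gradient, with classification into substrate-limited / overflow
  switching / overflow stages;
* metabolic-engineering target ranking by enzyme cost at a fixed
  biomass fraction.

Conventions: exchange fluxes are negative for uptake and positive for
secretion (on a split model the two directions are separate reactions
and are recombined here); "enzyme usage efficiency" is growth per gram
of enzyme used, mu / E_used (1/h per g/gDW); the oxidative
phosphorylation ratio is the fraction of carbon uptake entering a
configured respiratory reaction set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ec_model import EnzymeConstrainedModel, FluxSolution, enzyme_cost, solve_pfba
from .exceptions import LookupError_
from .model_core import MetabolicModel, base_reaction_id, parse_formula

__all__ = [
    "PhPPGrid",
    "phpp",
    "predict_growth",
    "growth_error_metrics",
    "substrate_sweep",
    "classify_stages",
    "predict_targets",
]

SECRETION_TOL = 1e-6   # mmol/gDW/h
SLACK_TOL = 1e-6       # g/gDW

STAGE_SUBSTRATE_LIMITED = "substrate-limited"
STAGE_SWITCHING = "switching"
STAGE_OVERFLOW = "overflow"


def _base_model(model_or_ecm) -> MetabolicModel:
    if isinstance(model_or_ecm, EnzymeConstrainedModel):
        return model_or_ecm.base
    return model_or_ecm


def _exchange_groups(model: MetabolicModel) -> dict[str, list[str]]:
    """Original exchange id -> split reaction ids (forward first)."""
    groups: dict[str, list[str]] = {}
    for r in model.reactions:
        if r.is_exchange:
            groups.setdefault(base_reaction_id(r.id), []).append(r.id)
    for ids in groups.values():
        ids.sort(key=lambda x: "_reverse" in x)
    return groups


def net_exchange_flux(model: MetabolicModel, solution: FluxSolution,
                      exchange_id: str) -> float:
    """Net flux of an exchange (negative = uptake), recombining split pairs."""
    total = 0.0
    for r in model.reactions:
        if base_reaction_id(r.id) != exchange_id:
            continue
        sign = -1.0 if "_reverse" in r.id else 1.0
        total += sign * float(solution.fluxes.get(r.id, 0.0))
    return total


def _carbon_count(model: MetabolicModel, met_id: str) -> float:
    formula = model.metabolite(met_id).formula
    if not formula.strip():
        return 0.0
    return parse_formula(formula).get("C", 0.0)


# ---------------------------------------------------------------------------
# Phenotype phase planes
# ---------------------------------------------------------------------------

@dataclass
class PhPPGrid:
    """Optimal growth over a substrate x oxygen uptake grid."""

    substrate_axis: np.ndarray   # mmol/gDW/h
    oxygen_axis: np.ndarray
    growth: np.ndarray           # shape (len(substrate_axis), len(oxygen_axis))
    optimal: np.ndarray          # bool mask; infeasible points have growth 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "substrate_uptake": float(s),
                "oxygen_uptake": float(o),
                "growth": float(self.growth[i, j]),
                "optimal": bool(self.optimal[i, j]),
            }
            for i, s in enumerate(self.substrate_axis)
            for j, o in enumerate(self.oxygen_axis)
        ]
        return pd.DataFrame(rows)


def phpp(
    model_or_ecm: MetabolicModel | EnzymeConstrainedModel,
    substrate_exchange: str,
    oxygen_exchange: str,
    substrate_range: tuple[float, float] = (0.0, 15.0),
    oxygen_range: tuple[float, float] = (0.0, 50.0),
    n_steps: int = 51,
    objective_id: str | None = None,
) -> PhPPGrid:
    """Phenotype phase plane: pFBA maximal growth at each uptake combination.

    Uptake bounds act as availability caps (the model may take less).
    Infeasible points are flagged and recorded as zero growth.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    s_axis = np.linspace(*substrate_range, n_steps)
    o_axis = np.linspace(*oxygen_range, n_steps)
    growth = np.zeros((n_steps, n_steps))
    optimal = np.zeros((n_steps, n_steps), dtype=bool)
    for i, s in enumerate(s_axis):
        for j, o in enumerate(o_axis):
            sol = solve_pfba(
                model_or_ecm, objective_id,
                bound_overrides={substrate_exchange: (-float(s), 1000.0),
                                 oxygen_exchange: (-float(o), 1000.0)},
            )
            if sol.optimal:
                growth[i, j] = max(sol.objective_value, 0.0)
                optimal[i, j] = True
    return PhPPGrid(s_axis, o_axis, growth, optimal)


# ---------------------------------------------------------------------------
# Growth prediction on carbon sources
# ---------------------------------------------------------------------------

def predict_growth(
    model_or_ecm: MetabolicModel | EnzymeConstrainedModel,
    carbon_sources: dict[str, dict[str, float]],
    free_uptake: tuple[str, ...] = (),
    objective_id: str | None = None,
) -> pd.DataFrame:
    """Simulate growth per condition with only the listed uptakes open.

    ``carbon_sources`` maps a condition name to {exchange id: uptake
    rate} (positive rates; multi-substrate conditions allowed). Every
    other exchange has its uptake closed except those in
    ``free_uptake`` (oxygen, water ...); secretion stays open
    everywhere. Unknown exchange ids raise a lookup error.
    """
    model = _base_model(model_or_ecm)
    groups = _exchange_groups(model)
    rows = []
    for name, uptakes in carbon_sources.items():
        for ex_id in uptakes:
            if ex_id not in groups:
                raise LookupError_(f"condition {name!r}: unknown exchange {ex_id!r}")
        overrides: dict[str, tuple[float, float]] = {}
        for ex_id, ids in groups.items():
            if ex_id in uptakes or ex_id in free_uptake:
                continue
            ub = model.reaction(ids[0]).upper_bound
            overrides[ex_id] = (0.0, ub)
        for ex_id, rate in uptakes.items():
            overrides[ex_id] = (-abs(float(rate)), 1000.0)
        sol = solve_pfba(model_or_ecm, objective_id, bound_overrides=overrides)
        rows.append(
            {
                "condition": name,
                "growth": sol.objective_value if sol.optimal else 0.0,
                "status": sol.status,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def growth_error_metrics(
    predicted: pd.DataFrame | pd.Series,
    experimental: pd.DataFrame | pd.Series,
    predicted_fluxes: pd.DataFrame | None = None,
    experimental_fluxes: pd.DataFrame | None = None,
    epsilon: float = 1e-6,
) -> dict:
    """Relative growth errors and (optionally) normalized flux errors.

    Growth error per condition is |mu_pred - mu_exp| / mu_exp
    (conditions with mu_exp = 0 are skipped with a warning). Flux
    errors, when flux tables are given, are |v_pred - v_exp| /
    max(|v_exp|, epsilon), summarized as mean/median/quartiles.
    """
    mu_pred = predicted["growth"] if isinstance(predicted, pd.DataFrame) else predicted
    mu_exp = (
        experimental["growth"] if isinstance(experimental, pd.DataFrame) else experimental
    )
    mu_pred, mu_exp = mu_pred.align(mu_exp, join="inner")
    zero = mu_exp == 0
    if zero.any():
        warnings.warn(
            f"skipping {int(zero.sum())} conditions with zero experimental growth",
            stacklevel=2,
        )
    mu_pred, mu_exp = mu_pred[~zero], mu_exp[~zero]
    growth_error = (mu_pred - mu_exp).abs() / mu_exp
    out = {
        "growth_relative_error": growth_error,
        "growth_relative_error_mean": float(growth_error.mean()),
        "growth_relative_error_median": float(growth_error.median()),
    }
    if predicted_fluxes is not None and experimental_fluxes is not None:
        vp, ve = predicted_fluxes.align(experimental_fluxes, join="inner")
        err = (vp - ve).abs() / ve.abs().clip(lower=epsilon)
        flat = err.to_numpy().ravel()
        flat = flat[~np.isnan(flat)]
        out["flux_normalized_error"] = {
            "mean": float(np.mean(flat)),
            "median": float(np.median(flat)),
            "q25": float(np.percentile(flat, 25)),
            "q75": float(np.percentile(flat, 75)),
        }
    return out


# ---------------------------------------------------------------------------
# Substrate sweeps and overflow staging
# ---------------------------------------------------------------------------

def _default_overflow_exchanges(model: MetabolicModel) -> list[str]:
    """Carbon-carrying exchanges that can secrete, excluding CO2."""
    out = []
    for ex_id, ids in _exchange_groups(model).items():
        met_id = next(iter(model.reaction(ids[0]).stoichiometry))
        formula = model.metabolite(met_id).formula.replace(" ", "").upper()
        if formula == "CO2":
            continue
        if _carbon_count(model, met_id) > 0 and any(
            model.reaction(i).upper_bound > 0 and "_reverse" not in i for i in ids
        ):
            out.append(ex_id)
    return sorted(out)


def substrate_sweep(
    ecm: EnzymeConstrainedModel,
    substrate_exchange: str,
    q_grid: np.ndarray | list[float],
    respiratory_reactions: tuple[str, ...] = (),
    energy_metabolite: str | None = None,
    overflow_exchanges: tuple[str, ...] | None = None,
    objective_id: str | None = None,
    bound_overrides: dict | None = None,
) -> pd.DataFrame:
    """pFBA along a substrate-uptake gradient.

    Per grid point: growth, actual uptake, secretion of every overflow
    product (positive exchange flux), enzyme usage and slack, biomass
    yield (gDW per g substrate), enzyme usage efficiency (mu per g
    enzyme), the carbon fraction entering ``respiratory_reactions``,
    and the summed enzyme cost of reactions producing
    ``energy_metabolite``. Overflow products default to carbon-carrying
    secretable exchanges other than CO2 and the substrate itself.
    """
    q_grid = np.asarray(list(q_grid), dtype=float)
    if np.any(np.diff(q_grid) < 0):
        raise ValueError("q_grid must be sorted ascending")
    model = ecm.base
    if overflow_exchanges is None:
        overflow_exchanges = tuple(
            e for e in _default_overflow_exchanges(model) if e != substrate_exchange
        )
    substrate_met = next(iter(
        model.reaction(_exchange_groups(model)[substrate_exchange][0]).stoichiometry
    ))
    substrate_mw = None
    formula = model.metabolite(substrate_met).formula
    if formula.strip():
        from .model_core import molar_mass

        substrate_mw = molar_mass(formula)  # g/mol
    substrate_carbon = _carbon_count(model, substrate_met)
    energy_reactions = []
    if energy_metabolite is not None:
        energy_reactions = [
            r.id for r in model.reactions
            if r.stoichiometry.get(energy_metabolite, 0.0) > 0
        ]
    rows = []
    for q in q_grid:
        overrides = dict(bound_overrides or {})
        overrides[substrate_exchange] = (-float(q), 1000.0)
        sol = solve_pfba(ecm, objective_id, bound_overrides=overrides)
        row: dict[str, float | str] = {"q_set": float(q)}
        if not sol.optimal:
            row.update({"status": sol.status, "growth": 0.0})
            rows.append(row)
            continue
        uptake = max(0.0, -net_exchange_flux(model, sol, substrate_exchange))
        mu = sol.objective_value
        row.update(
            {
                "status": "optimal",
                "q_uptake": uptake,
                "growth": mu,
                "enzyme_used": sol.total_enzyme_used,
                "budget_slack": sol.budget_slack,
                "enzyme_efficiency": (
                    mu / sol.total_enzyme_used if sol.total_enzyme_used > 0 else np.nan
                ),
            }
        )
        if substrate_mw and uptake > 0:
            row["biomass_yield"] = mu / (uptake * substrate_mw / 1000.0)
        else:
            row["biomass_yield"] = np.nan
        for ex_id in overflow_exchanges:
            row[f"secretion_{ex_id}"] = max(
                0.0, net_exchange_flux(model, sol, ex_id)
            )
        if respiratory_reactions and substrate_carbon > 0 and uptake > 0:
            carbon_in = 0.0
            for rxn_id in respiratory_reactions:
                r = model.reaction(rxn_id)
                v = float(sol.fluxes.get(rxn_id, 0.0))
                carbon_in += v * sum(
                    -coef * _carbon_count(model, met)
                    for met, coef in r.stoichiometry.items()
                    if coef < 0
                )
            row["oxphos_ratio"] = min(
                1.0, carbon_in / (uptake * substrate_carbon)
            )
        if energy_reactions:
            row["energy_enzyme_cost"] = float(
                sum(sol.enzyme_cost.get(rxn_id, 0.0) for rxn_id in energy_reactions)
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["overflow_exchanges"] = list(overflow_exchanges)
    df.attrs["enzyme_budget"] = ecm.enzyme_budget
    return df


def classify_stages(
    sweep: pd.DataFrame,
    secretion_tol: float = SECRETION_TOL,
    slack_tol: float = SLACK_TOL,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Annotate a sweep with overflow stages and return the boundaries.

    Substrate-limited: enzyme budget has slack; switching: budget
    binding but no overflow secretion above tolerance; overflow: any
    overflow product secreted. Boundaries are the first grid uptakes of
    the switching and overflow stages (NaN if a stage never occurs).
    Non-monotone staging yields a consistency warning, not an error.
    """
    df = sweep.copy()
    secretion_cols = [c for c in df.columns if c.startswith("secretion_")]
    total_secretion = (
        df[secretion_cols].sum(axis=1) if secretion_cols else pd.Series(0.0, index=df.index)
    )
    slack = df.get("budget_slack", pd.Series(np.inf, index=df.index)).fillna(np.inf)

    def stage(i) -> str:
        if total_secretion[i] > secretion_tol:
            return STAGE_OVERFLOW
        if slack[i] > slack_tol:
            return STAGE_SUBSTRATE_LIMITED
        return STAGE_SWITCHING

    df["stage"] = [stage(i) for i in df.index]
    order = {STAGE_SUBSTRATE_LIMITED: 0, STAGE_SWITCHING: 1, STAGE_OVERFLOW: 2}
    codes = df["stage"].map(order).to_numpy()
    if np.any(np.diff(codes) < 0):
        warnings.warn("stage sequence is non-monotone along the sweep", stacklevel=2)
    boundaries = {}
    for name, key in (("q_budget_onset", STAGE_SWITCHING),
                      ("q_overflow_onset", STAGE_OVERFLOW)):
        hit = df.loc[df["stage"].map(order) >= order[key], "q_set"]
        boundaries[name] = float(hit.iloc[0]) if len(hit) else float("nan")
    return df, boundaries


# ---------------------------------------------------------------------------
# Metabolic-engineering target ranking
# ---------------------------------------------------------------------------

def predict_targets(
    ecm: EnzymeConstrainedModel,
    product_exchange: str,
    biomass_fraction: float = 0.10,
    top_n: int = 15,
    bound_overrides: dict | None = None,
    biomass_id: str | None = None,
) -> pd.DataFrame:
    """Rank reactions by enzyme cost while producing a target compound.

    Procedure: (1) pFBA maximizing biomass gives mu_max; (2) the biomass
    lower bound is fixed at ``biomass_fraction * mu_max``; (3) pFBA
    maximizes the product exchange; (4) reactions are ranked by enzyme
    cost. Returns the ``top_n`` most expensive reactions with cost,
    cost share and genes; an unproducible product returns an empty
    table with ``attrs["status"] = "unproducible"``.
    """
    model = ecm.base
    biomass_id = biomass_id or model.biomass_reaction_id or model.objective_reaction_id
    growth_sol = solve_pfba(ecm, biomass_id, bound_overrides=bound_overrides)
    empty = pd.DataFrame(
        columns=["reaction", "flux", "kcat_per_s", "mw_kda", "sigma",
                 "cost", "cost_share", "genes"]
    )
    if not growth_sol.optimal:
        empty.attrs["status"] = "no-growth"
        return empty
    mu_max = growth_sol.objective_value
    overrides = dict(bound_overrides or {})
    overrides[biomass_id] = (
        biomass_fraction * mu_max,
        model.reaction(biomass_id).upper_bound,
    )
    groups = _exchange_groups(model)
    if product_exchange not in groups:
        raise LookupError_(f"unknown product exchange {product_exchange!r}")
    product_rxn = groups[product_exchange][0]  # forward = secretion direction
    product_sol = solve_pfba(ecm, product_rxn, bound_overrides=overrides)
    if not product_sol.optimal or product_sol.objective_value <= SECRETION_TOL:
        empty.attrs["status"] = "unproducible"
        return empty
    table = enzyme_cost(ecm, product_sol).head(top_n).reset_index(drop=True)
    table.attrs["status"] = "ok"
    table.attrs["mu_max"] = mu_max
    table.attrs["product_flux"] = product_sol.objective_value
    return table
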