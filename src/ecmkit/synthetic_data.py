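"""Self-contained toy fixtures with closed-form enzyme-constrained behaviour.

The generator emits a small core-metabolism network — glucose uptake,
transport, lumped glycolysis, two respiratory modes and a fermentative
branch feeding an ATP-driven biomass sink — together with consistent
kcat, protein and proteome-abundance tables, standing in for a
genome-scale model plus BRENDA/UniProt/PAXdb inputs.

The three catabolic routes are ordered so that overflow metabolism is
forced once protein becomes limiting:

* full respiration (a proton-pumping terminal oxidase, AND-complex GPR)
  — highest ATP yield per glucose, lowest ATP per gram of enzyme;
* a respiratory bypass (a low-yield alternative oxidase, as in the
  *B. subtilis* bd-type branch) — intermediate on both axes;
* fermentation to acetate (an isozyme pair, OR GPR) — lowest ATP yield,
  highest ATP per gram of enzyme.

With those orderings the optimal growth curve mu(q) over the substrate
uptake q is piecewise linear and concave with analytically computable
breakpoints: q* where the enzyme budget first binds (pure respiration
still optimal), q** where the last fully-respiratory solution dies and
acetate secretion begins, and q*** beyond which the cell is purely
fermentative and mu saturates. The generator derives these coefficients
from the spec at generation time; tests verify them against the LP.

Randomization (seeded) perturbs only proteome abundances; topology and
kinetics are fixed so the closed form stays exact. Abundance tables
include non-model "filler" genes sized so the enzyme mass fraction f
computed from the tables equals the spec value exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .ec_model import EnzymeConstrainedModel, build_ec_model
from .enzyme_data import (
    AbundanceTable,
    KcatRecord,
    KcatTable,
    ProteinInfo,
    ProteinTable,
    enzyme_mass_fraction,
)
from .exceptions import EcmkitError
from .model_core import MetabolicModel, Metabolite, Reaction, molar_mass, parse_gpr

__all__ = [
    "ToySpec",
    "ToyData",
    "ClosedForm",
    "make_toy_gem",
    "make_multisubstrate_variant",
    "build_toy_ec_model",
]

GLUCOSE_MW = molar_mass("C6H12O6")  # 180.156 g/mol
SECONDS_PER_HOUR = 3600.0


class ToySpecError(EcmkitError):
    """The spec violates a precondition for overflow metabolism."""


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the toy network (defaults are the study conditions).

    ATP yields are mmol ATP per mmol substrate of the reaction they
    annotate (glycolysis per glucose, branches per pyruvate); kcats are
    1/s, molecular weights kDa. The biomass sink consumes
    ``glc_per_biomass`` mmol glucose (its carbon skeleton; the default
    makes biomass weigh exactly 1 g/mmol so growth rate equals biomass
    flux) plus ``atp_per_biomass`` mmol ATP per mmol biomass.
    """

    uptake_cap: float = 10.0           # mmol/gDW/h, glucose exchange bound
    o2_cap: float = 1000.0

    atp_per_glc_glycolysis: float = 2.0
    atp_per_pyr_respiration: float = 12.5
    atp_per_pyr_bypass: float = 5.0
    atp_per_pyr_fermentation: float = 0.5
    atp_per_biomass: float = 30.0      # mmol ATP / mmol biomass
    glc_per_biomass: float = 1000.0 / GLUCOSE_MW  # mmol glc / mmol biomass

    kcat_transport: float = 200.0
    kcat_glycolysis: float = 50.0
    kcat_respiration: float = 0.18
    kcat_bypass: float = 0.55
    kcat_fermentation: float = 3.0

    mw_transport_monomer: float = 30.0   # homodimer
    n_transport: int = 2
    mw_glycolysis: float = 45.0
    mw_respiration_sub1: float = 50.0    # 2 copies in the complex
    n_respiration_sub1: int = 2
    mw_respiration_sub2: float = 30.0
    mw_bypass: float = 65.0
    mw_fermentation: float = 40.0

    sigma: float = 1.0
    ptot: float = 0.2806               # g protein / gDW
    enzyme_fraction: float = 0.588     # f; enzyme budget E = ptot * f
    enzyme_budget: float | None = None  # override E (math.inf relaxes it)

    abundance_noise: float = 0.0       # lognormal sd on model-gene abundances

    @property
    def budget(self) -> float:
        if self.enzyme_budget is not None:
            return self.enzyme_budget
        return self.ptot * self.enzyme_fraction


@dataclass(frozen=True)
class Route:
    """One catabolic route per unit glucose: ATP yield and enzyme cost."""

    name: str
    atp_per_glc: float     # y~ = y_gly + 2 * y_branch
    cost_per_glc: float    # c~ = c_gly + 2 * c_branch, g enzyme h / mmol

    @property
    def atp_per_enzyme(self) -> float:
        return self.atp_per_glc / self.cost_per_glc


@dataclass(frozen=True)
class Segment:
    q_lo: float
    q_hi: float
    intercept: float
    slope: float


@dataclass(frozen=True)
class ClosedForm:
    """Analytic mu(q) and overflow structure of the toy under its budget."""

    enzyme_budget: float
    transport_cost: float              # c_T, g enzyme h / mmol glucose
    routes: tuple[Route, ...]          # ordered by decreasing ATP yield
    atp_per_biomass: float
    glc_per_biomass: float
    q_budget: float                    # q*: budget row first binds
    q_overflow: float                  # q**: overflow secretion begins
    q_pure_ferment: float              # q***: growth saturates
    segments: tuple[Segment, ...] = field(default=())

    def mu(self, q: float) -> float:
        for seg in self.segments:
            if q <= seg.q_hi or seg is self.segments[-1]:
                return seg.intercept + seg.slope * min(q, self.q_pure_ferment)
        raise AssertionError("unreachable")

    def acetate_secretion(self, q: float) -> float:
        """Closed-form acetate flux (mmol/gDW/h): 0 up to q**, then rising."""
        if q <= self.q_overflow:
            return 0.0
        q_eff = min(q, self.q_pure_ferment)
        mu = self.mu(q_eff)
        y_lo = self.routes[1].atp_per_glc
        y_f = self.routes[2].atp_per_glc
        catabolic = q_eff - self.glc_per_biomass * mu
        glc_through_ferm = (y_lo * catabolic - self.atp_per_biomass * mu) / (y_lo - y_f)
        return 2.0 * glc_through_ferm  # 2 pyruvate -> 2 acetate per glucose


class ToyData(NamedTuple):
    model: MetabolicModel
    kcats: KcatTable
    proteins: ProteinTable
    abundances: AbundanceTable
    closed_form: ClosedForm


# ---------------------------------------------------------------------------
# Closed-form derivation
# ---------------------------------------------------------------------------

def _enzyme_cost_per_flux(mw: float, kcat: float, sigma: float) -> float:
    return mw / (sigma * kcat * SECONDS_PER_HOUR)


def _mixed_segment_line(i: Route, j: Route, c_t: float, e: float,
                        a_atp: float, a_glc: float) -> tuple[float, float]:
    """mu(q) = intercept + slope*q when routes i and j share the budget
    and the uptake cap, solved from glucose, ATP and enzyme balances."""
    cross = i.cost_per_glc * j.atp_per_glc - j.cost_per_glc * i.atp_per_glc
    d = a_atp * (i.cost_per_glc - j.cost_per_glc) + a_glc * cross
    slope = (cross - (i.atp_per_glc - j.atp_per_glc) * c_t) / d
    intercept = (i.atp_per_glc - j.atp_per_glc) * e / d
    return intercept, slope


def derive_closed_form(spec: ToySpec) -> ClosedForm:
    sigma = spec.sigma
    c_t = _enzyme_cost_per_flux(
        spec.n_transport * spec.mw_transport_monomer, spec.kcat_transport, sigma
    )
    c_gly = _enzyme_cost_per_flux(spec.mw_glycolysis, spec.kcat_glycolysis, sigma)
    mw_resp = (
        spec.n_respiration_sub1 * spec.mw_respiration_sub1 + spec.mw_respiration_sub2
    )
    branch = {
        "respiration": (
            spec.atp_per_pyr_respiration,
            _enzyme_cost_per_flux(mw_resp, spec.kcat_respiration, sigma),
        ),
        "bypass": (
            spec.atp_per_pyr_bypass,
            _enzyme_cost_per_flux(spec.mw_bypass, spec.kcat_bypass, sigma),
        ),
        "fermentation": (
            spec.atp_per_pyr_fermentation,
            _enzyme_cost_per_flux(spec.mw_fermentation, spec.kcat_fermentation, sigma),
        ),
    }
    routes = tuple(
        Route(
            name=name,
            atp_per_glc=spec.atp_per_glc_glycolysis + 2.0 * y,
            cost_per_glc=c_gly + 2.0 * c,
        )
        for name, (y, c) in branch.items()
    )
    r_hi, r_lo, r_f = routes
    # overflow preconditions, checked at generation time
    if not r_hi.atp_per_glc > r_lo.atp_per_glc > r_f.atp_per_glc:
        raise ToySpecError(
            "ATP yields must satisfy respiration > bypass > fermentation "
            f"(got {r_hi.atp_per_glc}, {r_lo.atp_per_glc}, {r_f.atp_per_glc})"
        )
    if not r_f.atp_per_enzyme > r_lo.atp_per_enzyme > r_hi.atp_per_enzyme:
        raise ToySpecError(
            "ATP per enzyme must satisfy fermentation > bypass > respiration "
            f"(got {r_f.atp_per_enzyme:.4g}, {r_lo.atp_per_enzyme:.4g}, "
            f"{r_hi.atp_per_enzyme:.4g})"
        )
    a_atp, a_glc = spec.atp_per_biomass, spec.glc_per_biomass
    e = spec.budget

    def pure_slope(route: Route) -> float:
        return route.atp_per_glc / (a_atp + route.atp_per_glc * a_glc)

    def pure_budget_uptake(route: Route) -> float:
        if not math.isfinite(e):
            return math.inf
        per_q = c_t + route.cost_per_glc * (1.0 - a_glc * pure_slope(route))
        return e / per_q

    q_star = pure_budget_uptake(r_hi)
    q_2star = pure_budget_uptake(r_lo)
    q_3star = pure_budget_uptake(r_f)
    s_hi = pure_slope(r_hi)
    if not math.isfinite(e):
        return ClosedForm(
            enzyme_budget=e, transport_cost=c_t, routes=routes,
            atp_per_biomass=a_atp, glc_per_biomass=a_glc,
            q_budget=math.inf, q_overflow=math.inf, q_pure_ferment=math.inf,
            segments=(Segment(0.0, math.inf, 0.0, s_hi),),
        )
    a12, b12 = _mixed_segment_line(r_hi, r_lo, c_t, e, a_atp, a_glc)
    a23, b23 = _mixed_segment_line(r_lo, r_f, c_t, e, a_atp, a_glc)
    if not (s_hi > b12 > b23 > 0):
        raise ToySpecError(
            "mu(q) must stay increasing and concave across stages "
            f"(slopes {s_hi:.4g}, {b12:.4g}, {b23:.4g})"
        )
    segments = (
        Segment(0.0, q_star, 0.0, s_hi),
        Segment(q_star, q_2star, a12, b12),
        Segment(q_2star, q_3star, a23, b23),
    )
    return ClosedForm(
        enzyme_budget=e, transport_cost=c_t, routes=routes,
        atp_per_biomass=a_atp, glc_per_biomass=a_glc,
        q_budget=q_star, q_overflow=q_2star, q_pure_ferment=q_3star,
        segments=segments,
    )


# ---------------------------------------------------------------------------
# Network emission
# ---------------------------------------------------------------------------

_MODEL_GENE_ABUNDANCE = {
    # baseline ppm, jittered by the seeded lognormal noise
    "gT": 5000.0, "gG": 20000.0, "gR1": 8000.0, "gR2": 8000.0,
    "gR3": 2000.0, "gF1": 3000.0, "gF2": 1000.0,
}
_FILLER_SHARES = {"gX1": 0.5, "gX2": 0.3, "gX3": 0.2}
_FILLER_MW = 50.0


def _metabolites(extra: list[Metabolite] = ()) -> list[Metabolite]:  # type: ignore[assignment]
    mets = [
        Metabolite("glc_e", "glucose (extracellular)", "e", "C6H12O6"),
        Metabolite("glc_c", "glucose", "c", "C6H12O6"),
        Metabolite("pyr_c", "pyruvate", "c", "C3H4O3"),
        Metabolite("o2_e", "oxygen (extracellular)", "e", "O2"),
        Metabolite("o2_c", "oxygen", "c", "O2"),
        Metabolite("co2_c", "carbon dioxide", "c", "CO2"),
        Metabolite("ac_c", "acetate", "c", "C2H4O2"),
        Metabolite("ac_e", "acetate (extracellular)", "e", "C2H4O2"),
        Metabolite("h2_c", "reducing equivalents (as H2)", "c", "H2"),
        Metabolite("h2o_c", "water", "c", "H2O"),
        Metabolite("atp_c", "energy token (ATP equivalents)", "c", ""),
        Metabolite("biomass_c", "biomass", "c", ""),
    ]
    return mets + list(extra)


def _reactions(spec: ToySpec) -> list[Reaction]:
    y_g = spec.atp_per_glc_glycolysis
    return [
        Reaction("EX_glc_e", {"glc_e": -1.0}, -spec.uptake_cap, 1000.0,
                 name="glucose exchange"),
        Reaction("EX_o2_e", {"o2_e": -1.0}, -spec.o2_cap, 1000.0,
                 name="oxygen exchange"),
        Reaction("EX_ac_e", {"ac_e": -1.0}, 0.0, 1000.0, name="acetate exchange"),
        Reaction("EX_co2_c", {"co2_c": -1.0}, 0.0, 1000.0, name="CO2 exchange"),
        Reaction("EX_h2_c", {"h2_c": -1.0}, 0.0, 1000.0, name="H2 exchange"),
        Reaction("EX_h2o_c", {"h2o_c": -1.0}, -1000.0, 1000.0, name="water exchange"),
        Reaction("DM_biomass_c", {"biomass_c": -1.0}, 0.0, 1000.0,
                 name="biomass drain"),
        Reaction("GLCt", {"glc_e": -1.0, "glc_c": 1.0}, 0.0, 1000.0,
                 gpr=parse_gpr("gT"), ec_numbers=["2.7.1.199"],
                 name="glucose PTS transport"),
        Reaction("O2t", {"o2_e": -1.0, "o2_c": 1.0}, 0.0, 1000.0,
                 name="oxygen diffusion"),
        Reaction(
            "GLY",
            {"glc_c": -1.0, "pyr_c": 2.0, "h2_c": 2.0, "atp_c": y_g},
            0.0, 1000.0, gpr=parse_gpr("gG"), ec_numbers=["2.7.1.40"],
            name="glycolysis (lumped)",
        ),
        Reaction(
            "RESP_HI",
            {"pyr_c": -1.0, "o2_c": -2.5, "co2_c": 3.0, "h2o_c": 2.0,
             "atp_c": spec.atp_per_pyr_respiration},
            0.0, 1000.0, gpr=parse_gpr("gR1 and gR2"), ec_numbers=["1.9.3.1"],
            name="respiration, proton-pumping oxidase (lumped)",
        ),
        Reaction(
            "RESP_LO",
            {"pyr_c": -1.0, "o2_c": -2.5, "co2_c": 3.0, "h2o_c": 2.0,
             "atp_c": spec.atp_per_pyr_bypass},
            0.0, 1000.0, gpr=parse_gpr("gR3"), ec_numbers=["1.10.3.10"],
            name="respiration, bypass oxidase (lumped)",
        ),
        Reaction(
            "FERM",
            {"pyr_c": -1.0, "h2o_c": -1.0, "ac_c": 1.0, "co2_c": 1.0,
             "h2_c": 1.0, "atp_c": spec.atp_per_pyr_fermentation},
            0.0, 1000.0, gpr=parse_gpr("gF1 or gF2"), ec_numbers=["2.7.2.1"],
            name="fermentation to acetate (lumped)",
        ),
        Reaction("ACt", {"ac_c": -1.0, "ac_e": 1.0}, -1000.0, 1000.0,
                 name="acetate transport (passive)"),
        Reaction(
            "BIOMASS",
            {"glc_c": -spec.glc_per_biomass, "atp_c": -spec.atp_per_biomass,
             "biomass_c": 1.0},
            0.0, 1000.0, name="biomass synthesis",
        ),
    ]


def _protein_rows(spec: ToySpec) -> list[ProteinInfo]:
    return [
        ProteinInfo("gT", spec.mw_transport_monomer, spec.n_transport),
        ProteinInfo("gG", spec.mw_glycolysis, 1),
        ProteinInfo("gR1", spec.mw_respiration_sub1, spec.n_respiration_sub1),
        ProteinInfo("gR2", spec.mw_respiration_sub2, 1),
        ProteinInfo("gR3", spec.mw_bypass, 1),
        ProteinInfo("gF1", spec.mw_fermentation, 1),
        ProteinInfo("gF2", spec.mw_fermentation, 1),
    ] + [ProteinInfo(g, _FILLER_MW, 1) for g in _FILLER_SHARES]


def _kcat_records(spec: ToySpec) -> list[KcatRecord]:
    return [
        KcatRecord("GLCt", spec.kcat_transport, "reaction"),
        KcatRecord("GLY", spec.kcat_glycolysis, "reaction"),
        KcatRecord("RESP_HI", spec.kcat_respiration, "reaction"),
        KcatRecord("RESP_LO", spec.kcat_bypass, "reaction"),
        # fermentation isozymes are matched through their shared EC number
        KcatRecord("2.7.2.1", spec.kcat_fermentation, "ec"),
    ]


def _abundances(spec: ToySpec, proteins: ProteinTable,
                model_genes: dict[str, float], seed: int | None) -> AbundanceTable:
    rng = np.random.default_rng(seed)
    rows: dict[str, float] = {}
    for gene, base in model_genes.items():
        jitter = (
            float(rng.lognormal(mean=0.0, sigma=spec.abundance_noise))
            if spec.abundance_noise > 0
            else 1.0
        )
        rows[gene] = base * jitter
    model_mass = sum(a * proteins[g].monomer_mw for g, a in rows.items())
    f = spec.enzyme_fraction
    filler_mass = model_mass * (1.0 / f - 1.0)
    for gene, share in _FILLER_SHARES.items():
        rows[gene] = share * filler_mass / _FILLER_MW
    return AbundanceTable(rows)


def make_toy_gem(spec: ToySpec = ToySpec(), seed: int | None = None) -> ToyData:
    """Generate the toy GEM with its kinetics/protein/abundance tables.

    The returned closed form is derived analytically from the spec (and
    verified against the LP in the test suite). Raises
    :class:`ToySpecError` if the spec violates an overflow precondition,
    naming the violated inequality.
    """
    closed_form = derive_closed_form(spec)
    model = MetabolicModel(
        metabolites=_metabolites(),
        reactions=_reactions(spec),
        genes=["gT", "gG", "gR1", "gR2", "gR3", "gF1", "gF2"],
        objective_reaction_id="BIOMASS",
        biomass_reaction_id="BIOMASS",
        id="toy_overflow",
    )
    model.validate()
    proteins = ProteinTable(_protein_rows(spec))
    abundances = _abundances(spec, proteins, _MODEL_GENE_ABUNDANCE, seed)
    return ToyData(model, KcatTable(_kcat_records(spec)), proteins,
                   abundances, closed_form)


def make_multisubstrate_variant(
    spec: ToySpec = ToySpec(),
    second_substrate_yield: float = 1.0,
    seed: int | None = None,
) -> ToyData:
    """Add a second carbon source feeding the same lower network.

    The second substrate (a hexose isomer) enters through its own
    transporter and yields ``second_substrate_yield`` glucose
    equivalents per mmol; with yield 1 the chemistry stays balanced and
    growth depends only on the summed uptake. The second exchange is
    closed by default (lower bound 0); open it with a bound override.
    """
    base = make_toy_gem(spec, seed=seed)
    model = base.model.copy()
    formula = "C6H12O6" if second_substrate_yield == 1.0 else ""
    model.metabolites.append(
        Metabolite("fru_e", "second hexose (extracellular)", "e", formula)
    )
    stoich: dict[str, float] = {"fru_e": -1.0}
    if second_substrate_yield != 0.0:
        stoich["glc_c"] = second_substrate_yield
    else:
        stoich["h2o_c"] = 1.0  # dead-end route: carbon lost, no growth benefit
    model.reactions.append(
        Reaction("EX_fru_e", {"fru_e": -1.0}, 0.0, 1000.0,
                 name="second hexose exchange")
    )
    model.reactions.append(
        Reaction("FRUt", stoich, 0.0, 1000.0, gpr=parse_gpr("gT2"),
                 ec_numbers=["2.7.1.202"], name="second hexose transport")
    )
    model.genes.append("gT2")
    model.reindex()
    model.validate()
    proteins = ProteinTable(
        _protein_rows(spec)
        + [ProteinInfo("gT2", spec.mw_transport_monomer, spec.n_transport)]
    )
    kcats = KcatTable(
        _kcat_records(spec) + [KcatRecord("FRUt", spec.kcat_transport, "reaction")]
    )
    genes = dict(_MODEL_GENE_ABUNDANCE)
    genes["gT2"] = genes["gT"]
    abundances = _abundances(spec, proteins, genes, seed)
    return ToyData(model, kcats, proteins, abundances, base.closed_form)


def build_toy_ec_model(
    toy: ToyData,
    spec: ToySpec = ToySpec(),
) -> EnzymeConstrainedModel:
    """Build the enzyme-constrained toy with f recomputed from its tables."""
    f = enzyme_mass_fraction(toy.abundances, toy.proteins, toy.model.genes)
    return build_ec_model(
        toy.model, toy.kcats, toy.proteins,
        ptot=spec.ptot, f=f, sigma_policy=spec.sigma, fill_policy=None,
    )
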