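"""Stoichiometric model data structures, I/O and structural transformations.

The model container is deliberately small: metabolites, reactions with
signed stoichiometry and flux bounds, GPR rules, and an objective. Two
transformations prepare a model for enzyme constraints — splitting
reversible reactions into irreversible pairs and splitting isozyme
(top-level OR) reactions so each reaction maps to exactly one enzyme —
plus biomass quality control: the implied molar mass of a formula-less
pseudo-species (g/mmol) and its normalization to 1 g/mmol.

SBML Level 3 + FBC input/output is delegated to cobrapy; the native
dialect is COBRA-style JSON with optional per-reaction enzyme keys
(``kcat_per_s``, ``enzyme_mw_kda``, ``sigma``).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from .atomic_masses import ATOMIC_MASSES
from .exceptions import (
    AmbiguousBiomassError,
    FormulaError,
    ModelIntegrityError,
    ModelParseError,
    NormalizationError,
    UnsupportedGPRError,
)
from .gpr import GPR, And, Gene, Or, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "read_model",
    "write_model",
    "parse_gpr",
    "parse_formula",
    "molar_mass",
    "split_reversible",
    "split_isozymes",
    "biomass_molar_mass",
    "normalize_macromolecule",
    "REVERSE_SUFFIX",
    "ISOZYME_SUFFIX",
]

DEFAULT_BOUND = 1000.0
REVERSE_SUFFIX = "_reverse"
ISOZYME_SUFFIX = "_num"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str = ""
    charge: int = 0


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPR = field(default_factory=GPR)
    ec_numbers: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gpr=self.gpr,
            ec_numbers=list(self.ec_numbers),
            name=self.name,
        )


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    objective_reaction_id: str = ""
    biomass_reaction_id: str = ""
    id: str = "model"

    def __post_init__(self):
        self._met_index: dict[str, Metabolite] = {}
        self._rxn_index: dict[str, Reaction] = {}
        self.reindex()

    def reindex(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_reaction_id=self.objective_reaction_id,
            biomass_reaction_id=self.biomass_reaction_id,
            id=self.id,
        )

    def validate(self) -> None:
        """Raise :class:`ModelIntegrityError` on broken references or duplicates."""
        if len(self._met_index) != len(self.metabolites):
            raise ModelIntegrityError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelIntegrityError("duplicate reaction ids")
        gene_set = set(self.genes)
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelIntegrityError(
                        f"reaction {r.id} references undeclared metabolite {met_id}"
                    )
            missing = r.gpr.genes - gene_set
            if missing:
                raise ModelIntegrityError(
                    f"reaction {r.id} GPR references undeclared genes {sorted(missing)}"
                )
        if self.objective_reaction_id and self.objective_reaction_id not in self._rxn_index:
            raise ModelIntegrityError(
                f"objective reaction {self.objective_reaction_id} not in model"
            )


# ---------------------------------------------------------------------------
# Elemental formulas
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula (``C6H12O6``) into element -> count."""
    formula = formula.strip()
    counts: dict[str, float] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_RE.match(formula, pos)
        if m is None or m.group(1) not in ATOMIC_MASSES:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        element = m.group(1)
        count = float(m.group(2)) if m.group(2) else 1.0
        counts[element] = counts.get(element, 0.0) + count
        pos = m.end()
    return counts


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol from an elemental formula.

    The empty formula returns 0.0 with a warning (pseudo-species such as
    biomass); unknown element symbols raise :class:`FormulaError`.
    """
    if not formula.strip():
        warnings.warn("empty formula: molar mass reported as 0", stacklevel=2)
        return 0.0
    return sum(ATOMIC_MASSES[el] * n for el, n in parse_formula(formula).items())


# ---------------------------------------------------------------------------
# I/O — native COBRA-style JSON; SBML via cobrapy
# ---------------------------------------------------------------------------

def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    return "json"


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from COBRA-style JSON or SBML L3+FBC.

    Bounds default to +/-1000 when absent; GPR strings are parsed into
    expression trees. Broken metabolite references raise
    :class:`ModelIntegrityError`; malformed files raise
    :class:`ModelParseError` naming the offending element.
    """
    fmt = _infer_format(path, format)
    if fmt == "json":
        model = _read_json(path)
    elif fmt == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as COBRA-style JSON or SBML L3+FBC (round-trip safe)."""
    fmt = _infer_format(path, format)
    if fmt == "json":
        _write_json(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def _read_json(path: str | Path) -> MetabolicModel:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON ({exc})") from exc

    metabolites = []
    for m in doc.get("metabolites", []):
        if "id" not in m:
            raise ModelParseError(f"{path}: metabolite entry without id: {m}")
        metabolites.append(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", ""),
                formula=m.get("formula") or "",
                charge=int(m.get("charge") or 0),
            )
        )
    reactions = []
    objective_id = doc.get("objective_reaction_id", "")
    for r in doc.get("reactions", []):
        if "id" not in r:
            raise ModelParseError(f"{path}: reaction entry without id: {r}")
        try:
            gpr = parse_gpr(r.get("gene_reaction_rule", ""))
        except Exception as exc:
            raise ModelParseError(f"{path}: reaction {r['id']}: bad GPR ({exc})") from exc
        reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r.get("metabolites", {}).items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=gpr,
                ec_numbers=list(r.get("ec_numbers", [])),
                name=r.get("name", ""),
            )
        )
        if not objective_id and float(r.get("objective_coefficient", 0) or 0) != 0:
            objective_id = r["id"]
    genes = [g["id"] if isinstance(g, dict) else str(g) for g in doc.get("genes", [])]
    if not genes:
        genes = sorted({g for r in reactions for g in r.gpr.genes})
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_reaction_id=objective_id,
        biomass_reaction_id=doc.get("biomass_reaction_id", ""),
        id=doc.get("id", "model"),
    )


def _reaction_to_json(r: Reaction, objective_id: str, extras: dict | None = None) -> dict:
    entry = {
        "id": r.id,
        "name": r.name,
        "metabolites": dict(r.stoichiometry),
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "gene_reaction_rule": r.gpr.to_string(),
        "ec_numbers": list(r.ec_numbers),
        "objective_coefficient": 1.0 if r.id == objective_id else 0.0,
    }
    if extras:
        entry.update(extras)
    return entry


def _write_json(model: MetabolicModel, path: str | Path,
                reaction_extras: dict[str, dict] | None = None,
                document_extras: dict | None = None) -> None:
    doc = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites
        ],
        "reactions": [
            _reaction_to_json(
                r,
                model.objective_reaction_id,
                (reaction_extras or {}).get(r.id),
            )
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in model.genes],
        "objective_reaction_id": model.objective_reaction_id,
        "biomass_reaction_id": model.biomass_reaction_id,
    }
    if document_extras:
        doc.update(document_extras)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (SBML I/O and LP cross-checks)."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, formula=m.formula or None, name=m.name,
            compartment=m.compartment or "c", charge=m.charge,
        )
        mets[m.id] = cmet
    for r in model.reactions:
        crxn = cobra.Reaction(r.id, name=r.name,
                              lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        rule = r.gpr.to_string()
        if rule:
            crxn.gene_reaction_rule = rule
        if r.ec_numbers:
            crxn.annotation["ec-code"] = list(r.ec_numbers)
    if model.objective_reaction_id:
        cm.objective = model.objective_reaction_id
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model into an ecmkit model."""
    metabolites = [
        Metabolite(
            id=m.id, name=m.name or "", compartment=m.compartment or "",
            formula=m.formula or "", charge=int(m.charge or 0),
        )
        for m in cm.metabolites
    ]
    objective_id = ""
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cm)
        if coeffs:
            objective_id = max(coeffs, key=lambda r: coeffs[r]).id
    except Exception:
        pass
    reactions = []
    for r in cm.reactions:
        ec = r.annotation.get("ec-code", [])
        if isinstance(ec, str):
            ec = [ec]
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: v for m, v in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule or ""),
                ec_numbers=list(ec),
                name=r.name or "",
            )
        )
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=[g.id for g in cm.genes],
        objective_reaction_id=objective_id,
        id=cm.id or "model",
    )


def _read_sbml(path: str | Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:
        raise ModelParseError(f"{path}: SBML parse failed ({exc})") from exc
    return from_cobra(cm)


def _write_sbml(model: MetabolicModel, path: str | Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# Structural transformations
# ---------------------------------------------------------------------------

def split_reversible(model: MetabolicModel) -> tuple[MetabolicModel, dict[str, list[str]]]:
    """Split every reversible reaction into an irreversible forward/reverse pair.

    A reaction with bounds [lb, ub], lb < 0 < ub, becomes the forward
    reaction (bounds [0, ub]) plus ``<id>_reverse`` with negated
    stoichiometry and bounds [0, -lb]. Reactions with lb >= 0 are kept;
    a purely backward reaction (ub <= 0) is replaced by its reversed
    form. Returns the new model and a mapping old id -> new ids.
    """
    out = model.copy()
    new_reactions: list[Reaction] = []
    mapping: dict[str, list[str]] = {}
    for r in out.reactions:
        if r.lower_bound >= 0:
            new_reactions.append(r)
            mapping[r.id] = [r.id]
        elif r.upper_bound <= 0:
            rev = r.copy()
            rev.id = r.id + REVERSE_SUFFIX
            rev.stoichiometry = {k: -v for k, v in r.stoichiometry.items()}
            rev.lower_bound, rev.upper_bound = -r.upper_bound, -r.lower_bound
            new_reactions.append(rev)
            mapping[r.id] = [rev.id]
        else:
            fwd = r.copy()
            fwd.lower_bound = 0.0
            rev = r.copy()
            rev.id = r.id + REVERSE_SUFFIX
            rev.stoichiometry = {k: -v for k, v in r.stoichiometry.items()}
            rev.lower_bound, rev.upper_bound = 0.0, -r.lower_bound
            new_reactions.extend([fwd, rev])
            mapping[r.id] = [fwd.id, rev.id]
    out.reactions = new_reactions
    out.reindex()
    return out, mapping


def _check_no_or_below_and(node) -> None:
    """Reject AND nodes containing OR anywhere below them."""
    if isinstance(node, And):
        for child in node.children:
            if isinstance(child, Or) or (
                not isinstance(child, Gene) and _contains_or(child)
            ):
                raise UnsupportedGPRError(
                    "OR nested below AND is not supported for isozyme splitting"
                )
    elif isinstance(node, Or):
        for child in node.children:
            _check_no_or_below_and(child)


def _contains_or(node) -> bool:
    if isinstance(node, Or):
        return True
    if isinstance(node, Gene):
        return False
    return any(_contains_or(c) for c in node.children)


def split_isozymes(model: MetabolicModel) -> tuple[MetabolicModel, dict[str, list[str]]]:
    """Split reactions catalysed by isozymes so each maps to one enzyme.

    A reaction whose GPR is a top-level OR of k alternatives becomes k
    reactions ``<id>_num1`` ... ``<id>_numk`` (order of the OR children),
    each with one alternative (a gene or an AND complex) and identical
    stoichiometry and bounds. The model must already be irreversible.
    GPRs with OR nested below AND raise :class:`UnsupportedGPRError`.
    """
    if any(r.lower_bound < 0 for r in model.reactions):
        raise ModelIntegrityError("split_isozymes requires an irreversible model "
                                  "(run split_reversible first)")
    out = model.copy()
    new_reactions: list[Reaction] = []
    mapping: dict[str, list[str]] = {}
    for r in out.reactions:
        root = r.gpr.root
        if root is not None:
            _check_no_or_below_and(root)
        if not isinstance(root, Or):
            new_reactions.append(r)
            mapping[r.id] = [r.id]
            continue
        ids = []
        for k, child in enumerate(root.children, start=1):
            iso = r.copy()
            iso.id = f"{r.id}{ISOZYME_SUFFIX}{k}"
            iso.gpr = GPR(child)
            new_reactions.append(iso)
            ids.append(iso.id)
        mapping[r.id] = ids
    out.reactions = new_reactions
    out.reindex()
    for old_id, new_ids in mapping.items():
        if out.objective_reaction_id == old_id:
            out.objective_reaction_id = new_ids[0]
        if out.biomass_reaction_id == old_id:
            out.biomass_reaction_id = new_ids[0]
    return out, mapping


def base_reaction_id(rxn_id: str) -> str:
    """Strip isozyme (``_num<k>``) and reverse (``_reverse``) suffixes."""
    rxn_id = re.sub(rf"{ISOZYME_SUFFIX}\d+$", "", rxn_id)
    if rxn_id.endswith(REVERSE_SUFFIX):
        rxn_id = rxn_id[: -len(REVERSE_SUFFIX)]
    return re.sub(rf"{ISOZYME_SUFFIX}\d+$", "", rxn_id)


# ---------------------------------------------------------------------------
# Biomass quality control
# ---------------------------------------------------------------------------

def element_imbalance(
    model: MetabolicModel,
    reaction_id: str,
    elements: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Net atoms produced minus consumed over formula-carrying metabolites.

    Formula-less species (pseudo-metabolites such as biomass or energy
    tokens) are skipped; a balanced reaction returns zeros.
    """
    reaction = model.reaction(reaction_id)
    imbalance: dict[str, float] = {}
    for met_id, coef in reaction.stoichiometry.items():
        formula = model.metabolite(met_id).formula
        if not formula.strip():
            continue
        for el, n in parse_formula(formula).items():
            imbalance[el] = imbalance.get(el, 0.0) + coef * n
    if elements is not None:
        imbalance = {el: imbalance.get(el, 0.0) for el in elements}
    return imbalance

def _find_pseudo_species(model: MetabolicModel, reaction: Reaction,
                         species_id: str | None) -> str:
    if species_id is not None:
        return species_id
    candidates = [
        met_id
        for met_id, coef in reaction.stoichiometry.items()
        if coef > 0 and not model.metabolite(met_id).formula.strip()
    ]
    if len(candidates) != 1:
        raise AmbiguousBiomassError(
            f"reaction {reaction.id}: expected exactly one formula-less product, "
            f"found {candidates}"
        )
    return candidates[0]


def biomass_molar_mass(
    model: MetabolicModel,
    reaction_id: str,
    species_id: str | None = None,
) -> tuple[float, dict[str, float]]:
    """Implied molar mass (g/mmol) of a formula-less pseudo-species.

    For a synthesis reaction producing a pseudo-species (biomass, protein,
    RNA ...), mass conservation implies the species weighs
    (sum of reactant mass - sum of other product mass) per unit produced.
    Returns that mass in g/mmol together with an element-imbalance report
    (product minus reactant atoms over metabolites that carry formulas).
    The pseudo-species defaults to the sole formula-less product.
    """
    reaction = model.reaction(reaction_id)
    species = _find_pseudo_species(model, reaction, species_id)
    species_coef = reaction.stoichiometry.get(species, 0.0)
    if species_coef <= 0:
        raise AmbiguousBiomassError(
            f"reaction {reaction_id}: species {species} is not a product"
        )
    net_mass = 0.0  # g/mol net consumed
    imbalance: dict[str, float] = {}
    for met_id, coef in reaction.stoichiometry.items():
        if met_id == species:
            continue
        formula = model.metabolite(met_id).formula
        if not formula.strip():
            continue  # other pseudo-species (e.g. energy tokens) carry no mass
        net_mass -= coef * molar_mass(formula)
        for el, n in parse_formula(formula).items():
            imbalance[el] = imbalance.get(el, 0.0) + coef * n
    return net_mass / 1000.0 / species_coef, imbalance


def normalize_macromolecule(
    model: MetabolicModel,
    reaction_id: str,
    species_id: str | None = None,
) -> tuple[MetabolicModel, float]:
    """Rescale a pseudo-species so one unit weighs exactly 1 g/mmol.

    If the species' implied mass is m g/mmol, the precursor coefficients
    of its synthesis reaction are divided by m (one new unit = 1 g) and
    the species' coefficient is multiplied by m wherever it is consumed
    elsewhere, conserving mass flow through the network. Returns the new
    model and the factor m. Raises :class:`NormalizationError` if m <= 0.
    """
    mass, _ = biomass_molar_mass(model, reaction_id, species_id)
    if mass <= 0:
        raise NormalizationError(
            f"reaction {reaction_id}: implied species mass {mass:.6g} g/mmol <= 0"
        )
    out = model.copy()
    reaction = out.reaction(reaction_id)
    species = _find_pseudo_species(out, reaction, species_id)
    species_coef = reaction.stoichiometry[species]
    # per one new unit (1 g) of species
    reaction.stoichiometry = {
        met: (1.0 if met == species else coef / (species_coef * mass))
        for met, coef in reaction.stoichiometry.items()
    }
    for r in out.reactions:
        if r.id == reaction_id or species not in r.stoichiometry:
            continue
        r.stoichiometry[species] *= mass
    return out, mass
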