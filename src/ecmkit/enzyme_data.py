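"""Kinetic, protein and proteomic evidence tables.

Three TSV inputs feed the enzyme constraint:

* kcat table — ``key, key_type{reaction,ec}, kcat_per_s``: turnover
  numbers keyed by reaction id or EC number;
* protein table — ``gene, monomer_mw_kda, subunit_count``: monomer
  molecular weight and homo-oligomer copy number per gene;
* abundance table — ``gene, abundance_ppm``: proteome abundances.

From these the module computes complex molecular weights (sum of
N_j * MW_j over subunits), the enzyme mass fraction f (the share of
proteome mass carried by genes present in the model), and a per-reaction
kcat assignment for a split model with provenance and coverage
statistics.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exceptions import DegenerateDataError, LookupError_
from .gpr import GPR, And, Gene
from .model_core import MetabolicModel, base_reaction_id

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinInfo",
    "ProteinTable",
    "KcatRecord",
    "KcatTable",
    "AbundanceTable",
    "CoverageStats",
    "complex_mw",
    "enzyme_mass_fraction",
    "assign_kcat",
    "read_protein_table",
    "read_kcat_table",
    "read_abundance_table",
]

PROVENANCE_DIRECT = "reaction-direct"
PROVENANCE_EC = "ec-match"
PROVENANCE_FILLED = "filled"


@dataclass(frozen=True)
class ProteinInfo:
    """Monomer MW (kDa) and homo-oligomer copy number for one gene."""

    gene: str
    monomer_mw: float  # kDa
    subunit_count: int = 1

    def __post_init__(self):
        if self.monomer_mw <= 0:
            raise ValueError(f"{self.gene}: monomer_mw must be > 0")
        if self.subunit_count < 1:
            raise ValueError(f"{self.gene}: subunit_count must be >= 1")


class ProteinTable:
    """Gene -> :class:`ProteinInfo` lookup."""

    def __init__(self, rows: list[ProteinInfo] | dict[str, ProteinInfo]):
        if isinstance(rows, dict):
            self._rows = dict(rows)
        else:
            self._rows = {r.gene: r for r in rows}

    def __contains__(self, gene: str) -> bool:
        return gene in self._rows

    def __getitem__(self, gene: str) -> ProteinInfo:
        try:
            return self._rows[gene]
        except KeyError:
            raise LookupError_(f"gene {gene!r} missing from protein table") from None

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def genes(self) -> list[str]:
        return list(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gene": r.gene, "monomer_mw_kda": r.monomer_mw,
                 "subunit_count": r.subunit_count}
                for r in self._rows.values()
            ]
        )


@dataclass(frozen=True)
class KcatRecord:
    """A turnover number keyed by reaction id or EC number (kcat in 1/s)."""

    key: str
    kcat: float  # 1/s
    key_type: str = "reaction"  # {"reaction", "ec"}

    def __post_init__(self):
        if self.kcat <= 0:
            raise ValueError(f"{self.key}: kcat must be > 0")
        if self.key_type not in ("reaction", "ec"):
            raise ValueError(f"{self.key}: key_type must be 'reaction' or 'ec'")


class KcatTable:
    """A collection of kcat records with reaction-id and EC indices."""

    def __init__(self, records: list[KcatRecord] = ()):  # type: ignore[assignment]
        self.records = list(records)
        self._by_reaction: dict[str, list[float]] = {}
        self._by_ec: dict[str, list[float]] = {}
        for rec in self.records:
            index = self._by_reaction if rec.key_type == "reaction" else self._by_ec
            index.setdefault(rec.key, []).append(rec.kcat)

    def __len__(self) -> int:
        return len(self.records)

    def reaction_max(self, rxn_id: str) -> float | None:
        """Max kcat among records matching a reaction id (split suffixes stripped)."""
        values = self._by_reaction.get(rxn_id) or self._by_reaction.get(
            base_reaction_id(rxn_id)
        )
        return max(values) if values else None

    def ec_max(self, ec_numbers: list[str]) -> float | None:
        values = [v for ec in ec_numbers for v in self._by_ec.get(ec, [])]
        return max(values) if values else None


class AbundanceTable:
    """Rows of (gene, abundance in ppm)."""

    def __init__(self, rows: dict[str, float] | list[tuple[str, float]]):
        self._rows = dict(rows)
        for gene, a in self._rows.items():
            if a < 0:
                raise ValueError(f"{gene}: abundance must be >= 0")

    def __len__(self) -> int:
        return len(self._rows)

    def items(self):
        return self._rows.items()

    def __getitem__(self, gene: str) -> float:
        return self._rows[gene]


@dataclass
class CoverageStats:
    """kcat-assignment bookkeeping over a split model."""

    n_reactions: int
    n_exchange: int
    n_direct: int = 0
    n_ec: int = 0
    n_filled: int = 0

    @property
    def n_assigned(self) -> int:
        return self.n_direct + self.n_ec + self.n_filled

    @property
    def coverage_total(self) -> float:
        """Fraction of all reactions with a kcat."""
        return self.n_assigned / self.n_reactions if self.n_reactions else 0.0

    @property
    def coverage_non_exchange(self) -> float:
        """Fraction of non-exchange reactions with a kcat."""
        denom = self.n_reactions - self.n_exchange
        return self.n_assigned / denom if denom else 0.0


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def complex_mw(gpr: GPR, proteins: ProteinTable) -> float:
    """Molecular weight (kDa) of the enzyme behind an OR-free GPR.

    A single gene g contributes subunit_count(g) * monomer_mw(g); an AND
    complex sums N_j * MW_j over its distinct subunits. OR nodes are a
    contract violation: isozymes must be split into separate reactions
    before MW assignment.
    """
    if gpr.is_empty:
        raise ValueError("complex_mw: empty GPR has no enzyme")
    if gpr.contains_or():
        raise ValueError("complex_mw: GPR contains OR; split isozymes first")

    def node_mw(node) -> float:
        if isinstance(node, Gene):
            info = proteins[node.name]
            return info.subunit_count * info.monomer_mw
        assert isinstance(node, And)
        seen: dict[str, float] = {}
        for child in node.children:
            assert isinstance(child, Gene)
            info = proteins[child.name]
            seen[child.name] = info.subunit_count * info.monomer_mw
        return sum(seen.values())

    return node_mw(gpr.root)


def enzyme_mass_fraction(
    abundances: AbundanceTable,
    proteins: ProteinTable,
    model_genes: list[str] | set[str],
) -> float:
    """Enzyme mass fraction f = sum_model A_i*MW_i / sum_all A_j*MW_j.

    Monomer molecular weights are used throughout: ppm abundances are
    per-polypeptide, so the ratio is a mass fraction regardless of
    complex organisation. Abundance rows whose gene has no MW are
    dropped (logged); a zero denominator raises
    :class:`DegenerateDataError`.
    """
    model_set = set(model_genes)
    numerator = 0.0
    denominator = 0.0
    dropped = 0
    for gene, abundance in abundances.items():
        if gene not in proteins:
            dropped += 1
            continue
        mass = abundance * proteins[gene].monomer_mw
        denominator += mass
        if gene in model_set:
            numerator += mass
    if dropped:
        logger.info("enzyme_mass_fraction: dropped %d abundance rows without MW", dropped)
    if denominator == 0:
        raise DegenerateDataError("total proteome mass is zero")
    return numerator / denominator


def assign_kcat(
    model: MetabolicModel,
    records: KcatTable,
    fill_policy: str | None = "median",
) -> tuple[dict[str, tuple[float, str]], CoverageStats]:
    """Assign a kcat (1/s) to every reaction of a split model where possible.

    Priority per reaction: a reaction-id record (isozyme/reverse suffixes
    stripped when matching, so both directions inherit an undirected
    record) beats an EC-number record (max over all matching ECs, the
    maximal-kcat convention); remaining enzymatic reactions are filled
    with the median of the values assigned so far when
    ``fill_policy="median"``, or left unconstrained when ``fill_policy``
    is None. Exchange and GPR-less reactions are never assigned.

    Returns (reaction id -> (kcat, provenance), coverage statistics).
    """
    assignments: dict[str, tuple[float, str]] = {}
    stats = CoverageStats(
        n_reactions=len(model.reactions),
        n_exchange=sum(1 for r in model.reactions if r.is_exchange),
    )
    unfilled: list[str] = []
    for r in model.reactions:
        if r.is_exchange or r.gpr.is_empty:
            continue
        direct = records.reaction_max(r.id)
        if direct is not None:
            assignments[r.id] = (direct, PROVENANCE_DIRECT)
            stats.n_direct += 1
            continue
        ec = records.ec_max(r.ec_numbers)
        if ec is not None:
            assignments[r.id] = (ec, PROVENANCE_EC)
            stats.n_ec += 1
            continue
        unfilled.append(r.id)
    if fill_policy == "median" and assignments and unfilled:
        fill_value = statistics.median(v for v, _ in assignments.values())
        for rxn_id in unfilled:
            assignments[rxn_id] = (fill_value, PROVENANCE_FILLED)
            stats.n_filled += 1
    elif fill_policy not in (None, "median"):
        raise ValueError(f"unknown fill_policy {fill_policy!r}")
    return assignments, stats


# ---------------------------------------------------------------------------
# TSV I/O (header row required, UTF-8)
# ---------------------------------------------------------------------------

def read_protein_table(path: str | Path) -> ProteinTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return ProteinTable(
        [
            ProteinInfo(
                gene=row["gene"],
                monomer_mw=float(row["monomer_mw_kda"]),
                subunit_count=int(row["subunit_count"]),
            )
            for _, row in df.iterrows()
        ]
    )


def read_kcat_table(path: str | Path) -> KcatTable:
    df = pd.read_csv(path, sep="\t", dtype={"key": str, "key_type": str})
    return KcatTable(
        [
            KcatRecord(
                key=row["key"],
                kcat=float(row["kcat_per_s"]),
                key_type=row.get("key_type", "reaction"),
            )
            for _, row in df.iterrows()
        ]
    )


def read_abundance_table(path: str | Path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return AbundanceTable(
        {row["gene"]: float(row["abundance_ppm"]) for _, row in df.iterrows()}
    )


def write_protein_table(table: ProteinTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_kcat_table(table: KcatTable, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"key": r.key, "key_type": r.key_type, "kcat_per_s": r.kcat}
            for r in table.records
        ]
    ).to_csv(path, sep="\t", index=False)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    pd.DataFrame(
        [{"gene": g, "abundance_ppm": a} for g, a in table.items()]
    ).to_csv(path, sep="\t", index=False)
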