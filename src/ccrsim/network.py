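"""Crowding-annotated metabolic network model, file I/O and the reduced fixture.

A :class:`MetabolicNetwork` is a stoichiometric model in which every reaction
carries, in addition to flux bounds, a *crowding coefficient* ``a`` (hr·gDW·mmol⁻¹):
the cytoplasmic volume demand of the enzyme needed to sustain one unit of flux.
The sum ``Σ aᵢ·vᵢ`` over enzyme-catalysed reactions is capped by a dimensionless
``crowding_budget`` (default 1), turning plain flux balance analysis into
FBA with macromolecular crowding (FBAwMC).

The module also builds a calibrated five-substrate reduced network
(glucose, galactose, maltose, lactate, glycerol feeding a pyruvate/ATP core
with a high-yield, high-crowding respiratory branch and a low-yield,
low-crowding acetate-secreting fermentative branch) that reproduces the
qualitative phenomenology of carbon catabolite repression.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkValidationError",
    "FixtureCalibrationError",
    "FixtureParams",
    "load_network",
    "write_network",
    "loads_network",
    "dumps_network",
    "read_stoichiometry_tsv",
    "write_stoichiometry_tsv",
    "split_reversible",
    "merge_split_fluxes",
    "build_fixture_network",
    "SUBSTRATES",
]

SCHEMA_VERSION = 1

#: canonical substrate order used by the fixture (preference order under crowding)
SUBSTRATES = ("glucose", "maltose", "galactose", "lactate", "glycerol")

REVERSE_SUFFIX = "__rev"


class NetworkValidationError(ValueError):
    """Raised when a network violates its structural invariants.

    ``code`` is a short machine-readable tag: ``no-biomass``, ``duplicate-id``,
    ``negative-crowding``, ``bad-bounds``, ``unknown-metabolite``,
    ``bad-exchange``, ``missing-reaction``, ``bad-budget``.
    """

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


class FixtureCalibrationError(ValueError):
    """Raised when fixture parameters fail a calibration property."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    carbon_atoms: int = 0
    is_external: bool = False
    molar_mass: float | None = None  # g/mol, needed only for g/L conversions

    def __post_init__(self):
        if self.carbon_atoms < 0:
            raise NetworkValidationError(
                "negative-carbon", f"metabolite {self.id}: carbon_atoms < 0"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction with bounds (mmol·gDW⁻¹·hr⁻¹) and a crowding coefficient.

    ``kind`` is one of ``internal``, ``exchange``, ``biomass``.  Exchange
    reactions are transport pseudo-reactions connecting one external and one
    internal species; they carry no enzyme cost in the default crowding sum.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    crowding_coefficient: float = 0.0
    kind: str = "internal"

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                "bad-bounds", f"reaction {self.id}: lower_bound > upper_bound"
            )
        if self.crowding_coefficient < 0:
            raise NetworkValidationError(
                "negative-crowding",
                f"reaction {self.id}: crowding_coefficient < 0",
            )
        if self.kind not in ("internal", "exchange", "biomass"):
            raise NetworkValidationError(
                "bad-kind", f"reaction {self.id}: unknown kind {self.kind!r}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicNetwork:
    """A validated crowding-annotated network.

    ``substrate_exchange_ids`` maps substrate name → exchange reaction id
    (uptake is the positive flux direction).  ``acetate_exchange_id`` names
    the acetate exchange (secretion positive; a negative flux, or the split
    reverse reaction, is reuptake).
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str
    substrate_exchange_ids: dict[str, str] = field(default_factory=dict)
    acetate_exchange_id: str | None = None
    crowding_budget: float = 1.0
    name: str = "network"

    def __post_init__(self):
        self.validate()

    # -- indexing -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    @property
    def internal_metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_external]

    def stoichiometric_matrix(self):
        """Dense S over internal metabolites (rows) × reactions (columns)."""
        import numpy as np

        rows = {m: i for i, m in enumerate(self.internal_metabolite_ids)}
        S = np.zeros((len(rows), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                i = rows.get(met)
                if i is not None:
                    S[i, j] = coef
        return S

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise NetworkValidationError("duplicate-id", f"duplicate metabolites {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise NetworkValidationError("duplicate-id", f"duplicate reactions {dup}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in self._met_index:
                    raise NetworkValidationError(
                        "unknown-metabolite",
                        f"reaction {rxn.id} references undeclared metabolite {met}",
                    )
            if rxn.kind == "exchange":
                internal = [
                    m for m in rxn.stoichiometry if not self._met_index[m].is_external
                ]
                if len(internal) != 1:
                    raise NetworkValidationError(
                        "bad-exchange",
                        f"exchange {rxn.id} must touch exactly one internal "
                        f"metabolite, touches {internal}",
                    )
        if self.biomass_id not in self._rxn_index:
            raise NetworkValidationError(
                "no-biomass", f"biomass reaction {self.biomass_id!r} not present"
            )
        for name, ex_id in self.substrate_exchange_ids.items():
            if ex_id not in self._rxn_index:
                raise NetworkValidationError(
                    "missing-reaction", f"substrate exchange {ex_id} ({name}) missing"
                )
        if (
            self.acetate_exchange_id is not None
            and self.acetate_exchange_id not in self._rxn_index
        ):
            raise NetworkValidationError(
                "missing-reaction", f"acetate exchange {self.acetate_exchange_id} missing"
            )
        if not self.crowding_budget > 0:
            raise NetworkValidationError("bad-budget", "crowding_budget must be > 0")

    # -- convenience --------------------------------------------------------

    def with_budget(self, budget: float) -> "MetabolicNetwork":
        """Copy of the network with a different crowding budget (``inf`` = plain FBA)."""
        new = MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            biomass_id=self.biomass_id,
            substrate_exchange_ids=dict(self.substrate_exchange_ids),
            acetate_exchange_id=self.acetate_exchange_id,
            crowding_budget=budget if budget != math.inf else math.inf,
            name=self.name,
        )
        return new

    def substrate_carbon_atoms(self) -> dict[str, int]:
        """Carbon atoms per molecule for each named substrate."""
        out = {}
        for name, ex_id in self.substrate_exchange_ids.items():
            rxn = self.reaction(ex_id)
            ext = [m for m in rxn.stoichiometry if self.metabolite(m).is_external]
            out[name] = self.metabolite(ext[0]).carbon_atoms if ext else 0
        return out

    def substrate_molar_masses(self) -> dict[str, float]:
        out = {}
        for name, ex_id in self.substrate_exchange_ids.items():
            rxn = self.reaction(ex_id)
            ext = [m for m in rxn.stoichiometry if self.metabolite(m).is_external]
            mm = self.metabolite(ext[0]).molar_mass if ext else None
            if mm is None:
                raise NetworkValidationError(
                    "missing-molar-mass", f"substrate {name} has no molar mass"
                )
            out[name] = mm
        return out


def _budget_to_json(budget: float):
    return "inf" if math.isinf(budget) else budget


def _budget_from_json(value) -> float:
    return math.inf if value == "inf" else float(value)


def dumps_network(net: MetabolicNetwork) -> str:
    """Serialize to the canonical JSON form (sorted keys, 2-space indent)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": net.name,
        "crowding_budget": _budget_to_json(net.crowding_budget),
        "biomass_id": net.biomass_id,
        "substrate_exchange_ids": net.substrate_exchange_ids,
        "acetate_exchange_id": net.acetate_exchange_id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "carbon_atoms": m.carbon_atoms,
                "is_external": m.is_external,
                "molar_mass": m.molar_mass,
            }
            for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lower_bound": _budget_to_json(r.lower_bound)
                if math.isinf(r.lower_bound)
                else r.lower_bound,
                "upper_bound": "inf" if math.isinf(r.upper_bound) else r.upper_bound,
                "crowding_coefficient": r.crowding_coefficient,
                "kind": r.kind,
            }
            for r in net.reactions
        ],
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def loads_network(text: str) -> MetabolicNetwork:
    doc = json.loads(text)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise NetworkValidationError(
            "bad-schema", f"unsupported schema_version {doc.get('schema_version')!r}"
        )

    def _bound(v):
        if v == "inf":
            return math.inf
        if v == "-inf":
            return -math.inf
        return float(v)

    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            carbon_atoms=int(m.get("carbon_atoms", 0)),
            is_external=bool(m.get("is_external", False)),
            molar_mass=m.get("molar_mass"),
        )
        for m in doc["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=_bound(r.get("lower_bound", 0.0)),
            upper_bound=_bound(r.get("upper_bound", 1000.0)),
            crowding_coefficient=float(r.get("crowding_coefficient", 0.0)),
            kind=r.get("kind", "internal"),
        )
        for r in doc["reactions"]
    ]
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        biomass_id=doc["biomass_id"],
        substrate_exchange_ids=dict(doc["substrate_exchange_ids"]),
        acetate_exchange_id=doc["acetate_exchange_id"],
        crowding_budget=_budget_from_json(doc.get("crowding_budget", 1.0)),
        name=doc.get("name", "network"),
    )


def write_network(net: MetabolicNetwork, path: str | Path) -> None:
    Path(path).write_text(dumps_network(net))


def load_network(path: str | Path, format: str = "json", **kwargs) -> MetabolicNetwork:
    """Load a network from JSON (full schema) or a TSV stoichiometry table.

    The TSV form carries only topology (columns ``reaction_id``,
    ``metabolite_id``, ``coefficient``); kinds are inferred (single-metabolite
    reactions become exchanges against an implicit external pool) and bounds,
    crowding coefficients, the biomass id and substrate map come from keyword
    arguments.  JSON round-trips bit-identically through :func:`write_network`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        return loads_network(path.read_text())
    if format == "tsv":
        stoich = read_stoichiometry_tsv(path)
        return _network_from_stoichiometry(stoich, **kwargs)
    raise ValueError(f"unknown format {format!r}")


def read_stoichiometry_tsv(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a ``reaction_id \\t metabolite_id \\t coefficient`` table."""
    stoich: dict[str, dict[str, float]] = {}
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise NetworkValidationError("bad-tsv", "empty stoichiometry table")
    header = lines[0].rstrip("\n").split("\t")
    if header[:3] != ["reaction_id", "metabolite_id", "coefficient"]:
        raise NetworkValidationError("bad-tsv", f"unexpected header {header}")
    for line in lines[1:]:
        if not line.strip():
            continue
        rxn, met, coef = line.split("\t")[:3]
        stoich.setdefault(rxn, {})[met] = float(coef)
    return stoich


def write_stoichiometry_tsv(net: MetabolicNetwork, path: str | Path) -> None:
    rows = ["reaction_id\tmetabolite_id\tcoefficient"]
    for rxn in net.reactions:
        for met, coef in sorted(rxn.stoichiometry.items()):
            rows.append(f"{rxn.id}\t{met}\t{coef:g}")
    Path(path).write_text("\n".join(rows) + "\n")


def _network_from_stoichiometry(
    stoich: dict[str, dict[str, float]],
    biomass_id: str = "biomass",
    substrate_exchange_ids: dict[str, str] | None = None,
    acetate_exchange_id: str | None = None,
    crowding_coefficients: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    crowding_budget: float = 1.0,
) -> MetabolicNetwork:
    crowding_coefficients = crowding_coefficients or {}
    bounds = bounds or {}
    met_ids = sorted({m for s in stoich.values() for m in s})
    mets = [Metabolite(id=m, is_external=m.endswith("_e")) for m in met_ids]
    rxns = []
    met_index = {m.id: m for m in mets}
    for rid in sorted(stoich):
        internal = [m for m in stoich[rid] if not met_index[m].is_external]
        if rid == biomass_id:
            kind = "biomass"
        elif len(internal) == 1 and len(stoich[rid]) <= 2 and rid.startswith("EX_"):
            kind = "exchange"
        else:
            kind = "internal"
        lb, ub = bounds.get(rid, (0.0, 1000.0))
        rxns.append(
            Reaction(
                id=rid,
                stoichiometry=stoich[rid],
                lower_bound=lb,
                upper_bound=ub,
                crowding_coefficient=crowding_coefficients.get(rid, 0.0),
                kind=kind,
            )
        )
    return MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        biomass_id=biomass_id,
        substrate_exchange_ids=substrate_exchange_ids or {},
        acetate_exchange_id=acetate_exchange_id,
        crowding_budget=crowding_budget,
    )


# ---------------------------------------------------------------------------
# reversible splitting


def split_reversible(net: MetabolicNetwork) -> MetabolicNetwork:
    """Return an equivalent network where every reaction has ``lower_bound ≥ 0``.

    Each reversible reaction ``R`` becomes a forward copy (bounds
    ``[0, ub]``) plus a reversed copy ``R__rev`` with negated stoichiometry and
    bounds ``[0, -lb]``; both inherit the crowding coefficient, so the
    crowding sum charges enzyme demand regardless of flux direction.  Any
    feasible flux of the original maps to a feasible split flux with the same
    biomass value.  Already-irreversible networks are returned unchanged.
    """
    if all(r.lower_bound >= 0 for r in net.reactions):
        return net
    rxns: list[Reaction] = []
    for r in net.reactions:
        if r.lower_bound >= 0:
            rxns.append(r)
            continue
        rxns.append(replace(r, lower_bound=0.0, upper_bound=max(r.upper_bound, 0.0)))
        rxns.append(
            Reaction(
                id=r.id + REVERSE_SUFFIX,
                stoichiometry={m: -c for m, c in r.stoichiometry.items()},
                lower_bound=0.0,
                upper_bound=-r.lower_bound,
                crowding_coefficient=r.crowding_coefficient,
                kind=r.kind,
            )
        )
    return MetabolicNetwork(
        metabolites=list(net.metabolites),
        reactions=rxns,
        biomass_id=net.biomass_id,
        substrate_exchange_ids=dict(net.substrate_exchange_ids),
        acetate_exchange_id=net.acetate_exchange_id,
        crowding_budget=net.crowding_budget,
        name=net.name,
    )


def merge_split_fluxes(fluxes: dict[str, float]) -> dict[str, float]:
    """Collapse ``R`` / ``R__rev`` flux pairs back to signed net fluxes."""
    out: dict[str, float] = {}
    for rid, v in fluxes.items():
        if rid.endswith(REVERSE_SUFFIX):
            base = rid[: -len(REVERSE_SUFFIX)]
            out[base] = out.get(base, 0.0) - v
        else:
            out[rid] = out.get(rid, 0.0) + v
    return out


# ---------------------------------------------------------------------------
# reduced fixture network

# molar masses, g/mol
_MOLAR_MASS = {
    "glucose": 180.16,
    "galactose": 180.16,
    "maltose": 342.30,
    "lactate": 90.08,
    "glycerol": 92.09,
    "acetate": 60.05,
    "co2": 44.01,
}
_CARBONS = {
    "glucose": 6,
    "galactose": 6,
    "maltose": 12,
    "lactate": 3,
    "glycerol": 3,
    "acetate": 2,
    "co2": 1,
}


@dataclass(frozen=True)
class FixtureParams:
    """Parameters of the reduced five-substrate network.

    Catabolism of one molecule of substrate *s* yields ``pyruvate_yield[s]``
    pyruvate plus ``atp_yield[s]`` ATP at enzyme cost ``catabolism_crowding[s]``.
    Respiration converts pyruvate to ``oxphos_atp`` ATP (+3 CO₂) at cost
    ``oxphos_crowding``; fermentation converts pyruvate to acetate + CO₂ +
    ``fermentation_atp`` ATP at the much smaller ``fermentation_crowding``.
    Biomass consumes ``biomass_pyruvate`` pyruvate and ``biomass_atp`` ATP per
    unit growth rate at ribosomal cost ``biomass_crowding``.  All crowding
    coefficients are package constants calibrated so that (a) without a
    crowding budget the optimum respires only, and (b) crowding-limited
    growth ranks glucose ≻ maltose ≻ galactose ≻ lactate ≻ glycerol.
    """

    pyruvate_yield: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": 2.0,
            "galactose": 2.0,
            "maltose": 4.0,
            "lactate": 1.0,
            "glycerol": 1.0,
        }
    )
    atp_yield: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": 2.0,
            "galactose": 2.0,
            "maltose": 3.0,
            "lactate": 0.5,
            "glycerol": 0.5,
        }
    )
    catabolism_crowding: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": 0.020,
            "galactose": 0.120,
            "maltose": 0.030,
            "lactate": 0.100,
            "glycerol": 0.150,
        }
    )
    uptake_capacity: dict[str, float] = field(
        default_factory=lambda: {
            "glucose": 12.0,
            "galactose": 10.0,
            "maltose": 5.0,
            "lactate": 20.0,
            "glycerol": 20.0,
        }
    )
    oxphos_atp: float = 15.0
    oxphos_crowding: float = 1.2
    fermentation_atp: float = 2.0
    fermentation_crowding: float = 0.03
    acetate_oxidation_atp: float = 6.0
    acetate_oxidation_crowding: float = 0.7
    acetate_anaplerosis_atp_cost: float = 2.0
    acetate_anaplerosis_crowding: float = 0.15
    biomass_pyruvate: float = 13.0
    biomass_atp: float = 40.0
    biomass_crowding: float = 0.25
    crowding_budget: float = 1.0


def build_fixture_network(
    params: FixtureParams | None = None, calibrate: bool = True
) -> MetabolicNetwork:
    """Construct (and by default calibration-check) the reduced network.

    Raises :class:`FixtureCalibrationError` if the parameterization fails
    either calibration property: (a) the uncrowded optimum secretes no
    acetate, or (b) crowding-limited growth does not rank the substrates
    glucose ≻ maltose ≻ galactose ≻ lactate ≻ glycerol.
    """
    p = params or FixtureParams()
    mets = [
        Metabolite("pyr", "pyruvate", carbon_atoms=3),
        Metabolite("atp", "ATP", carbon_atoms=0),
        Metabolite("ac", "acetate (intracellular)", carbon_atoms=2),
        Metabolite("co2", "CO2 (intracellular)", carbon_atoms=1),
        Metabolite(
            "ac_e", "acetate (medium)", carbon_atoms=2, is_external=True,
            molar_mass=_MOLAR_MASS["acetate"],
        ),
        Metabolite("co2_e", "CO2 (offgas)", carbon_atoms=1, is_external=True,
                   molar_mass=_MOLAR_MASS["co2"]),
    ]
    rxns: list[Reaction] = []
    substrate_ex: dict[str, str] = {}
    for s in SUBSTRATES:
        mets.append(
            Metabolite(f"{s[:3]}_e", f"{s} (medium)", carbon_atoms=_CARBONS[s],
                       is_external=True, molar_mass=_MOLAR_MASS[s])
        )
        mets.append(Metabolite(f"{s[:3]}_c", f"{s} (cytoplasm)", carbon_atoms=_CARBONS[s]))
        ex_id = f"EX_{s[:3]}"
        substrate_ex[s] = ex_id
        rxns.append(
            Reaction(ex_id, {f"{s[:3]}_e": -1.0, f"{s[:3]}_c": 1.0},
                     0.0, p.uptake_capacity[s], 0.0, "exchange")
        )
        rxns.append(
            Reaction(
                f"cat_{s[:3]}",
                {f"{s[:3]}_c": -1.0, "pyr": p.pyruvate_yield[s], "atp": p.atp_yield[s]},
                0.0, math.inf, p.catabolism_crowding[s], "internal",
            )
        )
    rxns += [
        Reaction("oxphos", {"pyr": -1.0, "atp": p.oxphos_atp, "co2": 3.0},
                 0.0, math.inf, p.oxphos_crowding, "internal"),
        Reaction("ferm", {"pyr": -1.0, "ac": 1.0, "co2": 1.0, "atp": p.fermentation_atp},
                 0.0, math.inf, p.fermentation_crowding, "internal"),
        Reaction("ac_ox", {"ac": -1.0, "atp": p.acetate_oxidation_atp, "co2": 2.0},
                 0.0, math.inf, p.acetate_oxidation_crowding, "internal"),
        # gluconeogenic/anaplerotic route allowing slow growth on acetate
        Reaction(
            "ac_ana",
            {"ac": -2.0, "atp": -p.acetate_anaplerosis_atp_cost, "pyr": 1.0, "co2": 1.0},
            0.0, math.inf, p.acetate_anaplerosis_crowding, "internal",
        ),
        Reaction("biomass", {"pyr": -p.biomass_pyruvate, "atp": -p.biomass_atp},
                 0.0, math.inf, p.biomass_crowding, "biomass"),
        # secretion positive; reuptake (negative direction) bounded by the simulators
        Reaction("EX_ac", {"ac": -1.0, "ac_e": 1.0}, -1000.0, 1000.0, 0.0, "exchange"),
        Reaction("EX_co2", {"co2": -1.0, "co2_e": 1.0}, 0.0, math.inf, 0.0, "exchange"),
    ]
    net = MetabolicNetwork(
        metabolites=mets,
        reactions=rxns,
        biomass_id="biomass",
        substrate_exchange_ids=substrate_ex,
        acetate_exchange_id="EX_ac",
        crowding_budget=p.crowding_budget,
        name="ccr-reduced-fixture",
    )
    if calibrate:
        report = calibration_report(net)
        failures = [k for k, ok in report.items() if not ok]
        if failures:
            raise FixtureCalibrationError(
                f"fixture-calibration: failed {failures}; report={report}"
            )
    return net


def calibration_report(net: MetabolicNetwork) -> dict[str, bool]:
    """Run the two fixture calibration checks; returns {check: passed}.

    (a) uncrowded (budget = ∞) biomass optimum secretes no acetate — the
        high-yield respiratory branch dominates when enzyme space is free;
    (b) crowding-limited maximal growth (uptake unbounded, budget active)
        is strictly ordered glucose > maltose > galactose > lactate > glycerol.
    """
    from .fba import FluxProblem, solve_fbawmc

    split = split_reversible(net)
    caps = {s: net.reaction(ex).upper_bound for s, ex in net.substrate_exchange_ids.items()}

    uncrowded = solve_fbawmc(
        FluxProblem(network=split, uptake_capacity=caps, crowding_budget=math.inf)
    )
    ac_net = uncrowded.fluxes.get(net.acetate_exchange_id, 0.0) - uncrowded.fluxes.get(
        net.acetate_exchange_id + REVERSE_SUFFIX, 0.0
    )
    check_a = uncrowded.status == "optimal" and ac_net <= 1e-9

    mu = {}
    for s in net.substrate_exchange_ids:
        one = {k: (1e6 if k == s else 0.0) for k in net.substrate_exchange_ids}
        sol = solve_fbawmc(FluxProblem(network=split, uptake_capacity=one))
        mu[s] = sol.growth_rate if sol.status == "optimal" else 0.0
    order = ["glucose", "maltose", "galactose", "lactate", "glycerol"]
    ranked = [s for s in order if s in mu]
    check_b = all(mu[a] > mu[b] + 1e-9 for a, b in zip(ranked, ranked[1:]))
    return {"uncrowded-no-acetate": check_a, "substrate-ranking": check_b}
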