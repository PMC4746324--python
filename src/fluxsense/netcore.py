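"""Domain types for compartmentalized metabolic networks.

A network is a set of metabolites placed in compartments and a set of
reactions over them; the stoichiometric matrix S (metabolites x reactions)
is assembled from it. Coefficients are stored as exact rationals so that
steady-state checks (S v = 0) do not accumulate parsing drift; they are
emitted as decimals on disk.

The on-disk TSV dialect is one reaction per line with columns
``id  name  equation  lb  ub  ec  pathway  genes`` where the equation uses
compartment tags in square brackets, e.g. ``2 g3p[h] + nadh[h] -> glyc[c]``.
Reversibility is encoded purely through the sign of the lower bound; the
arrow (``->`` vs ``<->``) is rendered from it when writing. A minimal SBML
Level 3 reader/writer (species, reactions, bounds, objective) is provided
for interchange with constraint-based tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "StoichMatrix",
    "Condition",
    "NetworkError",
    "ParseError",
    "IntegrityError",
    "load_network",
    "write_network",
    "build_stoich_matrix",
    "find_dead_ends",
    "set_condition_bounds",
    "parse_equation",
    "format_equation",
    "DEFAULT_COMPARTMENTS",
]

#: Default compartment vocabulary: cytosol, chloroplast, mitochondrion,
#: nucleus, endoplasmic reticulum, Golgi, flagellum, eyespot, glyoxysome,
#: extracellular. The vocabulary is open; this list documents the ten
#: compartments a fully compartmentalized algal model distinguishes.
DEFAULT_COMPARTMENTS = ["c", "h", "m", "n", "r", "g", "f", "s", "x", "e"]

#: Default magnitude used for "unbounded" finite flux bounds, mmol/gDW/h.
DEFAULT_BOUND = 1000.0


class NetworkError(ValueError):
    """Base class for network construction and validation failures."""


class ParseError(NetworkError):
    """A file could not be parsed in the named dialect."""


class IntegrityError(NetworkError):
    """A structurally parseable network violates a referential invariant."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species located in one compartment.

    ``group_counts`` optionally carries the structural-group decomposition
    used by the group-contribution Gibbs energy estimate.
    """

    id: str
    compartment: str
    name: str = ""
    formula: str | None = None
    group_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("metabolite id must be non-empty")
        if self.group_counts is not None:
            for g, c in self.group_counts.items():
                if c < 0:
                    raise NetworkError(f"negative group count for {g!r} in {self.id!r}")

    @property
    def species_name(self) -> str:
        """Compartment-agnostic species name (id with the tag stripped)."""
        return strip_compartment(self.id)


def strip_compartment(met_id: str) -> str:
    """``"glc[c]" -> "glc"``; ids without a tag pass through unchanged."""
    m = re.fullmatch(r"(.+)\[([^\[\]]+)\]", met_id)
    return m.group(1) if m else met_id


def compartment_of(met_id: str) -> str | None:
    m = re.fullmatch(r"(.+)\[([^\[\]]+)\]", met_id)
    return m.group(2) if m else None


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds in mmol/gDW/h.

    Negative coefficients are consumed, positive produced. ``reversible``
    is derived from the lower bound and never stored independently.
    Exchange reactions (single species, boundary import/export) are marked
    with ``is_exchange``.
    """

    id: str
    stoich: dict[str, Fraction]
    lb: float = 0.0
    ub: float = DEFAULT_BOUND
    name: str = ""
    ec: str | None = None
    pathway: str | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stoich:
            raise NetworkError(f"reaction {self.id!r} has empty stoichiometry")
        self.stoich = {m: Fraction(c) for m, c in self.stoich.items() if Fraction(c) != 0}
        if not self.stoich:
            raise NetworkError(f"reaction {self.id!r} has all-zero stoichiometry")
        if self.lb > self.ub:
            raise NetworkError(f"reaction {self.id!r}: lb {self.lb} > ub {self.ub}")

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def is_exchange(self) -> bool:
        return len(self.stoich) == 1

    def reversed(self) -> "Reaction":
        """The same conversion written in the opposite orientation."""
        return Reaction(
            id=self.id,
            stoich={m: -c for m, c in self.stoich.items()},
            lb=-self.ub,
            ub=-self.lb,
            name=self.name,
            ec=self.ec,
            pathway=self.pathway,
            gene_ids=list(self.gene_ids),
        )


@dataclass(frozen=True)
class Condition:
    """One environmental condition of the CO2 scan.

    ``co2_flux_ub`` caps the CO2 exchange in mmol/gDW/h; ``light_flux``
    pins the photon exchange in mE/gDW/h (the standard autotrophic
    setting fixes light and varies only CO2).
    """

    name: str
    co2_percent: float
    co2_flux_ub: float
    light_flux: float

    def __post_init__(self) -> None:
        if self.co2_percent < 0 or self.co2_flux_ub < 0 or self.light_flux < 0:
            raise NetworkError(f"condition {self.name!r}: negative parameter")


class MetabolicNetwork:
    """Compartments, metabolites, reactions and a biomass objective."""

    def __init__(
        self,
        compartments: Iterable[str],
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: str,
    ) -> None:
        self.compartments = list(dict.fromkeys(compartments))
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise IntegrityError(f"duplicate metabolite id {met.id!r}")
            if met.compartment not in self.compartments:
                raise IntegrityError(
                    f"metabolite {met.id!r} in undeclared compartment {met.compartment!r}"
                )
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise IntegrityError(f"duplicate reaction id {rxn.id!r}")
            dangling = sorted(m for m in rxn.stoich if m not in self.metabolites)
            if dangling:
                raise IntegrityError(
                    f"reaction {rxn.id!r} references undeclared metabolite(s): "
                    + ", ".join(repr(m) for m in dangling)
                )
            self.reactions[rxn.id] = rxn
        if objective_id not in self.reactions:
            raise IntegrityError(f"objective reaction {objective_id!r} not in network")
        self.objective_id = objective_id

    # -- convenience -------------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.metabolites)

    @property
    def n(self) -> int:
        return len(self.reactions)

    def species_names(self) -> set[str]:
        """All compartment-agnostic species names present in the network."""
        return {met.species_name for met in self.metabolites.values()}

    def species_compartments(self, name: str) -> set[str]:
        """Compartments in which species ``name`` occurs."""
        return {
            met.compartment
            for met in self.metabolites.values()
            if met.species_name == name
        }

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            self.compartments,
            self.metabolites.values(),
            [replace(r, stoich=dict(r.stoich), gene_ids=list(r.gene_ids))
             for r in self.reactions.values()],
            self.objective_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        return (
            self.compartments == other.compartments
            and self.metabolites == other.metabolites
            and self.objective_id == other.objective_id
            and self.reactions.keys() == other.reactions.keys()
            and all(
                _reactions_equal(self.reactions[k], other.reactions[k])
                for k in self.reactions
            )
        )


def _reactions_equal(a: Reaction, b: Reaction) -> bool:
    return (
        a.id == b.id
        and a.stoich == b.stoich
        and a.lb == b.lb
        and a.ub == b.ub
        and a.name == b.name
        and (a.ec or None) == (b.ec or None)
        and (a.pathway or None) == (b.pathway or None)
        and a.gene_ids == b.gene_ids
    )


@dataclass
class StoichMatrix:
    """Sparse m x n stoichiometric matrix with exact rational entries."""

    entries: dict[tuple[int, int], Fraction]
    row_index: dict[str, int]
    col_index: dict[str, int]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_index), len(self.col_index))

    @property
    def nnz(self) -> int:
        return len(self.entries)

    def to_sparse(self) -> sparse.csr_matrix:
        """Float CSR view for linear algebra / LP assembly."""
        m, n = self.shape
        if not self.entries:
            return sparse.csr_matrix((m, n))
        rows, cols, vals = zip(*((i, j, float(v)) for (i, j), v in self.entries.items()))
        return sparse.csr_matrix((vals, (rows, cols)), shape=(m, n))

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    def entry(self, met_id: str, rxn_id: str) -> Fraction:
        return self.entries.get((self.row_index[met_id], self.col_index[rxn_id]), Fraction(0))


# ---------------------------------------------------------------------------
# equation strings

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?|\d+/\d+)\s+)?(\S.*?)\s*$")


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``"2 A[c] + B[c] -> C[m]"`` into (stoich, reversible-arrow).

    Either side may be empty (exchange reactions). Coefficients may be
    integers, decimals or fractions; default 1.
    """
    if "<->" in text:
        lhs, rhs = text.split("<->", 1)
        rev = True
    elif "->" in text:
        lhs, rhs = text.split("->", 1)
        rev = False
    else:
        raise ParseError(f"no reaction arrow in equation {text!r}")
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            m = _TERM_RE.match(term)
            if not m or not m.group(2):
                raise ParseError(f"malformed term {term!r} in equation {text!r}")
            coeff = Fraction(m.group(1)) if m.group(1) else Fraction(1)
            met = m.group(2).strip()
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff

    add_side(lhs, -1)
    add_side(rhs, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ParseError(f"equation {text!r} has empty or cancelling stoichiometry")
    return stoich, rev


def _fmt_coeff(c: Fraction) -> str:
    c = abs(c)
    if c == 1:
        return ""
    if c.denominator == 1:
        return f"{c.numerator} "
    return f"{float(c):g} "


def format_equation(stoich: Mapping[str, Fraction], reversible: bool) -> str:
    subs = sorted((m for m, c in stoich.items() if c < 0))
    prods = sorted((m for m, c in stoich.items() if c > 0))
    lhs = " + ".join(f"{_fmt_coeff(stoich[m])}{m}" for m in subs)
    rhs = " + ".join(f"{_fmt_coeff(stoich[m])}{m}" for m in prods)
    arrow = "<->" if reversible else "->"
    return f"{lhs} {arrow} {rhs}".strip()


# ---------------------------------------------------------------------------
# TSV dialect

_TSV_COLUMNS = ["id", "name", "equation", "lb", "ub", "ec", "pathway", "genes"]


def _network_from_tsv(path: Path) -> MetabolicNetwork:
    reactions: list[Reaction] = []
    met_ids: dict[str, None] = {}
    objective_id: str | None = None
    compartments: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("objective:"):
                    objective_id = body.split(":", 1)[1].strip()
                elif body.startswith("compartments:"):
                    compartments = body.split(":", 1)[1].split()
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 tab-separated columns")
            parts += [""] * (len(_TSV_COLUMNS) - len(parts))
            rid, name, equation, lb_s, ub_s, ec, pathway, genes = parts[:8]
            try:
                stoich, _ = parse_equation(equation)
                lb, ub = float(lb_s), float(ub_s)
            except (ParseError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            reactions.append(
                Reaction(
                    id=rid, stoich=stoich, lb=lb, ub=ub, name=name,
                    ec=ec or None, pathway=pathway or None,
                    gene_ids=genes.split(";") if genes else [],
                )
            )
            for m in stoich:
                met_ids.setdefault(m, None)
    if objective_id is None:
        raise ParseError(f"{path}: missing '# objective: <reaction id>' header")
    mets = []
    for mid in met_ids:
        comp = compartment_of(mid)
        if comp is None:
            raise ParseError(f"{path}: metabolite {mid!r} lacks a [compartment] tag")
        mets.append(Metabolite(id=mid, compartment=comp))
    if not compartments:
        compartments = sorted({m.compartment for m in mets})
    return MetabolicNetwork(compartments, mets, reactions, objective_id)


def _network_to_tsv(net: MetabolicNetwork, path: Path) -> None:
    lines = [
        "# compartments: " + " ".join(net.compartments),
        f"# objective: {net.objective_id}",
        "# " + "\t".join(_TSV_COLUMNS),
    ]
    for rid in sorted(net.reactions):
        r = net.reactions[rid]
        lines.append(
            "\t".join(
                [
                    r.id,
                    r.name,
                    format_equation(r.stoich, r.reversible),
                    f"{r.lb:g}",
                    f"{r.ub:g}",
                    r.ec or "",
                    r.pathway or "",
                    ";".join(r.gene_ids),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# minimal SBML L3

def _sbml_safe(sid: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]", "__", sid)


def _network_to_sbml(net: MetabolicNetwork, path: Path) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel("metabolic_network")
    id_map: dict[str, str] = {}
    for comp_id in net.compartments:
        comp = model.createCompartment()
        comp.setId(_sbml_safe("comp_" + comp_id))
        comp.setName(comp_id)
        comp.setConstant(True)
    for met in net.metabolites.values():
        sp = model.createSpecies()
        sid = "M_" + _sbml_safe(met.id)
        id_map[met.id] = sid
        sp.setId(sid)
        sp.setName(met.id)
        sp.setCompartment(_sbml_safe("comp_" + met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
    for rid in sorted(net.reactions):
        r = net.reactions[rid]
        rx = model.createReaction()
        rx.setId("R_" + _sbml_safe(r.id))
        if r.name:
            rx.setName(r.name)
        rx.setReversible(r.reversible)
        for m, c in sorted(r.stoich.items()):
            ref = rx.createReactant() if c < 0 else rx.createProduct()
            ref.setSpecies(id_map[m])
            ref.setStoichiometry(abs(float(c)))
            ref.setConstant(True)
        # bounds via local parameters on a kinetic law (minimal core-only encoding)
        kl = rx.createKineticLaw()
        kl.setMath(libsbml.parseL3Formula("0"))
        for pname, val in (("LOWER_BOUND", r.lb), ("UPPER_BOUND", r.ub)):
            p = kl.createLocalParameter()
            p.setId(pname)
            p.setValue(val)
        meta = {"pathway": r.pathway or "", "ec": r.ec or "",
                "genes": ";".join(r.gene_ids), "orig_id": r.id}
        rx.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'>"
            + "".join(f"<p>{k}: {v}</p>" for k, v in meta.items())
            + "</body>"
        )
    obj = model.createParameter()
    obj.setId("OBJECTIVE_REACTION")
    obj.setName(net.objective_id)
    obj.setConstant(True)
    obj.setValue(0.0)
    libsbml.writeSBMLToFile(doc, str(path))


def _sbml_notes_dict(notes: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for m in re.finditer(r"<p>\s*([^:<]+):\s*([^<]*)</p>", notes or ""):
        out[m.group(1).strip()] = m.group(2).strip()
    return out


def _network_from_sbml(path: Path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ParseError(f"{path}: SBML parse error: "
                         f"{doc.getError(0).getMessage()}")
    model = doc.getModel()
    if model is None:
        raise ParseError(f"{path}: no model in SBML document")
    comp_names = {}
    for i in range(model.getNumCompartments()):
        c = model.getCompartment(i)
        comp_names[c.getId()] = c.getName() or c.getId()
    mets = []
    sid_to_id = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        mid = sp.getName() or sp.getId()
        sid_to_id[sp.getId()] = mid
        mets.append(Metabolite(id=mid, compartment=comp_names[sp.getCompartment()]))
    reactions = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        notes = _sbml_notes_dict(rx.getNotesString() if rx.isSetNotes() else "")
        rid = notes.get("orig_id") or rx.getId().removeprefix("R_")
        stoich: dict[str, Fraction] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[sid_to_id[ref.getSpecies()]] = stoich.get(
                sid_to_id[ref.getSpecies()], Fraction(0)) - Fraction(ref.getStoichiometry()).limit_denominator(10**6)
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[sid_to_id[ref.getSpecies()]] = stoich.get(
                sid_to_id[ref.getSpecies()], Fraction(0)) + Fraction(ref.getStoichiometry()).limit_denominator(10**6)
        lb, ub = 0.0, DEFAULT_BOUND
        if rx.isSetKineticLaw():
            kl = rx.getKineticLaw()
            for j in range(kl.getNumLocalParameters()):
                p = kl.getLocalParameter(j)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
        reactions.append(
            Reaction(
                id=rid, stoich=stoich, lb=lb, ub=ub,
                name=rx.getName() or "",
                ec=notes.get("ec") or None,
                pathway=notes.get("pathway") or None,
                gene_ids=notes.get("genes", "").split(";") if notes.get("genes") else [],
            )
        )
    objective_id = None
    for i in range(model.getNumParameters()):
        p = model.getParameter(i)
        if p.getId() == "OBJECTIVE_REACTION":
            objective_id = p.getName()
    if objective_id is None:
        raise ParseError(f"{path}: no OBJECTIVE_REACTION parameter")
    compartments = list(comp_names.values())
    return MetabolicNetwork(compartments, mets, reactions, objective_id)


# ---------------------------------------------------------------------------
# public I/O

def load_network(path: str | Path, format: str = "tsv") -> MetabolicNetwork:
    """Read a network from ``path`` in the named dialect (``tsv``/``sbml``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _network_from_tsv(path)
    if format == "sbml":
        return _network_from_sbml(path)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: MetabolicNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write ``net`` so that :func:`load_network` round-trips it."""
    if not net.reactions:
        raise NetworkError("refusing to write a network with no reactions")
    path = Path(path)
    if format == "tsv":
        _network_to_tsv(net, path)
    elif format == "sbml":
        _network_to_sbml(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# matrix assembly and structural queries

def build_stoich_matrix(net: MetabolicNetwork) -> StoichMatrix:
    """Assemble S: entry (i, j) is the coefficient of metabolite i in reaction j."""
    row_index = {mid: i for i, mid in enumerate(sorted(net.metabolites))}
    col_index = {rid: j for j, rid in enumerate(sorted(net.reactions))}
    entries: dict[tuple[int, int], Fraction] = {}
    for rid, rxn in net.reactions.items():
        j = col_index[rid]
        for mid, coeff in rxn.stoich.items():
            entries[(row_index[mid], j)] = coeff
    return StoichMatrix(entries=entries, row_index=row_index, col_index=col_index)


def find_dead_ends(net: MetabolicNetwork) -> list[str]:
    """Metabolites that can only be produced or only consumed.

    A reversible reaction supplies both roles to every participating
    species. Returned sorted lexicographically.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in net.reactions.values():
        for mid, coeff in rxn.stoich.items():
            if rxn.reversible:
                producible.add(mid)
                consumable.add(mid)
            elif coeff > 0:
                producible.add(mid)
            else:
                consumable.add(mid)
    dead = [
        mid
        for mid in net.metabolites
        if (mid in producible) != (mid in consumable)
    ]
    return sorted(dead)


def set_condition_bounds(
    net: MetabolicNetwork,
    cond: Condition,
    co2_exchange_id: str = "EX_co2",
    photon_exchange_id: str = "EX_photon",
) -> MetabolicNetwork:
    """Return a copy of ``net`` with the condition's exchange bounds applied.

    The CO2 exchange upper bound is capped at ``cond.co2_flux_ub``; the
    photon exchange is pinned (lb = ub = ``cond.light_flux``). No other
    reaction is touched.
    """
    for rid in (co2_exchange_id, photon_exchange_id):
        if rid not in net.reactions:
            raise NetworkError(
                f"designated exchange reaction {rid!r} missing from network"
            )
    out = net.copy()
    co2 = out.reactions[co2_exchange_id]
    co2.ub = cond.co2_flux_ub
    co2.lb = min(co2.lb, co2.ub)
    photon = out.reactions[photon_exchange_id]
    photon.lb = cond.light_flux
    photon.ub = cond.light_flux
    return out
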