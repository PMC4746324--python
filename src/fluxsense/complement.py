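"""Network complementation from homology hits and a reaction catalog.

The base model is extended in five documented stages:

1. associate — homology hits carrying EC numbers pull candidate reactions
   out of a KEGG-style catalog;
2. dedupe — candidates whose stoichiometry already exists in the base
   model (orientation-insensitive for reversibles) are dropped;
3. reactant filter — only candidates all of whose species are already
   known to the base model survive (generic names are blacklisted);
4. compartmentalize — each survivor is placed in every compartment where
   all its species exist;
5. gap fill — dead ends introduced by the new reactions are connected
   through the shortest catalog path, with a sink/exchange fallback.

Every candidate carries an ordered verdict trail, and the report records
stage counts (non-increasing through dedupe and the reactant filter) so
reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .netcore import (
    DEFAULT_BOUND,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    find_dead_ends,
    parse_equation,
    strip_compartment,
)

__all__ = [
    "HomologyHit",
    "CatalogReaction",
    "ReactionCandidate",
    "ComplementReport",
    "load_homology_hits",
    "load_catalog",
    "associate_reactions",
    "dedupe_against_base",
    "filter_known_reactants",
    "compartmentalize",
    "gap_fill",
    "complement_network",
    "DEFAULT_EVALUE_MAX",
]

DEFAULT_EVALUE_MAX = 1e-10

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass(frozen=True)
class HomologyHit:
    """One protein-to-EC homology assignment from a BLAST-style hit table."""

    protein_id: str
    ec: str
    bitscore: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if not _EC_RE.match(self.ec):
            raise ValueError(f"malformed EC number {self.ec!r}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.protein_id!r}")


@dataclass(frozen=True)
class CatalogReaction:
    """A catalog entry: EC cross-reference plus a generic-compartment equation."""

    catalog_id: str
    ec: str
    equation: str
    pathway: str | None = None

    @property
    def stoich(self) -> dict[str, Fraction]:
        s, _ = parse_equation(self.equation)
        return s


@dataclass
class ReactionCandidate:
    """A catalog reaction under evaluation, with its ordered filter trail."""

    catalog_id: str
    ec: str
    stoich: dict[str, Fraction]
    pathway: str | None = None
    verdicts: dict[str, str] = field(default_factory=dict)

    def record(self, filter_name: str, verdict: str) -> None:
        self.verdicts[filter_name] = verdict

    @property
    def passing(self) -> bool:
        return all(v == "pass" for v in self.verdicts.values())


@dataclass
class ComplementReport:
    """Stage counts and provenance of every reaction added to the network."""

    counts: dict[str, int] = field(default_factory=dict)
    added_reactions: list[str] = field(default_factory=list)
    unmatched_ecs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "added_reactions": list(self.added_reactions),
            "unmatched_ecs": list(self.unmatched_ecs),
        }


# ---------------------------------------------------------------------------
# input tables

def load_homology_hits(path: str | Path, evalue_max: float | None = None) -> list[HomologyHit]:
    """Read hits from an outfmt-6-style table with a trailing EC column,
    or from a two-column ``protein<TAB>ec`` map.
    """
    hits: list[HomologyHit] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 13:  # qseqid..bitscore + ec
                protein, ec = parts[0], parts[12]
                evalue, bitscore = float(parts[10]), float(parts[11])
            elif len(parts) == 2:
                protein, ec = parts
                evalue, bitscore = 0.0, 0.0
            else:
                raise ValueError(f"unrecognized homology table row: {line!r}")
            hit = HomologyHit(protein_id=protein, ec=ec, evalue=evalue, bitscore=bitscore)
            if evalue_max is None or hit.evalue <= evalue_max:
                hits.append(hit)
    return hits


def load_catalog(path: str | Path) -> list[CatalogReaction]:
    """Read a TSV of ``catalog_id  ec  equation  pathway``."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    return [
        CatalogReaction(
            catalog_id=row.catalog_id,
            ec=row.ec,
            equation=row.equation,
            pathway=row.pathway or None,
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# stage 1: associate

def associate_reactions(
    hits: list[HomologyHit],
    catalog: list[CatalogReaction],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    pathway_blacklist: frozenset[str] = frozenset(),
) -> tuple[list[ReactionCandidate], list[str]]:
    """One candidate per catalog reaction reachable from any hit EC.

    Hits failing the e-value cutoff are ignored; hit ECs absent from the
    catalog are recorded as unmatched, never raised. Candidates are
    deduplicated by catalog_id and returned in catalog_id order.
    """
    by_ec: dict[str, list[CatalogReaction]] = {}
    for cat in catalog:
        by_ec.setdefault(cat.ec, []).append(cat)
    seen: dict[str, ReactionCandidate] = {}
    unmatched: list[str] = []
    for hit in hits:
        if hit.evalue > evalue_max:
            continue
        if hit.ec not in by_ec:
            if hit.ec not in unmatched:
                unmatched.append(hit.ec)
            continue
        for cat in by_ec[hit.ec]:
            if cat.catalog_id in seen:
                continue
            cand = ReactionCandidate(
                catalog_id=cat.catalog_id,
                ec=cat.ec,
                stoich=cat.stoich,
                pathway=cat.pathway,
            )
            if cat.pathway and cat.pathway in pathway_blacklist:
                cand.record("pathway_filter", f"fail: blacklisted pathway {cat.pathway!r}")
            else:
                cand.record("pathway_filter", "pass")
            seen[cat.catalog_id] = cand
    ordered = [seen[k] for k in sorted(seen)]
    return [c for c in ordered if c.passing], sorted(unmatched)


# ---------------------------------------------------------------------------
# stage 2: dedupe against the base model

def _canonical_stoich(stoich: dict[str, Fraction]) -> tuple:
    """Species-name-keyed, order-independent form of a stoichiometry."""
    merged: dict[str, Fraction] = {}
    for mid, c in stoich.items():
        name = strip_compartment(mid)
        merged[name] = merged.get(name, Fraction(0)) + c
    return tuple(sorted((k, v) for k, v in merged.items() if v != 0))


def dedupe_against_base(
    cands: list[ReactionCandidate], base: MetabolicNetwork
) -> list[ReactionCandidate]:
    """Drop candidates whose stoichiometry already exists in the base model.

    Comparison is compartment-agnostic; for reversible base reactions both
    orientations count as existing.
    """
    existing: set[tuple] = set()
    for rxn in base.reactions.values():
        existing.add(_canonical_stoich(rxn.stoich))
        if rxn.reversible:
            existing.add(_canonical_stoich({m: -c for m, c in rxn.stoich.items()}))
    out = []
    for cand in cands:
        if _canonical_stoich(cand.stoich) in existing:
            cand.record("dedupe", "fail: duplicates an existing base reaction")
        else:
            cand.record("dedupe", "pass")
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# stage 3: reactant filter

#: Generic KEGG species names that can never be matched to model species.
DEFAULT_GENERIC_BLACKLIST = frozenset(
    {"an_alcohol", "an_aldehyde", "a_lipid", "a_carbohydrate", "a_protein"}
)


def filter_known_reactants(
    cands: list[ReactionCandidate],
    base: MetabolicNetwork,
    generic_blacklist: frozenset[str] = DEFAULT_GENERIC_BLACKLIST,
) -> list[ReactionCandidate]:
    """Keep candidates all of whose species names already occur in the base."""
    known = base.species_names()
    out = []
    for cand in cands:
        names = {strip_compartment(m) for m in cand.stoich}
        generic = sorted(names & generic_blacklist)
        novel = sorted(n for n in names if n not in known)
        if generic:
            cand.record("reactant_filter", f"fail: generic species {', '.join(generic)}")
        elif novel:
            cand.record("reactant_filter", f"fail: unknown species {', '.join(novel)}")
        else:
            cand.record("reactant_filter", "pass")
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# stage 4: compartmentalize

def compartmentalize(
    cands: list[ReactionCandidate],
    base: MetabolicNetwork,
    single_placement: bool = False,
    compartment_preference: tuple[str, ...] = ("c", "h", "m", "n", "r", "g", "f", "s", "x", "e"),
) -> list[Reaction]:
    """Place each candidate in every compartment where all its species live.

    With ``single_placement`` the first viable compartment in preference
    order wins. Reaction ids are suffixed ``__<compartment>``.
    """
    out: list[Reaction] = []
    for cand in cands:
        names = {strip_compartment(m) for m in cand.stoich}
        viable = None
        for name in names:
            comps = base.species_compartments(name)
            viable = comps if viable is None else viable & comps
        viable = sorted(viable or set())
        if not viable:
            cand.record("compartmentalize", "fail: no viable compartment")
            continue
        if single_placement:
            pref = [c for c in compartment_preference if c in viable]
            viable = [pref[0]] if pref else [viable[0]]
        cand.record("compartmentalize", f"pass: {','.join(viable)}")
        for comp in viable:
            out.append(
                Reaction(
                    id=f"{cand.catalog_id}__{comp}",
                    stoich={
                        f"{strip_compartment(m)}[{comp}]": c
                        for m, c in cand.stoich.items()
                    },
                    lb=0.0,
                    ub=DEFAULT_BOUND,
                    ec=cand.ec,
                    pathway=cand.pathway,
                )
            )
    return out


# ---------------------------------------------------------------------------
# stage 5: gap filling

def _roles(net: MetabolicNetwork, mid: str) -> tuple[bool, bool]:
    """(producible, consumable) for one metabolite."""
    prod = cons = False
    for rxn in net.reactions.values():
        c = rxn.stoich.get(mid)
        if c is None:
            continue
        if rxn.reversible or c > 0:
            prod = True
        if rxn.reversible or c < 0:
            cons = True
    return prod, cons


def _add_metabolites_for(net: MetabolicNetwork, stoich: dict[str, Fraction]) -> None:
    for mid in stoich:
        if mid not in net.metabolites:
            from .netcore import compartment_of

            comp = compartment_of(mid)
            net.metabolites[mid] = Metabolite(id=mid, compartment=comp or "c")


def gap_fill(
    net: MetabolicNetwork,
    catalog: list[CatalogReaction],
    max_depth: int = 3,
    focus_metabolites: set[str] | None = None,
) -> tuple[MetabolicNetwork, ComplementReport]:
    """Resolve dead ends via shortest catalog paths, else sink reactions.

    For each dead-end metabolite the catalog (restricted to species already
    in the network) is searched breadth-first for the missing role
    (consumer for an orphan product, producer for an orphan substrate).
    Catalog reactions are placed in the dead end's own compartment and may
    themselves introduce dead ends, which are resolved recursively up to
    ``max_depth`` levels; beyond that, a reversible exchange ``SK_<met>``
    guarantees resolution. Ties break lexicographically by catalog_id.
    """
    net = net.copy()
    report = ComplementReport()
    known = net.species_names()
    usable = sorted(
        (c for c in catalog
         if all(strip_compartment(m) in known for m in c.stoich)),
        key=lambda c: c.catalog_id,
    )

    def place(cat: CatalogReaction, comp: str) -> Reaction | None:
        stoich = {f"{strip_compartment(m)}[{comp}]": c for m, c in cat.stoich.items()}
        rid = f"{cat.catalog_id}__gf_{comp}"
        if rid in net.reactions:
            return None
        if not all(m in net.metabolites for m in stoich):
            return None
        return Reaction(id=rid, stoich=stoich, lb=0.0, ub=DEFAULT_BOUND,
                        ec=cat.ec, pathway=cat.pathway)

    def add_sink(mid: str) -> None:
        rid = f"SK_{mid}"
        if rid in net.reactions:
            return
        net.reactions[rid] = Reaction(
            id=rid, stoich={mid: Fraction(-1)}, lb=-DEFAULT_BOUND, ub=DEFAULT_BOUND,
            name=f"gap-filling exchange for {mid}",
        )
        report.added_reactions.append(rid)

    def resolve(mid: str, depth: int) -> None:
        prod, cons = _roles(net, mid)
        if prod == cons:
            return
        if depth <= 0:
            add_sink(mid)
            return
        need_consumer = prod and not cons
        comp = net.metabolites[mid].compartment
        name = strip_compartment(mid)
        for cat in usable:
            coeff = {strip_compartment(m): c for m, c in cat.stoich.items()}.get(name)
            if coeff is None:
                continue
            if need_consumer and coeff >= 0:
                continue
            if not need_consumer and coeff <= 0:
                continue
            rxn = place(cat, comp)
            if rxn is None:
                continue
            net.reactions[rxn.id] = rxn
            report.added_reactions.append(rxn.id)
            for other in rxn.stoich:
                if other != mid:
                    resolve(other, depth - 1)
            return
        add_sink(mid)

    targets = find_dead_ends(net)
    if focus_metabolites is not None:
        targets = [m for m in targets if m in focus_metabolites]
    for mid in targets:
        resolve(mid, max_depth)
    report.counts["gap_filled"] = len(report.added_reactions)
    return net, report


# ---------------------------------------------------------------------------
# full pipeline

def complement_network(
    base: MetabolicNetwork,
    hits: list[HomologyHit],
    catalog: list[CatalogReaction],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    pathway_blacklist: frozenset[str] = frozenset(),
    generic_blacklist: frozenset[str] = DEFAULT_GENERIC_BLACKLIST,
    max_depth: int = 3,
    single_placement: bool = False,
) -> tuple[MetabolicNetwork, ComplementReport, list[ReactionCandidate]]:
    """Run associate -> dedupe -> reactant filter -> compartmentalize -> gap fill.

    Returns the extended network, a stage-count report, and the candidate
    list with full verdict trails.
    """
    report = ComplementReport()
    cands, unmatched = associate_reactions(hits, catalog, evalue_max, pathway_blacklist)
    report.unmatched_ecs = unmatched
    report.counts["associated"] = len(cands)
    all_cands = list(cands)

    cands = dedupe_against_base(cands, base)
    report.counts["deduplicated"] = len(cands)

    cands = filter_known_reactants(cands, base, generic_blacklist)
    report.counts["reactant_filtered"] = len(cands)

    placed = compartmentalize(cands, base, single_placement=single_placement)
    report.counts["compartmentalized"] = len(placed)

    net = base.copy()
    added_species: set[str] = set()
    for rxn in placed:
        if rxn.id in net.reactions:
            continue
        _add_metabolites_for(net, rxn.stoich)
        net.reactions[rxn.id] = rxn
        report.added_reactions.append(rxn.id)
        added_species.update(rxn.stoich)

    net, gf_report = gap_fill(net, catalog, max_depth, focus_metabolites=added_species or None)
    report.counts["gap_filled"] = gf_report.counts["gap_filled"]
    report.added_reactions.extend(gf_report.added_reactions)
    report.counts["exchanges_added"] = sum(
        1 for r in gf_report.added_reactions if r.startswith("SK_")
    )
    return net, report, all_cands
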