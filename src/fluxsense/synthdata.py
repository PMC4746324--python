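"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its blueprint and seed and returns a
ground-truth manifest alongside the data, so every downstream stage can be
asserted without re-deriving truth. The network generator builds a small
autotrophic scaffold (CO2 exchange, pinned photon exchange, biomass drain)
around two planted subnetworks:

* a CO2-limited linear pathway whose optimal fluxes equal the CO2 exchange
  bound and therefore vary across conditions (the planted sensitive set);
* pinned chains driven by fixed-rate exchanges whose fluxes are constant
  in every condition (rho = 0 by construction).

The CO2 exchange and the biomass drain themselves necessarily co-vary
with the CO2 bound — they are the perturbation — so the manifest records
them as scaffold, disjoint from the planted sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .complement import CatalogReaction, HomologyHit
from .netcore import (
    DEFAULT_BOUND,
    MetabolicNetwork,
    Metabolite,
    Reaction,
)
from .sensitivity import DEFAULT_LIGHT_FLUX
from .validation import FluorescenceCurve, MetaboliteTable, QpcrRecord

__all__ = [
    "NetworkBlueprint",
    "OmicsBlueprint",
    "generate_network",
    "generate_random_lp_network",
    "generate_homology_inputs",
    "generate_qpcr",
    "generate_metabolites",
    "generate_group_tables",
    "generate_concordance_truth",
]

_PATHWAYS = [
    "glycolysis/gluconeogenesis",
    "TCA cycle",
    "glyoxylate and dicarboxylate metabolism",
    "carbon fixation",
    "photorespiration",
    "transport, mitochondria",
    "transport, chloroplast",
    "oxidative phosphorylation",
]


@dataclass(frozen=True)
class NetworkBlueprint:
    """Design of one synthetic network with known sensitive/pinned sets."""

    n_compartments: int = 3
    n_reactions: int = 60
    n_sensitive: int = 6
    n_orphans: int = 2
    seed: int = 0

    @property
    def planted_sensitive(self) -> tuple[str, ...]:
        return tuple(f"SEN_{i:03d}" for i in range(self.n_sensitive))

    @property
    def planted_orphans(self) -> tuple[str, ...]:
        return tuple(f"orph_{j}[c]" for j in range(self.n_orphans))

    @property
    def scaffold_ids(self) -> tuple[str, ...]:
        return ("EX_co2", "EX_photon", "PHOTON_SINK", "BIOMASS")

    @property
    def min_reactions(self) -> int:
        return len(self.scaffold_ids) + self.n_sensitive + self.n_orphans


def generate_network(bp: NetworkBlueprint) -> tuple[MetabolicNetwork, dict]:
    """Build the blueprint network; returns (network, ground-truth manifest)."""
    if bp.n_sensitive < 1:
        raise ValueError("blueprint needs at least one sensitive reaction")
    if bp.n_reactions < bp.min_reactions:
        raise ValueError(
            f"infeasible blueprint: n_reactions={bp.n_reactions} < scaffold "
            f"minimum {bp.min_reactions}"
        )
    if not (1 <= bp.n_compartments <= 10):
        raise ValueError("n_compartments must be in 1..10")
    rng = np.random.default_rng(bp.seed)
    comps = ["c", "h", "m", "n", "r", "g", "f", "s", "x", "e"][: bp.n_compartments]
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    def met(mid: str, comp: str) -> str:
        full = f"{mid}[{comp}]"
        if all(m.id != full for m in mets):
            mets.append(Metabolite(id=full, compartment=comp))
        return full

    co2 = met("co2", "c")
    photon = met("photon", "c")
    prec = met("prec", "c")

    rxns.append(Reaction(id="EX_co2", stoich={co2: Fraction(1)}, lb=0.0, ub=10.0,
                         name="CO2 exchange", pathway="exchange"))
    rxns.append(Reaction(id="EX_photon", stoich={photon: Fraction(1)},
                         lb=DEFAULT_LIGHT_FLUX, ub=DEFAULT_LIGHT_FLUX,
                         name="photon exchange", pathway="exchange"))
    rxns.append(Reaction(id="PHOTON_SINK", stoich={photon: Fraction(-1)},
                         lb=0.0, ub=DEFAULT_BOUND, name="photon dissipation",
                         pathway="exchange"))
    rxns.append(Reaction(id="BIOMASS", stoich={prec: Fraction(-1)},
                         lb=0.0, ub=DEFAULT_BOUND, name="biomass drain",
                         pathway="biomass"))

    # CO2-limited sensitive chain: co2 -> s1 -> ... -> prec, fluxes = CO2 bound
    chain = [co2]
    for i in range(1, bp.n_sensitive):
        chain.append(met(f"s{i}", comps[i % len(comps)]))
    chain.append(prec)
    for i in range(bp.n_sensitive):
        rxns.append(
            Reaction(
                id=f"SEN_{i:03d}",
                stoich={chain[i]: Fraction(-1), chain[i + 1]: Fraction(1)},
                lb=0.0, ub=DEFAULT_BOUND,
                pathway=_PATHWAYS[i % len(_PATHWAYS)],
                gene_ids=[f"GENE_S{i:02d}"],
            )
        )

    # orphan producers drain the biomass precursor into a dead end, so
    # their flux is forced to zero and any later gap-filled consumer of
    # the orphan only closes a neutral cycle (it can never shortcut the
    # CO2-limited chain or feed extra carbon into it)
    for j in range(bp.n_orphans):
        orph = met(f"orph_{j}", "c")
        rxns.append(
            Reaction(id=f"ORPH_{j:02d}", stoich={prec: Fraction(-1), orph: Fraction(1)},
                     lb=0.0, ub=DEFAULT_BOUND, pathway="unconnected")
        )

    # pinned chains: fixed-rate source -> internal steps -> free sink
    pinned_ids: list[str] = []
    pinned_rates: dict[str, float] = {}
    budget = bp.n_reactions - len(rxns)
    k = 0
    while budget >= 3:
        n_internal = int(min(budget - 2, 1 + rng.integers(1, 4)))
        if budget - (n_internal + 2) in (1, 2):
            n_internal = budget - 2  # absorb a remainder too small for a new chain
        rate = round(float(0.2 + 0.8 * rng.random()), 3)
        nodes = [met(f"q{k}_{j}", comps[(j + k) % len(comps)])
                 for j in range(n_internal + 1)]
        rxns.append(Reaction(id=f"PIN_SRC_{k:02d}", stoich={nodes[0]: Fraction(1)},
                             lb=rate, ub=rate, pathway="exchange"))
        for j in range(n_internal):
            rid = f"PIN_{k:02d}_{j:02d}"
            lb = -DEFAULT_BOUND if (k == 0 and j == 0) else 0.0
            rxns.append(
                Reaction(id=rid,
                         stoich={nodes[j]: Fraction(-1), nodes[j + 1]: Fraction(1)},
                         lb=lb, ub=DEFAULT_BOUND,
                         pathway=_PATHWAYS[(j + k) % len(_PATHWAYS)])
            )
            pinned_ids.append(rid)
            pinned_rates[rid] = rate
        rxns.append(Reaction(id=f"PIN_SNK_{k:02d}", stoich={nodes[-1]: Fraction(-1)},
                             lb=0.0, ub=DEFAULT_BOUND, pathway="exchange"))
        budget = bp.n_reactions - len(rxns)
        k += 1

    net = MetabolicNetwork(comps, mets, rxns, objective_id="BIOMASS")
    src_ids = [r.id for r in rxns if r.id.startswith(("PIN_SRC", "PIN_SNK"))]
    truth = {
        "seed": bp.seed,
        "sensitive": list(bp.planted_sensitive),
        "pinned": pinned_ids,
        "pinned_rates": pinned_rates,
        "scaffold": list(bp.scaffold_ids) + src_ids,
        "orphan_reactions": [f"ORPH_{j:02d}" for j in range(bp.n_orphans)],
        "orphan_metabolites": list(bp.planted_orphans),
        "n_reactions": len(rxns),
        "n_metabolites": len(mets),
    }
    return net, truth


def generate_random_lp_network(seed: int, max_reactions: int = 8) -> MetabolicNetwork:
    """A tiny random network with finite bounds for exhaustive LP checking.

    Bounds always bracket zero, so v = 0 is feasible and the LP has an
    optimum; coefficients are small integers.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, max_reactions + 1))
    m = int(rng.integers(2, 5))
    met_ids = [f"x{i}[c]" for i in range(m)]
    mets = [Metabolite(id=mid, compartment="c") for mid in met_ids]
    rxns = []
    for j in range(n):
        k = int(rng.integers(1, min(3, m) + 1))
        chosen = rng.choice(m, size=k, replace=False)
        stoich = {}
        for i in chosen:
            coeff = int(rng.choice([-2, -1, 1, 2]))
            stoich[met_ids[i]] = Fraction(coeff)
        lb = float(rng.integers(-3, 1))
        ub = float(rng.integers(0, 5))
        rxns.append(Reaction(id=f"r{j}", stoich=stoich, lb=lb, ub=ub))
    objective = f"r{int(rng.integers(0, n))}"
    return MetabolicNetwork(["c"], mets, rxns, objective)


# ---------------------------------------------------------------------------
# homology inputs

def generate_homology_inputs(
    base: MetabolicNetwork,
    truth: dict,
    seed: int = 0,
    n_ok: int = 4,
    n_duplicate: int = 3,
    n_novel: int = 2,
    n_generic: int = 1,
    n_gap_fill: int = 1,
    n_sink_fallback: int = 1,
) -> tuple[list[CatalogReaction], list[HomologyHit], dict]:
    """Catalog + hit table exercising every complementation stage.

    The manifest records the intended verdict of every candidate, the
    catalog reactions reachable only through gap filling, and the expected
    per-stage counts, so bookkeeping can be asserted exactly. Candidate
    species are drawn from single-compartment species of the base network,
    making each surviving candidate have exactly one viable placement.
    """
    rng = np.random.default_rng(seed)
    catalog: list[CatalogReaction] = []
    hits: list[HomologyHit] = []
    manifest: dict = {"candidates": {}, "gap_only_catalog": [],
                      "planned_sinks": [], "planned_gap_reactions": []}
    counter = 0

    def next_ids() -> tuple[str, str]:
        nonlocal counter
        counter += 1
        return f"C{counter:04d}", f"9.9.{counter // 10}.{counter % 10}"

    def add_candidate(equation: str, verdict: str, pathway: str = "synthetic") -> str:
        cid, ec = next_ids()
        catalog.append(CatalogReaction(catalog_id=cid, ec=ec, equation=equation,
                                       pathway=pathway))
        hits.append(HomologyHit(protein_id=f"P_{cid}", ec=ec,
                                evalue=1e-30, bitscore=200.0))
        manifest["candidates"][cid] = verdict
        return cid

    from .complement import _canonical_stoich
    from .netcore import parse_equation as _parse_eq

    base_canon = set()
    for rxn in base.reactions.values():
        base_canon.add(_canonical_stoich(rxn.stoich))
        if rxn.reversible:
            base_canon.add(_canonical_stoich({m: -c for m, c in rxn.stoich.items()}))

    # cytosolic species of the CO2-limited chain: candidates recycle them
    # back to CO2 (decarboxylation-style), so they close cycles that carry
    # zero flux at the parsimonious optimum and exactly one compartment
    # (the cytosol) is viable for placement
    pool = sorted(
        n for n in base.species_names()
        if base.species_compartments(n) == {"c"}
        and (n == "prec" or n.startswith("s"))
    )

    added_ok = 0
    coeff = 1
    while added_ok < n_ok:
        a = pool[added_ok % len(pool)]
        prefix = "" if coeff == 1 else f"{coeff} "
        eq = f"{prefix}{a} -> co2"
        if _canonical_stoich(_parse_eq(eq)[0]) in base_canon:
            coeff += 1
            continue
        add_candidate(eq, "ok", pathway="carbon recycling")
        added_ok += 1
        if added_ok % len(pool) == 0:
            coeff += 1  # vary coefficients once the species pool cycles

    # duplicates of existing base reactions (compartment-stripped); one is
    # the reverse of a reversible base reaction when available
    internal = [r for r in base.reactions.values()
                if not r.is_exchange and not r.id.startswith("C")]
    reversible = [r for r in internal if r.reversible]
    dup_sources = (reversible[:1] + [r for r in internal if not r.reversible])[:n_duplicate]
    for idx, rxn in enumerate(dup_sources):
        stoich = rxn.stoich if not (idx == 0 and reversible) else {
            m: -c for m, c in rxn.stoich.items()
        }
        from .netcore import format_equation, strip_compartment

        generic = {strip_compartment(m): c for m, c in stoich.items()}
        add_candidate(format_equation(generic, False), "duplicate")

    for i in range(n_novel):
        add_candidate(f"co2 -> novel_met_{i}", "novel")
    for i in range(n_generic):
        add_candidate("co2 -> an_alcohol", "generic")

    # candidates that orphan a known dead-end species; one resolvable via a
    # gap-only catalog reaction, the rest by sink fallback
    orphans = truth.get("orphan_metabolites", [])[: n_gap_fill + n_sink_fallback]
    for i, orph in enumerate(orphans):
        from .netcore import strip_compartment

        name = strip_compartment(orph)
        cid = add_candidate(f"2 prec -> {name}", "ok_gap")
        if i < n_gap_fill:
            gcid, gec = next_ids()
            catalog.append(CatalogReaction(catalog_id=gcid, ec=gec,
                                           equation=f"{name} -> prec",
                                           pathway="gap closure"))
            manifest["gap_only_catalog"].append(gcid)
            manifest["planned_gap_reactions"].append(f"{gcid}__gf_c")
        else:
            manifest["planned_sinks"].append(f"SK_{orph}")

    # noise the association stage must ignore
    hits.append(HomologyHit(protein_id="P_unmatched", ec="1.1.99.99",
                            evalue=1e-40, bitscore=300.0))
    hits.append(HomologyHit(protein_id="P_weak", ec=catalog[0].ec,
                            evalue=0.5, bitscore=20.0))
    hits = [hits[i] for i in rng.permutation(len(hits))]

    verdicts = manifest["candidates"]
    n_assoc = len(verdicts)
    n_dedup = n_assoc - sum(v == "duplicate" for v in verdicts.values())
    n_filter = n_dedup - sum(v in ("novel", "generic") for v in verdicts.values())
    manifest["expected_counts"] = {
        "associated": n_assoc,
        "deduplicated": n_dedup,
        "reactant_filtered": n_filter,
        "compartmentalized": n_filter,
        "gap_filled": len(manifest["planned_gap_reactions"])
        + len(manifest["planned_sinks"]),
        "exchanges_added": len(manifest["planned_sinks"]),
    }
    manifest["unmatched_ecs"] = ["1.1.99.99"]
    return catalog, hits, manifest


# ---------------------------------------------------------------------------
# omics inputs

#: Default low-vs-high expression ratios (>1 = higher at low CO2, the CCM
#: induction pattern); reference genes are flat.
_DEFAULT_EXPRESSION = {
    "CAH5": 4.0, "LCIA": 3.0, "GLYK": 1.8, "GCSH": 0.6,
    "MDH3": 1.5, "PDC3": 0.7, "ADH1": 1.4, "GPM2": 0.8,
}

#: Default metabolite fold changes, high over low CO2. Thirteen analytes
#: carry a planted effect (xylose >5-fold up, sucrose/glycine down, amino
#: acids shifted); the rest are nulls.
_DEFAULT_FOLD_CHANGES = {
    "xylose": 5.5, "glycerate": 1.8, "proline": 1.7, "b_alanine": 1.7,
    "phenylalanine": 1.6, "lysine": 1.6, "malate": 1.5, "glutamate": 1.5,
    "alanine": 1.5,
    "sucrose": 0.4, "glycine": 0.5, "asparagine": 0.6, "isocitrate": 0.6,
    "citrate": 1.0, "serine": 1.0, "succinate": 1.0, "fumarate": 1.0,
    "glucose": 1.0,
}
# ~50 further unchanged analytes bring the panel to 67, the scale of a
# GC-TOF-MS primary-metabolite screen; with most of the total ion content
# unchanged, TIC normalization leaves the planted fold changes intact
_DEFAULT_FOLD_CHANGES.update({f"analyte_{i:02d}": 1.0 for i in range(1, 50)})

#: Paper-style discordance: model direction disagrees with measurement for
#: these three analytes; the other ten planted analytes agree.
_DEFAULT_DISCORDANT = ("glycine", "isocitrate", "sucrose")


@dataclass(frozen=True)
class OmicsBlueprint:
    """Ground truth for the qPCR and metabolomics generators."""

    expression_ratios: dict = field(default_factory=lambda: dict(_DEFAULT_EXPRESSION))
    reference_genes: tuple[str, ...] = ("ACT", "UBQ")
    efficiencies: dict | None = None  # gene -> E; default drawn in (1.75, 2.0]
    fold_changes: dict = field(default_factory=lambda: dict(_DEFAULT_FOLD_CHANGES))
    discordant: tuple[str, ...] = _DEFAULT_DISCORDANT
    noise_cv: float = 0.10
    ct_sd: float = 0.15
    curve_noise: float = 0.0
    n_low: int = 3
    n_high: int = 2
    seed: int = 0


CT_THRESHOLD = 1000.0
BASELINE = 50.0
PLATEAU = 10000.0
N_CYCLES = 40


def _curve_readings(e: float, ct: float, rng, noise: float) -> np.ndarray:
    cycles = np.arange(1, N_CYCLES + 1, dtype=float)
    f0 = CT_THRESHOLD / e**ct
    amp = np.minimum(f0 * e**cycles, PLATEAU)
    readings = BASELINE + amp
    if noise > 0:
        readings = readings * (1.0 + noise * rng.standard_normal(N_CYCLES))
    return np.maximum(readings, 0.0)


def generate_qpcr(
    bp: OmicsBlueprint,
) -> tuple[list[FluorescenceCurve], list[QpcrRecord], dict]:
    """Fluorescence curves and Ct records with known efficiencies and ratios.

    Curves follow F(c) = baseline + min(F0 * E^c, plateau); Ct is the
    threshold-crossing cycle. The low/high Ct offset encodes the true
    expression ratio via dCt = log_E(ratio).
    """
    rng = np.random.default_rng(bp.seed)
    genes = list(bp.expression_ratios) + [g for g in bp.reference_genes
                                          if g not in bp.expression_ratios]
    eff = dict(bp.efficiencies or {})
    for g in genes:
        if g not in eff:
            eff[g] = round(float(1.75 + 0.25 * rng.random()), 3)
        if not (1.0 < eff[g] <= 2.2):
            raise ValueError(f"efficiency for {g} outside (1, 2.2]")
    curves: list[FluorescenceCurve] = []
    records: list[QpcrRecord] = []
    for gene in genes:
        ratio = bp.expression_ratios.get(gene, 1.0)
        e = eff[gene]
        ct_high = float(18.0 + 6.0 * rng.random())
        ct_low = ct_high - float(np.log(ratio) / np.log(e))
        for condition, base_ct, n_rep in (
            ("low", ct_low, bp.n_low), ("high", ct_high, bp.n_high)
        ):
            for rep in range(1, n_rep + 1):
                ct = base_ct + float(bp.ct_sd * rng.standard_normal())
                well = f"{gene}_{condition}_{rep}"
                curves.append(
                    FluorescenceCurve(
                        well=well, gene=gene, condition=condition, replicate=rep,
                        cycles=np.arange(1, N_CYCLES + 1, dtype=float),
                        readings=_curve_readings(e, ct, rng, bp.curve_noise),
                    )
                )
                records.append(
                    QpcrRecord(gene=gene, condition=condition, ct=ct,
                               efficiency=e, replicate=rep)
                )
    truth = {"efficiencies": eff,
             "expression_ratios": dict(bp.expression_ratios),
             "reference_genes": list(bp.reference_genes)}
    return curves, records, truth


def generate_metabolites(bp: OmicsBlueprint) -> tuple[MetaboliteTable, dict]:
    """Intensity table with planted fold changes under the 3-low/2-high design.

    Raw intensity = analyte base level x condition fold change x
    multiplicative log-normal noise x cell count x per-sample capture
    scale; the capture scale cancels under TIC normalization.
    """
    rng = np.random.default_rng(bp.seed + 1)
    analytes = sorted(bp.fold_changes)
    samples = [f"low_{i+1}" for i in range(bp.n_low)] + [
        f"high_{i+1}" for i in range(bp.n_high)
    ]
    conditions = pd.Series(
        ["low"] * bp.n_low + ["high"] * bp.n_high, index=samples
    )
    # responding analytes are trace species; the stable bulk dominates the
    # total ion content (the regime in which TIC normalization is valid)
    base = {
        a: float(10 ** ((3.0 if bp.fold_changes[a] != 1.0 else 4.0)
                        + 0.5 * rng.random()))
        for a in analytes
    }
    cell_counts = pd.Series(
        [float(2e6 * (1 + 0.1 * rng.standard_normal())) for _ in range(bp.n_low)]
        + [float(6e6 * (1 + 0.1 * rng.standard_normal())) for _ in range(bp.n_high)],
        index=samples,
    )
    sigma = float(np.sqrt(np.log(1 + bp.noise_cv**2)))
    rows = {}
    for s in samples:
        scale = float(np.exp(0.2 * rng.standard_normal()))
        cond = conditions[s]
        rows[s] = {
            a: base[a]
            * (bp.fold_changes[a] if cond == "high" else 1.0)
            * float(np.exp(sigma * rng.standard_normal() - sigma**2 / 2))
            * cell_counts[s] * scale
            for a in analytes
        }
    intensities = pd.DataFrame.from_dict(rows, orient="index")[analytes]
    table = MetaboliteTable(
        intensities=intensities, cell_counts=cell_counts, conditions=conditions
    )
    truth = {
        "fold_changes": dict(bp.fold_changes),
        "log2_fold_changes": {a: float(np.log2(f)) for a, f in bp.fold_changes.items()},
        "planted": sorted(a for a, f in bp.fold_changes.items() if f != 1.0),
        "null": sorted(a for a, f in bp.fold_changes.items() if f == 1.0),
        "discordant": list(bp.discordant),
    }
    return table, truth


def generate_group_tables(
    net: MetabolicNetwork, seed: int = 0
) -> tuple[dict[str, float], dict[str, dict[str, int]]]:
    """Toy group-contribution parameters and per-species decompositions.

    Formation energies derive from a single per-species surrogate group, so
    they are consistent with a chemical potential: CO2 sits far downhill
    (oxidative recycling toward it is strongly favorable), the biomass
    precursor uphill, and chain intermediates in between. A consistent
    potential is what keeps thermodynamic reorientation from fabricating
    energy-releasing carbon-creating cycles, mirroring the role elemental
    balance plays in a curated model. A small seeded jitter (< 2 kJ/mol,
    never threshold-crossing) varies the numbers across bundles.

    Returns (contributions, decompositions keyed by species name).
    """
    rng = np.random.default_rng(seed)

    def potential(name: str) -> float:
        if name == "co2":
            return -200.0
        if name == "photon":
            return 0.0
        if name == "prec":
            return 50.0
        if name.startswith("orph"):
            return 40.0  # gap-closing orphan -> prec comes out reversible
        if name.startswith("s"):
            return 25.0
        return 0.0

    groups: dict[str, float] = {}
    decomp: dict[str, dict[str, int]] = {}
    for name in sorted(net.species_names()):
        gid = f"grp_{name}"
        jitter = float(np.round(rng.uniform(-2.0, 2.0), 2))
        groups[gid] = potential(name) + jitter
        decomp[name] = {gid: 1}
    return groups, decomp


def generate_concordance_truth(bp: OmicsBlueprint) -> list:
    """Model-side net-flux records matching the planted fold changes.

    For concordant analytes the model's net flux moves in the measured
    direction (net_high / net_low = fold change); for the planted
    discordant trio it moves the opposite way.
    """
    from .sensitivity import NetFluxRecord

    records = []
    for analyte, fc in sorted(bp.fold_changes.items()):
        if fc == 1.0:
            continue
        ratio_hl = fc if analyte not in bp.discordant else 1.0 / fc
        net_low = 1.0
        net_high = net_low * ratio_hl
        records.append(
            NetFluxRecord(
                metabolite_id=analyte,
                net_flux_low=net_low,
                net_flux_high=net_high,
                ratio=net_low / net_high,
            )
        )
    return records
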