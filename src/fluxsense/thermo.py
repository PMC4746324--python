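"""Group-contribution Gibbs energies and reaction directionality.

Formation energies are estimated at 27 degC and pH 7 as an origin term plus
a sum of structural-group contributions; reaction energies follow by
stoichiometric summation. A symmetric threshold tau (default 30 kJ/mol, a
common constraint-based-modelling heuristic) splits reactions into forward
irreversible, reverse irreversible, or reversible. Group decompositions are
input data, not derived from structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd

from .netcore import Metabolite, Reaction

__all__ = [
    "GroupContributionTable",
    "ReactionEnergy",
    "Verdict",
    "ThermoError",
    "estimate_dgf",
    "estimate_dgr",
    "classify_reversibility",
    "apply_directionality",
    "load_group_table",
    "load_decompositions",
    "DEFAULT_TAU",
]

#: Reversibility threshold, kJ/mol.
DEFAULT_TAU = 30.0


class ThermoError(ValueError):
    pass


class Verdict(str, Enum):
    FORWARD_IRREVERSIBLE = "forward_irreversible"
    REVERSE_IRREVERSIBLE = "reverse_irreversible"
    REVERSIBLE = "reversible"


@dataclass(frozen=True)
class GroupContributionTable:
    """Origin and per-group contributions, kJ/mol, conditioned at 300.15 K, pH 7."""

    origin: float
    contributions: Mapping[str, float]
    temperature_k: float = 300.15
    ph: float = 7.0


@dataclass(frozen=True)
class ReactionEnergy:
    reaction_id: str
    dgr: float
    verdict: Verdict


def estimate_dgf(met: Metabolite, table: GroupContributionTable) -> float:
    """Formation energy: origin + sum of count * contribution over groups."""
    if met.group_counts is None:
        raise ThermoError(f"metabolite {met.id!r} has no group decomposition")
    total = table.origin
    for group, count in met.group_counts.items():
        if group not in table.contributions:
            raise ThermoError(
                f"group {group!r} (metabolite {met.id!r}) missing from contribution table"
            )
        total += count * table.contributions[group]
    return total


def estimate_dgr(rxn: Reaction, energies: Mapping[str, float]) -> float:
    """Reaction energy: stoichiometry-weighted sum of formation energies."""
    total = 0.0
    for mid, coeff in rxn.stoich.items():
        if mid not in energies:
            raise ThermoError(
                f"no formation energy for {mid!r} (reaction {rxn.id!r})"
            )
        total += float(coeff) * energies[mid]
    return total


def classify_reversibility(dgr: float, tau: float = DEFAULT_TAU) -> Verdict:
    """|dGr| <= tau -> reversible; strongly negative -> forward; strongly positive -> reverse."""
    if tau <= 0:
        raise ThermoError(f"tau must be positive, got {tau}")
    if dgr < -tau:
        return Verdict.FORWARD_IRREVERSIBLE
    if dgr > tau:
        return Verdict.REVERSE_IRREVERSIBLE
    return Verdict.REVERSIBLE


def apply_directionality(
    rxn: Reaction,
    energies: Mapping[str, float],
    tau: float = DEFAULT_TAU,
    default_bound: float = 1000.0,
    overrides: Mapping[str, Verdict] | None = None,
) -> tuple[Reaction, ReactionEnergy]:
    """Set a reaction's bounds from its estimated Gibbs energy.

    Reverse-irreversible reactions are flipped so that the written
    orientation always carries forward flux. ``overrides`` lets curated
    calls from prior studies win over the group-contribution estimate.
    """
    dgr = estimate_dgr(rxn, energies)
    verdict = (overrides or {}).get(rxn.id) or classify_reversibility(dgr, tau)
    if verdict is Verdict.REVERSIBLE:
        out = Reaction(id=rxn.id, stoich=dict(rxn.stoich), lb=-default_bound,
                       ub=default_bound, name=rxn.name, ec=rxn.ec,
                       pathway=rxn.pathway, gene_ids=list(rxn.gene_ids))
    elif verdict is Verdict.FORWARD_IRREVERSIBLE:
        out = Reaction(id=rxn.id, stoich=dict(rxn.stoich), lb=0.0,
                       ub=default_bound, name=rxn.name, ec=rxn.ec,
                       pathway=rxn.pathway, gene_ids=list(rxn.gene_ids))
    else:
        flipped = rxn.reversed()
        out = Reaction(id=rxn.id, stoich=flipped.stoich, lb=0.0,
                       ub=default_bound, name=rxn.name, ec=rxn.ec,
                       pathway=rxn.pathway, gene_ids=list(rxn.gene_ids))
    return out, ReactionEnergy(reaction_id=rxn.id, dgr=dgr, verdict=verdict)


def load_group_table(path: str | Path, origin: float = 0.0) -> GroupContributionTable:
    """Read a TSV of ``group_id  contribution_kj_mol``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return GroupContributionTable(
        origin=origin,
        contributions=dict(zip(df["group_id"], df["contribution_kj_mol"])),
    )


def load_decompositions(path: str | Path) -> dict[str, dict[str, int]]:
    """Read a TSV of ``metabolite_id  group_id  count`` into nested dicts."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.metabolite_id, {})[row.group_id] = int(row.count)
    return out
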