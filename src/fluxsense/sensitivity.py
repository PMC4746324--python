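"""CO2 condition scan and sensitive-reaction classification.

A network is solved (parsimonious FBA) at each CO2 condition; a reaction's
flux variation coefficient rho = sd(flux) / max(|mean(flux)|, eps) measures
how strongly its optimal flux responds to the CO2 supply. Reactions with
rho >= 0.01 (inclusive) are classified CO2-sensitive, then aggregated by
pathway annotation and compartment. Per-metabolite net fluxes over the
sensitive set (production minus consumption) and their low/high-CO2 ratio
feed the metabolomics reconciliation.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import FluxSolution, assemble_lp, solve_unique
from .netcore import Condition, MetabolicNetwork, set_condition_bounds

__all__ = [
    "SensitivityTable",
    "NetFluxRecord",
    "SensitivityError",
    "default_conditions",
    "scan_conditions",
    "build_sensitivity_table",
    "net_flux_records",
    "flux_variation_coefficient",
    "classify_sensitive",
    "aggregate",
    "net_metabolite_flux",
    "flux_ratio_low_high",
    "RHO_THRESHOLD",
    "RHO_EPS",
]

RHO_THRESHOLD = 0.01
RHO_EPS = 1e-9
NET_FLUX_EPS = 1e-9

#: mmol CO2 / gDW / h permitted per % CO2 in the gas phase (linear scaling).
CO2_FLUX_PER_PERCENT = 1.0
#: photon uptake pinned for all conditions, mE/gDW/h (cool-white light).
DEFAULT_LIGHT_FLUX = 57.54


class SensitivityError(RuntimeError):
    pass


def default_conditions(
    co2_levels: tuple[float, ...] = (0.04, 2.5, 5.0, 8.0, 10.0),
    flux_per_percent: float = CO2_FLUX_PER_PERCENT,
    light_flux: float = DEFAULT_LIGHT_FLUX,
) -> list[Condition]:
    """The five-condition scan: air (0.04%) through 10% CO2, fixed light."""
    return [
        Condition(
            name=f"co2_{lvl:g}pct",
            co2_percent=lvl,
            co2_flux_ub=flux_per_percent * lvl,
            light_flux=light_flux,
        )
        for lvl in co2_levels
    ]


@dataclass
class SensitivityTable:
    """Per-reaction fluxes across conditions, rho, and sensitivity flags."""

    condition_names: list[str]
    fluxes: pd.DataFrame  # index reaction_id, one column per condition
    rho: pd.Series = field(default_factory=pd.Series)
    sensitive: pd.Series = field(default_factory=pd.Series)
    pathway: pd.Series = field(default_factory=pd.Series)
    compartment: pd.Series = field(default_factory=pd.Series)
    rho_threshold: float = RHO_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        df = self.fluxes.copy()
        df["rho"] = self.rho
        df["sensitive"] = self.sensitive
        df["pathway"] = self.pathway
        df["compartment"] = self.compartment
        return df

    def sensitive_ids(self) -> list[str]:
        return sorted(self.sensitive[self.sensitive].index)


@dataclass
class NetFluxRecord:
    """Net flux of one metabolite over the sensitive set at low vs high CO2."""

    metabolite_id: str
    net_flux_low: float
    net_flux_high: float
    ratio: float | None  # low / high; None when |high| <= eps
    concordant: bool | None = None


def scan_conditions(
    net: MetabolicNetwork,
    conditions: list[Condition],
    co2_exchange_id: str = "EX_co2",
    photon_exchange_id: str = "EX_photon",
) -> dict[str, FluxSolution]:
    """Solve the parsimonious FBA once per condition.

    Any infeasible condition aborts the scan, naming the condition.
    """
    if len(conditions) < 2:
        raise SensitivityError("need at least 2 conditions to scan")
    names = [c.name for c in conditions]
    if len(set(names)) != len(names):
        raise SensitivityError(f"duplicate condition names in {names}")
    out: dict[str, FluxSolution] = {}
    for cond in conditions:
        bounded = set_condition_bounds(net, cond, co2_exchange_id, photon_exchange_id)
        sol = solve_unique(assemble_lp(bounded))
        if sol.status != "optimal":
            raise SensitivityError(
                f"condition {cond.name!r} is {sol.status}; scan aborted"
            )
        out[cond.name] = sol
    return out


def flux_variation_coefficient(fluxes) -> float:
    """rho = sample sd / max(|mean|, eps); always >= 0.

    The epsilon guard makes all-zero flux profiles come out as 0 rather
    than 0/0.
    """
    arr = np.asarray(list(fluxes), dtype=float)
    if arr.size < 2:
        raise SensitivityError("rho needs at least 2 condition fluxes")
    sd = float(np.std(arr, ddof=1))
    return sd / max(abs(float(np.mean(arr))), RHO_EPS)


def build_sensitivity_table(
    net: MetabolicNetwork,
    solutions: dict[str, FluxSolution],
) -> SensitivityTable:
    """Tabulate per-reaction fluxes from a finished scan, with annotations."""
    condition_names = list(solutions)
    reaction_ids = sorted(net.reactions)
    data = {
        name: [solutions[name].fluxes.get(r, 0.0) for r in reaction_ids]
        for name in condition_names
    }
    fluxes = pd.DataFrame(data, index=reaction_ids)
    pathway = pd.Series(
        {r: net.reactions[r].pathway or "unannotated" for r in reaction_ids}
    )
    compartment = pd.Series({r: _reaction_compartment(net, r) for r in reaction_ids})
    return SensitivityTable(
        condition_names=condition_names,
        fluxes=fluxes,
        pathway=pathway,
        compartment=compartment,
    )


def _reaction_compartment(net: MetabolicNetwork, rid: str) -> str:
    comps = sorted(
        {net.metabolites[m].compartment for m in net.reactions[rid].stoich}
    )
    return comps[0] if len(comps) == 1 else "+".join(comps)


def classify_sensitive(
    table: SensitivityTable, rho_threshold: float = RHO_THRESHOLD
) -> SensitivityTable:
    """Compute rho per reaction and flag rho >= threshold (inclusive)."""
    rho = table.fluxes.apply(
        lambda row: flux_variation_coefficient(row.values), axis=1
    )
    table.rho = rho
    table.sensitive = rho >= rho_threshold
    table.rho_threshold = rho_threshold
    return table


def aggregate(table: SensitivityTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count sensitive reactions per pathway and per compartment.

    Returns (pathway_summary, compartment_summary) with count and percent
    columns; percentages sum to 100 within rounding.
    """
    if table.sensitive.empty or not table.sensitive.any():
        empty = pd.DataFrame(columns=["count", "percent"])
        return empty, empty.copy()
    sens = table.sensitive[table.sensitive].index

    def summarize(labels: pd.Series) -> pd.DataFrame:
        counts = labels.loc[sens].value_counts().sort_index()
        df = counts.to_frame("count")
        df["percent"] = 100.0 * df["count"] / df["count"].sum()
        return df

    return summarize(table.pathway), summarize(table.compartment)


def net_metabolite_flux(
    table: SensitivityTable,
    net: MetabolicNetwork,
    metabolite_id: str,
    condition: str,
) -> float:
    """Net production of a metabolite by the sensitive reactions only.

    Phi = sum over sensitive reactions j of S[met, j] * v_j(condition):
    production enters positively, consumption negatively via the sign of
    the stoichiometric coefficient.
    """
    if metabolite_id not in net.metabolites:
        raise SensitivityError(f"unknown metabolite {metabolite_id!r}")
    if condition not in table.fluxes.columns:
        raise SensitivityError(f"unknown condition {condition!r}")
    total = 0.0
    for rid in table.sensitive[table.sensitive].index:
        coeff = net.reactions[rid].stoich.get(metabolite_id)
        if coeff is not None:
            total += float(coeff) * table.fluxes.at[rid, condition]
    return total


def flux_ratio_low_high(
    metabolite_id: str, net_low: float, net_high: float
) -> NetFluxRecord:
    """Ratio of net flux at low CO2 over net flux at high CO2.

    Undefined (None) when the high-CO2 net flux is numerically zero; that
    is a value, not an error.
    """
    ratio: float | None
    if abs(net_high) > NET_FLUX_EPS:
        ratio = net_low / net_high
    else:
        ratio = None
    return NetFluxRecord(
        metabolite_id=metabolite_id,
        net_flux_low=net_low,
        net_flux_high=net_high,
        ratio=ratio,
    )


def net_flux_records(
    table: SensitivityTable,
    net: MetabolicNetwork,
    metabolite_ids: list[str],
    low_condition: str,
    high_condition: str,
) -> list[NetFluxRecord]:
    """Convenience: net-flux records for many metabolites at once."""
    out = []
    for mid in metabolite_ids:
        lo = net_metabolite_flux(table, net, mid, low_condition)
        hi = net_metabolite_flux(table, net, mid, high_condition)
        out.append(flux_ratio_low_high(mid, lo, hi))
    return out
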