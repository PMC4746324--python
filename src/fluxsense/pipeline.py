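"""End-to-end orchestration: complement -> thermo -> FBA scan -> validation.

A single config (YAML on disk, :class:`RunConfig` in memory) names every
input, threshold and output location; :func:`run` executes the stages in
order, writes each stage's table under the output directory, and returns a
run report. Identical config and inputs give byte-identical outputs. The
click CLI exposes each stage as a subcommand over the same config schema.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import complement as cmod
from . import sensitivity as smod
from . import synthdata, thermo, validation
from .netcore import Condition, MetabolicNetwork, load_network, write_network

__all__ = ["RunConfig", "run", "cli", "load_conditions", "write_conditions",
           "write_qpcr_tables", "read_qpcr_tables", "write_metabolite_table",
           "read_metabolite_table"]

log = logging.getLogger("fluxsense")


@dataclass
class RunConfig:
    """Paths, thresholds and contrast definition for one pipeline run."""

    base_network: str
    conditions: str
    out_dir: str
    homology_hits: str | None = None
    catalog: str | None = None
    group_table: str | None = None
    decompositions: str | None = None
    qpcr_ct: str | None = None
    fluorescence: str | None = None
    metabolites: str | None = None
    metabolite_map: str | None = None
    rho_threshold: float = smod.RHO_THRESHOLD
    tau: float = thermo.DEFAULT_TAU
    evalue_max: float = cmod.DEFAULT_EVALUE_MAX
    alpha: float = 0.05
    contrast: tuple[str, str] = ("low", "high")
    co2_exchange_id: str = "EX_co2"
    photon_exchange_id: str = "EX_photon"
    low_condition: str | None = None
    high_condition: str | None = None
    reference_genes: tuple[str, ...] = ("ACT",)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.rho_threshold < 1):
            raise ValueError(f"rho_threshold {self.rho_threshold} out of range")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha {self.alpha} out of range")
        for name in ("base_network", "conditions"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config field {name!r}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


# ---------------------------------------------------------------------------
# table I/O

def load_conditions(path: str | Path) -> list[Condition]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        Condition(name=str(row["name"]), co2_percent=float(row["co2_percent"]),
                  co2_flux_ub=float(row["co2_flux_ub"]),
                  light_flux=float(row["light_flux"]))
        for _, row in df.iterrows()
    ]


def write_conditions(conds: list[Condition], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": c.name, "co2_percent": c.co2_percent,
             "co2_flux_ub": c.co2_flux_ub, "light_flux": c.light_flux}
            for c in conds
        ]
    ).to_csv(path, sep="\t", index=False)


def write_qpcr_tables(curves, records, ct_path, fluor_path) -> None:
    pd.DataFrame(
        [
            {"gene": r.gene, "condition": r.condition, "replicate": r.replicate,
             "ct": r.ct, "efficiency": r.efficiency, "melt_ok": r.melt_ok}
            for r in records
        ]
    ).to_csv(ct_path, index=False)
    rows = []
    for c in curves:
        for cyc, val in zip(c.cycles, c.readings):
            rows.append({"well": c.well, "gene": c.gene, "condition": c.condition,
                         "replicate": c.replicate, "cycle": cyc, "value": val})
    pd.DataFrame(rows).to_csv(fluor_path, index=False)


def read_qpcr_tables(ct_path, fluor_path=None):
    ct = pd.read_csv(ct_path)
    records = [
        validation.QpcrRecord(
            gene=row.gene, condition=row.condition, ct=row.ct,
            efficiency=row.efficiency, replicate=int(row.replicate),
            melt_ok=bool(row.melt_ok),
        )
        for row in ct.itertuples(index=False)
    ]
    curves = []
    if fluor_path is not None and Path(fluor_path).exists():
        df = pd.read_csv(fluor_path)
        for well, grp in df.groupby("well", sort=True):
            grp = grp.sort_values("cycle")
            curves.append(
                validation.FluorescenceCurve(
                    well=well, gene=grp["gene"].iloc[0],
                    condition=grp["condition"].iloc[0],
                    replicate=int(grp["replicate"].iloc[0]),
                    cycles=grp["cycle"].to_numpy(),
                    readings=grp["value"].to_numpy(),
                )
            )
    return curves, records


def write_metabolite_table(table: validation.MetaboliteTable, path) -> None:
    df = table.intensities.copy()
    df.insert(0, "condition", table.conditions)
    df.insert(1, "cell_count", table.cell_counts)
    df.index.name = "sample"
    df.to_csv(path)


def read_metabolite_table(path) -> validation.MetaboliteTable:
    df = pd.read_csv(path, index_col="sample")
    return validation.MetaboliteTable(
        intensities=df.drop(columns=["condition", "cell_count"]),
        cell_counts=df["cell_count"],
        conditions=df["condition"],
    )


# ---------------------------------------------------------------------------
# stages

def _stage_complement(cfg: RunConfig, base: MetabolicNetwork, out: Path):
    if not (cfg.homology_hits and cfg.catalog):
        log.info("complement: no homology inputs configured; using base network")
        return base, None
    hits = cmod.load_homology_hits(cfg.homology_hits)
    catalog = cmod.load_catalog(cfg.catalog)
    net, report, cands = cmod.complement_network(
        base, hits, catalog, evalue_max=cfg.evalue_max
    )
    (out / "complement_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    pd.DataFrame(
        [
            {"catalog_id": c.catalog_id, "ec": c.ec,
             **{f"verdict_{k}": v for k, v in c.verdicts.items()}}
            for c in cands
        ]
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)
    log.info("complement: %s", report.counts)
    return net, report


def _stage_thermo(cfg: RunConfig, net: MetabolicNetwork, added: list[str], out: Path):
    if not (cfg.group_table and cfg.decompositions):
        return net, None
    table = thermo.load_group_table(cfg.group_table)
    decomp = thermo.load_decompositions(cfg.decompositions)
    energies = {}
    for mid, met in net.metabolites.items():
        groups = decomp.get(mid) or decomp.get(met.species_name)
        if groups is not None:
            energies[mid] = thermo.estimate_dgf(
                type(met)(id=met.id, compartment=met.compartment, name=met.name,
                          formula=met.formula, group_counts=groups),
                table,
            )
    rows = []
    for rid in added:
        rxn = net.reactions[rid]
        if rxn.is_exchange:
            continue  # boundary pseudo-reactions have no reaction chemistry
        if all(m in energies for m in rxn.stoich):
            new_rxn, energy = thermo.apply_directionality(rxn, energies, cfg.tau)
            net.reactions[rid] = new_rxn
            rows.append({"reaction_id": rid, "dgr_kj_mol": energy.dgr,
                         "verdict": energy.verdict.value})
    df = pd.DataFrame(rows)
    df.to_csv(out / "directionality.tsv", sep="\t", index=False)
    n_rev = int((df["verdict"] == "reversible").sum()) if len(df) else 0
    log.info("thermo: %d reactions evaluated, %d reversible", len(df), n_rev)
    return net, df


def _stage_scan(cfg: RunConfig, net: MetabolicNetwork, conditions, out: Path):
    solutions = smod.scan_conditions(
        net, conditions, cfg.co2_exchange_id, cfg.photon_exchange_id
    )
    table = smod.build_sensitivity_table(net, solutions)
    table = smod.classify_sensitive(table, cfg.rho_threshold)
    table.to_frame().to_csv(out / "sensitivity.tsv", sep="\t")
    pathway_summary, compartment_summary = smod.aggregate(table)
    pathway_summary.to_csv(out / "pathway_summary.tsv", sep="\t")
    compartment_summary.to_csv(out / "compartment_summary.tsv", sep="\t")
    objectives = {name: sol.objective for name, sol in solutions.items()}
    log.info("scan: %d/%d reactions sensitive; objectives %s",
             int(table.sensitive.sum()), len(table.sensitive), objectives)
    return table, solutions, objectives


def _stage_validate(cfg: RunConfig, net, table, conditions, out: Path):
    results = {}
    if cfg.qpcr_ct:
        curves, records = read_qpcr_tables(cfg.qpcr_ct, cfg.fluorescence)
        by_gene: dict[str, list] = {}
        for r in records:
            by_gene.setdefault(r.gene, []).append(r)
        refs = {g: by_gene[g] for g in cfg.reference_genes if g in by_gene}
        ratios = []
        for gene, recs in sorted(by_gene.items()):
            if gene in refs:
                continue
            try:
                er = validation.pfaffl_ratio(recs, refs, *cfg.contrast)
                ratios.append({"gene": gene, "ratio": er.ratio,
                               "reference_genes": ";".join(er.reference_genes)})
            except validation.ValidationError as exc:
                log.warning("qPCR %s skipped: %s", gene, exc)
        pd.DataFrame(ratios).to_csv(out / "expression_ratios.tsv", sep="\t", index=False)
        results["n_expression_ratios"] = len(ratios)
    if cfg.metabolites:
        table_m = read_metabolite_table(cfg.metabolites)
        normalized = validation.normalize_metabolites(table_m)
        fc = validation.log2_fold_change(
            normalized, table_m.conditions, *cfg.contrast, alpha=cfg.alpha
        )
        fc.to_csv(out / "metabolite_fc.tsv", sep="\t")
        results["n_significant_metabolites"] = int(fc["significant"].sum())
        if table is not None and cfg.metabolite_map:
            low = cfg.low_condition or conditions[0].name
            high = cfg.high_condition or conditions[-1].name
            mm = pd.read_csv(cfg.metabolite_map, sep="\t")
            name_map = dict(zip(mm["metabolite_id"], mm["analyte"]))
            shared = [m for m in sorted(net.metabolites)
                      if name_map.get(m, m) in fc.index]
            records = smod.net_flux_records(table, net, shared, low, high)
            report = validation.concordance(records, fc, name_map)
            report.to_frame().to_csv(out / "concordance.tsv", sep="\t", index=False)
            results["concordant"] = report.concordant
            results["discordant"] = report.discordant
            results["unevaluable"] = report.unevaluable
    return results


def run(config: RunConfig) -> dict:
    """Execute every configured stage; returns the run report (also written
    as ``run_report.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    base = load_network(config.base_network)
    conditions = load_conditions(config.conditions)
    report["base"] = {"metabolites": base.m, "reactions": base.n}

    net, comp_report = _stage_complement(config, base, out)
    if comp_report is not None:
        report["complement"] = comp_report.to_dict()["counts"]
        added = comp_report.added_reactions
    else:
        added = []

    net, thermo_df = _stage_thermo(config, net, added, out)
    if thermo_df is not None and len(thermo_df):
        report["thermo"] = {
            "evaluated": int(len(thermo_df)),
            "reversible": int((thermo_df["verdict"] == "reversible").sum()),
        }

    write_network(net, out / "network.tsv")
    table, solutions, objectives = _stage_scan(config, net, conditions, out)
    report["scan"] = {
        "objectives": objectives,
        "n_sensitive": int(table.sensitive.sum()),
        "n_reactions": int(len(table.sensitive)),
    }

    report["validation"] = _stage_validate(config, net, table, conditions, out)
    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


# ---------------------------------------------------------------------------
# CLI

def _build_cli():
    import click

    @click.group()
    @click.option("--log-level", default="INFO", show_default=True)
    def cli(log_level):
        """CO2-sensitivity analysis of compartmentalized metabolic models."""
        logging.basicConfig(
            stream=sys.stderr, level=getattr(logging, log_level.upper(), logging.INFO),
            format="%(asctime)s %(name)s %(levelname)s %(message)s",
        )

    @cli.command("run")
    @click.option("--config", "config_path", required=True,
                  type=click.Path(exists=True))
    @click.option("--seed", type=int, default=None)
    def run_cmd(config_path, seed):
        """Run the full pipeline from a YAML config."""
        cfg = RunConfig.from_yaml(config_path)
        if seed is not None:
            cfg.seed = seed
        report = run(cfg)
        click.echo(json.dumps(report, indent=2, sort_keys=True))

    @cli.command("synth")
    @click.option("--out", "out_dir", required=True, type=click.Path())
    @click.option("--seed", type=int, default=0, show_default=True)
    @click.option("--n-reactions", type=int, default=60, show_default=True)
    @click.option("--n-sensitive", type=int, default=6, show_default=True)
    def synth_cmd(out_dir, seed, n_reactions, n_sensitive):
        """Generate a full synthetic input bundle with ground truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bp = synthdata.NetworkBlueprint(
            n_reactions=n_reactions, n_sensitive=n_sensitive, seed=seed
        )
        net, truth = synthdata.generate_network(bp)
        write_network(net, out / "base_network.tsv")
        write_conditions(smod.default_conditions(), out / "conditions.tsv")
        catalog, hits, manifest = synthdata.generate_homology_inputs(net, truth, seed)
        pd.DataFrame(
            [{"catalog_id": c.catalog_id, "ec": c.ec, "equation": c.equation,
              "pathway": c.pathway or ""} for c in catalog]
        ).to_csv(out / "catalog.tsv", sep="\t", index=False)
        with open(out / "hits.tsv", "w") as fh:
            for h in hits:
                fh.write(f"{h.protein_id}\t{h.ec}\n")
        groups, decomp = synthdata.generate_group_tables(net, seed)
        pd.DataFrame(
            [{"group_id": g, "contribution_kj_mol": v} for g, v in sorted(groups.items())]
        ).to_csv(out / "group_table.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"metabolite_id": m, "group_id": g, "count": c}
             for m, gs in sorted(decomp.items()) for g, c in sorted(gs.items())]
        ).to_csv(out / "decompositions.tsv", sep="\t", index=False)
        obp = synthdata.OmicsBlueprint(seed=seed)
        curves, records, qpcr_truth = synthdata.generate_qpcr(obp)
        write_qpcr_tables(curves, records, out / "qpcr_ct.csv", out / "fluorescence.csv")
        table, met_truth = synthdata.generate_metabolites(obp)
        write_metabolite_table(table, out / "metabolites.csv")
        (out / "truth.json").write_text(json.dumps(
            {"network": truth, "complement": manifest, "qpcr": qpcr_truth,
             "metabolites": met_truth}, indent=2, sort_keys=True, default=str) + "\n")
        click.echo(f"synthetic bundle written to {out}")

    @cli.command("scan")
    @click.option("--network", required=True, type=click.Path(exists=True))
    @click.option("--conditions", "conditions_path", required=True,
                  type=click.Path(exists=True))
    @click.option("--out", "out_dir", required=True, type=click.Path())
    @click.option("--rho-threshold", type=float, default=smod.RHO_THRESHOLD,
                  show_default=True)
    def scan_cmd(network, conditions_path, out_dir, rho_threshold):
        """Scan CO2 conditions and classify sensitive reactions."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        net = load_network(network)
        conds = load_conditions(conditions_path)
        cfg = RunConfig(base_network=network, conditions=conditions_path,
                        out_dir=out_dir, rho_threshold=rho_threshold)
        table, _, objectives = _stage_scan(cfg, net, conds, out)
        click.echo(json.dumps({"objectives": objectives,
                               "n_sensitive": int(table.sensitive.sum())},
                              indent=2, sort_keys=True))

    return cli


cli = _build_cli()

if __name__ == "__main__":
    cli()
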