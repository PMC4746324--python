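#!/usr/bin/env python
"""Reconcile the flux predictions with qPCR and metabolomics observations.

Computes efficiency-corrected Pfaffl expression ratios (Actin reference)
against the generator truth, normalizes metabolite intensities by cell
count and TIC, tests per-analyte log2 fold changes (Welch + BH), and
scores direction concordance between the model's net sensitive fluxes and
the measured changes. Outputs go to results/validation/.
"""

import json
from pathlib import Path

import pandas as pd

from fluxsense.pipeline import read_metabolite_table, read_qpcr_tables
from fluxsense.synthdata import OmicsBlueprint, generate_concordance_truth
from fluxsense.validation import (
    concordance,
    log2_fold_change,
    normalize_metabolites,
    pfaffl_ratio,
)

SEED = 7
ROOT = Path(__file__).resolve().parent.parent / "results"
IN, OUT = ROOT / "inputs", ROOT / "validation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((IN / "truth.json").read_text())

    _, records = read_qpcr_tables(IN / "qpcr_ct.csv", IN / "fluorescence.csv")
    by_gene: dict[str, list] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    refs = {"ACT": by_gene["ACT"]}
    rows = []
    for gene in sorted(by_gene):
        if gene in ("ACT", "UBQ"):
            continue
        er = pfaffl_ratio(by_gene[gene], refs)
        rows.append({"gene": gene, "ratio": round(er.ratio, 3),
                     "true_ratio": truth["qpcr"]["expression_ratios"].get(gene)})
    ratios = pd.DataFrame(rows)
    ratios.to_csv(OUT / "expression_ratios.tsv", sep="\t", index=False)
    print("relative expression, low vs high CO2 (Pfaffl, Actin reference):")
    print(ratios.to_string(index=False))

    table = read_metabolite_table(IN / "metabolites.csv")
    fc = log2_fold_change(normalize_metabolites(table), table.conditions)
    fc.to_csv(OUT / "metabolite_fc.tsv", sep="\t")
    planted = truth["metabolites"]["planted"]
    print(f"\n{int(fc['significant'].sum())} of {len(fc)} analytes significant "
          f"(BH < 0.05); planted non-null: {len(planted)}")
    print("xylose log2FC (high vs low): "
          f"{fc.at['xylose', 'log2fc']:.2f} (planted {2.46:.2f})")

    netflux = generate_concordance_truth(OmicsBlueprint(seed=SEED))
    report = concordance(netflux, fc)
    report.to_frame().to_csv(OUT / "concordance.tsv", sep="\t", index=False)
    print(f"\nconcordance with model net fluxes: {report.concordant} concordant, "
          f"{report.discordant} discordant, {report.unevaluable} unevaluable "
          f"of {len(report.records)} compared")
    discordant = [r.metabolite_id for r in report.records if r.concordant is False]
    print("discordant metabolites:", ", ".join(discordant))


if __name__ == "__main__":
    main()
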