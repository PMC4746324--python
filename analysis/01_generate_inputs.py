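#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes a complete input bundle under results/inputs/: a base
compartmentalized network with a planted CO2-sensitive pathway, the
five-level CO2 condition table, a homology-hit table and reaction catalog,
group-contribution tables, qPCR Ct/fluorescence tables, and a metabolite
intensity table — plus truth.json recording every planted fact.
"""

import json
from pathlib import Path

import pandas as pd

from fluxsense import synthdata
from fluxsense.netcore import write_network
from fluxsense.pipeline import (
    write_conditions,
    write_metabolite_table,
    write_qpcr_tables,
)
from fluxsense.sensitivity import default_conditions

SEED = 7
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bp = synthdata.NetworkBlueprint(seed=SEED)
    net, truth = synthdata.generate_network(bp)
    write_network(net, OUT / "base_network.tsv")
    write_conditions(default_conditions(), OUT / "conditions.tsv")

    catalog, hits, manifest = synthdata.generate_homology_inputs(net, truth, SEED)
    pd.DataFrame(
        [{"catalog_id": c.catalog_id, "ec": c.ec, "equation": c.equation,
          "pathway": c.pathway or ""} for c in catalog]
    ).to_csv(OUT / "catalog.tsv", sep="\t", index=False)
    with open(OUT / "hits.tsv", "w") as fh:
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.ec}\n")

    groups, decomp = synthdata.generate_group_tables(net, SEED)
    pd.DataFrame(
        [{"group_id": g, "contribution_kj_mol": v} for g, v in sorted(groups.items())]
    ).to_csv(OUT / "group_table.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"metabolite_id": m, "group_id": g, "count": c}
         for m, gs in sorted(decomp.items()) for g, c in sorted(gs.items())]
    ).to_csv(OUT / "decompositions.tsv", sep="\t", index=False)

    obp = synthdata.OmicsBlueprint(seed=SEED)
    curves, records, qpcr_truth = synthdata.generate_qpcr(obp)
    write_qpcr_tables(curves, records, OUT / "qpcr_ct.csv", OUT / "fluorescence.csv")
    table, met_truth = synthdata.generate_metabolites(obp)
    write_metabolite_table(table, OUT / "metabolites.csv")

    (OUT / "truth.json").write_text(json.dumps(
        {"network": truth, "complement": manifest, "qpcr": qpcr_truth,
         "metabolites": met_truth}, indent=2, sort_keys=True, default=str) + "\n")

    print(f"wrote input bundle to {OUT}")
    print(f"  network: {net.m} metabolites, {net.n} reactions, "
          f"{len(truth['sensitive'])} planted sensitive, "
          f"{len(truth['pinned'])} pinned, "
          f"{len(truth['orphan_metabolites'])} planted orphans")
    print(f"  catalog: {len(catalog)} reactions, {len(hits)} homology hits")
    print(f"  omics: {len(records)} qPCR records, "
          f"{table.intensities.shape[1]} analytes x {len(table.intensities)} samples")


if __name__ == "__main__":
    main()
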