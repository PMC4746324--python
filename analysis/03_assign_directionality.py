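#!/usr/bin/env python
"""Assign directionality to the added reactions by group contribution.

Estimates each added reaction's Gibbs energy at 27 degC / pH 7 from the
bundled group tables and sets bounds: |dGr| <= 30 kJ/mol is reversible,
strongly negative stays forward, strongly positive is flipped. Writes the
energy table and the directed network under results/thermo/.
"""

import json
from pathlib import Path

import pandas as pd

from fluxsense.netcore import Metabolite, load_network, write_network
from fluxsense.thermo import (
    apply_directionality,
    estimate_dgf,
    load_decompositions,
    load_group_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
IN, COMP, OUT = ROOT / "inputs", ROOT / "complement", ROOT / "thermo"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    net = load_network(COMP / "complemented_network.tsv")
    table = load_group_table(IN / "group_table.tsv")
    decomp = load_decompositions(IN / "decompositions.tsv")
    report = json.loads((COMP / "report.json").read_text())

    energies = {}
    for mid, met in net.metabolites.items():
        groups = decomp.get(met.species_name)
        if groups is not None:
            energies[mid] = estimate_dgf(
                Metabolite(id=met.id, compartment=met.compartment,
                           group_counts=groups),
                table,
            )

    rows = []
    for rid in report["added_reactions"]:
        rxn = net.reactions[rid]
        if rxn.is_exchange:
            continue  # gap-fill sinks are boundary pseudo-reactions
        if all(m in energies for m in rxn.stoich):
            new_rxn, energy = apply_directionality(rxn, energies)
            net.reactions[rid] = new_rxn
            rows.append({"reaction_id": rid, "dgr_kj_mol": round(energy.dgr, 3),
                         "verdict": energy.verdict.value})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "directionality.tsv", sep="\t", index=False)
    write_network(net, OUT / "directed_network.tsv")

    counts = df["verdict"].value_counts().to_dict() if len(df) else {}
    print(f"evaluated {len(df)} added reactions: {counts}")
    print(f"directed network -> {OUT / 'directed_network.tsv'}")


if __name__ == "__main__":
    main()
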