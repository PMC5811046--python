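#!/usr/bin/env python
"""Generate the synthetic study system all downstream analyses consume.

Emits, under results/synthetic_data/:
  * one protein FASTA per strain (pan-genome with a core/accessory split and
    a planted core motif depletion),
  * orthology.tsv (og_id, strain, protein_id),
  * annotations.tsv (domain + TMH intervals, with motif enrichment planted
    upstream of domain starts and in non-TMH site-III windows),
  * expression.tsv and profiling.tsv (translation-efficiency table with a
    planted negative rank correlation to motif density; stall scores
    associated with predicted motif strength),
  * ground_truth.json (core labels, planted windows, generator parameters).

Sizes are desk-scale (a handful of strains, ~1,500 proteins each); every
byte is determined by --seed.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from polypro import io
from polypro.expression import motif_density_table
from polypro.motifs import StrengthClass, default_rule_table, scan_proteome
from polypro.positional import DEFAULT_TMH_SITES
from polypro.simulate import (
    SyntheticSpec,
    generate_annotations,
    generate_expression,
    generate_pangenome,
    plant_in_windows,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_data"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-strains", type=int, default=4)
    ap.add_argument("--proteome-size", type=int, default=1500)
    args = ap.parse_args()

    rules = default_rule_table()
    spec = SyntheticSpec(
        seed=args.seed,
        n_strains=args.n_strains,
        proteome_size=args.proteome_size,
        core_fraction=0.55,
        accessory_sharing_rate=0.3,
        unassigned_fraction=0.05,
        target_rho=-0.105,
    )
    data = generate_pangenome(
        spec, rules,
        core_plant={StrengthClass.WEAK: 0.4, StrengthClass.MEDIUM: 0.1},
        accessory_plant={StrengthClass.WEAK: 0.5, StrengthClass.MEDIUM: 0.125,
                         StrengthClass.STRONG: 0.05},
    )

    OUT.mkdir(parents=True, exist_ok=True)
    for strain, proteome in sorted(data["proteomes"].items()):
        io.write_fasta(proteome, OUT / f"{strain}.fasta")
    data["og_table"].to_csv(OUT / "orthology.tsv", sep="\t", index=False)

    # reference strain gets annotations with planted positional structure
    ref = sorted(data["proteomes"])[0]
    proteome = data["proteomes"][ref]
    ann = generate_annotations(spec, proteome, tmh_fraction=0.25)
    boundary_windows = [
        (pid, max(s - 12, 3), s - 2)
        for pid, ivs in ann["domains"].intervals.items()
        for s, _ in ivs
        if s > 14
    ]
    proteome, planted_boundary = plant_in_windows(
        proteome, boundary_windows, StrengthClass.WEAK, 0.4, seed=spec.seed, stream=101
    )
    lo, hi = DEFAULT_TMH_SITES["III"]
    site_windows = []
    for pid, ivs in ann["tmh"].intervals.items():
        for s, _ in ivs:
            a, b = s + lo, s + hi
            if a >= 3 and b <= len(proteome[pid]) - 3 and not any(
                x <= (a + b) // 2 <= y for x, y in ivs
            ):
                site_windows.append((pid, a, b))
    proteome, planted_site = plant_in_windows(
        proteome, site_windows, StrengthClass.WEAK, 0.5, seed=spec.seed, stream=102
    )
    data["proteomes"][ref] = proteome
    io.write_fasta(proteome, OUT / f"{ref}.fasta")  # overwrite with plantings
    io.write_annotation_tracks([ann["domains"], ann["tmh"]], OUT / "annotations.tsv")

    # expression for the reference strain, correlated with motif density
    table, counts = scan_proteome(proteome, rules)
    densities = motif_density_table(proteome, counts.to_dict())
    strong = table[table["strength"].isin(["MEDIUM", "STRONG"])]["protein_id"]
    max_strength = {pid: StrengthClass.MEDIUM for pid in strong}
    expr = generate_expression(spec, densities.to_dict(), max_strength=max_strength)
    expr["expression"].rename(
        columns={"protein_abundance": "abundance", "transcription_level": "transcription"}
    ).to_csv(OUT / "expression.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": list(expr["stall_scores"]), "asymmetry_score": list(expr["stall_scores"].values())}
    ).to_csv(OUT / "profiling.tsv", sep="\t", index=False)

    truth = {
        "seed": args.seed,
        "reference_strain": ref,
        "core_labels": data["true_labels"].to_dict(),
        "planted_boundary_motifs": planted_boundary,
        "planted_site3_motifs": planted_site,
        "target_rho": spec.target_rho,
    }
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(truth, fh)

    n_prot = sum(len(p) for p in data["proteomes"].values())
    print(f"wrote {args.n_strains} strain FASTAs ({n_prot} proteins), orthology, "
          f"annotations ({sum(len(v) for v in ann['domains'].intervals.values())} domains, "
          f"{sum(len(v) for v in ann['tmh'].intervals.values())} TMHs), expression "
          f"({len(expr['expression'])} genes) to {OUT}")
    print(f"planted: {len(planted_boundary)} boundary motifs, "
          f"{len(planted_site)} site-III motifs, core motif density 0.8x accessory")


if __name__ == "__main__":
    main()
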