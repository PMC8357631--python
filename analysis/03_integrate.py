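"""Integrate Ub-site changes with protein levels; rescue and summaries.

Joins the day-15-vs-day-5 site and protein contrasts, classifies every
significant Ub-site change against its protein's behaviour (concordant /
inverse / stable / not quantified), scores which wild-type ageing
changes are rescued in the long-lived eat-2 and daf-2 mutants, and
tallies synthetic E3/DUB family and tissue annotations (the maps are
generated here and are synthetic stand-ins for curated annotation
lists).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ubage.integration import (
    classify_change,
    family_summary,
    join_site_protein,
    proteins_site_down_protein_up,
    rescue_analysis,
    tissue_summary,
)
from ubage.io_tables import read_differential_table, write_results

BASE = Path(__file__).resolve().parents[1]
OUT = BASE / "results"
SEED = 1
TISSUES = ("germline", "intestine", "muscle", "neuron", "epidermis")


def synthetic_annotation_maps(protein_ids, rng):
    """Random E3/DUB family and tissue maps over the synthetic proteome."""
    ids = list(protein_ids)
    rng.shuffle(ids)
    families = {pid: "E3" for pid in ids[:170]}
    families.update({pid: "DUB" for pid in ids[170:215]})
    tissue_map = {
        pid: list(rng.choice(TISSUES, size=rng.integers(1, 3), replace=False))
        for pid in ids
    }
    return families, tissue_map


def main() -> None:
    site = read_differential_table(OUT / "site_diff_WT_d15_vs_d5.tsv")
    protein = read_differential_table(OUT / "protein_diff_WT_d15_vs_d5.tsv")
    records = classify_change(join_site_protein(site, protein), 0.05)
    part = records["protein_status"].value_counts()
    print("significant Ub-site changes vs their protein (WT d15/d5):")
    print(part.to_string())
    down_up = proteins_site_down_protein_up(records)
    print(f"\nproteins less ubiquitinated at >= 1 site while accumulating: {len(down_up)}")

    mutant = {
        g: read_differential_table(OUT / f"site_diff_{g}_d15_vs_d5.tsv")
        for g in ("eat-2", "daf-2")
    }
    rescue = rescue_analysis(site, mutant, "within_strain")
    for g in ("eat-2", "daf-2"):
        frac = rescue[f"rescued_{g}"].mean()
        print(f"WT ageing changes rescued in {g}: {100 * frac:.0f}%")

    rng = np.random.default_rng(SEED)
    families, tissue_map = synthetic_annotation_maps(protein.index, rng)
    fam = family_summary(protein, families)
    tis = tissue_summary(records, tissue_map)
    print("\nE3/DUB family summary (synthetic annotation):")
    print(fam.to_string())

    write_results(
        {
            "change_records": records,
            "rescue": rescue,
            "family_summary": fam.reset_index(),
            "tissue_summary": tis.reset_index(),
        },
        OUT,
    )
    pd.Series(families, name="family").rename_axis("protein_id").reset_index().to_csv(
        OUT / "synthetic_family_map.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
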