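"""Triangulate age-dysregulated proteasome targets and annotate linkage.

Intersects the rpn-6-knockdown evidence (protein and Ub-site both up)
with the ageing evidence (protein up while >= 1 site deubiquitinated),
annotates each candidate's polyubiquitin linkage from the K48/K63 IP
enrichment contrasts, and scores recovery against the planted ground
truth.
"""

from pathlib import Path

import pandas as pd

from ubage.io_tables import read_differential_table, write_results
from ubage.synthetic_data import evaluate_recovery
from ubage.target_inference import (
    age_dysregulated_targets,
    annotate_linkage,
    enriched_set,
    near_misses,
    rpn6_upregulated_set,
)

BASE = Path(__file__).resolve().parents[1]
OUT = BASE / "results"


def main() -> None:
    rpn6_site = read_differential_table(OUT / "site_diff_rpn6_vs_vector.tsv")
    rpn6_prot = read_differential_table(OUT / "protein_diff_rpn6_vs_vector.tsv")
    records = pd.read_csv(OUT / "change_records.tsv", sep="\t", index_col=0)
    age_prot = read_differential_table(OUT / "protein_diff_WT_d15_vs_d5.tsv")

    rpn6_set = rpn6_upregulated_set(rpn6_site, rpn6_prot)
    print(f"proteins up in both total and Ub-peptide level after rpn-6 RNAi: {len(rpn6_set)}")

    targets = age_dysregulated_targets(rpn6_set, records, age_prot, rpn6_site, rpn6_prot)
    k48 = enriched_set(read_differential_table(OUT / "protein_diff_K48_vs_Flag.tsv"))
    k63 = enriched_set(read_differential_table(OUT / "protein_diff_K63_vs_Flag.tsv"))
    targets = annotate_linkage(targets, k48, k63)

    candidates = targets[targets["is_candidate"]]
    print(f"age-dysregulated proteasome targets: {len(candidates)}")
    for pid, row in candidates.iterrows():
        print(f"  {pid}  linkage={row['linkage']}")
    print(f"near-misses (3 of 4 evidence flags): {len(near_misses(targets))}")

    truth = pd.read_csv(OUT / "data" / "truth_proteins.tsv", sep="\t", index_col=0)
    planted = set(truth.index[truth["effect_class"] == "proteasome_target"])
    rec = evaluate_recovery(set(candidates.index), planted)
    print(f"recovery vs planted truth: precision {rec['precision']:.2f}, "
          f"recall {rec['recall']:.2f} ({rec['tp']}/{len(planted)} targets found)")

    write_results({"targets": targets}, OUT)


if __name__ == "__main__":
    main()
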