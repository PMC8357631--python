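"""Differential abundance of Ub-peptides and proteins with permutation FDR.

Reads the raw tables written by 01_simulate.py, runs the full contrast
battery (per-genotype ages vs day 1, day 15 vs day 5, cross-strain aged
comparisons, rpn-6 knockdown, linkage IPs), and writes per-contrast
differential tables, the up/down count summary and the per-genotype
heatmap matrices (features significant at >= 1 age) under results/.
"""

from pathlib import Path

from ubage.differential import summarize_counts
from ubage.io_tables import (
    export_heatmap_matrix,
    filter_flagged,
    read_annotations,
    read_quant_table_tsv,
    write_results,
)
from ubage.workflow import PipelineConfig, default_contrasts, prepare_and_test

BASE = Path(__file__).resolve().parents[1]
DATA = BASE / "results" / "data"
OUT = BASE / "results"
SEED = 1


def main() -> None:
    ann = read_annotations(DATA / "annotations.tsv")
    site = filter_flagged(read_quant_table_tsv(DATA / "sites.tsv"))
    protein = filter_flagged(read_quant_table_tsv(DATA / "proteins.tsv"))
    config = PipelineConfig(seed=SEED, inputs={})
    specs = default_contrasts(ann, config)

    ip_names = {"K48_vs_Flag", "K63_vs_Flag"}
    protein_names = {"WT_d15_vs_d5", "rpn6_vs_vector"} | ip_names
    tables = {}
    site_diffs = {}
    for name, spec in specs.items():
        if name not in ip_names:
            site_diffs[name] = prepare_and_test(site, spec, config)
            tables[f"site_diff_{name}"] = site_diffs[name]
        if name in protein_names:
            tables[f"protein_diff_{name}"] = prepare_and_test(protein, spec, config)

    counts = summarize_counts(site_diffs)
    tables["counts"] = counts.reset_index()
    for geno in ("WT", "eat-2", "daf-2"):
        per_age = {d: site_diffs[f"{geno}_d{d}_vs_d1"] for d in (5, 10, 15)}
        tables[f"heatmap_{geno}"] = export_heatmap_matrix(per_age, f"{geno}_d1")

    write_results(tables, OUT)
    print(counts.round(1).to_string())
    main_row = counts.loc["WT_d15_vs_d5"]
    print(f"\nWT day 15 vs day 5: {int(main_row['up'])} Ub-peptides up, "
          f"{int(main_row['down'])} down — ageing skews toward deubiquitination "
          f"({main_row['down_pct']:.0f}% of changes are losses)")
    for geno in ("WT", "eat-2", "daf-2"):
        print(f"heatmap_{geno}: {len(tables[f'heatmap_{geno}'])} Ub-peptides "
              f"significant at >= 1 age")


if __name__ == "__main__":
    main()
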