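"""Generate the synthetic ubiquitinome ageing study.

Emulates the full design — 3 genotypes (WT, eat-2, daf-2) x adulthood
days {1, 5, 10, 15} x 4 replicates, a day-5 rpn-6-RNAi-vs-vector contrast
(n = 3) and K48/K63/Flag immunoprecipitations (n = 3) — with planted
effect classes and intensity-dependent missingness, and writes the raw
site table, protein table, sample annotations and ground truth under
results/data/.
"""

from pathlib import Path

from ubage.io_tables import write_quant_table, write_results
from ubage.synthetic_data import SimulationParams, default_design, simulate_experiment

BASE = Path(__file__).resolve().parents[1]
OUT = BASE / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = SimulationParams(seed=SEED)
    design = default_design()
    site, protein, truth = simulate_experiment(design, params)

    write_quant_table(site, OUT / "sites.tsv")
    write_quant_table(protein, OUT / "proteins.tsv")
    design.to_csv(OUT / "annotations.tsv", sep="\t", index=False)
    write_results({"truth_proteins": truth.proteins, "truth_sites": truth.sites}, OUT)

    n_missing = site.intensities.isna().mean().mean()
    print(f"simulated {site.n_features} diGly sites on {protein.n_features} proteins "
          f"across {len(design)} samples (seed {SEED})")
    print(f"site-level missingness: {100 * n_missing:.1f}% of cells")
    print(f"planted classes:\n{truth.proteins['effect_class'].value_counts().to_string()}")
    print(f"wrote raw tables to {OUT}")


if __name__ == "__main__":
    main()
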