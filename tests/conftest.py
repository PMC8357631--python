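import numpy as np
import pandas as pd
import pytest

from ubage.io_tables import PROTEIN, SITE, QuantTable
from ubage.synthetic_data import SimulationParams, default_design, simulate_experiment


def make_site_tsv(path, rows, intensity_cols=("Intensity s1", "Intensity s2")):
    """Write a minimal MaxQuant-like diGly site TSV."""
    header = ["Protein", "Position", "Modified sequence", "Reverse",
              "Potential contaminant", "Only identified by site", *intensity_cols]
    lines = ["\t".join(header)]
    for r in rows:
        lines.append("\t".join(str(x) for x in r))
    path.write_text("\n".join(lines) + "\n")
    return path


def make_quant_table(values, samples, level=SITE, protein_ids=None, scale="log2"):
    """QuantTable from a plain 2-D array; feature ids F0, F1, ..."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = [f"F{i}" for i in range(n)]
    protein_ids = protein_ids or [f"P{i}" for i in range(n)]
    features = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "site_position": [10] * n if level == SITE else [np.nan] * n,
            "peptide": [f"PEP{i}" for i in range(n)] if level == SITE else [""] * n,
            "reverse": False,
            "contaminant": False,
            "only_by_site": False,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    intens = pd.DataFrame(values, index=features.index, columns=list(samples))
    return QuantTable(level=level, features=features, intensities=intens, scale=scale)


def diff_table(rows):
    """Differential-result DataFrame from (feature_id, protein_id, log2_fc, q) tuples."""
    df = pd.DataFrame(
        rows, columns=["feature_id", "protein_id", "log2_fc", "q_value"]
    ).set_index("feature_id")
    df["site_position"] = 10.0
    df["t_stat"] = np.sign(df["log2_fc"]) * 5.0
    df["p_value"] = df["q_value"] / 2
    df["significant"] = df["q_value"] < 0.05
    df["n_valid_a"] = 4
    df["n_valid_b"] = 4
    return df


@pytest.fixture(scope="session")
def small_experiment():
    """One simulated experiment shared by read-only tests."""
    params = SimulationParams(n_proteins=200, seed=7)
    design = default_design()
    site, protein, truth = simulate_experiment(design, params)
    return design, params, site, protein, truth
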