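"""Integrate site-level and protein-level differential results.

A significant change in a diGly site can reflect a genuine change in
ubiquitination occupancy, or merely track the abundance of its parent
protein. This module joins the two levels on the protein's leading
accession and classifies every significant site change against its
protein's behaviour (concordant / inverse / stable / not quantified),
derives the proteins that lose ubiquitination while accumulating
(candidate impaired-degradation substrates), scores rescue of wild-type
ageing changes in long-lived genotypes, and tallies annotation families
(E3 ligases, deubiquitinases) and predicted tissues.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import ValidationError

STRICT = "strict"
SIGN_ONLY = "sign_only"

PROTEIN_STATUSES = ("concordant", "inverse", "stable", "not_quantified")


def join_site_protein(
    site_diff: pd.DataFrame, protein_diff: pd.DataFrame
) -> pd.DataFrame:
    """Left-join site differential rows with their protein's row.

    Both tables must come from the same biological contrast. Protein-level
    columns arrive with a ``protein_`` prefix; sites whose protein has no
    row keep NaN there and will classify as ``not_quantified``.
    """
    prot = protein_diff[["log2_fc", "t_stat", "p_value", "q_value", "significant"]]
    prot = prot.add_prefix("protein_")
    joined = site_diff.join(prot, on="protein_id")
    joined["protein_quantified"] = joined["protein_q_value"].notna()
    return joined


def classify_change(
    joined: pd.DataFrame,
    fdr_threshold: float = 0.05,
    mode: str = STRICT,
) -> pd.DataFrame:
    """Classify each significant site change against its protein.

    One record per site with ``q_value < fdr_threshold``. In ``strict``
    mode the protein must itself be significant to count as concordant or
    inverse; in ``sign_only`` mode any quantified protein with a non-zero
    fold change of matching (opposing) sign is concordant (inverse), and
    ``stable`` is reserved for an exactly zero protein fold change. The
    four statuses partition the significant sites exhaustively.
    """
    if mode not in (STRICT, SIGN_ONLY):
        raise ValidationError(f"unknown classification mode {mode!r}")
    sig = joined[joined["q_value"] < fdr_threshold].copy()
    records = pd.DataFrame(index=sig.index)
    records["protein_id"] = sig["protein_id"]
    records["site_position"] = sig["site_position"]
    records["site_direction"] = np.where(sig["log2_fc"] > 0, "up", "down")
    records["site_log2_fc"] = sig["log2_fc"]
    records["protein_log2_fc"] = sig["protein_log2_fc"]

    same_sign = np.sign(sig["protein_log2_fc"]) == np.sign(sig["log2_fc"])
    if mode == STRICT:
        prot_sig = sig["protein_q_value"] < fdr_threshold
        concordant = prot_sig & same_sign
        inverse = prot_sig & ~same_sign
        stable = ~prot_sig
    else:
        nonzero = sig["protein_log2_fc"] != 0
        concordant = nonzero & same_sign
        inverse = nonzero & ~same_sign
        stable = ~nonzero
    status = np.select(
        [~sig["protein_quantified"], concordant, inverse, stable],
        ["not_quantified", "concordant", "inverse", "stable"],
        default="stable",
    )
    records["protein_status"] = status
    records.loc[records["protein_status"] == "not_quantified", "protein_log2_fc"] = np.nan
    return records


def proteins_site_down_protein_up(records: pd.DataFrame) -> set[str]:
    """Proteins less ubiquitinated at >= 1 lysine while more abundant.

    From one contrast's change-class records: distinct proteins with at
    least one site going down whose protein status is inverse (the protein
    therefore going up).
    """
    mask = (records["site_direction"] == "down") & (records["protein_status"] == "inverse")
    return set(records.loc[mask, "protein_id"])


# ---------------------------------------------------------------------------
# rescue in long-lived genotypes
# ---------------------------------------------------------------------------

WITHIN_STRAIN = "within_strain"
CROSS_STRAIN = "cross_strain"


def rescue_analysis(
    wt_diff: pd.DataFrame,
    mutant_diffs: Mapping[str, pd.DataFrame],
    mode: str = WITHIN_STRAIN,
    fdr_threshold: float = 0.05,
    genotypes: Sequence[str] = ("eat-2", "daf-2"),
) -> pd.DataFrame:
    """Which wild-type ageing changes disappear in long-lived mutants.

    One record per site significant in the wild-type ageing contrast.
    ``within_strain`` mode asks whether the mutant's own ageing contrast
    reproduces the change: rescued if the site is not significant there,
    or significant with the opposite sign. ``cross_strain`` mode uses
    mutant-versus-wild-type contrasts at the aged time point: rescued if
    that contrast is significant with sign opposite to the wild-type
    ageing change. ``rescued_in`` lists the rescuing genotypes.
    """
    if mode not in (WITHIN_STRAIN, CROSS_STRAIN):
        raise ValidationError(f"unknown rescue mode {mode!r}")
    missing = [g for g in genotypes if g not in mutant_diffs]
    if missing:
        raise ValidationError(f"no differential table supplied for genotypes {missing}")

    sig = wt_diff[wt_diff["significant"]]
    out = pd.DataFrame(index=sig.index)
    out["protein_id"] = sig["protein_id"]
    out["wt_direction"] = np.where(sig["log2_fc"] > 0, "up", "down")
    out["wt_log2_fc"] = sig["log2_fc"]
    out["mode"] = mode

    rescued_lists = [[] for _ in range(len(sig))]
    for geno in genotypes:
        mut = mutant_diffs[geno].reindex(sig.index)
        mut_sig = (mut["q_value"] < fdr_threshold).fillna(False).to_numpy()
        opposite = (np.sign(mut["log2_fc"]) != np.sign(sig["log2_fc"])).to_numpy()
        if mode == WITHIN_STRAIN:
            rescued = ~mut_sig | (mut_sig & opposite)
        else:
            rescued = mut_sig & opposite
        out[f"rescued_{geno}"] = rescued
        for i, r in enumerate(rescued):
            if r:
                rescued_lists[i].append(geno)
    out["rescued_in"] = [",".join(lst) for lst in rescued_lists]
    return out


# ---------------------------------------------------------------------------
# annotation summaries
# ---------------------------------------------------------------------------


def family_summary(
    protein_diff: pd.DataFrame, families: Mapping[str, str]
) -> pd.DataFrame:
    """Significant-member counts per annotation family (E3 / DUB / other).

    ``families`` maps protein ids to a family label; unmapped proteins
    count under ``other``. Families with no member present are absent
    from the output rather than zero rows.
    """
    fam = protein_diff.index.to_series().map(lambda p: families.get(p, "other"))
    sig = protein_diff["significant"]
    up = sig & (protein_diff["log2_fc"] > 0)
    down = sig & (protein_diff["log2_fc"] < 0)
    out = pd.DataFrame(
        {
            "up": up.groupby(fam).sum(),
            "down": down.groupby(fam).sum(),
            "unchanged": (~sig).groupby(fam).sum(),
        }
    ).astype(int)
    out.index.name = "family"
    return out


def tissue_summary(
    records: pd.DataFrame, tissue_map: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Per-tissue counts of proteins with down / up site changes.

    ``tissue_map`` maps protein ids to an iterable of tissue labels; a
    protein contributes once to every tissue it maps to. Proteins without
    a mapping are dropped (the prediction database does not cover them).
    """
    counts: dict[str, dict[str, set]] = {}
    for _, row in records.iterrows():
        for tissue in tissue_map.get(row["protein_id"], ()):  # multi-label join
            bucket = counts.setdefault(tissue, {"down": set(), "up": set()})
            bucket[row["site_direction"]].add(row["protein_id"])
    rows = [
        {"tissue": t, "down": len(b["down"]), "up": len(b["up"])}
        for t, b in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["tissue", "down", "up"]).set_index("tissue")


def read_annotation_map(path) -> dict[str, str]:
    """Two-column TSV (protein_id, label) to a dict."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValidationError(f"annotation map {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_tissue_map(path) -> dict[str, list[str]]:
    """Two-column TSV (protein_id, comma-separated tissues) to a dict."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValidationError(f"tissue map {path} needs two columns")
    return {
        pid: [t.strip() for t in str(ts).split(",") if t.strip()]
        for pid, ts in zip(df.iloc[:, 0], df.iloc[:, 1])
    }
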