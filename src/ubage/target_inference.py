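"""Triangulation of age-dysregulated proteasome targets.

A protein qualifies as a candidate proteasome target when four lines of
evidence intersect: under proteasome knockdown (rpn-6 RNAi versus vector
RNAi in young adults) both its total level and at least one of its
ubiquitination sites go up; and in untreated ageing (day 15 versus day 5)
its total level goes up while at least one lysine site is significantly
less ubiquitinated. Candidates are then annotated with their
polyubiquitin linkage type from K48- and K63-specific
immunoprecipitation enrichment against a control anti-Flag pull-down:
K48 linkage is the canonical proteasomal degradation signal.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .differential import ContrastSpec, run_contrast
from .integration import SIGN_ONLY, STRICT, proteins_site_down_protein_up
from .io_tables import QuantTable, ValidationError

LINKAGE_LABELS = ("K48", "K63", "both", "none", "unknown")


def rpn6_upregulated_set(
    site_diff_rpn6: pd.DataFrame,
    protein_diff_rpn6: pd.DataFrame,
    fdr_threshold: float = 0.05,
    mode: str = STRICT,
) -> set[str]:
    """Proteins up in both total and Ub-peptide level after rpn-6 RNAi.

    Both inputs must be oriented rpn-6 RNAi minus vector RNAi. A protein
    qualifies with a significant positive protein-level change plus at
    least one qualifying site: significant and positive in ``strict``
    mode, merely positive in ``sign_only`` mode.
    """
    prot_up = protein_diff_rpn6["significant"] & (protein_diff_rpn6["log2_fc"] > 0)
    proteins_up = set(protein_diff_rpn6.index[prot_up])
    if mode == STRICT:
        site_up = site_diff_rpn6["significant"] & (site_diff_rpn6["log2_fc"] > 0)
    elif mode == SIGN_ONLY:
        site_up = site_diff_rpn6["log2_fc"] > 0
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    proteins_with_site_up = set(site_diff_rpn6.loc[site_up, "protein_id"])
    return proteins_up & proteins_with_site_up


def age_dysregulated_targets(
    rpn6_set: Iterable[str],
    age_records: pd.DataFrame,
    age_protein_diff: pd.DataFrame,
    site_diff_rpn6: pd.DataFrame | None = None,
    protein_diff_rpn6: pd.DataFrame | None = None,
    mode: str = STRICT,
) -> pd.DataFrame:
    """Intersect the rpn-6 evidence with the ageing evidence.

    ``age_records`` are change-class records of the wild-type day-15
    versus day-5 site contrast; ``age_protein_diff`` the matching
    protein-level contrast. Candidates carry all four evidence flags;
    the full flag table is returned for every protein in the union of the
    evidence sets so near-misses (3 of 4 flags) remain auditable. When
    the rpn-6 differential tables are supplied, the two rpn-6 flags are
    recomputed per protein rather than collapsed into membership of
    ``rpn6_set``.
    """
    rpn6_set = set(rpn6_set)
    age_set = proteins_site_down_protein_up(age_records)

    if protein_diff_rpn6 is not None:
        rpn6_protein_up = set(
            protein_diff_rpn6.index[
                protein_diff_rpn6["significant"] & (protein_diff_rpn6["log2_fc"] > 0)
            ]
        )
    else:
        rpn6_protein_up = rpn6_set
    if site_diff_rpn6 is not None:
        if mode == SIGN_ONLY:
            up = site_diff_rpn6["log2_fc"] > 0
        else:
            up = site_diff_rpn6["significant"] & (site_diff_rpn6["log2_fc"] > 0)
        rpn6_site_up = set(site_diff_rpn6.loc[up, "protein_id"])
    else:
        rpn6_site_up = rpn6_set

    age_protein_up = set(
        age_protein_diff.index[
            age_protein_diff["significant"] & (age_protein_diff["log2_fc"] > 0)
        ]
    )
    down_sites = age_records[
        (age_records["site_direction"] == "down")
        & (age_records["protein_status"].isin(["inverse", "stable", "not_quantified"]))
    ]
    age_site_down = set(
        age_records.loc[age_records["site_direction"] == "down", "protein_id"]
    )

    universe = sorted(rpn6_set | age_set | (rpn6_protein_up & rpn6_site_up))
    out = pd.DataFrame(index=pd.Index(universe, name="protein_id"))
    out["rpn6_protein_up"] = [p in rpn6_protein_up for p in universe]
    out["rpn6_site_up"] = [p in rpn6_site_up for p in universe]
    out["age_protein_up"] = [p in age_protein_up for p in universe]
    out["age_site_down"] = [p in age_site_down for p in universe]
    flags = out[["rpn6_protein_up", "rpn6_site_up", "age_protein_up", "age_site_down"]]
    out["n_flags"] = flags.sum(axis=1)
    # all four flags true is equivalent to membership of both parent sets:
    # the rpn-6 pair reconstructs rpn6_set and a significant down site on a
    # significantly-up protein is by construction an inverse record
    out["is_candidate"] = [p in rpn6_set and p in age_set for p in universe]
    out["linkage"] = "unknown"
    # supporting site keys per criterion, for audit
    site_keys = (
        down_sites.reset_index()
        .groupby("protein_id")["feature_id"]
        .apply(lambda s: ";".join(sorted(s)))
        if "feature_id" in down_sites.reset_index().columns
        else pd.Series(dtype=object)
    )
    out["age_down_site_keys"] = site_keys.reindex(universe).fillna("")
    return out


def near_misses(targets: pd.DataFrame) -> pd.DataFrame:
    """Proteins satisfying exactly three of the four evidence flags."""
    return targets[(targets["n_flags"] == 3) & ~targets["is_candidate"]]


def ip_enrichment(
    ip_table: QuantTable, spec: ContrastSpec
) -> pd.DataFrame:
    """Differential table of an IP versus its Flag-antibody control.

    ``spec.group_a`` are the linkage-specific IP samples, ``spec.group_b``
    the control pull-down; a protein is *enriched* when significant with
    positive log2 fold change (membership queried via
    :func:`enriched_set`).
    """
    return run_contrast(ip_table, spec)


def enriched_set(ip_diff: pd.DataFrame) -> set[str]:
    """Proteins significantly enriched (positive fold change) in an IP."""
    mask = ip_diff["significant"] & (ip_diff["log2_fc"] > 0)
    return set(ip_diff.loc[mask, "protein_id"])


def annotate_linkage(
    targets: pd.DataFrame,
    k48_enriched: Iterable[str] | None,
    k63_enriched: Iterable[str] | None,
) -> pd.DataFrame:
    """Label each target's polyubiquitin linkage from IP enrichment sets.

    ``K48`` / ``K63`` when enriched in only one pull-down, ``both`` when
    in both, ``none`` when IP data were supplied but the protein is in
    neither set, ``unknown`` when IP data are absent.
    """
    out = targets.copy()
    if k48_enriched is None and k63_enriched is None:
        out["linkage"] = "unknown"
        return out
    k48 = set(k48_enriched or ())
    k63 = set(k63_enriched or ())
    labels = []
    for pid in out.index:
        in48, in63 = pid in k48, pid in k63
        labels.append(
            "both" if in48 and in63 else "K48" if in48 else "K63" if in63 else "none"
        )
    out["linkage"] = labels
    return out
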