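"""Reading, validating, filtering and writing quantification tables.

The input dialect mirrors MaxQuant-style outputs: a diGly (K-epsilon-GG)
site table whose features are (protein accession, lysine position, modified
peptide) triples, and a protein-group table whose features are protein
groups carrying the usual ``Reverse`` / ``Potential contaminant`` / ``Only
identified by site`` quality flags. Intensities are raw label-free
quantification (LFQ) values, one column per sample; a zero or empty cell
means the feature was not quantified in that sample and is treated as
missing.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE = "site"
PROTEIN = "protein"
RAW = "raw"
LOG2 = "log2"

#: feature-metadata columns carried by every QuantTable
FEATURE_COLUMNS = ("protein_id", "site_position", "peptide")
FLAG_COLUMNS = ("reverse", "contaminant", "only_by_site")

#: default dialect column names (MaxQuant-like); overridable via column_map
DEFAULT_COLUMN_MAP = {
    "protein_id": "Protein",
    "site_position": "Position",
    "peptide": "Modified sequence",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
    "localization_prob": "Localization prob",
    "intensity_prefix": "Intensity ",
}

GENOTYPES = ("WT", "eat-2", "daf-2", "other")


class FormatError(ValueError):
    """A mandatory column is absent or unparseable."""


class ValidationError(ValueError):
    """Table content violates a structural invariant."""


def leading_accession(protein_group: str) -> str:
    """Leading accession of a protein group: text before the first ';'.

    This is the deterministic join key between site and protein tables.
    """
    return str(protein_group).split(";")[0].strip()


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ("sample_id", "genotype", "day", "treatment", "replicate")


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-annotation table and return it with canonical dtypes.

    Required columns: sample_id, genotype, day, treatment, replicate.
    sample_id and the (genotype, day, treatment, replicate) tuple must both
    be unique within a design.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in annotations.columns]
    if missing:
        raise FormatError(f"sample annotation lacks columns: {missing}")
    ann = annotations.copy()
    ann["day"] = ann["day"].astype(int)
    ann["replicate"] = ann["replicate"].astype(int)
    if (ann["day"] < 0).any():
        raise ValidationError("negative adulthood day")
    if (ann["replicate"] < 1).any():
        raise ValidationError("replicate numbers start at 1")
    bad = sorted(set(ann["genotype"]) - set(GENOTYPES))
    if bad:
        raise ValidationError(f"unknown genotypes: {bad}")
    dup = ann["sample_id"][ann["sample_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate sample ids: {dup}")
    key = ann[["genotype", "day", "treatment", "replicate"]].apply(tuple, axis=1)
    dup = key[key.duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate design cells: {dup}")
    return ann.reset_index(drop=True)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation TSV."""
    return validate_annotations(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# QuantTable
# ---------------------------------------------------------------------------


@dataclass
class QuantTable:
    """Features x samples intensity matrix with feature keys and flags.

    Parameters
    ----------
    level
        ``"site"`` (diGly peptide features) or ``"protein"`` (protein
        groups).
    features
        DataFrame indexed by a unique feature id, with columns
        ``protein_id`` (leading accession), ``site_position`` (lysine
        residue number; NaN for protein-level rows), ``peptide`` (modified
        peptide sequence; empty for protein-level rows) and the boolean
        quality flags ``reverse``, ``contaminant``, ``only_by_site``.
    intensities
        DataFrame with the same index, one column per sample; NaN marks a
        missing (unquantified) cell.
    scale
        ``"raw"`` or ``"log2"``. Scale transitions happen only through
        :func:`ubage.preprocess.log2_transform`.
    """

    level: str
    features: pd.DataFrame
    intensities: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.level not in (SITE, PROTEIN):
            raise ValidationError(f"unknown level {self.level!r}")
        if self.scale not in (RAW, LOG2):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not self.features.index.equals(self.intensities.index):
            raise ValidationError("features and intensities indexes differ")
        if self.features.index.has_duplicates:
            dups = self.features.index[self.features.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature keys: {dups}")
        if self.scale == RAW and (self.intensities.to_numpy() < 0).any():
            raise ValidationError("negative raw intensities")
        if self.level == SITE and self.features["site_position"].isna().any():
            raise ValidationError("site-level features need a site_position")

    # -- convenience ------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def subset_samples(self, sample_ids: Sequence[str]) -> "QuantTable":
        missing = [s for s in sample_ids if s not in self.intensities.columns]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        return replace(self, intensities=self.intensities[list(sample_ids)])

    def copy(self) -> "QuantTable":
        return QuantTable(
            self.level, self.features.copy(), self.intensities.copy(), self.scale
        )


def make_feature_index(features: pd.DataFrame, level: str) -> pd.Index:
    """Canonical unique feature id: accession for proteins,
    ``accession_K<pos>_<peptide>`` for sites."""
    if level == PROTEIN:
        return pd.Index(features["protein_id"].astype(str), name="feature_id")
    pos = features["site_position"].astype(int).astype(str)
    pep = features["peptide"].fillna("").astype(str)
    return pd.Index(
        features["protein_id"].astype(str) + "_K" + pos + "_" + pep, name="feature_id"
    )


def read_quant_table(
    path: str | Path,
    level: str,
    column_map: Mapping[str, str] | None = None,
    intensity_columns: Sequence[str] | None = None,
    min_localization_prob: float | None = None,
) -> QuantTable:
    """Read a tab-separated site or protein-group table.

    Intensity columns are either listed explicitly (``intensity_columns``,
    which wins) or discovered by the ``intensity_prefix`` convention in the
    column map (default ``"Intensity "``); the sample id is the column name
    with the prefix stripped. Zero and empty intensity cells are marked
    missing; flags use the literal ``"+"`` convention.

    ``min_localization_prob`` optionally drops site rows whose diGly
    localization probability falls below the threshold (commonly 0.75);
    the filter is off by default and ignored when the column is absent.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if min_localization_prob is not None and level == SITE:
        col = cmap.get("localization_prob")
        if col in df.columns:
            prob = pd.to_numeric(df[col], errors="coerce")
            n0 = len(df)
            df = df[prob >= min_localization_prob].reset_index(drop=True)
            logger.info(
                "localization filter >= %.2f removed %d of %d site rows",
                min_localization_prob, n0 - len(df), n0,
            )
        else:
            logger.warning(
                "min_localization_prob set but column %r absent in %s", col, path
            )

    required = ["protein_id"] + (["site_position", "peptide"] if level == SITE else [])
    for key in required:
        if cmap[key] not in df.columns:
            raise FormatError(f"missing mandatory column {cmap[key]!r} in {path}")

    features = pd.DataFrame(
        {"protein_id": df[cmap["protein_id"]].map(leading_accession)}
    )
    if level == SITE:
        try:
            features["site_position"] = df[cmap["site_position"]].astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric site positions in {path}: {exc}") from exc
        features["peptide"] = df[cmap["peptide"]]
    else:
        features["site_position"] = np.nan
        features["peptide"] = ""
    for flag in FLAG_COLUMNS:
        col = cmap.get(flag)
        if col in df.columns:
            features[flag] = df[col].astype(str).str.strip() == "+"
        else:
            features[flag] = False
            logger.warning("flag column %r absent in %s; treating as false", col, path)

    if intensity_columns is not None:
        missing = [c for c in intensity_columns if c not in df.columns]
        if missing:
            raise FormatError(f"missing intensity columns {missing} in {path}")
        icols = list(intensity_columns)
        sample_ids = icols
    else:
        prefix = cmap["intensity_prefix"]
        icols = [c for c in df.columns if c.startswith(prefix)]
        if not icols:
            raise FormatError(
                f"no intensity columns with prefix {prefix!r} in {path}"
            )
        sample_ids = [c[len(prefix):] for c in icols]

    intens = df[icols].replace("", np.nan).astype(float)
    intens.columns = sample_ids
    if (intens.to_numpy() < 0).any():
        raise ValidationError(f"negative intensities in {path}")
    intens = intens.mask(intens == 0)  # LFQ zero means not quantified

    idx = make_feature_index(features, level)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature keys in {path}: {dups}")
    features.index = idx
    intens.index = idx
    return QuantTable(level=level, features=features, intensities=intens, scale=RAW)


def filter_flagged(table: QuantTable) -> QuantTable:
    """Drop reverse hits, potential contaminants and protein groups only
    identified by a modification site."""
    flags = table.features[list(FLAG_COLUMNS)].any(axis=1)
    removed = int(flags.sum())
    logger.info(
        "filter_flagged: removed %d of %d features (%d reverse, %d contaminant, %d only-by-site)",
        removed,
        table.n_features,
        int(table.features["reverse"].sum()),
        int(table.features["contaminant"].sum()),
        int(table.features["only_by_site"].sum()),
    )
    keep = ~flags
    return QuantTable(
        table.level,
        table.features.loc[keep],
        table.intensities.loc[keep],
        table.scale,
    )


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------


def export_heatmap_matrix(
    diff_by_age: Mapping[object, pd.DataFrame],
    reference_label: str = "day1",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fold-change matrix of features significant in at least one age.

    ``diff_by_age`` maps an age label to that age-vs-reference differential
    table (see :mod:`ubage.differential`). Rows are the union of features
    with ``q_value < fdr_threshold`` in any age; columns are the ages; cells
    are the log2 fold change versus the shared reference. Row order is
    deterministic: descending mean fold change, ties broken by feature id.
    """
    if not diff_by_age:
        raise ValidationError("no differential tables supplied")
    tables = dict(diff_by_age)
    universes = [set(t.index) for t in tables.values()]
    common = set.intersection(*universes)
    if not common:
        raise ValidationError(
            f"differential tables for reference {reference_label!r} share no features"
        )
    selected: set = set()
    for t in tables.values():
        selected |= set(t.index[t["q_value"] < fdr_threshold])
    mat = pd.DataFrame(
        {age: t["log2_fc"].reindex(sorted(selected)) for age, t in tables.items()}
    )
    if mat.empty:
        return mat
    order = (
        mat.assign(_mean=mat.mean(axis=1))
        .sort_values(["_mean"], ascending=False, kind="mergesort")
        .index
    )
    return mat.loc[order]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> pd.DataFrame:
    """Write named result tables as TSV and return a manifest.

    Each table is written as ``<name>.tsv`` with its index labelled
    ``feature_id`` when it carries one. The manifest lists file name, row
    count and a sha256 content checksum, and is itself written as
    ``manifest.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        index = df.index.name is not None or not isinstance(df.index, pd.RangeIndex)
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        rows.append(
            {"file": path.name, "rows": len(df), "sha256": _checksum(path)}
        )
    manifest = pd.DataFrame(rows, columns=["file", "rows", "sha256"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def read_differential_table(path: str | Path) -> pd.DataFrame:
    """Read back a differential-result TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return df


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Serialize a QuantTable (features + intensities) to one TSV."""
    df = pd.concat([table.features, table.intensities], axis=1)
    df.insert(0, "level", table.level)
    df.insert(1, "scale", table.scale)
    df.to_csv(path, sep="\t", index=True, index_label="feature_id", float_format="%.10g")


def read_quant_table_tsv(path: str | Path) -> QuantTable:
    """Read a TSV produced by :func:`write_quant_table`."""
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    level = df.pop("level").iloc[0] if len(df) else SITE
    scale = df.pop("scale").iloc[0] if len(df) else RAW
    meta_cols = list(FEATURE_COLUMNS) + list(FLAG_COLUMNS)
    features = df[meta_cols].copy()
    for flag in FLAG_COLUMNS:
        features[flag] = features[flag].astype(bool)
    features["peptide"] = features["peptide"].fillna("")
    intens = df.drop(columns=meta_cols).astype(float)
    return QuantTable(level=level, features=features, intensities=intens, scale=scale)
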