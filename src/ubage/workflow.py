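"""End-to-end orchestration: config in, result bundle out.

The pipeline runs the full downstream analysis of a diGly ubiquitinome
ageing experiment: flag filtering, per-contrast preprocessing
(log2 / minimum-valid / downshifted imputation), permutation-FDR
differential testing for every declared contrast, site-versus-protein
change classification, rescue scoring in long-lived genotypes,
proteasome-target triangulation with linkage annotation, annotation-family
and tissue summaries, and heatmap matrix export. A single global seed
fans out into named per-stage streams, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import ContrastSpec, run_contrast, summarize_counts
from .integration import (
    STRICT,
    WITHIN_STRAIN,
    classify_change,
    family_summary,
    join_site_protein,
    proteins_site_down_protein_up,
    read_annotation_map,
    read_tissue_map,
    rescue_analysis,
    tissue_summary,
)
from .io_tables import (
    PROTEIN,
    SITE,
    QuantTable,
    ValidationError,
    export_heatmap_matrix,
    filter_flagged,
    read_annotations,
    read_quant_table,
    write_results,
)
from .preprocess import ImputationParams, preprocess
from .synthetic_data import (
    SimulationParams,
    SyntheticTruth,
    default_design,
    evaluate_recovery,
    simulate_experiment,
)
from .target_inference import (
    age_dysregulated_targets,
    annotate_linkage,
    enriched_set,
    near_misses,
    rpn6_upregulated_set,
)

logger = logging.getLogger(__name__)


def derive_seed(seed: int, name: str) -> int:
    """Stable sub-seed for a named stage, below 2**31."""
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML mapping."""

    seed: int = 0
    out_dir: str = "results/run"
    fdr_threshold: float = 0.05
    mode: str = STRICT  # "strict" or "sign_only" site/protein support
    rescue_mode: str = WITHIN_STRAIN
    n_permutations: int | str = 250
    s0: float = 0.0
    min_valid: int | None = None
    imputation: ImputationParams = field(default_factory=ImputationParams)
    simulate: SimulationParams | None = None
    inputs: dict[str, Any] | None = None  # site_table / protein_table / annotations
    family_map: str | None = None
    tissue_map: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        simple = (
            "seed",
            "out_dir",
            "fdr_threshold",
            "mode",
            "rescue_mode",
            "n_permutations",
            "s0",
            "min_valid",
            "family_map",
            "tissue_map",
        )
        for key in simple:
            if key in raw:
                setattr(cfg, key, raw[key])
        if "imputation" in raw:
            cfg.imputation = ImputationParams(**raw["imputation"])
        if "simulate" in raw:
            cfg.simulate = SimulationParams(**(raw["simulate"] or {}))
        if "inputs" in raw:
            cfg.inputs = dict(raw["inputs"])
        if cfg.simulate is None and cfg.inputs is None:
            raise ValidationError("config needs either a 'simulate' block or 'inputs'")
        if cfg.simulate is not None and "seed" not in (raw.get("simulate") or {}):
            cfg.simulate.seed = derive_seed(cfg.seed, "simulate")
        return cfg


@dataclass
class ResultsBundle:
    """All pipeline outputs, as in-memory tables."""

    site_diffs: dict[str, pd.DataFrame]
    protein_diffs: dict[str, pd.DataFrame]
    counts: pd.DataFrame
    change_records: pd.DataFrame
    rescue: pd.DataFrame
    targets: pd.DataFrame
    heatmaps: dict[str, pd.DataFrame]
    family: pd.DataFrame | None
    tissue: pd.DataFrame | None
    recovery: pd.DataFrame | None
    truth: SyntheticTruth | None
    run_log: list[str]


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _ageing_samples(ann: pd.DataFrame, genotype: str, day: int) -> list[str]:
    mask = (
        (ann["genotype"] == genotype)
        & (ann["day"] == day)
        & (ann["treatment"] == "none")
    )
    return ann.loc[mask, "sample_id"].tolist()


def _treatment_samples(ann: pd.DataFrame, treatment: str) -> list[str]:
    return ann.loc[ann["treatment"] == treatment, "sample_id"].tolist()


def default_contrasts(ann: pd.DataFrame, config: PipelineConfig) -> dict[str, ContrastSpec]:
    """The study's contrast battery, derived from the annotation table.

    Per-genotype age-versus-day-1 contrasts (heatmaps and count
    summaries), the day-15-versus-day-5 main ageing contrasts, the
    cross-strain aged comparisons, the rpn-6-versus-vector knockdown
    contrast and the two linkage-IP-versus-control contrasts. Contrasts
    whose samples are absent from the design are skipped.
    """

    def spec(name: str, a: list[str], b: list[str]) -> ContrastSpec | None:
        if len(a) < 2 or len(b) < 2:
            return None
        return ContrastSpec(
            name,
            a,
            b,
            fdr_threshold=config.fdr_threshold,
            n_permutations=config.n_permutations,
            s0=config.s0,
            seed=derive_seed(config.seed, f"contrast:{name}"),
        )

    specs: dict[str, ContrastSpec] = {}
    genotypes = [g for g in ("WT", "eat-2", "daf-2") if (ann["genotype"] == g).any()]
    days = sorted(ann.loc[ann["treatment"] == "none", "day"].unique())
    for geno in genotypes:
        for day in days:
            if day == 1:
                continue
            s = spec(
                f"{geno}_d{day}_vs_d1",
                _ageing_samples(ann, geno, day),
                _ageing_samples(ann, geno, 1),
            )
            if s:
                specs[s.name] = s
        s = spec(
            f"{geno}_d15_vs_d5",
            _ageing_samples(ann, geno, 15),
            _ageing_samples(ann, geno, 5),
        )
        if s:
            specs[s.name] = s
    for geno in ("eat-2", "daf-2"):
        s = spec(
            f"{geno}_d15_vs_WT_d15",
            _ageing_samples(ann, geno, 15),
            _ageing_samples(ann, "WT", 15),
        )
        if s:
            specs[s.name] = s
    s = spec(
        "rpn6_vs_vector",
        _treatment_samples(ann, "rpn-6-RNAi"),
        _treatment_samples(ann, "vector-RNAi"),
    )
    if s:
        specs[s.name] = s
    for ip in ("K48", "K63"):
        s = spec(
            f"{ip}_vs_Flag",
            _treatment_samples(ann, f"IP-{ip}"),
            _treatment_samples(ann, "IP-Flag"),
        )
        if s:
            specs[s.name] = s
    return specs


def prepare_and_test(
    table: QuantTable, spec: ContrastSpec, config: PipelineConfig
) -> pd.DataFrame:
    """Preprocess the contrast's samples and run the differential test."""
    sub = table.subset_samples(list(spec.group_a) + list(spec.group_b))
    groups = {"a": list(spec.group_a), "b": list(spec.group_b)}
    observed = pd.DataFrame(
        {
            "n_valid_a": sub.intensities[list(spec.group_a)].notna().sum(axis=1),
            "n_valid_b": sub.intensities[list(spec.group_b)].notna().sum(axis=1),
        }
    )
    imput = ImputationParams(
        width=config.imputation.width,
        shift=config.imputation.shift,
        seed=derive_seed(config.seed, f"impute:{spec.name}"),
    )
    ready = preprocess(sub, groups, imput, config.min_valid)
    return run_contrast(ready, spec, observed_counts=observed)


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_full_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Run every stage and return the full results bundle."""
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    note(f"ubage {__version__} | numpy {np.__version__} | pandas {pd.__version__}")
    note(f"global seed {config.seed}; fdr_threshold {config.fdr_threshold}; "
         f"mode {config.mode}; rescue_mode {config.rescue_mode}; "
         f"n_permutations {config.n_permutations}; s0 {config.s0}")

    truth: SyntheticTruth | None = None
    if config.simulate is not None:
        ann = default_design()
        site_table, protein_table, truth = simulate_experiment(ann, config.simulate)
        note(
            f"simulated {site_table.n_features} sites / {protein_table.n_features} "
            f"proteins x {len(ann)} samples (simulation seed {config.simulate.seed})"
        )
    else:
        inputs = config.inputs or {}
        ann = read_annotations(inputs["annotations"])
        site_table = read_quant_table(
            inputs["site_table"], SITE, inputs.get("column_map"),
            inputs.get("site_intensity_columns"),
        )
        protein_table = read_quant_table(
            inputs["protein_table"], PROTEIN, inputs.get("column_map"),
            inputs.get("protein_intensity_columns"),
        )
        note(
            f"read {site_table.n_features} sites / {protein_table.n_features} proteins"
        )

    n0s, n0p = site_table.n_features, protein_table.n_features
    site_table = filter_flagged(site_table)
    protein_table = filter_flagged(protein_table)
    note(
        f"flag filtering removed {n0s - site_table.n_features} site / "
        f"{n0p - protein_table.n_features} protein features"
    )

    specs = default_contrasts(ann, config)
    ip_names = {"K48_vs_Flag", "K63_vs_Flag"}
    protein_level_names = {"WT_d15_vs_d5", "rpn6_vs_vector"} | ip_names

    site_diffs: dict[str, pd.DataFrame] = {}
    protein_diffs: dict[str, pd.DataFrame] = {}
    for name, spec in specs.items():
        if name not in ip_names:
            site_diffs[name] = prepare_and_test(site_table, spec, config)
        if name in protein_level_names:
            protein_diffs[name] = prepare_and_test(protein_table, spec, config)
        n_sig = int(site_diffs[name]["significant"].sum()) if name in site_diffs else 0
        note(f"contrast {name}: {n_sig} significant sites")

    counts = summarize_counts(site_diffs)

    heatmaps: dict[str, pd.DataFrame] = {}
    for geno in ("WT", "eat-2", "daf-2"):
        per_age = {
            day: site_diffs[f"{geno}_d{day}_vs_d1"]
            for day in (5, 10, 15)
            if f"{geno}_d{day}_vs_d1" in site_diffs
        }
        if per_age:
            heatmaps[geno] = export_heatmap_matrix(
                per_age, f"{geno}_d1", config.fdr_threshold
            )
            note(f"heatmap {geno}: {len(heatmaps[geno])} rows")

    # -- site vs protein integration on the main ageing contrast ----------
    main = "WT_d15_vs_d5"
    if main not in site_diffs or main not in protein_diffs:
        raise ValidationError("the WT day-15 vs day-5 contrast is required")
    joined = join_site_protein(site_diffs[main], protein_diffs[main])
    change_records = classify_change(joined, config.fdr_threshold, config.mode)
    partition = change_records["protein_status"].value_counts().to_dict()
    note(f"change classification ({main}): {partition}")
    age_down_up = proteins_site_down_protein_up(change_records)
    note(f"proteins with >=1 site down while protein up: {len(age_down_up)}")

    mutant_tables = {
        g: site_diffs[n]
        for g, n in (
            ("eat-2", "eat-2_d15_vs_d5" if config.rescue_mode == WITHIN_STRAIN else "eat-2_d15_vs_WT_d15"),
            ("daf-2", "daf-2_d15_vs_d5" if config.rescue_mode == WITHIN_STRAIN else "daf-2_d15_vs_WT_d15"),
        )
        if n in site_diffs
    }
    if mutant_tables:
        rescue = rescue_analysis(
            site_diffs[main],
            mutant_tables,
            config.rescue_mode,
            config.fdr_threshold,
            genotypes=tuple(mutant_tables),
        )
        note(f"rescue ({config.rescue_mode}): {len(rescue)} WT-significant sites scored")
    else:
        rescue = pd.DataFrame()

    # -- proteasome-target triangulation ----------------------------------
    if "rpn6_vs_vector" in site_diffs and "rpn6_vs_vector" in protein_diffs:
        rpn6_set = rpn6_upregulated_set(
            site_diffs["rpn6_vs_vector"],
            protein_diffs["rpn6_vs_vector"],
            config.fdr_threshold,
            config.mode,
        )
        note(f"rpn-6 up-in-both set: {len(rpn6_set)} proteins")
        targets = age_dysregulated_targets(
            rpn6_set,
            change_records,
            protein_diffs[main],
            site_diffs["rpn6_vs_vector"],
            protein_diffs["rpn6_vs_vector"],
            mode=config.mode,
        )
        k48 = enriched_set(protein_diffs["K48_vs_Flag"]) if "K48_vs_Flag" in protein_diffs else None
        k63 = enriched_set(protein_diffs["K63_vs_Flag"]) if "K63_vs_Flag" in protein_diffs else None
        targets = annotate_linkage(targets, k48, k63)
        n_cand = int(targets["is_candidate"].sum())
        note(
            f"age-dysregulated proteasome targets: {n_cand} candidates, "
            f"{len(near_misses(targets))} near-misses (3/4 flags)"
        )
    else:
        targets = pd.DataFrame(
            columns=[
                "rpn6_protein_up", "rpn6_site_up", "age_protein_up",
                "age_site_down", "n_flags", "is_candidate", "linkage",
            ]
        )
        note("rpn-6 contrast absent; no target triangulation")

    family = tissue = None
    if config.family_map:
        family = family_summary(protein_diffs[main], read_annotation_map(config.family_map))
    if config.tissue_map:
        tissue = tissue_summary(change_records, read_tissue_map(config.tissue_map))

    recovery = None
    if truth is not None:
        candidates = set(targets.index[targets["is_candidate"]])
        rec = evaluate_recovery(
            candidates, truth.proteins_of_class("proteasome_target")
        )
        recovery = pd.DataFrame([{"call_set": "proteasome_target", **rec}]).set_index(
            "call_set"
        )
        note(
            f"planted-target recovery: precision {rec['precision']:.3f} "
            f"recall {rec['recall']:.3f}"
        )

    return ResultsBundle(
        site_diffs=site_diffs,
        protein_diffs=protein_diffs,
        counts=counts,
        change_records=change_records,
        rescue=rescue,
        targets=targets,
        heatmaps=heatmaps,
        family=family,
        tissue=tissue,
        recovery=recovery,
        truth=truth,
        run_log=log,
    )


def save_bundle(bundle: ResultsBundle, out_dir: str | Path) -> pd.DataFrame:
    """Write every bundle table as TSV plus the run log; returns the manifest."""
    out = Path(out_dir)
    tables: dict[str, pd.DataFrame] = {}
    for name, df in bundle.site_diffs.items():
        tables[f"site_diff_{name}"] = df
    for name, df in bundle.protein_diffs.items():
        tables[f"protein_diff_{name}"] = df
    tables["counts"] = bundle.counts.reset_index()
    tables["change_records"] = bundle.change_records
    if len(bundle.rescue):
        tables["rescue"] = bundle.rescue
    tables["targets"] = bundle.targets
    for geno, mat in bundle.heatmaps.items():
        tables[f"heatmap_{geno}"] = mat
    if bundle.family is not None:
        tables["family_summary"] = bundle.family.reset_index()
    if bundle.tissue is not None:
        tables["tissue_summary"] = bundle.tissue.reset_index()
    if bundle.recovery is not None:
        tables["recovery"] = bundle.recovery.reset_index()
    if bundle.truth is not None:
        tables["truth_proteins"] = bundle.truth.proteins
        tables["truth_sites"] = bundle.truth.sites
    manifest = write_results(tables, out)
    (out / "run_log.txt").write_text("\n".join(bundle.run_log) + "\n")
    return manifest


def make_report(bundle: ResultsBundle) -> str:
    """Human-readable run summary mirroring the pipeline's main readouts."""
    lines = ["# ubage run report", ""]
    lines.append("## Significant Ub-peptides per contrast (up / down, % of changed)")
    for name, row in bundle.counts.iterrows():
        if row["total_significant"]:
            lines.append(
                f"  {name}: {int(row['up'])} up ({row['up_pct']:.1f}%), "
                f"{int(row['down'])} down ({row['down_pct']:.1f}%)"
            )
        else:
            lines.append(f"  {name}: no significant Ub-peptides")
    lines.append("")
    lines.append("## Site-vs-protein classification (WT day 15 vs day 5)")
    part = bundle.change_records["protein_status"].value_counts()
    total = int(part.sum())
    for status in ("concordant", "inverse", "stable", "not_quantified"):
        lines.append(f"  {status}: {int(part.get(status, 0))}")
    lines.append(f"  total significant sites: {total}")
    lines.append("")
    lines.append("## Age-dysregulated proteasome targets")
    cands = bundle.targets[bundle.targets["is_candidate"]]
    if cands.empty:
        lines.append("  zero candidates")
    else:
        for pid, row in cands.iterrows():
            lines.append(f"  {pid} (linkage {row['linkage']})")
    if bundle.recovery is not None:
        rec = bundle.recovery.iloc[0]
        lines.append("")
        lines.append(
            f"## Planted-truth recovery: precision {rec['precision']:.3f}, "
            f"recall {rec['recall']:.3f}"
        )
    return "\n".join(lines) + "\n"
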