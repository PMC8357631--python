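"""Synthetic diGly-site and protein quantification tables with ground truth.

The generator emulates the design of a whole-organism ubiquitinome ageing
study in *C. elegans*: three genotypes (wild type and the long-lived
``eat-2`` dietary-restriction and ``daf-2`` insulin/IGF-1 mutants) sampled
at adulthood days 1, 5, 10 and 15 with four biological replicates; a
day-5 proteasome-knockdown contrast (``rpn-6`` RNAi versus vector RNAi,
n = 3); and K48-, K63- and control-Flag immunoprecipitations (n = 3).

Site-level log2 intensity is the protein's noise-free log2 abundance plus
a per-site offset plus a planted occupancy effect, so protein-level
changes propagate mechanistically into sites and "concordant" classes
emerge without being painted on. Missingness is intensity-dependent
(missing-not-at-random): a cell with underlying log2 intensity x is
dropped with probability ``logistic((tau - x) / kappa)``, mimicking the
left-censored missingness of label-free quantification.

Planted effect classes (one per protein; ``e`` = ``effect_size_log2``):

``null``
    no planted effect anywhere.
``age_deub_stable_protein``
    one site loses ``e`` log2 units of occupancy with age; the protein is
    stable — pure age-related deubiquitination.
``concordant_up`` / ``concordant_down``
    the protein gains / loses ``e`` with age; sites follow passively.
``inverse_other``
    the protein gains ``e`` with age while every site loses ``2e`` of
    occupancy (net site change ``-e``): less ubiquitinated yet more
    abundant, but not proteasome-modulated.
``proteasome_target``
    like ``inverse_other`` with age, *plus* accumulation under rpn-6
    knockdown (protein up ``2e`` — blocked degradation accumulates
    substrates strongly — and site occupancy up ``e`` on top), *plus*
    K48-IP enrichment (every second target also K63) — the full
    triangulation signature.
``rpn6_responsive``
    proteasome knockdown remodels the proteome far beyond its direct
    substrates; these proteins go up (half, protein ``2e`` with site
    occupancy ``e``) or down (half, protein ``-2e``) after rpn-6 RNAi
    but carry no age dysregulation.
``rescued_in_mutants``
    one site loses ``e`` with age in the wild type only; the planted
    effect in ``eat-2`` and ``daf-2`` is exactly zero.

Polyubiquitin-linkage IP enrichment is ubiquitome-wide, as a linkage
pull-down against a Flag control is: by default 40% of proteins enrich in
the K48 IP only, 10% in K63 only, 10% in both and 40% in neither, with
proteasome targets always K48 (every second one dual K48+K63).

Age effects ramp with adulthood day (0 at days 1 and 5, half at day 10,
full at day 15), so the day-15 versus day-5 contrast carries the full
planted effect and the per-age versus day-1 contrasts show a progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stream
from .io_tables import (
    PROTEIN,
    RAW,
    SITE,
    QuantTable,
    ValidationError,
    make_feature_index,
    validate_annotations,
)

EFFECT_CLASSES = (
    "age_deub_stable_protein",
    "concordant_up",
    "concordant_down",
    "inverse_other",
    "proteasome_target",
    "rpn6_responsive",
    "rescued_in_mutants",
    "null",
)

#: fraction of planted age effect realized at each adulthood day
AGE_RAMP = {1: 0.0, 5: 0.0, 10: 0.5, 15: 1.0}

DEFAULT_FRACTIONS: Mapping[str, float] = {
    "age_deub_stable_protein": 0.08,
    "concordant_up": 0.04,
    "concordant_down": 0.10,
    "inverse_other": 0.03,
    "proteasome_target": 0.005,
    "rpn6_responsive": 0.15,
    "rescued_in_mutants": 0.05,
}

#: ubiquitome-wide linkage composition of non-target proteins
DEFAULT_LINKAGE_FRACTIONS: Mapping[str, float] = {
    "K48": 0.40,
    "K63": 0.10,
    "both": 0.10,
    "none": 0.40,
}


@dataclass
class SimulationParams:
    """Tunable knobs of the generator; defaults are the study conditions.

    ``baseline_log2_mean``/``sd`` set the per-protein abundance
    distribution (log2 LFQ units); ``site_offset_mean``/``sd`` place diGly
    peptides below their parent protein's abundance; ``replicate_noise_sd``
    is per-cell biological+technical noise; ``effect_size_log2`` the
    planted contrast effect; ``ip_enrichment_log2`` the planted
    linkage-IP pull-down enrichment; ``missingness_tau``/``kappa`` the
    logistic MNAR midpoint and width (log2 units).
    """

    n_proteins: int = 1000
    sites_per_protein_mean: float = 1.3  # sites ~ 1 + Poisson(mean)
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.0
    site_offset_mean: float = -1.0
    site_offset_sd: float = 1.0
    replicate_noise_sd: float = 0.35
    effect_size_log2: float = 1.5
    rpn6_effect_multiplier: float = 2.0
    ip_enrichment_log2: float = 3.0
    fractions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    linkage_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINKAGE_FRACTIONS)
    )
    missingness_tau: float = 22.0
    missingness_kappa: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        for name in ("baseline_log2_sd", "site_offset_sd", "replicate_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.missingness_kappa <= 0:
            raise ValidationError("missingness_kappa must be > 0")
        unknown = set(self.fractions) - set(EFFECT_CLASSES)
        if unknown:
            raise ValidationError(f"unknown effect classes: {sorted(unknown)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValidationError("negative effect fraction")
        if sum(self.fractions.values()) > 1.0 + 1e-12:
            raise ValidationError("effect fractions sum to more than 1")
        if abs(sum(self.linkage_fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("linkage fractions must sum to 1")
        if self.rpn6_effect_multiplier <= 0:
            raise ValidationError("rpn6_effect_multiplier must be > 0")


@dataclass
class SyntheticTruth:
    """Planted per-feature ground truth emitted alongside the tables.

    ``proteins`` is indexed by protein id with the effect class, the
    planted protein-level log2 effects per context (age, rpn-6, K48/K63
    IP) and the true linkage label; ``sites`` is indexed by site feature
    id with the planted occupancy effects. ``scope`` says which genotypes
    carry the age effect (``all`` or ``WT``).
    """

    proteins: pd.DataFrame
    sites: pd.DataFrame
    seed: int

    def proteins_of_class(self, effect_class: str) -> set[str]:
        mask = self.proteins["effect_class"] == effect_class
        return set(self.proteins.index[mask])

    def sites_of_class(self, effect_class: str) -> set[str]:
        mask = self.sites["effect_class"] == effect_class
        return set(self.sites.index[mask])


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def default_design() -> pd.DataFrame:
    """The full sample-annotation table the generator emulates.

    48 ageing samples (3 genotypes x days {1, 5, 10, 15} x 4 replicates),
    6 proteasome-knockdown samples (vector vs rpn-6 RNAi, day 5, n = 3)
    and 9 linkage-IP samples (K48 / K63 / Flag control, n = 3).
    """
    rows = []
    for geno in ("WT", "eat-2", "daf-2"):
        for day in (1, 5, 10, 15):
            for rep in range(1, 5):
                rows.append(
                    {
                        "sample_id": f"{geno}_d{day}_r{rep}",
                        "genotype": geno,
                        "day": day,
                        "treatment": "none",
                        "replicate": rep,
                    }
                )
    for treatment in ("vector-RNAi", "rpn-6-RNAi"):
        for rep in range(1, 4):
            short = treatment.split("-RNAi")[0].replace("-", "")
            rows.append(
                {
                    "sample_id": f"WT_d5_{short}_r{rep}",
                    "genotype": "WT",
                    "day": 5,
                    "treatment": treatment,
                    "replicate": rep,
                }
            )
    for ip in ("IP-K48", "IP-K63", "IP-Flag"):
        for rep in range(1, 4):
            rows.append(
                {
                    "sample_id": f"WT_d5_{ip}_r{rep}",
                    "genotype": "WT",
                    "day": 5,
                    "treatment": ip,
                    "replicate": rep,
                }
            )
    return validate_annotations(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# truth assembly
# ---------------------------------------------------------------------------


def _assign_classes(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Deterministic class counts (round(fraction * n)), shuffled positions."""
    n = params.n_proteins
    classes = []
    for name in EFFECT_CLASSES[:-1]:
        k = int(round(params.fractions.get(name, 0.0) * n))
        classes.extend([name] * k)
    if len(classes) > n:
        raise ValidationError("effect fractions allocate more proteins than exist")
    classes.extend(["null"] * (n - len(classes)))
    arr = np.array(classes, dtype=object)
    rng.shuffle(arr)
    return arr


def _build_truth(params: SimulationParams, rng: np.random.Generator) -> SyntheticTruth:
    e = params.effect_size_log2
    r = params.rpn6_effect_multiplier * e
    ip = params.ip_enrichment_log2
    classes = _assign_classes(params, rng)
    protein_ids = [f"P{i:05d}" for i in range(params.n_proteins)]

    prot = pd.DataFrame(index=pd.Index(protein_ids, name="protein_id"))
    prot["effect_class"] = classes
    prot["age_protein_effect"] = 0.0
    prot["rpn6_protein_effect"] = 0.0
    prot["k48_effect"] = 0.0
    prot["k63_effect"] = 0.0
    prot["scope"] = "all"

    cls = prot["effect_class"]
    prot.loc[cls == "concordant_up", "age_protein_effect"] = e
    prot.loc[cls == "concordant_down", "age_protein_effect"] = -e
    prot.loc[cls == "inverse_other", "age_protein_effect"] = e
    prot.loc[cls == "proteasome_target", "age_protein_effect"] = e
    prot.loc[cls == "proteasome_target", "rpn6_protein_effect"] = r
    prot.loc[cls == "rescued_in_mutants", "scope"] = "WT"
    responsive = prot.index[cls == "rpn6_responsive"]
    up = responsive[: (len(responsive) + 1) // 2]
    down = responsive[(len(responsive) + 1) // 2 :]
    prot.loc[up, "rpn6_protein_effect"] = r
    prot.loc[down, "rpn6_protein_effect"] = -r

    # linkage-IP enrichment: ubiquitome-wide background, targets overridden
    labels = list(params.linkage_fractions)
    probs = np.array([params.linkage_fractions[k] for k in labels], dtype=float)
    linkage = rng.choice(labels, size=params.n_proteins, p=probs / probs.sum())
    targets = prot.index[cls == "proteasome_target"]
    linkage[cls.to_numpy() == "proteasome_target"] = "K48"
    both_targets = targets[::2]  # every second target also carries K63 chains
    linkage[prot.index.isin(both_targets)] = "both"
    prot["linkage"] = linkage
    prot.loc[prot["linkage"].isin(["K48", "both"]), "k48_effect"] = ip
    prot.loc[prot["linkage"].isin(["K63", "both"]), "k63_effect"] = ip

    rpn6_site_up = set(up) | set(targets)
    n_sites = 1 + rng.poisson(params.sites_per_protein_mean, size=params.n_proteins)
    site_rows = []
    for pid, k, c in zip(protein_ids, n_sites, classes):
        for j in range(k):
            # protein-level dysregulation (impaired degradation) touches
            # every lysine site; site-specific regulatory classes only one
            first = j == 0
            age_occ = 0.0
            rpn6_occ = 0.0
            if c in ("inverse_other", "proteasome_target"):
                age_occ = -2.0 * e
            elif first and c == "age_deub_stable_protein":
                age_occ = -e
            elif first and c == "rescued_in_mutants":
                age_occ = -e
            if pid in rpn6_site_up:
                rpn6_occ = e
            pos = 20 * (j + 1) + 1  # synthetic lysine residue numbers
            site_rows.append(
                {
                    "protein_id": pid,
                    "site_position": pos,
                    "peptide": f"PEP{pid}K{pos}",
                    "effect_class": c,
                    "age_occupancy_effect": age_occ,
                    "rpn6_occupancy_effect": rpn6_occ,
                }
            )
    sites = pd.DataFrame(site_rows)
    sites.index = make_feature_index(sites, SITE)
    return SyntheticTruth(proteins=prot, sites=sites, seed=params.seed)


# ---------------------------------------------------------------------------
# intensity generation
# ---------------------------------------------------------------------------


def _context_effects(
    ann_row: pd.Series, prot: pd.DataFrame, sites: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Planted log2 effect of one sample on every protein and site."""
    geno, day, treatment = ann_row["genotype"], ann_row["day"], ann_row["treatment"]
    p_eff = np.zeros(len(prot))
    s_occ = np.zeros(len(sites))
    if treatment == "none":
        ramp = AGE_RAMP.get(int(day), 1.0)
        in_scope = (prot["scope"] == "all") | (geno == "WT")
        p_eff = ramp * prot["age_protein_effect"].to_numpy() * in_scope.to_numpy()
        site_scope = (
            prot["scope"].reindex(sites["protein_id"]).to_numpy() == "all"
        ) | (geno == "WT")
        s_occ = ramp * sites["age_occupancy_effect"].to_numpy() * site_scope
    elif treatment == "rpn-6-RNAi":
        p_eff = prot["rpn6_protein_effect"].to_numpy().copy()
        s_occ = sites["rpn6_occupancy_effect"].to_numpy().copy()
    elif treatment == "IP-K48":
        p_eff = prot["k48_effect"].to_numpy().copy()
    elif treatment == "IP-K63":
        p_eff = prot["k63_effect"].to_numpy().copy()
    # vector-RNAi and IP-Flag are reference conditions: no planted effect
    return p_eff, s_occ


def simulate_experiment(
    design: pd.DataFrame, params: SimulationParams
) -> tuple[QuantTable, QuantTable, SyntheticTruth]:
    """Generate raw-scale site and protein QuantTables plus ground truth.

    Protein log2 abundance = baseline + planted protein effect + replicate
    noise; site log2 intensity = the protein's *noise-free* log2 abundance
    + site offset + planted occupancy effect + replicate noise. Each cell
    is then independently censored with probability
    ``logistic((tau - x) / kappa)`` and the surviving cells returned on the
    raw scale (2**x). Identical (design, params, seed) give bit-identical
    outputs.
    """
    params.validate()
    design = validate_annotations(design)
    if design.empty:
        raise ValidationError("empty design")
    group_sizes = design.groupby(["genotype", "day", "treatment"]).size()
    if (group_sizes < 2).any():
        warnings.warn("some design cells have < 2 replicates; contrasts on them will fail")

    truth = _build_truth(params, stream(params.seed, "truth"))
    prot, sites = truth.proteins, truth.sites
    n_p, n_s, n_samp = len(prot), len(sites), len(design)

    rng_base = stream(params.seed, "baselines")
    baseline = rng_base.normal(params.baseline_log2_mean, params.baseline_log2_sd, n_p)
    # proteasome targets are abundant structural/regulatory proteins,
    # robustly quantified in every condition
    is_target = (prot["effect_class"] == "proteasome_target").to_numpy()
    baseline[is_target] = rng_base.normal(
        params.baseline_log2_mean + params.baseline_log2_sd,
        params.baseline_log2_sd / 2,
        int(is_target.sum()),
    )
    site_offset = rng_base.normal(params.site_offset_mean, params.site_offset_sd, n_s)
    prot_pos = {pid: i for i, pid in enumerate(prot.index)}
    site_parent = sites["protein_id"].map(prot_pos).to_numpy()

    p_signal = np.empty((n_p, n_samp))
    s_signal = np.empty((n_s, n_samp))
    for j, (_, row) in enumerate(design.iterrows()):
        p_eff, s_occ = _context_effects(row, prot, sites)
        p_signal[:, j] = baseline + p_eff
        s_signal[:, j] = (baseline + p_eff)[site_parent] + site_offset + s_occ

    rng_noise = stream(params.seed, "noise")
    p_log2 = p_signal + rng_noise.normal(0, params.replicate_noise_sd, p_signal.shape)
    s_log2 = s_signal + rng_noise.normal(0, params.replicate_noise_sd, s_signal.shape)

    rng_miss = stream(params.seed, "missingness")
    for mat in (p_log2, s_log2):
        p_missing = expit((params.missingness_tau - mat) / params.missingness_kappa)
        mat[rng_miss.random(mat.shape) < p_missing] = np.nan

    sample_ids = design["sample_id"].tolist()

    def _table(level: str, feats: pd.DataFrame, log2_mat: np.ndarray) -> QuantTable:
        features = pd.DataFrame(index=feats.index)
        features["protein_id"] = feats["protein_id"] if "protein_id" in feats else feats.index
        if level == SITE:
            features["site_position"] = feats["site_position"]
            features["peptide"] = feats["peptide"]
        else:
            features["site_position"] = np.nan
            features["peptide"] = ""
        for flag in ("reverse", "contaminant", "only_by_site"):
            features[flag] = False
        intens = pd.DataFrame(
            np.exp2(log2_mat), index=feats.index, columns=sample_ids
        )
        return QuantTable(level=level, features=features, intensities=intens, scale=RAW)

    protein_table = _table(PROTEIN, prot, p_log2)
    site_table = _table(SITE, sites, s_log2)
    return site_table, protein_table, truth


def missingness_probability(log2_intensity, params: SimulationParams):
    """Logistic MNAR dropout probability for a given underlying log2 value."""
    return expit((params.missingness_tau - np.asarray(log2_intensity, dtype=float)) / params.missingness_kappa)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------


def evaluate_recovery(
    calls: Iterable[str],
    truth_positives: Iterable[str],
    universe: Iterable[str] | None = None,
) -> dict[str, float]:
    """Precision / recall / F1 of a call set against planted positives.

    An empty call set has precision 1.0 by convention (no false claims)
    and recall 0.0 when positives exist. If ``universe`` is given, calls
    outside it raise a validation error.
    """
    calls = set(calls)
    positives = set(truth_positives)
    if universe is not None:
        universe = set(universe)
        stray = calls - universe
        if stray:
            raise ValidationError(f"calls outside the feature universe: {sorted(stray)[:5]}")
    tp = len(calls & positives)
    fp = len(calls - positives)
    fn = len(positives - calls)
    precision = 1.0 if not calls else tp / (tp + fp)
    recall = 1.0 if not positives else tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "tp": tp,
        "fp": fp,
        "fn": fn,
    }


def recovery_by_class(
    calls_by_class: Mapping[str, Iterable[str]], truth: SyntheticTruth
) -> pd.DataFrame:
    """Score one call set per effect class against the planted truth."""
    rows = {}
    for effect_class, calls in calls_by_class.items():
        rows[effect_class] = evaluate_recovery(calls, truth.proteins_of_class(effect_class))
    return pd.DataFrame(rows).T
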