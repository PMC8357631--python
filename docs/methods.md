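# Methods

`ubage` implements the downstream statistics of a quantitative
diGly (K-ε-GG) ubiquitinomics ageing experiment in *C. elegans*: label-free
quantification (LFQ) tables for ubiquitination sites and protein groups are
filtered, log2-transformed and imputed; two-group contrasts are tested with
a pooled-variance t statistic under permutation-based FDR control; site- and
protein-level results are integrated; and proteasome substrates that become
dysregulated with age are triangulated across the ageing, proteasome-knockdown
and linkage-IP arms of the design. The package ships a synthetic-data
generator that emulates the full experimental design with planted ground
truth, so every stage is testable without any external download.

## Input model and preprocessing

Features are either diGly sites (protein accession, lysine position, modified
peptide) or protein groups. The leading accession — the text before the first
`;` of a protein-group identifier — is the deterministic join key between the
two levels. Protein groups flagged as reverse hits, potential contaminants or
"only identified by site" are removed before any statistics. A raw LFQ
intensity of zero denotes non-quantification and is coerced to missing on
read. The site reader accepts an optional localization-probability
threshold (commonly 0.75) for the diGly position; it is off by default
because the confidence filter a search engine applies upstream is not a
property this pipeline can verify.

Preprocessing applies three steps in a fixed order:

1. **log2 transform** of observed intensities.
2. **Minimum-valid filtering**: a feature is retained when it has at least
   `min_valid` observed values in *at least one* group of the contrast
   (default: group size − 1). Filtering precedes imputation because imputing
   a feature absent from an entire group would fabricate a group difference
   out of the imputation distribution.
3. **Downshifted-normal imputation** (the Perseus convention): per sample
   column with observed mean *m* and standard deviation *s*, missing cells
   draw independently from Normal(*m* − 1.8·*s*, (0.3·*s*)²). The defaults
   `shift = 1.8` and `width = 0.3` encode the assumption that missing LFQ
   values are left-censored — the peptide was near or below the detection
   limit. Imputation is per column (robust to per-run depth differences),
   never touches observed cells, and is deterministic under the run seed.

## Differential testing

Each contrast (test group minus reference group) is scored per feature with
the pooled-variance Student t statistic

  t = (x̄_a − x̄_b) / (s_p · √(1/n_a + 1/n_b) + s₀),

with a two-sided p-value from the t distribution on n_a + n_b − 2 degrees of
freedom. `s0` (default 0) is the SAM-style fudge constant that damps
significance of tiny absolute changes; it is exposed for Perseus-faithful
reruns. With zero pooled variance and s₀ = 0, identical means return
(t = 0, p = 1) and different means a perfectly separated feature (p = 0).

**Permutation FDR.** Group labels are reassigned over the contrast's
samples; for every observed threshold c,

  FDR(c) = mean permuted count of |t| ≥ c ÷ observed count of |t| ≥ c,

capped at 1. The per-feature q-value is the step-down envelope of FDR over
decreasing |t| (a running maximum walking from the most significant feature
down), which makes q monotone non-increasing in |t| without letting a
feature borrow a luckily low estimate from a more lenient threshold.
Significance means q < 0.05 unless configured otherwise.

Three design choices matter here:

- **The observed labelling is excluded from the null** (together with its
  complement in balanced designs). Including it floors the FDR estimate at
  1/n_permutations, which for a 3-vs-3 design (20 distinct assignments)
  makes q < 0.05 mathematically unattainable — yet linkage-IP and knockdown
  contrasts at n = 3 are a core part of the design. The null is therefore
  built from all *other* distinct label assignments: 18 for 3 vs 3, 68 for
  4 vs 4. When more permutations are requested than exist, all distinct
  shuffles are used (and logged); above the exhaustive budget assignments
  are sampled uniformly under the run seed.
- **Assignments always select the smaller group**, so a contrast and its
  role-swapped twin see identical |t| null distributions: swapping group
  roles negates every fold change and t while leaving p and q unchanged.
- **Observed-evidence guard.** Under intensity-dependent missingness a
  feature can lose a whole replicate group by chance; the downshifted
  imputer then fabricates a tight cluster at the imputation floor whose
  separation no label shuffle can reproduce, producing spurious q ≈ 0
  calls. A feature must therefore have at least 2 *observed*
  (pre-imputation) values in each group to be eligible for significance —
  the same minimum the imputer and the t-test themselves require. Ineligible
  features keep their fold change and statistic but are reported with q = 1;
  their true observed counts are carried in `n_valid_a` / `n_valid_b`.

Under a global null (~2,000 simulated sites, n = 4 vs 4) the pipeline's
mean observed false-discovery proportion at FDR 0.05 is ≈ 0.04 over 200
seeds — in a global null every discovery is false, so this mean is the rate
of datasets with any spurious call and its nominal value is the FDR level
itself.

## Integration of site and protein levels

Every site significant in a contrast is classified against its protein:

- **concordant** — protein significant with the same sign;
- **inverse** — protein significant with the opposite sign;
- **stable** — protein quantified but not significant;
- **not_quantified** — no protein-level row for the accession.

This is the strictest reading of "correlated in the same direction"
(both levels significant at FDR < 0.05). A `sign_only` mode relaxes the
protein requirement to a matching fold-change sign; the switch propagates
into the target triangulation, where it relaxes the *site*-support
requirement of the knockdown arm. The four statuses partition the
significant sites exactly.

**Rescue in long-lived genotypes.** For each site significant in the
wild-type ageing contrast (day 15 vs day 5), `within_strain` mode calls the
site rescued in a mutant when the mutant's own ageing contrast does not
reproduce the change (not significant, or significant with opposite sign);
`cross_strain` mode instead requires the mutant-vs-wild-type contrast at
day 15 to be significant with sign opposite to the wild-type change.
`within_strain` is the default: absence of the age change in the mutant is
the directly interpretable notion of rescue, and it does not depend on the
power of an additional contrast. The two modes agree on cleanly planted
rescue structure up to FDR-level false calls; under realistic noise the
cross-strain mode is conservative because its contrast has few true
positives and therefore a demanding permutation threshold.

**Annotation summaries** count significant protein-level changes per
enzyme family (E3 ligases, deubiquitinases, other) and per predicted tissue
label; multi-tissue proteins count once in every tissue they map to.

## Proteasome-target triangulation

A protein is an age-dysregulated proteasome-target candidate when four
evidence flags all hold:

1. protein level up after rpn-6 knockdown (significant, positive);
2. ≥ 1 ubiquitination site up after rpn-6 knockdown;
3. protein level up with age (day 15 vs day 5);
4. ≥ 1 site significantly *less* ubiquitinated with age while the protein
   rises (an inverse record).

One qualifying site suffices per criterion. The full flag table is kept for
every protein in the union of the evidence sets, and near-misses (3 of 4
flags) are emitted by default because small intersections are sensitive to
the FDR threshold. Candidates are annotated with their polyubiquitin linkage
from K48- and K63-IP enrichment against the Flag-antibody control
(enriched = significant with positive fold change): `K48`, `K63`, `both`,
`none` (IP data present, no enrichment) or `unknown` (no IP data).

## The synthetic-data generator

The generator is first-class, tested code. It emulates the study design —
3 genotypes × adulthood days {1, 5, 10, 15} × 4 replicates, a day-5
rpn-6-RNAi vs vector-RNAi contrast at n = 3, and K48/K63/Flag IPs at
n = 3 — with a mechanistic two-layer model:

- protein log2 abundance = baseline + planted protein effect + replicate
  noise, with baselines ~ Normal(25, 2²) in log2 LFQ units;
- site log2 intensity = the protein's *noise-free* log2 abundance + a
  per-site offset (Normal(−1, 1²)) + a planted occupancy effect +
  replicate noise (SD 0.35).

Because sites inherit the protein term, protein changes propagate into
sites and "concordant" classes emerge mechanistically rather than being
painted on. Age effects ramp with day (0 at days 1 and 5, half at day 10,
full at day 15). Every cell is independently censored with probability
logistic((τ − x)/κ), τ = 22, κ = 0.8 — missing-not-at-random dropout that
yields ≈ 10–30% missing site cells at the default baselines. All
randomness flows from one seed through named streams, so identical
(design, params, seed) give bit-identical tables.

Planted effect classes (e = 1.5 log2 by default) and their default
fractions:

| class | fraction | age (protein / site occupancy) | rpn-6 (protein / occupancy) |
|---|---|---|---|
| `age_deub_stable_protein` | 0.08 | 0 / −e at one site | — |
| `concordant_up` / `concordant_down` | 0.04 / 0.10 | ±e / 0 (sites follow) | — |
| `inverse_other` | 0.03 | +e / −2e at all sites | — |
| `proteasome_target` | 0.005 | +e / −2e at all sites | +2e / +e at all sites |
| `rpn6_responsive` | 0.15 | — | ±2e (half up, half down); +e occupancy when up |
| `rescued_in_mutants` | 0.05 | −e at one site, wild type only | — |
| `null` | remainder | — | — |

Rationale for the non-obvious choices:

- *Widespread responses.* Proteasome knockdown remodels the proteome far
  beyond its direct substrates, and ageing changes a large share of the
  ubiquitinome; the generator reflects both. This is also a statistical
  requirement: a permutation FDR at n = 3–4 can only call features when the
  observed-positive count dominates the heavy-tailed permutation null, so a
  sparse design (a handful of affected features among thousands) makes
  FDR < 0.05 unattainable for *any* estimator of this family.
- *Knockdown accumulation at 2e.* Blocking degradation accumulates
  substrates strongly; a 3-log2 protein response is a realistic magnitude
  and gives the n = 3 contrast usable power.
- *Multi-site occupancy loss* for degradation-impaired proteins (all their
  lysine sites), versus one-site effects for the site-specific regulatory
  classes: impaired turnover affects the whole protein pool, while
  regulatory (de)ubiquitination is site-targeted.
- *Abundant targets.* Planted proteasome targets draw baselines from the
  upper end of the abundance distribution (Normal(mean + SD, (SD/2)²)),
  reflecting that such targets are abundant structural/regulatory proteins
  robustly quantified in every condition; a target whose evidence is
  censored below the detection limit is unrecoverable by construction and
  probes the censoring, not the inference.
- *Ubiquitome-wide IP enrichment.* A linkage-specific IP against a Flag
  control enriches much of the ubiquitinated proteome, not only the
  targets: by default 40% of proteins enrich K48-only, 10% K63-only, 10%
  both, 40% neither; planted targets are always K48 (every second one dual
  K48+K63).

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: LFQ-scale
log-normal intensities, site–protein coupling, MNAR dropout, replicate
noise, planted contrast structure. It does **not** simulate peptide
detectability, chromatographic or batch effects, shared/ambiguous protein
groups, correlated noise across sites of one protein, or normalization
artefacts. Passing tests therefore demonstrate that the *inference
machinery* is correct and calibrated under the assumed model — not that
real LFQ data meet those assumptions.

## Recovery scoring

`evaluate_recovery` computes precision/recall/F1 of a call set against
planted positives; an empty call set has precision 1.0 by convention.
Under the default conditions (5 planted targets among 1,000 proteins,
effect 1.5 log2, noise 0.35) the triangulation attains precision ≈ 1.0 and
recall ≈ 0.8 averaged over 10 seeds. The recall ceiling is statistical, not
algorithmic: a candidate must clear four independent significance tests,
each with per-test power ≈ 0.9–0.95 at these sample sizes, so the
intersection loses the occasional target whose fold-change draw lands two
standard errors low in one arm. Rescue recall is scored over planted rescue
sites whose wild-type change is detected (rescue records exist only for
WT-significant sites); unconditional recall is bounded by MNAR censoring of
low-abundance sites, which no downstream step can undo.

## Problem sizes and determinism

Default analysis and test problem sizes — 1,000 proteins (≈ 2,300 sites),
10 seeds for recovery averages, 200 seeds for the null-calibration rate —
were chosen so each quantity's Monte-Carlo error is small relative to the
bands checked while a full run stays in the tens of seconds on one CPU.
The whole pipeline is deterministic under the single global seed: each
stage (simulation, per-contrast imputation, permutation sampling) draws
from a named stream derived from it, and a rerun with the same config is
byte-identical, which the test suite asserts.

## Known limitations

- The imputation constants (1.8, 0.3) and the minimum-valid rule are
  conventions, not measured properties; analyses of real data should check
  sensitivity to them.
- The permutation null at n = 3 has only 18 usable shuffles; q-values are
  correspondingly granular, and calls at that depth lean on the pooled
  (cross-feature) null.
- Features failing the observed-evidence guard (a near-wholly-imputed
  group) are never significant even when the presence/absence pattern is
  itself informative; an explicit presence/absence test is out of scope.
- Protein inference, normalization across runs and peptide-level ambiguity
  are upstream of this package and assumed resolved by the search software.
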