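# ubage — differential analysis of the ubiquitin-modified proteome

`ubage` is an analysis pipeline for quantitative diGly (K-ε-GG)
ubiquitinomics of ageing *C. elegans*: it takes MaxQuant-style site and
protein-group LFQ tables and asks how the ubiquitinated proteome is
rewired with age, which changes long-lived mutants avoid, and which
proteins are proteasome substrates that accumulate because they lose
ubiquitination. It is written for proteomics analysts who have the
search-engine output in hand and need the downstream statistics to be
explicit, seeded and testable.

The core statistical machinery:

- **Preprocessing** — contaminant/reverse/only-by-site filtering, log2
  transform, minimum-valid filtering, and Perseus-style downshifted-normal
  imputation of missing-not-at-random LFQ values
  (per column: Normal(m − 1.8·s, (0.3·s)²)).
- **Differential abundance** — pooled-variance Student t per feature,
  t = (x̄_a − x̄_b)/(s_p·√(1/n_a + 1/n_b) + s₀), with permutation-based FDR:
  FDR(c) = mean permuted count of |t| ≥ c over observed count of |t| ≥ c,
  capped at 1, with a monotone step-down q-value envelope. Significance is
  q < 0.05.
- **Integration** — every significant Ub-site change classified against
  its protein (concordant / inverse / stable / not quantified), rescue
  scoring in *eat-2* and *daf-2* mutants, E3/DUB family and tissue
  summaries.
- **Target triangulation** — proteins up in both total and Ub-peptide
  level after *rpn-6* (proteasome) knockdown **and** more abundant yet
  less site-ubiquitinated with age, annotated with K48/K63 polyubiquitin
  linkage from IP-enrichment contrasts.
- **Synthetic data** — a generator that emulates the full design
  (3 genotypes × 4 ages × 4 replicates, knockdown and IP arms) with
  planted effect classes and ground truth, used by every test.

See `docs/methods.md` for the model, parameter defaults and their
rationale.

## Worked example

Run the numbered analysis scripts from the repository root (each is a thin
driver over the library; outputs land under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_differential.py
python analysis/03_integrate.py
python analysis/04_targets.py
python analysis/05_null_calibration.py
```

`01_simulate.py` generates the synthetic study (seed 1): 2,243 diGly sites
on 1,000 proteins across 63 samples with 23.1% missing site cells.
`02_differential.py` then prints the contrast battery, including

```
WT day 15 vs day 5: 81 Ub-peptides up, 202 down — ageing skews toward
deubiquitination (71% of changes are losses)
```

i.e. of the 283 significantly changed Ub-peptides in aged wild-type worms,
71% are losses of ubiquitination, while the long-lived mutants show a less
down-skewed profile. `03_integrate.py` classifies those significant site
changes against total protein levels:

```
concordant        136
stable            100
inverse            46
not_quantified      1

proteins less ubiquitinated at >= 1 site while accumulating: 23
WT ageing changes rescued in eat-2: 34%
WT ageing changes rescued in daf-2: 32%
```

so roughly half of the ubiquitination changes cannot be explained by the
protein's own abundance (stable or inverse), and 23 proteins show the
impaired-degradation signature (site down, protein up). `04_targets.py`
triangulates these against the proteasome-knockdown arm:

```
proteins up in both total and Ub-peptide level after rpn-6 RNAi: 65
age-dysregulated proteasome targets: 4
  P00155  linkage=both
  P00826  linkage=both
  P00913  linkage=K48
  P00987  linkage=both
recovery vs planted truth: precision 1.00, recall 0.80 (4/5 targets found)
```

Four of the five planted proteasome targets are recovered with no false
calls; each candidate carries the K48 linkage that marks it for
proteasomal degradation. `05_null_calibration.py` verifies type-I control
on all-null data (mean observed false-discovery proportion ≈ 0.04 at
FDR 0.05 over 100 seeds).

The same run is available as one command driven by a YAML config:

```bash
ubage run-all --config config.yaml     # simulate | preprocess | test | integrate | targets
```

with a minimal `config.yaml`:

```yaml
seed: 1
out_dir: results/run
simulate:
  n_proteins: 1000
```

Real data run the same way by replacing the `simulate` block with an
`inputs` block naming the site TSV, protein TSV and sample-annotation TSV.

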