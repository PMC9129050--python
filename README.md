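# microcause

Design-based causal inference for binary environmental exposures on gut
microbiome count data. The package implements a four-stage workflow:

1. **Design** — constrained pair matching of exposed to control units under
   per-covariate thresholds (maximum bipartite matching), with balance
   diagnostics and a propensity-score matcher for sensitivity analyses.
2. **Assignment permutation** — within-pair exposure relabelings (exhaustive
   when `2^P` is affordable, unique uniform samples otherwise) shared by all
   downstream tests.
3. **Analysis** — randomization tests at five levels:
   - within-sample diversity (Chao1 richness / plug-in Shannon with
     bootstrap SEs, or externally supplied estimates) via a
     measurement-error-aware meta-regression coefficient;
   - between-sample diversity via kernel score statistics on unweighted
     UniFrac, Aitchison, Jaccard and Gower-on-CLR distances;
   - high-dimensional compositional means via a studentized max-CLR
     statistic at any taxonomic rank;
   - per-taxon differential abundance via reference-set
     normalization-by-ratio and log-fold statistics;
   - differential taxon–taxon associations via per-arm graphical-lasso
     partial-correlation networks (StARS-selected penalty) re-estimated
     under permutation.
4. **Adjustment & reporting** — fully permutation-based min-p
   familywise-error adjustment within each hypothesis family, plus JSON/TSV
   reports.

A synthetic-cohort module generates paired observational cohorts with known
ground truth (confounded assignment, logistic-normal–multinomial counts with
a sparse latent precision matrix, injectable effects on taxa, diversity and
network edges), so every stage can be validated end to end without external
data.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the heavier simulation-based checks
(type-I-error calibration, FWER control, power/recovery runs); the full
suite takes a few minutes on one CPU.

## CLI

```bash
microcause simulate --n-exposed 100 --n-control 100 --n-taxa 60 --seed 1 --out cohort/
microcause match --meta cohort/metadata.tsv --thresholds thresholds.json --out design/
microcause test-diversity --counts cohort/counts.tsv --pairs design/pairs.tsv --which shannon
microcause test-beta --counts cohort/counts.tsv --pairs design/pairs.tsv --tree cohort/tree.nwk
microcause test-composition --counts cohort/counts.tsv --pairs design/pairs.tsv --taxonomy cohort/taxonomy.tsv --ranks Genus,Phylum
microcause test-da --counts cohort/counts.tsv --pairs design/pairs.tsv
microcause test-network --counts cohort/counts.tsv --pairs design/pairs.tsv --n-perm 200
microcause run-all --config analysis.json
```

`thresholds.json` maps covariate names to matching tolerances, e.g.
`{"age": 5, "bmi": 4, "alcohol": 25, "sex": 0, "diabetes": 0}` (0 means
exact match). Input formats are plain TSV (counts: `sample_id` ×
taxon columns; metadata: `sample_id`, covariates, `exposure` ∈ {0,1};
taxonomy: `taxon_id`, `Phylum` … `Genus`), Newick trees, and JSON/YAML
configs. Assignment matrices can be exported/imported as TSV to reuse one
set of permutations across analyses.

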