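# organfield

Whole-organ bladder-mucosa analysis as a tested, reusable pipeline:

- **organ_io** — MAF-like per-field variant tables (long/wide TSV dialects),
  field-annotation TSV (NU/LGIN/HGIN/UC histology, merged into NU_LGIN /
  HGIN / UC groups), COSMIC-v2-style 96×K signature CSV, GMT pathway sets
  and omics TSV matrices, all with strict validation.
- **mutation_classes** — presence calling at a VAF threshold (default
  ≥ 0.01), private/regional/widespread spread categories and α/β/γ
  clonality classes (α private; β spread with consistently low VAF < 0.20;
  γ spread with median VAF > 0.20), with per-field/per-group summaries and
  COSMIC-driver fractions.
- **signatures** — 6-class and 96-motif catalogs (pyrimidine-reference,
  purine contexts reverse-complemented), signature weights by the
  simplex-constrained quadratic program min_H (WH−V)ᵀ(WH−V), bootstrap
  empirical p-values (B=2000 default; a `mode="literal"` variant implements
  the descriptive resampling-quantile definition), and group comparisons
  (exact r×c test with enumeration/Monte-Carlo, rank-sum + BH, Kruskal-Wallis).
- **phylogeny** — binary character matrices, Hamming distances, and
  maximum-parsimony clonal trees rooted at an all-zero ancestral `node0`
  (bit-parallel Fitch; exhaustive enumeration for small sample counts,
  seeded stepwise-addition + NNI otherwise), Newick export and a
  deterministic leaf order for heat maps.
- **chronology** — branching-process-with-immigration expectations
  EV₀ = eᵃ/c, EVᵢ = eᵃ (b/(a+b))ⁱ P(i, a+b)/c; per-mutation (a, b) fits of
  sorted field-VAF profiles; inversion to proliferation rate ρ and age t
  under ν = ν₀ρ^σ (σ = 6 default); dormant/progressive phase split at
  5 years; cell-count scans over 10²–10⁵.
- **omics_scores** — half-minimum imputation, Welch t-test + 1.5-fold
  differential rule, strictly monotonic NU_LGIN→HGIN→UC trend selection,
  and ssGSEA (weighted ECDF-difference integral, exponent 0.75).
- **synthetic_data** — whole-organ generator with known ground truth:
  clone VAFs from the same branching process (Poisson immigration,
  exponential growth), binomial read sampling at ~300X, contexts drawn from
  a signature mixture, histology gradient on the field grid, and omics
  tables with planted monotone trends.
- **pipeline_cli** — `organfield` command with `validate / classify /
  signatures / tree / chronology / omics / simulate / run` subcommands; the
  `run` stage orchestrator consumes a YAML config with mandatory seeds and
  writes a manifest (input hashes, config hash, output hashes).

## Quick start

```sh
# synthetic organ with planted alpha/beta/gamma ground truth
organfield simulate --preset paper-like --seed 7 --out data/

organfield validate data/mutations.tsv data/fields.tsv
organfield classify  --mutations data/mutations.tsv --fields data/fields.tsv --out out/
organfield tree      --mutations data/mutations.tsv --fields data/fields.tsv --method heuristic --out out/
organfield chronology --mutations data/mutations.tsv --fields data/fields.tsv --b-max 5000 --out out/
```

Or run everything from a config:

```yaml
# run.yaml
seed: 7
output_dir: out
inputs:
  mutations: data/mutations.tsv
  fields: data/fields.tsv
  signature_matrix: data/signatures.csv
stages: {classify: true, signatures: true, tree: true, chronology: true}
params: {bootstrap_B: 2000, b_max: 5000.0}
```

```sh
organfield run --config run.yaml
```

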