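# profilemix

Latent-profile allocation and treatment-outcome comparison for routine
mental-health cohorts.

The package implements a person-centred prediction pipeline around a finite
mixture model with mixed indicators: four continuous scores (PHQ-9, GAD-7,
WSAS, age) modelled as within-profile normals and five binary flags (phobia
caseness, gender, medication, welfare, ethnic group) as within-profile
Bernoullis, with local independence. Cases are allocated to the profile with
the highest Bayes-rule posterior membership probability; the runner-up
("secondary") profile feeds the refinement tables.

Components:

- `profilemix.mixture` — likelihood, EM estimation with restarts, model
  selection (AIC/BIC/relative entropy), posterior allocation, label
  alignment, JSON model serialization.
- `profilemix.outcomes` — caseness (PHQ-9 ≥ 10 or GAD-7 ≥ 8), reliable
  improvement / deterioration (≥ 6 PHQ-9 / ≥ 4 GAD-7 points), recovery,
  reliable recovery, attrition, and the cohort inclusion filter
  (missingness → sessions → caseness precedence).
- `profilemix.stratify` — prevalence by year, outcome rates per profile,
  2×2 odds ratios with Woolf CIs (equivalent to two-level logistic
  regression; Haldane–Anscombe correction on zero cells), yearly stability
  with small-cell suppression. No multiple-testing adjustment is applied.
- `profilemix.treatment` — episode intensity classification (LI/HI/mixed),
  main-modality rule (last modality, strict session majority,
  single intensity), propensity scores from a logistic regression on the
  membership posteriors, greedy 1:1 nearest-neighbour matching within a
  caliper (default 0.001, probability scale, with replacement), and matched
  odds-ratio comparison.
- `profilemix.secondary` — outcome tables keyed by secondary profile, and
  the per-primary split on a flagged secondary profile.
- `profilemix.summary_tests` — pooled/Welch t tests and two-proportion z
  tests from published summary statistics.
- `profilemix.simulate` — synthetic cohort generator with a shipped
  eight-profile preset (`src/profilemix/data/default_preset.yaml`):
  published prevalences, qualitative indicator structure, severity-linked
  (confounded) treatment assignment, and profile×treatment outcome effects.
- `profilemix.io` / `profilemix.cli` — CSV readers/writers, run manifests,
  and the `profilemix` command-line pipeline.

## CLI

```bash
profilemix simulate --n 5000 --seed 1 --out-dir out
profilemix outcomes --cohort out/cohort.csv --out-dir out
profilemix allocate --cohort out/cohort.csv --out-dir out
profilemix fit --cohort out/cohort.csv --n-profiles 8 --out-dir out
profilemix stratify --cohort out/cohort.csv --out-dir out
profilemix match-compare --cohort out/cohort.csv --episodes out/episodes.csv \
    --arms intensity --outcome reliably_recovered --out-dir out
profilemix secondary --cohort out/cohort.csv --primary LP6 --out-dir out
profilemix summary-test --table table.csv
```

Each subcommand writes its CSV artifacts plus `manifest.json` (seed, stage
counts, output hashes); identical config + seed reproduce identical files.

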