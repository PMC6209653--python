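# genemeta

Case-control SNP association meta-analysis, from per-study genotype counts
to screening recommendations:

* **Genetic models** — genotype triples → 2×2 exposure tables under the
  allele, dominant and recessive models; pooled allele frequencies; an
  optional Hardy–Weinberg diagnostic.
* **Meta engine** — per-study Woolf log-OR effects (+0.5 continuity
  correction for zero cells), Mantel–Haenszel fixed-effects pooling with
  the Robins–Breslow–Greenland variance, DerSimonian–Laird random-effects
  pooling, Cochran's Q / I² heterogeneity, and the selection rule
  *fixed iff p(Q) > 0.1 or I² ≤ 50%*.
* **Pipeline** — eligibility filtering (≥ 4 studies per variant), pooled
  analysis overall and by ethnicity/country subgroups, two-tier
  classification (*recommended* at p < 0.05, *most recommended* at
  p < 1×10⁻⁵), and dominant/recessive decomposition attributing top-tier
  signals to heterozygotes and/or homozygotes.
* **Diagnostics** — leave-one-out sensitivity (with fixed/random
  re-selection per deletion) and publication-bias assessment (funnel data
  export + Egger's regression).
* **Synthetic data** — a generative simulator (HWE controls,
  odds-tilted cases, optional between-study heterogeneity, per-ethnicity
  allele frequencies) with a ground-truth manifest, so every stage is
  testable without external data.

A bundled example dataset (`genemeta.datasets`) provides a 36-study
roster and published overall pooled estimates for 16 SNCA variants.

## Input format

UTF-8 TSV, one row per study × variant:

```
study_id  author_year  ethnicity  country  nos  variant_id  risk_allele
other_allele  case_hom_risk  case_het  case_hom_other  ctrl_hom_risk
ctrl_het  ctrl_hom_other  [superseded_by]  [af_gnomad]
```

`ethnicity` is one of `European`, `East Asian`, `Latino`, `West Asian`,
`Mixed`. Rows whose declared risk allele is the complement of the
variant's first-seen orientation are flipped automatically. A row with
`superseded_by` marks an overlapping cohort replaced by a newer study; it
stays in the roster but is excluded from pooled analyses.

## CLI

```bash
# simulate a dataset with known ground truth
genemeta --seed 7 simulate --variant-id rs1000001 --true-or 1.3 \
    --k-studies 10 --control-af 0.4 --out sim/

# full analysis: results.tsv + forest.csv + funnel.csv
genemeta run --input sim/input.tsv --group ethnicity \
    --models allele,dominant,recessive --tier1 0.05 --tier2 1e-5 \
    --min-studies 4 --out results/

# leave-one-out sensitivity and publication bias for one variant
genemeta loo  --input sim/input.tsv --variant rs1000001 --out loo/
genemeta bias --input sim/input.tsv --variant rs1000001 --out bias/
```

Global flags: `--seed`, `--log-level`, and `--config FILE` (a flat
`key = value` file mirroring the option names, used as defaults).

Raw p-values are written at full precision; a `p_display` column applies
the conventional `<0.00001` floor for presentation only.

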