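# metbiom

Biometrical analysis of balanced multi-environment crop trials (MET), built
around the classical workflow used to evaluate clonal crop germplasm:

- **RCBD ANOVA per environment** with moment (expected-mean-square) variance
  components, standard errors, CV% and critical differences;
- **genetic parameters** per trait and season: ECV/GCV/PCV, broad-sense
  heritability with low/moderate/high classification, genetic advance and
  genetic gain at a configurable selection intensity (k = 2.06 default);
- **genotypic and phenotypic trait correlations** from paired mean
  cross-product analyses, with capping and not-estimable flagging of the
  genotypic estimator;
- **yield regression**: OLS of fresh yield on component traits over genotype
  means, with sequential (type-I) contribution shares;
- **divergence clustering**: Mahalanobis D² over genotype trait means with a
  pooled within-genotype covariance, grouped by Tocher's rule or Ward/average
  linkage (Newick dendrogram export);
- **geometric adaptability index (GAI)**: per-trait geometric means across
  years, average-tie ranking, mean-rank consolidation, top-10 occurrence
  counting and minimum-occurrence selection;
- **combined genotype × year ANOVA** with replication nested in year and a
  percent-of-total-SS partition;
- a **simulator** for balanced MET plot data with configurable genotypic /
  year / interaction / error variances and cross-trait correlations, plus an
  analytic truth ledger for parameter-recovery testing.

`metbiom.reference` bundles the published summary statistics of a three-year,
53-genotype turmeric trial (two replications, twelve traits) used as fixture
inputs and as fixed oracles for the formulas.

## Data format

Long-format CSV, one plot observation per row:

```csv
genotype,environment,replicate,trait,value
G001,2019-20,1,PH,86.2
```

Column names are configurable; the design must be a complete
genotype × environment × replicate × trait grid (missing cells are a hard
error for the ANOVA stages).

## CLI

```sh
metbiom simulate --seed 42 --out met.csv --truth truth.json
metbiom validate met.csv
metbiom means met.csv --trait PH
metbiom anova met.csv --trait FY --combined
metbiom params met.csv --out table1.csv
metbiom corr met.csv --pooled
metbiom regress met.csv --year E1 --response FY
metbiom cluster met.csv --method tocher
metbiom gai met.csv --min-occurrence 5
metbiom run --config pipeline.yaml
```

`metbiom run` drives every stage from one YAML config and writes a
deterministic output bundle (CSV tables + a manifest with checksums).

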