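# droughtrank

Multi-trait drought-resistance screening of genotype panels: fuzzy
membership transformation, correlation-matrix PCA, eigenvalue-weighted
composite scoring (F and D values), genotype ranking, hierarchical
classification into resistance groups, leaf-physiology assay formulas, and a
synthetic-panel generator so the whole pipeline is testable end to end
without any external data.

## What it does

Given a tidy genotype × trait table (control/treatment, replicated), the
pipeline:

1. **respond** — per-(genotype, index) response statistics: percent change,
   drought coefficient (treatment/control), paired two-tailed t-test with
   "a"/"b" significance letters.
2. **membership** — min–max membership transform of each index across
   genotypes, inverted for injury indices (EL, MDA) so 1 always means
   "most resistant".
3. **PCA** — eigen-decomposition of the correlation matrix of the membership
   values; contribution rates; component scores `F_j = Σ a_ij·ZX_i`;
   retention by fixed m (default 3), Kaiser, or cumulative threshold.
4. **score** — eigenvalue weights `W_j = λ_j/p` (or `λ_j/Σλ`), composite
   `F = Σλ_jF_j/Σλ_j`, comprehensive `D = Σ μ(F_j)·W_j`, and ranking.
5. **classify** — complete-linkage ("furthest neighbour") or average-linkage
   clustering of the component scores, SPSS-style 0–25 rescaled dendrogram
   heights, cuts by k or rescaled height, Newick export, heatmap matrix.
6. **correlate** — Pearson matrix with exact-t two-tailed p-values and
   `*`/`**` star annotations.

A bundled reference dataset (`droughtrank.datasets.load_daylily25`) carries
the published summary tables of a 25-genotype daylily deficit-irrigation
screen — eigenvalue spectrum, component scores, membership/D evaluation and
pigment means — used by the regression tests and the acceptance report.

## CLI

```sh
droughtrank simulate --seed 1 --out panel.csv --truth-out truth.csv
droughtrank respond  --input panel.csv --out response.csv
droughtrank score    --scores f_columns.csv --eigenvalues eig.csv --out d.csv
droughtrank classify --scores f_columns.csv --k 3 --labels-out labels.csv \
                     --newick-out tree.nwk
droughtrank correlate --matrix membership.csv --out corr.csv
droughtrank assay    --kind rwc --input readings.csv --out rwc.csv
droughtrank run      --config pipeline.yaml
```

`run` executes the full pipeline from a YAML config and writes response,
membership, PCA, score, label, dendrogram and correlation artifacts plus a
manifest (config hash + version); identical config and inputs produce
byte-identical outputs. A minimal config:

```yaml
outdir: out
synthetic: {seed: 7}        # or: input_csv: panel.csv
pca_input: drought_coefficient   # or treatment_mean / percent_change
retention_rule: fixed_m
retention_m: 3
linkage: complete
cut_k: 3
```

## Assay formulas

`mda_content`, `rwc_percent`, `pigment_concentration` and `el_percent`
implement the standard bench formulas verbatim (MDA:
`[6.452·(A532−A600) − 0.559·A450]·(V/W)·1000`, V in mL; RWC:
`100·(Wf−Wd)/(Wt−Wd)`; pigments: `(A·V·1000)/(E·l)` with the absorption
coefficient E supplied by the caller; EL: conductivity ratio, optionally
blank-corrected). Reported magnitudes depend on these unit conventions.

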