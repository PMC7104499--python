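# hepamark

A tested, reusable pipeline for discriminating genotoxic hepatocarcinogens
(GTHC) from non-genotoxic hepatocarcinogens and non-carcinogens
(NGTHC/NGTNHC) from targeted liver RNA-Seq read counts of a 12-marker-gene
panel (*Aen, Bax, Btg2, Ccnf, Ccng1, Cdkn1a, Gdf15, Lrp1, Mbd1, Phlda3,
Plk2, Tubb4b*) plus the normalizer candidates *Dazap2* and *Ube2d3*.

The stages:

1. **normalization** — log2-transform raw counts, subtract the normalizer
   gene's log2 value per sample (library-depth invariant), and center each
   gene on its control-group mean, yielding log2(exp/cont) ratio vectors.
2. **group_stats** — per-gene Tukey–Kramer all-pairs comparisons using the
   studentized range distribution.
3. **pca_discrimination** — correlation-matrix PCA of labeled reference
   points (plus optional query profiles), PC1 sign orientation, a midpoint
   decision border on PC1, and classification.
4. **fixed_score** — the portable approximate-PC1 score
   `Y1 = Σ a_g (χ_g − μ_g)/σ_g` with published per-gene constants embedded
   verbatim and a fixed decision border of −0.710 (scores strictly below
   are called "GTHC-like").
5. **synthetic_data** — negative-binomial count simulation and multivariate-
   normal reference-panel simulation, so every stage runs and is testable
   with no external data.

## CLI

All stages are exposed through one entry point:

```sh
hepamark simulate        --outdir sim --seed 1          # counts + groups + truth
hepamark simulate-panel  --outdir ref --seed 2          # labeled reference panel
hepamark normalize       --counts sim/counts.tsv --groups sim/groups.tsv --outdir norm
hepamark stats           --ratio norm/ratio.tsv --groups sim/groups.tsv --outdir stats
hepamark pca             --panel ref/panel.tsv --query norm/ratio.tsv --outdir pca
hepamark score           --input norm/ratio.tsv --outdir score
```

or chained from a YAML config (`counts`, `groups`, optional `panel`, plus
`normalizer` / `pseudocount` / `alphas` / `control_label`):

```sh
hepamark all --config run.yaml --outdir out
```

Every run writes a `manifest.json`. Exit codes: 0 success, 1 usage error,
2 data validation error, 3 numeric failure. All tables are TSV (UTF-8,
header row); gene columns always appear in the canonical panel order.

## Library use

```python
from hepamark import (
    simulate_counts, normalize_pipeline, tukey_hsd, significant_gene_sets,
    fit_panel_pca, pc1_border, default_constants, approximate_pc1, classify_fixed,
)
from hepamark.synthetic_data import default_study_config
from hepamark.normalization import condition_profile

counts = simulate_counts(default_study_config(seed=1))
ratio = normalize_pipeline(counts)                      # log2(exp/cont), Dazap2-normalized
genes = significant_gene_sets(tukey_hsd(ratio), "cont-AAF", 0.05)
c = default_constants()
y1 = approximate_pc1(condition_profile(ratio, "AAF"), c)
print(genes, y1, classify_fixed(y1, c))
```
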