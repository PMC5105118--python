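# cranolex

Joint analysis of cranial shape, vocabulary, and geography across human
populations.

Population history leaves parallel traces in skeletal phenotype and in
language. This package implements the quantitative machinery needed to ask
whether core-vocabulary distances between populations track the same
history as cranial-shape differentiation once geography is accounted for:

- **Morphometrics** — generalized Procrustes analysis (GPA) of 3D landmark
  configurations, imputation of missing bilateral landmarks by reflected
  relabelling, post-GPA partitioning into cranial regions (whole cranium,
  face, neurocranium, temporal bone), and PCA with a bootstrap broken-stick
  stopping rule for choosing how many shape components to keep.
- **P_ST** — pairwise phenotypic differentiation from retained PC scores
  under the Harpending–Ward R-matrix model with heritability scaling
  (default h² = 0.3). P_ST is the quantitative-trait analogue of F_ST:
  for populations *i*, *j* and traits *t*,

      c_ij = (1/T) Σ_t (z̄_it − z̄_t)(z̄_jt − z̄_t) / V_t
      r_ij = c_ij (1 − F) / (2 h²),   F = Σ_i w_i r_ii

  with pooled within-population variance V_t standing in for
  heterozygosity and F solved self-consistently.
- **Lexical distances** — ASJP-style 40-concept word lists in the
  41-symbol ASJPcode alphabet, word-pair similarity by weighted
  Needleman–Wunsch global alignment under a sound-pair log-odds matrix,
  doculect distance by calibrating synonymous scores against the empirical
  distribution of non-synonymous (cross-concept) scores, candidate-doculect
  selection by ethnonym / island / 500-km-radius heuristics, and
  aggregation to population (L) and language-family (F) distances.
- **Geography** — great-circle distances on a sphere of radius 6373 km,
  with inter-continental routes constrained through waypoints (Cairo for
  Africa–Asia, Phnom Penh for Asia–Australia) so that oceans act as
  barriers.
- **Matrix statistics** — Spearman-based Mantel, partial Mantel, and
  Dow–Cheverud (ρ1Z) permutation tests with exhaustive enumeration at
  small n, plus multiple and sequential Bonferroni corrections.
- **Synthetic data** — coalescent population trees with Brownian landmark
  evolution, word lists evolving by cognate replacement and sound
  substitution, and arc-placed geography, so every stage has a
  parameter-recovery test surface with known ground truth.

## Worked example

Run the full pipeline on a synthetic 8-population world (20 specimens per
population, 32 landmarks, defaults throughout):

```python
from cranolex import pipeline

config = pipeline.AnalysisConfig(seed=42, n_perm=2000, n_boot=500)
bundle = pipeline.run_all(config)
print(bundle.tables["table1_pst_vs_l"].round(3).to_string(index=False))
```

```
     measure     r     p
       whole 0.782 0.007
        face 0.806 0.013
neurocranium 0.666 0.010
    temporal 0.532 0.028
```

Each row is the Spearman Mantel correlation between a cranial region's
pairwise P_ST matrix and the linguistic distance matrix L, with a
two-tailed permutation p-value. Because the synthetic world generates
cranial, lexical, and geographic divergence from one population tree, all
regions correlate positively with language. The partial correlations
controlling for geography (`table3_partial_pst_l_given_g`) are weaker —
geography explains much of the shared signal — and the Dow–Cheverud grid
(`table4_dow_cheverud_r`/`_p`) compares regions pairwise against L, plain
below the diagonal and geography-controlled above it.

The same analysis is available from the shell:

```
cranolex simulate --seed 5 --out fixtures/          # TPS + ASJP + CSV bundle
cranolex geodist --coords fixtures/coordinates.csv --out G.csv
cranolex mantel G.csv fixtures/divergence.csv --nperm 1000 --seed 2
# r = 0.9065, p = 0.001998 (1000 permutations)
cranolex run-all --seed 42 --out results/ --nperm 2000 --nboot 500
```

### File dialects

Landmarks are read from 3D TPS files (`LM3=` blocks,
`ID=population:specimen`) or long CSV (`specimen,population,landmark,x,y,z`
with empty cells marking missing landmarks). Word lists use an ASJP-style
dialect:

```
TAMIL{Dra.SOUTHERN}
  10.0000 78.0000
1 I	na
2 you	ni, nir
```

— a name line with a WALS-style `FAMILY.GENUS` classification, a metadata
line (`lat lon`, optionally `island=...`), then tab-separated numbered
concept lines; commas separate synonyms, `XXX` marks missing entries, and
a `%` prefix marks loanwords. Sound-pair weight matrices are TSVs of
`symbol<TAB>symbol<TAB>weight` rows with `# gap_open` / `# gap_extend`
headers, so a published weight scheme can be loaded verbatim; absent that,
weights can be estimated from plausible cognate pairs with
`lexical.estimate_weights`.

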