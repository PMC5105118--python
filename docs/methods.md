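# Methods

This note documents the models, estimators, and numerical choices behind
cranolex, and what the synthetic-data tests do and do not establish about
real data.

## Morphometrics

**Superimposition.** Landmark configurations (p ≥ 4 points in 3D) are
superimposed by generalized Procrustes analysis: each configuration is
centered, scaled to unit centroid size, and iteratively rotated to the
running consensus by the Kabsch solution restricted to proper rotations
(no reflections); iteration stops when the consensus changes by less than
1e-8 in any coordinate. The stored consensus is the plain arithmetic mean
of the aligned shapes. Collinear configurations are rejected — the optimal
rotation is not identifiable for them.

**Missing landmarks.** A missing bilateral landmark is imputed by
reflected relabelling: the configuration is reflected across the
least-squares plane of its midline landmarks (normal = direction of least
midline variance), left/right labels are swapped, the reflected copy is
superimposed on the original by ordinary Procrustes (rotation +
translation, no scaling — same specimen, same size) over landmarks present
on both sides, and the missing coordinates are read off the superimposed
reflection. Reflection followed by label-swapping preserves chirality, so
the proper-rotation restriction is sound. A missing midline landmark has
no homologue to reflect from; such specimens are unrecoverable and
excluded.

**Partitioning.** Regional subsets (face, neurocranium, temporal bone) are
taken from the whole-configuration alignment *without* re-superimposition,
so each region retains its position relative to the rest of the cranium.
The canonical 32-landmark scheme assigns 13/8/13 landmarks to
face/neurocranium/temporal with small boundary overlaps (the three subsets
sum to more than 32, as in real cranial schemes).

**PCA and the stopping rule.** PCA is the eigendecomposition of the
covariance (not correlation) matrix of the flattened, mean-centered
aligned coordinates — after GPA all variables share units, so no scaling
is appropriate. Component retention uses a three-step bootstrap rule:

1. resample specimens with replacement (default 10,000 replicates,
   `n_boot`) and recompute the PCA each time;
2. re-order each bootstrap solution so that every empirical axis is paired
   with its best-matching bootstrap axis (greedy in descending empirical
   eigenvalue order, by absolute loading correlation, ties to the lower
   index; sign flips are irrelevant to eigenvalues);
3. form a 95% confidence interval per eigenvalue and retain the components
   strictly before the first rank whose interval falls entirely below the
   broken-stick expectation for that rank, where the broken-stick spectrum
   is scaled to the total observed variance over the m = min(3p − 7, n − 1)
   candidate components.

Seven degrees of freedom are consumed by 3D superimposition, so the last 7
components are never candidates; components explaining < 1% of variance
are also dropped. Two numerical choices matter here. First, "interval
below the trendline" is read conservatively as *upper bound* below the
broken-stick value. Second, the intervals are **basic (reflected)
bootstrap intervals**, 2λ̂_k − q_{1−α/2} to 2λ̂_k − q_{α/2}, rather than raw
percentile intervals: resampling with replacement duplicates specimens and
inflates the leading sample eigenvalues, and percentile intervals inherit
that upward bias — on pure isotropic noise they keep dozens of spurious
components, while the reflected intervals correctly retain none. On
planted low-rank structure the two interval types agree.

## P_ST

Retained PC scores are the traits. Under the Harpending–Ward model the
population trait mean proxies a mean allele frequency and the pooled
within-population variance proxies heterozygosity. With weights w_i
(equal by default), codivergence c_ij = (1/T) Σ_t (z̄_it − z̄_t)(z̄_jt −
z̄_t)/V_t is scaled to the relationship matrix r_ij = c_ij(1 − F)/(2h²)
where F = Σ_i w_i r_ii appears on both sides. The defining fixed point
F = C(1 − F)/(2h²) (C = Σ w_i c_ii) is linear with slope −C/(2h²); the
naive substitution iteration diverges whenever C > 2h², so the solver uses
a relaxed update F ← (1 − λ)F + λG(F) with λ = 1/(1 + C/(2h²)), which
contracts for every C ≥ 0 and converges to the same fixed point
F = C/(2h² + C) (verified against an independent bisection oracle to
1e-8).

"Pairwise P_ST" treats each population pair as its own two-population
system with equal weights and reports that system's F; a global-R
alternative (d²_ij = r_ii + r_jj − 2r_ij) is available via
`method="global"` and agrees in rank order. Heritability enters only as a
common scale factor across pairs, so every rank-based matrix correlation
downstream is exactly invariant to h² (tested across h² ∈ {0.15, 0.3,
0.6, 1.0}); h² = 0.3 is the conventional default for cranial traits.
P_ST may exceed 1 under this scaling. An optional small-sample bias
correction subtracts 1/n_i from the diagonal codivergence before scaling
(off by default, since the reference protocol states none).

## Lexical distances

Word-pair similarity is the optimal global alignment score under a
symmetric sound-pair weight matrix with affine gap runs costing
gap_open + (len − 1)·gap_extend (the default schemes use equal penalties,
i.e. a linear gap model; the worked examples in the literature are
gapless). Tie-breaking in the traceback is deterministic: substitution
over gap, then gap in the second string. The aligner is verified against
exhaustive enumeration for every string pair of length ≤ 5 over a 3-symbol
alphabet.

Doculect distance calibrates signal against chance: for each shared
concept, the best synonymous alignment score (max over synonym pairs) is
placed within the pool of all non-synonymous cross-concept scores; the
concept's similarity is the strict empirical CDF value (fraction of the
pool strictly below), doculect similarity is the mean over shared
concepts, and distance = 1 − similarity, giving exact [0, 1] endpoints.
The pool is capped at 20,000 pairs by fixed-seed subsampling so results
are deterministic and runtime bounded. Two identical doculects whose
synonymous scores exceed every cross-concept score have distance exactly
0; doculects sharing no concepts have no defined distance.

Weight matrices are log-odds of sounds being historically related versus
matched by chance. When a published matrix is available it is loaded
verbatim from TSV; otherwise `estimate_weights` estimates one by iterated
alignment: starting identity-favoring, align plausibly related pairs and a
background sample with current weights, tally aligned symbol pairs on each
side with additive smoothing (pseudo-count 0.5, so unseen pairs stay
finite), and set weight(x, y) = log₂ of the ratio of relative
frequencies. Gap penalties are not re-estimated. The synthetic pipeline
trains on the generator's true cognate pairs; with real data the published
matrix or a curated cognate sample should be supplied.

Population distance L averages doculect distances over all cross pairs of
candidate doculects; candidates come from three ordered heuristics —
explicit ethnonym/classification match, else island restriction, else all
doculects within 500 km great-circle distance. Family distance F averages
over all cross-family doculect pairs under WALS-style family labels.

## Geography

Distances use the haversine formula on a perfect sphere of radius 6373 km
(no ellipsoid). Inter-continental paths sum great-circle legs through
fixed waypoints: Cairo (30 N, 31 E) linking Africa and Asia, Phnom Penh
(11.5 N, 105 E) linking Asia and Australia, and Cairo-then-Phnom-Penh for
Africa–Australia, implied by composing the two links. The waypoint table
is configurable. Routed distance dominates the direct great-circle
distance for every pair (triangle inequality on the sphere).

## Permutation statistics

All matrix correlations are Spearman over the strictly-upper-triangle
entries with average ranks for ties. The null permutes rows and columns of
one matrix jointly: the second matrix for the Mantel test, the first for
the partial Mantel (the vegan/ecodist raw-matrix convention), the target
for the Dow–Cheverud test. Two-tailed p-values use the add-one estimator
(hits + 1)/(n_perm + 1), so p > 0 always and "p < 0.0001" is attainable
at 10,000 permutations; with n ≤ 7 populations the full permutation group
is enumerated and the p-value is exact. Because the off-diagonal multiset
of a symmetric matrix is permutation-invariant, each matrix is
rank-transformed once and permutations reduce to reindexing — 10,000
permutations cost milliseconds.

The partial statistic is the first-order partial correlation on ranks,
r_AB·C = (r_AB − r_AC·r_BC)/√((1 − r_AC²)(1 − r_BC²)), degenerate when a
conditioning correlation is ±1. The Dow–Cheverud statistic z-scores the
off-diagonal entries of the two compared matrices, forms the contrast
Z = A_std − B_std, and correlates Z with the target (partially on G when
spatial autocorrelation is a concern); positive r means A correlates more
strongly with the target. When A = B the contrast is identically zero and
(r = 0, p = 1) is reported by convention. Bonferroni corrections over the
k = 3 cranial subsets use α/3 in multiple-comparison mode and the
sequentially rejective (Holm) thresholds 0.05/3, 0.025, 0.05 with
stop-at-first-failure.

## Synthetic worlds

The generator defines the conditions under which the pipeline is tested.
A Kingman coalescent tree over n populations (default 8) supplies the
ground truth: any two lineages coalesce at rate 1, so expected pairwise
divergence (twice the coalescence time) is 2 in tree units regardless of
n — the analytic oracle for the Monte-Carlo tree tests. A balanced
variant of unit height is available for tests that need fixed topology.

- **Landmarks**: a random ~100 mm root shape; each raw coordinate
  performs Brownian motion with variance `brownian_rate` (default 4 mm²
  per unit time, giving between-population mean-shape displacement well
  above the default 1 mm within-population noise, comparable to real
  cranial data where population differences are a few landmark-noise
  units); specimens add isotropic N(0, noise_sd²). Brownian motion acts on
  raw (pre-GPA) coordinates so superimposition itself is on the tested
  path. E‖m_i − m_j‖² = 3p·rate·d is the regression oracle.
- **Word lists**: along each branch of length t, a concept is replaced by
  a fresh random word (new cognate class) with probability 1 − exp(−0.3t),
  else each segment substitutes with probability 1 − exp(−0.2t). With
  expected divergence 2, roughly 45% of concept pairs between two random
  populations are non-cognate — mid-range differentiation where distances
  are informative but not saturated. New words are uniform over lengths
  2–6, matching short ASJP word lengths.
- **Geography**: populations sit on a west-to-east corridor in tree leaf
  order, adjacent tips spaced by their tree distance, spanning 140° of
  longitude; continents (Africa/Asia/Australia) are assigned by position
  relative to the Cairo and Phnom Penh meridians so waypoint routing is
  exercised. The generator reports the achieved Spearman correlation
  between direct great-circle distance and divergence (routing is a
  downstream step).

Every generator is a pure function of (params, seed); sub-generators use
streams split off the world seed by fixed offsets so stages rerun
independently yet reproducibly.

**What the synthetic tests do not show.** Real crania have anatomically
structured (non-isotropic, non-Brownian) covariance, allometry, and
asymmetry; real vocabularies have structured phoneme inventories,
borrowing, and sound changes that are systematic rather than uniform over
the alphabet; real populations do not sit on an arc, and real trees are
not ultrametric clocks. Passing the recovery tests shows the estimators
invert the generating model they were given — correct bookkeeping, rank
monotonicity, calibrated permutation inference — not that cranial or
lexical evolution follows that model.

## Problem sizes and determinism

Defaults match the reference protocol (10,000 permutations, 10,000
bootstrap replicates, h² = 0.3, 500 km candidate radius, α = 0.05 with
k = 3 model comparisons). The test suite and acceptance script scale
simulation sizes down — typically 150–1,000 bootstrap replicates,
199–10,000 permutations, 6–8 populations — sizes at which every checked
property is already stable. Parameter-recovery correlations are reported
as the median over five replicate worlds because a minority of coalescent
draws produce near-star trees whose 28 pairwise divergences are nearly
exchangeable, leaving too little rank signal for any estimator; the median
summarizes recovery under the model without conditioning on a favorable
tree. All randomized procedures take explicit seeds and every pipeline
stage derives its stream from the analysis seed by fixed offsets, so a
full rerun with the same configuration is byte-identical.

## Known limitations

- The exact calibration formula and gap model of the published weight
  scheme are not reproduced here; its worked-example scores are
  reproducible only with that weight file loaded via `read_weight_matrix`.
- Heritability is an assumed constant, not estimated; unequal census
  weights are supported structurally but not exercised.
- No semilandmark sliding, allometry correction, or asymmetry
  decomposition; no least-cost geographic paths over land masks; no
  multiple-matrix regression.
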