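# amfsoil

Analysis of soil **arbuscular mycorrhizal fungus (AMF)** communities from
barcoded SSU rRNA amplicon reads: demultiplexing, closed-reference
virtual-taxon (VT) assignment, community-matrix construction and filtering,
and the spatial/temporal inference that such surveys rely on — Bray–Curtis
dissimilarity, rarefaction, PERMANOVA, multivariate dispersion, Poisson
richness models, and logit-scale distance decay of similarity with
permutation inference — plus the robustness experiments (depth
equalisation by repeated thinning and 3′ read trimming) and a synthetic
study generator so the whole pipeline is testable without sequencing data.

It is written for community ecologists working with 454-style barcoded
amplicon surveys of Glomeromycota (NS31/AML2 amplicon, MaarjAM-style VT
reference), but every statistical component is generic over any sample × taxon
count matrix with sample metadata.

## The model and statistics at the core

Reads of structure `[8-nt barcode][NS31 primer][amplicon]` are kept if the
barcode matches the study set, the forward primer is correct, and the
stripped payload is ≥ 170 nt. Reads are assigned to VT from 12-column
tabular alignment hits under the closed-reference criteria: identity ≥ 97 %,
alignment length within 10 nt of the shorter of query and subject, e-value
< 1e−50; ties on bitscore break by e-value then subject id. Samples with
< 10 hits and VT that are singletons over the whole run are removed, and the
matrix is row-normalised.

Between samples *i*, *j* with proportional composition *x*,

> BC_ij = Σ_k |x_ik − x_jk| / Σ_k (x_ik + x_jk)

- **PERMANOVA** partitions the Gower-centred squared-distance matrix with
  sequential sums of squares; the pseudo-F of each term is tested against
  999 free permutations of sample labels, p = (1+b)/(1+B).
- **Dispersion homogeneity** embeds samples by principal coordinates
  (negative eigenvalues handled by the d² = d²_real − d²_imag correction),
  and one-way ANOVA with (k−1, n−k) df compares distances to group
  centroids.
- **Distance decay** regresses logit(1 − BC) on spatial distance (metres)
  or temporal distance (days) by OLS; because pairs are not independent,
  the slope's significance comes only from label permutation, one-sided
  toward decay. AICs of untransformed- vs log-distance models are reported.
- **Expected rarefied richness** is E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)],
  computed with log-gamma.
- **Thinning** draws each sample down to a common depth (multivariate
  hypergeometric) and repeats the main analyses over many thinned matrices.

The synthetic generator emulates the study design: three 10×10 m plots
(3×3 grid, 5 m spacing), one plot revisited four times May–September,
37 VT, reads of 170–557 nt (median ≈ 382), ≈ 5.8 % of reads assignable to
AMF, per-sample assigned depths 13–1986, plot-level compositional
differences with no seasonal effect, and a weak logit-scale spatial decay
(β ≈ −0.011 per metre). See `docs/methods.md` for model details.

## Worked example

```python
import amfsoil as am

cfg = am.SimulationConfig(seed=7)                 # the default study conditions
truth, design = am.simulate_communities(cfg)
counts = am.simulate_counts(truth, cfg)
matrix, log = am.filter_matrix(counts)

sept = design.index[design["date"] == design["date"].max()]
dm = am.distance_matrix(matrix.subset(sept).normalise())

res = am.Permanova(dm, design.loc[sept, ["plot"]], ["plot"]).fit(
    n_permutations=999, seed=1)
print(res.summary())

pairs = am.build_pairs(dm, positions=design.loc[sept])
model = am.DistanceDecay(pairs)
print(model.fit().summary())
print(model.permutation_test(n_perm=999, seed=1).summary())
```

prints

```
PERMANOVA (sequential SS, 999 permutations, seed=1)
           df     SS      MS  pseudo_F     R2  p_perm
term
plot        2 0.9147  0.4574     5.215 0.3029   0.001
Residuals  24  2.105 0.08771       NaN 0.6971     NaN
Total      26   3.02     NaN       NaN    NaN     NaN
spatial distance decay (none distance, 351 pairs, 0 clamped):
  slope (logit scale) = -0.011234 [-0.01407, -0.0083985]
  intercept = 0.46957
  AIC untransformed = 398.37, log-distance = 398.70
permutation test (999 label permutations, alternative=less): slope = -0.011234, P = 0.001
```

The plot factor explains ≈ 30 % of Bray–Curtis variation among the 27
September samples (p = 0.001 over 999 label permutations), and pairwise
community similarity declines by ≈ 0.011 logit units per metre of
separation — the compositional signal the survey design is built to detect.

A console script exposes the same steps
(`amfsoil simulate | demux | assign | permanova | decay | thin-study |
trim-compare | run`); try `amfsoil --help`.

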