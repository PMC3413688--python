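# Methods

This note documents the models, conventions and numerical choices behind
`amfsoil`, and what the synthetic-data experiments do and do not show.

## Read preprocessing

Raw reads are `[8-nt barcode][forward primer NS31][payload]`. Acceptance
requires, in order: a barcode present in the study's barcode map, an exact
forward-primer match, and a stripped payload of ≥ 170 nt. Each read
increments exactly one counter (`n_pass`, `n_bad_barcode`, `n_bad_primer`,
`n_too_short`), so counters always partition the input. Matching is exact
by default; an optional Hamming budget exists for both barcode and primer
but is off because the acceptance criteria are stated in terms of the
*correct* primer and a *matching* barcode. Reads with ambiguous bases in
the barcode are rejected (counted as bad barcode) rather than rescued.
The reverse primer is not required. Median read length for an even count
is the mean of the central pair. The trimming utility keeps the 5′ end,
cuts to an exact target length, and drops reads shorter than the target;
the robustness experiment first selects reads of > 400 nt.

## Closed-reference assignment

Hits are consumed as the standard 12-column tabular alignment dialect; the
package does not run an aligner (an external BLAST can produce the file).
A hit passes when identity ≥ 97 %, |alignment length − min(query length,
subject length)| ≤ 10 nt, and e-value < 1e−50 (strict). Per read the
passing hit with maximal bitscore wins; ties break by lower e-value, then
lexicographically smallest subject id, making assignment independent of
input order.

Filtering removes samples with < 10 assigned reads and singleton VT.
"Singleton" is read as *total read count of exactly one across the retained
run* (the conventional amplicon-QC meaning); a per-sample-occurrence
variant is available via `singleton_rule="samples"`. The two filters are
iterated to a fixed point so the result does not depend on the order in
which they are stated; VT left with zero reads after sample removal are
dropped and logged separately. Row-normalisation divides by row totals and
refuses zero rows by name.

## Distance-based inference

**Bray–Curtis** follows the proportional-composition formula; it is
computed on whatever mode the matrix is in, and a test guards the fact
that counts and proportions give the same value only when row totals are
equal (no silent normalisation).

**PERMANOVA.** With A = −d²/2 and G = JAJ (J the centring matrix),
SS_total = tr(G). Terms are dummy-coded sequentially (Type I); the m-th
term's SS is tr(H_m G) − tr(H_{m−1} G) with H the hat matrix of the nested
design, and its pseudo-F is MS_term/MS_residual. Significance uses free
permutation of sample labels (rows/columns of G), p = (1+b)/(1+B) so p is
never zero. Because sequential SS depend on term order, the two-factor
seasonal analysis is reported in both orders. Degenerate inputs —
all-identical samples, single-level factors, non-positive residual df —
raise instead of returning numbers.

**Dispersion.** Principal coordinates are taken from the eigendecomposition
of G; axes with negative eigenvalues are retained as "imaginary" axes and
squared distances to the group centre are corrected as d² = d²_real −
d²_imag, clipped at zero (clips are counted). The default centre is the
group centroid; a spatial-median centre (Weiszfeld iteration) is available
for compatibility with the common R implementation. Group differences in
the resulting distances are tested by one-way ANOVA with (k−1, n−k) df.
The implementation reproduces R vegan's `betadisper(type="centroid")`
distances to 1e-7 on a fixture.

**Poisson richness.** Per-sample VT richness is modelled by a log-link
Poisson GLM on the grouping factor, fitted by IRLS (tolerance 1e−10,
max 100 iterations, non-convergence raises with diagnostics). The group
effect is the deviance difference against the intercept-only model on a
χ² with k−1 df. Log-link MLE group means equal arithmetic group means,
which doubles as a self-check.

**Rarefaction.** E[S_n] is evaluated with log-gamma; taxa with N−N_i < n
contribute exactly 1. The group curve averages per-sample expectations at
each depth over the samples deep enough to support it.

## Distance decay

Similarity is 1 − BC. The dependent variable is logit-transformed after
clamping into [ε, 1−ε] (ε = 1e−3, configurable; clamps are counted and
reported since similarity can hit 0 or 1 exactly). Spatial distance is
Euclidean in metres; temporal distance is the absolute difference in days
— the day scale is the package's convention, chosen because a slope of
order −1e−3 per unit is only plausible per day across a ~100-day season.
OLS gives slope and intercept; the Gaussian AIC with estimated variance
(k = 3 parameters) is reported for the untransformed- and log-distance
models. When zero distances are present (repeat visits to the same
location on the same date make 0-day pairs), the log transform falls back
to log1p and this is the documented convention. Pairwise observations are
not independent, so no analytic p-value is attached to the slope; instead
sample labels of the similarity matrix are permuted (the pair structure,
n(n−1)/2 pairs, is preserved by construction) and the one-sided tail
toward decay is reported with the (1+b)/(1+B) convention. The label
permutation acts on the similarity side; permuting before or after
computing similarities is equivalent because distances attach to labels.

## Robustness experiments

**Thinning.** Each sample is drawn down to a common depth (default: the
minimum row total) by a multivariate hypergeometric draw, so zero cells
never gain reads and row sums are exact. For each of (by default) 1000
thinned matrices the spatial PERMANOVA, the two-factor seasonal PERMANOVA
and both decay fits are re-run. To keep 1000 repetitions desk-scale the
PERMANOVAs inside the study use 199 permutations (headline analyses use
999) and the decay slopes are recorded without permutation inference —
only their signs are summarised. Per-matrix significance uses α = 0.05;
because "< α" versus "≤ α" is a matter of reading, both counts are kept.
The sample/singleton filters are *not* re-applied after thinning: the
study thins the final matrix.

**Trimming.** Assignments of the same reads at a reference length and a
3′-trimmed length are compared: % identical (None = None counts as
identical), % identical omitting reads unassigned in either set, trimmed
VT richness and its % of the reference set, and — after dropping samples
with < 10 assigned reads in either set and normalising per-sample profiles
over the union VT set — mean Bray–Curtis distance and mean Pearson
correlation between matched samples.

## Synthetic study generator

The generator is the package's study stand-in, a pure function of
(config, seed):

- **Design.** Three plots of 3×3 grid points at 5 m spacing; plot centres
  on an equilateral triangle of side 40 m (plots 30 m apart edge to edge),
  so the maximum pairwise sample distance is ≈ 54 m. One plot is sampled
  on four dates (2009-05-25 … 2009-09-03, a 101-day span), the others on
  the final date only. The plot geometry is a documented convention, not a
  measured layout.
- **Communities.** Per-sample VT proportions are Dirichlet draws
  (concentration 30) around softmax-transformed log-abundance fields
  combining: a common VT profile (sd 2.0, giving realistic dominance and
  per-sample richness ≈ 13 of 37 VT), per-plot shifts (sd 0.4), optional
  per-season shifts (sd 0 by default — no seasonal effect), and a
  time-constant Gaussian-process field over grid locations (Gaussian
  kernel, range 25 m). The Dirichlet-multinomial is the standard
  compositional-count model and produces realistic overdispersion.
- **Decay calibration.** The field sd is set to sqrt(|β|/c) with
  c = 0.05, a constant found by simulation (not claimed analytically) such
  that, at the default plot effect, the fitted September logit decay slope
  averages ≈ β = −0.011 per metre. Changing the plot effect or kernel
  range shifts the realised slope; the calibration holds near the
  defaults.
- **Reads.** Per sample, the AMF-assigned depth is log-uniform in
  [13, 1986]; non-target reads are added so AMF reads are 5.8 % of the
  total. Reads are barcode + NS31 + a 5′ prefix of the (557 nt) reference
  sequence with independent substitution errors at 0.25 % per base;
  lengths follow a scaled Beta(2.35, 2) on [170, 557], median ≈ 382.
  Non-target templates are shuffled reference sequences, which guarantees
  they fall far below the 97 % identity criterion without modelling any
  particular non-target taxon.
- **Hits.** Identity is recomputed by positional comparison of the
  stripped payload against its template prefix, so it reflects the errors
  actually introduced. Bitscore/e-value come from a fixed, documented
  monotone surrogate (bitscore = 2·matches − 3·mismatches; e-value =
  L·3191·2^−bitscore floored at 1e−180); tests depend only on the
  criteria thresholds, never on this scale. A small fraction of AMF reads
  also receive a truthfully-scored hit against a wrong reference to
  exercise best-hit selection; non-target reads receive no hits.

**What passing tests do and do not show.** The generator has no homopolymer
or chimera error structure, no alignment gaps (identity is positional), no
database incompleteness, and its non-target pool is statistically, not
biologically, realistic. Tests on it validate the *procedures* — criteria
logic, partitioning identities, permutation calibration, power at the
study's sample sizes — not field conclusions about any real soil.

Two emulation caveats are worth knowing. First, the time-constant spatial
field gives repeated visits to a grid point genuinely correlated
communities, so the seasonal model's sample-point term carries a weak real
signal (detected in ~10 % of thinned matrices) where the original survey
found none. Second, the seasonal PERMANOVA under the generator's *default*
conditions is conservative for the season term (repeated measures at fixed
points violate exchangeability in the conservative direction); the type-I
error calibration tests therefore run under a fully exchangeable null
(all effects zero), which is the regime where uniformity of the p-value is
the correct expectation.

## Problem sizes

The test suite runs the full design at reduced depth (per-sample assigned
depths ≤ ~150 and 8–12 VT) for read-level checks, and the statistical
calibrations use 300–500 Monte-Carlo replicates with 99 permutations each.
The acceptance script runs the full survey scale: ~300 000 reads,
37 VT, 54 samples, 999 permutations for headline analyses and 1000
thinned matrices at 199 permutations — about a minute on one CPU. These
sizes are the package's own defaults for a desk-scale reproduction.

## Known limitations

- No FASTQ/quality-score handling, denoising or chimera scoring; the
  closed-reference criteria are the quality filter.
- The aligner is external by design; only its tabular output is consumed.
- Sequential (Type I) sums of squares only; no marginal (Type III)
  PERMANOVA, no restricted permutation schemes.
- No NMDS ordination or Mantel-type spatial statistics beyond the logit
  decay procedure.
- Reference-database versioning is out of scope: assignments are only as
  good as the reference provided.
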