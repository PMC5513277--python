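# Methods

## Data model and units

The atomic unit is the note: a continuous spectrogram trace with start
and end time (seconds) and low and high frequency (Hz).  Notes carry
song, individual and population labels; song membership is taken from
the labels (songs in the target study were delimited manually), and a
silence-gap segmenter (default threshold 1.0 s) is available but off
by default because "distinctly separated in time" has no published
quantitative threshold.  Notes inside a song are ordered by start time
(ties by end time, then input order) and may overlap — overlap is a
signal, not an error.  Validation is strict by default (a bad row
fails the read); lenient mode drops bad rows with logged row numbers.
All times stay in seconds and frequencies in Hz throughout; the 2 ms
CVM threshold is held internally as 0.002 s to avoid unit drift.

## Spectral features

Fourteen song-level variables are derived per song.  The exact
published list of the target design is not available in full, so the
set is reconstructed from the named principal-component loadings
(mean/SD of high frequency, note bandwidth, song bandwidth, SD of low
frequency; mean/SD of note length, delivery rate; the two CVM
variables) completed with the standard measures (mean low frequency,
song duration, note count) to reach fourteen.  The set is exposed as
`features.FEATURE_NAMES` and the extractor is column-driven, so it can
be amended.

Definitions: internote interval i = start(i+1) − end(i), negative on
overlap.  CVM counters: *short interval* = interval in [0, 2 ms);
*overlap* = interval < 0; each consecutive pair feeds exactly one
counter (the source description treats them as two variables without
stating exclusivity; exclusivity keeps the two rates interpretable as
disjoint event frequencies).  Both counts are divided by the song's
note count.  The SD of a single observation is defined as 0 so
one-note songs stay usable.  Delivery rate is notes per second
(count / song duration).  Frequency shift for pair i = high(i) −
low(i−1); its interval class uses the same interval as the CVM
counters, with exactly 2 ms falling in the upper (at-or-above) class.
The two classes are compared with a two-sample Kolmogorov–Smirnov test
pooled over all songs (the per-song variant is available), p from the
asymptotic distribution.

## Syntax complexity

Song-type identity was originally a trained visual judgement; the
package operationalizes it with an explicit, reproducible rule.  Notes
are quantized into classes on log duration × log bandwidth with bin
width log(1 + tolerance), tolerance 20 % by default; absolute
frequency position is excluded, so a transposed song keeps its type.
Maximal runs of ≥ 2 identical consecutive classes (trills) collapse to
a single run marker: trill elongation or shortening does not create a
new type, but adding or deleting a non-trill note does.

Bouts are the first N = 11 consecutive songs of each individual
(random start points available as the robustness diagnostic);
individuals with fewer songs are excluded with a warning.  Categories,
in precedence order: *same* (equals the previous song's signature),
*old* (equals an earlier non-adjacent song's), *mod* (novel signature
sharing a contiguous two-class block with any earlier song in the
bout — a weaker, length-1 criterion would make nearly every song
"mod"), else *new*; the first song is "new" by convention.  SVI =
distinct signatures / N.  Bootstrap CIs resample individuals within a
population (the unit that the per-population summaries average over),
percentile method, 1,000 replications, seeded.

## Multivariate battery

PCA runs on the correlation matrix (the variables mix Hz, seconds,
counts and proportions); components with eigenvalue > 1 are retained,
capped at rank, with signs fixed deterministically (largest-|loading|
element positive).  The nested MANOVA tests the population effect
against the individual-within-population SSCP and the individual
effect against the song-level residual, using Wilks' Λ (the common
default of desktop statistics packages) with Rao's F approximation;
Λ reduces exactly to the classical nested ANOVA F for one response,
which is how it is unit-tested.  Individuals are treated as fixed
nested effects.  The DFA solves the generalized eigenproblem
B v = λ W v; canonical correlation per axis is √(λ/(1+λ)); a
near-singular W is ridge-regularized with a logged epsilon.  The
reported classification rate is resubstitution — matching how such
rates are usually reported for a fitted discriminant model —
with leave-one-individual-out cross-validation available as the honest
alternative.  NMDS uses SMACOF with monotone regression on Euclidean
distances between z-scored feature vectors (the dissimilarity is not
pinned down by the source design; Euclidean on standardized variables
is the transparent default), best of R seeded random restarts,
reporting Kruskal's normalized stress-1.  The CVM rates are far from
normal, so population differences use Kruskal–Wallis (tie-corrected)
with Dunn's z from pooled mean ranks and Bonferroni adjustment over
all pairs.

## Isolation analysis

Distance matrices are label-aligned, symmetric, zero-diagonal.
Geographic distance is great-circle km (the original supplementary
definition is unavailable; haversine is the transparent default, and
user-supplied matrices are accepted everywhere).  Barrier distance
assigns populations to ordered zones along the mountain chain with one
barrier between consecutive zones; the entry is the zone difference
(count, 0–3), with a binary any-barrier encoding available.  Both
encodings were evaluated on simulated defaults: the count preserves
the syntax-vs-spectral contrast better, so it stays the default.
Song distances: spectral = Euclidean between population centroids in
retained-PC space; syntax = Euclidean over (mean SVI, four mean
category proportions).  F_ST matrices are inputs only.

Mantel r is the Pearson correlation of upper triangles; the null
permutes one matrix's rows and columns jointly.  When n! ≤ the
requested permutation count the null is enumerated exhaustively and p
is exact (identity included); otherwise p uses the add-one correction
(1 + extreme)/(1 + permutations).  The default tail is one-sided
positive, matching the isolation-by-distance hypothesis; the default
permutation count is 9,999.  The partial Mantel correlates residuals
after regressing both triangles on the control's, permuting the first
matrix with residual recomputation.

## The simulator

The generator emulates the hierarchical structure the analysis
assumes, at the published design scale: 6 populations (2–10
individuals each, 38 total), 11–30 songs per individual (truncated
normal 22 ± 7), notes with Gaussian lengths and bandwidths truncated
positive, a uniform transposition window per rendition, and internote
gaps drawn per consecutive pair: with probability `cvm_prob` from the
CVM window [−10 ms, 2 ms) (uniform — no distributional shape is
published, so uniform is the least-assumptive choice), otherwise from
a positive uniform window centred so the target delivery rate is met
in expectation (an infeasible rate/note-length combination is a config
error).

Song organization is a 4-state categorical chain per individual: at
each position, novelty occurs with probability `repertoire_turnover`,
split between "new" and "mod" by `new_frac`; repeats split between
"same" and "old" by `same_frac`.  The split fractions differ by song
cluster (simple 0.80/0.65, complex 0.55/0.35, intermediate 0.65/0.50)
because the clusters in the target system differ in versatility
composition — the complex cluster modifies songs often and rarely
repeats, the simple cluster the reverse — not only in turnover.  The
SVI implied by the chain depends only on turnover; its expectation is
computed by Monte Carlo from the same chain and used as the recovery
target.  "Mod" types retain a copied contiguous block of ≥ 2 note
classes from a parent type, and independently created types within an
individual never share an ordered class pair, so the bout classifier
recovers the planted categories exactly by construction.  Signatures
are globally unique across individuals (enforced by registry), so the
sharing matrix off-diagonal is exactly zero, reproducing the empirical
no-sharing observation generatively.  Synthetic F_ST is fabricated as
`clip(0.06·barriers + 0.00015·km + N(0, 0.01), 0, 0.5)` — a monotone
function of both isolation axes plus noise.

Default per-population parameters place the simple cluster (long,
narrow-band, slowly delivered notes; turnover ~0.5) in the north, the
complex cluster (short, wide-band, fast; turnover 0.84; CVM prevalence
high in two of its three populations) in the centre, and an
intermediate population in the south, with coordinates spanning
~600 km and turnover constant within the central barrier zone so that
syntax distances are generated by barriers while spectral distances
carry the cluster-plus-gradient geography.

### What the simulator does not emulate

Notes are stationary boxes (no frequency modulation within a note);
types re-render with identical durations and bandwidths up to
transposition and trill length, so the visual-matching tolerance is
never stressed by within-type drift; recording noise, missed notes and
annotation error are absent.  Passing tests therefore show that the
pipeline's *inference machinery* is correct and calibrated at study
scale — they do not show that the 20 % matching tolerance or the
distance definitions are right for real shortwing recordings.

## Statistical behaviour at study scale

Two properties of the design deserve explicit statement, both verified
by simulation and reported in the test suite:

* Single-dataset Mantel contrasts are noisy.  With the published
  population SVI means and sample sizes (one population has two
  individuals), the expectation-level syntax↔barrier correlation
  (≈ 0.66) exceeds the spectral↔barrier one (≈ 0.55), but the
  per-dataset margin is smaller than the sampling noise of population
  syntax means: the contrast appears in roughly three quarters of
  replicate datasets.  The acceptance test therefore asserts the
  contrast across 15 replicate simulations (majority rule) rather
  than on a single arbitrary dataset.
* Permutation tests are calibrated: under simulation nulls the
  one-tailed Mantel and the Kruskal–Wallis tests reject at ~5 % at
  α = 0.05 (2,000 replicates each), and for n = 4 populations the
  Mantel p equals exact enumeration over all 24 relabelings.

## Problem sizes and numerical choices

The default test-suite and acceptance runs use the full 38-individual
design (~800 songs, ~5,000–6,000 notes), 999 Mantel permutations in
pipeline context (9,999 via CLI default), 1,000 bootstrap replications
and 2 NMDS restarts with up to 200–300 SMACOF iterations (the
ordination dominates runtime; restarts are a quality/time dial and 20
remains the function default).  Degenerate inputs are handled
explicitly: all-equal dissimilarities flag a degenerate ordination,
globally tied rank tests return χ² = 0 with p = 1, constant distance
matrices raise an undefined-correlation error, a constant control
matrix demotes the partial Mantel to a simple one with a warning, and
single-individual populations yield point estimates with the CI
flagged unavailable.
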