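# Methods

## Size/shape decomposition

All analyses work on natural logarithms of linear measurements (µm).
For specimen *i* with measurements $x_{i1},\dots,x_{ip}$:

- *isosize* $z_i = \tfrac1p \sum_j \ln x_{ij}$ — the log geometric mean,
  an isometric size score;
- *shape* $s_{ij} = \ln x_{ij} - z_i$ — the per-variable deviation from
  that mean.  Each shape vector sums to zero, and multiplying all of a
  specimen's measurements by $c>0$ adds $\ln c$ to isosize and leaves
  shape untouched.

Covariance (not correlation) is used throughout: the variables are
commensurate log-micrometre quantities, so their scales are meaningful
and should not be equalized.

Missing cells are dropped listwise before the decomposition (no
imputation); the dropped specimen ids are reported on the result.  The
default variable selection is the full 31-code measurement vocabulary
minus eye length, head length and temple length (28 variables), the
three distances with clearly higher measurement error.

## Shape PCA

The shape matrix is centred across specimens and decomposed by SVD.
Because shape vectors sum to zero, all loadings are orthogonal to the
equal-weights (isometric) direction; the rank is at most
min(n−1, p−1) and trailing numerically-zero components are discarded.
Variance fractions are percentages of total *shape* variance (the trace
of the shape covariance) and sum to 100 over the retained components.
Signs follow a deterministic convention — each loading's
largest-magnitude entry is made positive — so results are reproducible
across runs and platforms.  Rank-zero input (all specimens identical in
shape) is returned with all eigenvalues zero and a `degenerate` flag
rather than an error.

## PCA ratio spectrum

A shape PC's loadings are ordered on a line; the two extreme variables
define the single ratio that best approximates the PC, and variables
clustered near the centre contribute little to it.  Bootstrap intervals
resample specimens with replacement, recompute the shape PCA, and
sign-align each replicate's loading vector to the point estimate by dot
product before taking percentile 95% bounds.  The bounds are widened to
include the point estimate in the rare replicate geometries where the
percentile interval would not contain it, so the documented invariant
(interval contains estimate) always holds.  The default replicate count
is 1000 and every bootstrap is seeded.

## Allometry diagnostics

For each group the PC score is regressed on isosize by OLS.  A pooled
common-slope model with a group indicator (ANCOVA) then estimates the
between-group score offset at equal size.  When |offset| exceeds twice
its standard error the groups are flagged as *not* lying on a common
allometric axis — their shape difference cannot be explained as a
shared size–shape trend.  The 2-SE factor is a package decision (no
numeric criterion is standard in the field) and is exposed as a
parameter.  A group with zero isosize variance gets `slope = None`
rather than a crash.

## LDA ratio extractor

The Fisher discriminant direction
$d \propto S_w^{-1}(\bar s_1 - \bar s_2)$ separates two groups best but
mixes all variables.  The extractor therefore searches the restricted
family of ratio directions $(e_i-e_j)/\sqrt2$: for each of the
$p(p-1)/2$ pairs the specimens' log ratios are projected and scored by
standardized separation |Δmean| / pooled within-group SD.  Pairs are
ranked by that score (ties broken lexicographically by variable code).
This exhaustive definition is directly verifiable against a brute-force
oracle and matches the published intent of the method; the original
method's δ/ε quality coefficients and its orthogonalized second-ratio
search are not reproduced.

Each reported pair carries the raw-scale per-group ratio ranges and
which group lies high.  When the ranges are disjoint a threshold is
reported at the midpoint of the gap, rounded to two decimals — unless
rounding would leave the gap, in which case the exact midpoint is kept
so that max(low group) < threshold < min(high group) always holds.
Published thresholds of this kind (e.g. 2.73 for eye distance : POL)
are treated as bounds the data satisfy, not as values the midpoint must
equal, since how they were rounded is not documented.  A ridge term
(default $10^{-8}\,\mathrm{tr}(S_w)/p$) stabilizes the pooled solve for
the full discriminant when shape data are rank-deficient.

## Bland–Altman gauge agreement

Differences are taken as second series minus first; bias is their mean,
and limits of agreement are bias ± 1.96 sample SD.  The conventional
1.96 multiplier is fixed.  Used to confirm that a new measurer's values
are interchangeable with an earlier campaign's before pooling data.

## Key engine

Descriptors are categorical (≥ 2 named states, taxa may carry several)
or quantitative (closed [min, max] range per taxon), each with an
importance weight 1–5.  Elimination semantics: a taxon survives an
observation iff its cell contains the chosen state / covers the entered
value, or the cell is unknown or inapplicable — unknown data never
eliminate, which is what lets damaged specimens be identified.
Inapplicable cells behave like unknown for elimination but are reported
separately by the diagnostics.  Weights influence only the suggestion
order, never elimination.  Quantitative matching accepts an optional
relative tolerance (default 0) because real specimens routinely exceed
a key's recorded ranges.

Suggested descriptors are ordered by (weight desc, expected elimination
power desc, name), where power is the expected fraction of remaining
taxa excluded under a uniform choice over states; quantitative
descriptors are discretized at the remaining taxa's range endpoints.

`checkbase` reports identical description pairs, undescribed (unknown)
cells, descriptors unknown for every taxon, and inapplicable cells, in
deterministic order.

`shortest_identification_path` searches for the minimum number of
observations — drawn from the target's own description, so the target
always survives — that reduce the remaining set to exactly the target.
Candidate numeric observations are one representative per cell of the
arrangement of all taxa's range endpoints clipped to the target's
range (endpoints plus gap midpoints); distinct elimination outcomes are
deduplicated, and iterative-deepening DFS with a covering bound prunes
the search.  Taxa that no observation can eliminate (e.g. identical
descriptions) raise "not isolatable"; exceeding the depth bound raises
"bound exceeded".  Path lengths on real published keys depend on the
full descriptor matrix, so the search is a tool for auditing one's own
matrix, not a reproduction of any published step count.

The flat-key export recursively applies the same best-split criterion:
each node emits one lead per informative choice, taxa with unknown
cells follow every lead, and leaves list one taxon or a flagged
indistinguishable group.  A descriptor is only accepted at a node if it
genuinely splits the remaining taxa, and is consumed along the branch,
which guarantees termination.

## Synthetic data

The measurement generator draws
$x_{ij} = \exp(\mu_j + \delta_{g(i)j} + \beta_j s_i + \varepsilon_{ij})$
with $s_i \sim N(0, \sigma_s^2)$ and
$\varepsilon_{ij} \sim N(0, \sigma_\varepsilon^2)$.  Defaults model a
typical two-species delimitation study: two groups of 30 specimens, the
28 standard variable codes, base log means spread over 80–1500 µm,
σ_s = 0.1 (≈ 10% joint size variation), σ_ε = 0.02 (≈ 2% residual
measurement/shape noise — the order observed in careful insect
morphometrics), slopes all 1 (pure isometry, so size cancels from every
ratio).  A planted contrast adds ±δ to a chosen variable pair in the
second group; the recovery benchmarks use δ = 3σ_ε.  What the generator
does *not* emulate: per-gauger error structure, correlated measurement
error between neighbouring body parts, allometry differences between
groups (unless planted), or phylogenetic signal across taxa — so
passing recovery benchmarks demonstrate statistical correctness of the
pipeline, not that any particular real dataset will separate.

The key-matrix generator draws random descriptors (2–4 states or
decade-grid ranges) and cells with controlled polymorphism and
unknown-cell rates.  With distinctness requested it redraws a taxon
until it is both unique and mutually separable from all previous taxa
(each possesses an observation eliminating the other), which is exactly
the condition for every taxon to have a finite identification path;
when the descriptor space cannot support this it raises an error rather
than looping.

## Reference fixture

The built-in *Pteromalus* key matrix carries the 47 published taxon
names (29 tagged as members of the *P. albipennis* species group) and a
representative descriptor subset: the paraspiracular inclination
(sharp/blunt), the two metasternum characters (pit, fissure), and the
two published discriminating ratios with their threshold-consistent
ranges.  Interval ends away from the published 2.73 / 5.85 bounds are
synthetic plausible extremes, marked as such in the source.  Cells not
stated in the published diagnoses are unknown — the fixture is a
faithful miniature of a partly-described working database, not a
transcription of the full published key.

## Problem sizes

The test suite and the acceptance script use 200 replicates of 30+30
specimens × 28 variables for the recovery benchmarks, 50 × 50 matrices
for the diagnostics completeness check, and 6–10-taxon matrices for the
exhaustive path-search oracles; the whole suite runs in well under a
minute on one CPU.

## Known limitations

- Two-group discriminant analysis only; multi-group ratio extraction
  and classification of new specimens are out of scope.
- The three checks against the deposited *Pteromalus* measurement files
  require those CSVs to be supplied locally (`data/README.md`); the
  loader for them infers the species column heuristically and may need
  adjustment to the exact deposited layout.
- The variance-explained convention (percent of total shape variance)
  could not be confirmed against the deposited data in this build for
  the same reason.
- SDD XML interchange is not implemented; the key format is the
  documented JSON schema plus CSV/flat-text export.
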