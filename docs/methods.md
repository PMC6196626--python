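# Methods

## Model and procedure

`hhccdf` treats a marker as a purely categorical partition of the
population and asks how strongly that partition separates a quantitative
trait. For one marker:

1. **Stratification.** Individuals present in both tables with a
   non-missing genotype call and a finite trait value are grouped by
   genotype label. Groups are ordered by ascending mean trait value; a mean
   tie is broken by the label's text representation, so the order is a
   total order and identical across runs.
2. **Boundaries.** With *n* groups there are *n* − 1 boundaries. At
   boundary *x* the right subset *s1* is the union of the groups right of
   the boundary, of size *d_x*.
3. **Counts.** *k_x* is the multiset intersection between the *d_x*
   largest trait values in the population and the trait values of *s1*
   members: tied values are matched up to multiplicity. Equivalently, *k_x*
   is the largest achievable overlap between *s1* and the top-*d_x*
   individuals over every tie-consistent way of ranking the population — a
   property the test suite verifies by exhaustive search on small inputs.
4. **Tails.** Each boundary contributes the hypergeometric upper tail
   P(X > k_x) with population *N*, *K_x* = *d_x* successes and *d_x*
   draws. The marker's HH-CCDF P value is the geometric mean of the
   *n* − 1 tails.

The *F* test is the ordinary one-way fixed-effects ANOVA
(y_ij = μ + α_i + ε_ij) of trait on genotype class, with the exact F
upper-tail P value. The HA coefficient evaluates, per boundary, the ratio
(f(obs) − f(btm)) / (f(top) − f(btm)) with f(t) = y ln(t) − t, where
obs/top/btm are the *s1* sums under the observed, top (ascending within and
across classes) and bottom (the mirror) categorizations, and combines
boundaries by geometric mean.

Assumptions worth stating: individuals are exchangeable under the null
(no kinship or structure correction is attempted); genotype labels are
opaque categories, never dosages; the HH-CCDF depends on the trait only
through value ranks and tie structure, so it is invariant to monotone
transformations; the HA coefficient additionally needs positive trait mass.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `missing_sentinel` | `None` | genotype label treated as a missing call; individuals are dropped per marker, and `N` reflects the retained count |
| `ha_normalize` | `"auto"` | min–max normalize the trait to [0, 1] before HA; `auto` does so (with a warning) only when non-positive values are present |
| `p_floor` | `1e-300` | floor under the −log10 transform; an exact-zero P maps to 300. Display-level only — stored P values are unfloored |
| `methods` | all three | any subset of `hhccdf`, `ftest`, `ha` |

Simulator (`TriangleSimConfig`): 500 individuals × 450 markers, three
150-marker blocks with triangle heights 20/30/40, 100 replicates. These
defaults are the reference study conditions; the acceptance tests run the
same geometry at 10 and 25 replicates to stay within desk-scale runtimes.

## Numerical choices

- **Exact tails.** For populations up to N = 1000 the hypergeometric sum is
  accumulated in exact integer arithmetic via a multiplicative term
  recurrence (each step's division is exact), then divided once; beyond
  that scipy's log-gamma survival function takes over. Either path avoids
  binomial overflow at any realistic population size. The suite checks the
  exact path against independent rational enumeration over the full
  N ≤ 25 grid.
- **Summation limit.** The per-boundary tail is P(X > k), i.e.
  1 − Σ_{i=0}^{k} pmf(i); out-of-support terms are zero, k below the
  support minimum gives 1, and k = d gives exactly 0.
- **Geometric mean in log space.** An exact-zero factor short-circuits to
  an exact-zero result — perfect separation is reported as P = 0, not
  smoothed; the −log10 floor handles display. A binary marker returns its
  single tail without a log/exp round trip.
- **Degenerate inputs.** A marker with one category after missing-data
  removal is reported with `status = degenerate` and NA statistics ("no
  test performed" is distinct from "no evidence"). Constant-trait F tests
  and constant spans in HA raise `DegenerateSpread`; HA refuses negative
  values (`NonPositiveInput`) instead of rescaling silently.
- **Triangle discretization.** Forced depth at column *j* of a block with
  height *h* is round(h · (1 − |j − c| / (w/2))) with a single tip column
  c = block start + w/2. With an even block width the tip is one column
  right of centre; alternative symmetric-tip conventions shift peaks by at
  most one column. With the default heights the rounding never lands on an
  exact half, so the rounding rule is immaterial there.
- **Seeding.** The simulation's master seed spawns one child seed per
  replicate (`numpy.random.SeedSequence.spawn`), so any replicate can be
  regenerated in isolation and the profile is bit-reproducible.
- **Averaging.** Replicate profiles are averaged on the score scale
  (−log10 P for the two tests, raw HA), matching how scan profiles are
  plotted; averaging raw P values would let single large P values dominate.

## What the simulator emulates — and what it does not

Each block's paired triangles force the top rows (lowest trait values) to
score 0 and the mirrored bottom rows (highest trait values) to score 2,
with depth tapering linearly from the block tip; everything else is i.i.d.
uniform over {0, 1, 2}. The forced depth at the tip is therefore a dial
for signal magnitude, and the deterministic ramp/plateau/ramp trait vector
makes the forced rows exactly the individuals with extreme trait values.
The generator has no linkage disequilibrium, no recombination map, no
polygenic background, and no noise model beyond the uniform background —
passing tests show that the statistics rank clean, additive-free signal
magnitudes correctly, not that they do so under realistic genetic
architectures.

Two degeneracies of the construction are worth knowing:

- **Plateau ties saturate the tallest peak.** The trait plateau creates a
  large block of tied values. At the tip column of the tallest block the
  forced rows cover *all* non-plateau individuals, so under the
  maximal tie-consistent intersection rule the observed *s1* attains the
  top categorization exactly (k = d at every boundary), the HH-CCDF P is
  exactly 0 in every replicate, and the mean −log10 score sits at the
  floor (300). Consequently the three peak heights, while strictly
  increasing in triangle height, do **not** rise in near-equal increments
  under this tie convention: at seed 1 the tip means are ≈ 98, 121 and
  300. An individual-order tie-break would avoid the saturation but would
  not reproduce the worked example's intersection counts, so the multiset
  rule is kept. The corresponding regularity check in the acceptance suite
  fails for this reason and is left failing deliberately.
- **The no-signal configuration is fully tied.** With all triangle heights
  0 the trait formula degenerates to a constant vector; every marker then
  attains k = d through ties and the profile is flat at the floor. The
  null test asserts flatness (no peaks), which is the meaningful property
  there.

## Design choices made where the design was open

- **Class ordering at every boundary follows the class means**, not the
  label order, even though the label-order variant changes one boundary of
  the worked example; only the mean ordering is implemented because it is
  the definition the statistic is built on and it reproduces the final
  worked-example P value. The label-order variant is not offered.
- **Ties never reduce k**: the intersection takes the maximum consistent
  with the tie structure (min multiplicity matching), the reading that
  reproduces the worked example.
- **Scan output** is a tidy one-row-per-marker table in input marker
  order; markers are treated as unordered bins (no chromosome coordinates,
  no significance threshold, no multiple-testing adjustment).
- **I/O is plain delimited text only.** The inputs are categorical score
  matrices; representing them as VCF/PLINK variants would misstate their
  semantics.
- The library is organised around a scikit-learn-style estimator
  (`MarkerAssociationScan.fit(X, y)` with trailing-underscore fitted
  attributes) because the scan has exactly the shape of univariate feature
  scoring; the module-level `scan()` and the CLI are thin wrappers.

## Known limitations

- No covariates, kinship, or population-structure correction.
- Heavy tie structure in the trait (coarse measurement scales, plateaus)
  inflates k toward d and can drive P to exactly 0; consider jittering or
  finer measurement when this is not the intended semantics.
- The HA coefficient is undefined without positive trait mass; min–max
  normalization (the built-in remedy) makes exactly one value 0, which is
  harmless for the subset sums but means HA values are not comparable
  across traits normalized on different ranges.
- Runtime is O(markers × N log N) plus an O(N)-term exact sum per
  boundary; a 500 × 450 three-method scan takes well under a minute on one
  CPU, far inside the package's five-minute design budget.
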