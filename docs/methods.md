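# Methods

`sisterdiv` asks whether gall induction — an insect's reprogramming of plant
tissue into a feeding gall — behaves as a key innovation that accelerates
diversification, or as a specialization that suppresses it.  The evidence is
comparative: thirteen matched comparisons between a gall-inducing clade and
its non-galling sister, plus maximum-likelihood birth–death modeling on
richness trees.  This note records the models, conventions and numerical
choices, and what the synthetic-data world does and does not establish.

## Host breadth

Host range is quantified as the age (Ma) of the most recent common ancestor
of a clade's host plants — an evolutionary-depth measure that is comparable
across datasets, unlike host counts at an arbitrary taxonomic rank.  An age
of 0 encodes comparisons in which neither clade's host MRCA is resolvable
(both sisters confined to a single host genus); such pairs are treated as
exact ties.  The one-tailed alternative is that gallers have the narrower
(younger-MRCA) host range, the direction expected a priori from the
literature on galler specificity.

## ERM bipartition probabilities

Under an Equal Rates Markov null — every lineage sharing one speciation and
one extinction rate — each split of `n` extant species between two sisters
is equiprobable, so the probability that a focal clade holds at least its
observed `k` of `n` species is

    P(K >= k) = (n - k)/(n - 1),  k in {1..n-1}.

Each pair is tested against both directional alternatives (galler more
diverse, galler less diverse) with a Bonferroni correction across the two
hypotheses: each tail is compared to alpha/2 = 0.025.  No correction is
applied across the thirteen pairs, and no Fisher combination of the
per-pair probabilities is attempted (its known pathologies with two-tailed
component tests are the reason).  The two tails overlap in exactly one
split, giving the identity `p_galler + p_nongaller = n/(n-1)` which the
tests assert exactly (rational arithmetic internally).

### Comparison to printed reference values

Computed probabilities are compared to the printed cells of the source
comparison table via a *guard-digit* convention: round half-up at the
printed precision plus one digit, then at the printed precision.  The
convention exists because one cell (0.53488… printed as 0.54) is evidently
the product of two-stage rounding; every value that matches under direct
rounding also matches under the guard digit.  Two reference values are
flagged as unreproducible rather than reconciled:

* one galler ERM cell prints 0.97 where the formula with k = 1, n = 31
  gives exactly 1.00;
* the one-tailed host-breadth p prints as 0.050 with "five" significant
  differences, where the table's age columns yield six nonzero differences,
  all positive, hence an exact p of (1/2)^6 = 0.015625 under the drop-zeros
  convention.  (Under Pratt zero-inclusion, available behind a flag, the
  printed value is not recovered either.)

The printed two-tailed signed-rank p of 0.95 on the diversity contrasts is
likewise flagged: enumeration at W+ = 50, m = 13 gives 0.7869.

## Matched-pair contrast tests

Richness (or host age) of each pair is reduced to one contrast — raw
difference, proportional difference `(a-b)/(a+b)`, or log ratio `ln(a/b)`
(the metric of choice for richness, since it is symmetric and
scale-free).  The proportional form is the standard symmetric ratio; the
source cites its formula only by reference, so this definition is a design
choice.  Zero contrasts are dropped before ranking (standard signed-rank
practice).  The significance machinery dispatches on the number m of
nonzero contrasts:

* m <= 10: exact sign-permutation (randomization) test — all 2^m sign
  assignments enumerated; "at least as extreme" is inclusive, so
  p in [2/2^m, 1];
* 11 <= m <= 19: Wilcoxon signed-rank with the null distribution of W+
  enumerated exactly over sign patterns on the realized tie-averaged ranks
  (a conditional-on-ties exact test); two-tailed
  p = P(W >= max(W+, W-)) + P(W <= min(W+, W-)), capped at 1;
* m >= 20: normal approximation with tie correction and a 0.5 continuity
  correction toward the mean.

The one-tailed host test uses the exact signed-rank enumeration at any
m <= 19.  The binomial sign test doubles the smaller exact tail and caps at
1 (so 7 of 13 gives exactly p = 1).  All tests are invariant to pair order
and to a global sign flip (two-tailed case), properties asserted against
brute-force oracles in the suite.

## Birth–death taxonomic likelihood

Richness trees carry collapsed clades as tips: tip i has extant richness
n_i and stem age t_i (the age of its parent node).  Under a constant-rate
birth–death process with net rate r = lambda - mu and relative extinction
eps = mu/lambda, a clade that survives from one stem lineage has geometric
size:

    P(N = n | N >= 1) = (1 - beta) beta^(n-1),
    beta = (e^{rt} - 1)/(e^{rt} - eps).

The model log-likelihood is the sum over terminal clades.  Internal
branching times are deliberately *not* part of the likelihood: the
real trees behind the original analysis are unavailable, the stem-age
richness term is the component the method description specifies, and
recovery simulations define the validation surface.  Consequences: fits
depend on the tree only through the partition of tips into rate classes
and their stem ages, and the likelihood is invariant to jointly rescaling
time and rates (t -> ct, r -> r/c) — root height is therefore fixed at an
arbitrary 100 units, the convention used after nonparametric rate
smoothing.

Three fitting modes:

* **fixed** — one (r, eps) for all clades; eps fixed (0 and 0.95 are the
  conventional bracketing values) or free; n_params 1 or 2.
* **flexible** — an ancestral rate shifting to a descendant rate on the
  single best branch.  Candidate shifts sit on branches subtending internal
  nodes (two-rate tree-splitting at nodes); the two classes are fitted
  independently, which is exact because the likelihood separates.  The LRT
  against the fixed model uses chi-square df = 1 (fixed eps) or 2 (free
  eps); no correction is applied for selecting the best branch.
* **stepwise** — MEDUSA-style: start from one class with free eps, add the
  AIC-best shift (any branch, terminal included; the shifted class applies
  from the stem branch downward, with nested shifts overriding), stop when
  the improvement falls below the cutoff (default 4 AIC units).  Each class
  costs 2 parameters and each shift location 1, so
  n_params = 2·classes + shifts.

Numerical choices: beta is computed with `expm1`, switching to an
asymptotic form beyond rt = 500; r = 0 is the degenerate no-diversification
boundary (all mass on n = 1), reported as such when every clade is a
singleton.  Optimization is a vectorized log-spaced grid (64 points in r up
to log(total richness)·5/min stem age; 13 eps values) followed by one
bounded polish — deterministic, no stochastic restarts.  When two shift
placements induce exactly the same tip partition (a root child versus its
sibling), their likelihoods and AICs tie to machine precision; ties (within
1e-9) resolve to the smaller, derived clade, so reports are deterministic
and name the nested clade rather than the paraphyletic rest.

### Known statistical behavior

The best-branch LRT is strongly anti-conservative: maximizing over dozens
of candidate branches without correction rejects a true single-rate model
far above nominal levels in simulation.  This is expected — it is the
standard argument for preferring the stepwise-AIC criterion with a
conservative cutoff — and is why the null-model validation targets the
stepwise search (which retains the one-class model in ≥ 90% of
constant-rate replicates) rather than the raw LRT.  Shift *localization* by
the flexible fit is intrinsically limited: when the shifted clade contains
shallow, species-poor subclades, nested placements differ by fractions of
a log-likelihood unit, and the best branch identifies the true stem in
roughly three-quarters of replicates under the simulated regime below.

## The synthetic world

Generators emulate the statistical structure the analysis assumes, not any
particular empirical dataset:

* **ERM splits** — k uniform on {1..n-1}.
* **Sister tables** — each pair shares a stem age uniform on 10–60 Ma;
  clade sizes are survival-conditioned birth–death richnesses at net rate
  0.05/Ma (the magnitude estimated for the empirical trees) for the
  non-galler and 0.05·rate_ratio for the galler; rate_ratio = 1 is the
  exchangeable null used for type-I calibration.  Host ages are uniform on
  20–150 Ma with a 0.4 point mass of exact double-zero ties, mirroring the
  five fully tied rows of the empirical table.
* **Birth–death trees** — event-driven (Gillespie) simulation from two root
  lineages, complete with extinct lineages, pruned to the reconstructed
  extant-only tree; survival conditioning by rejection (capped at 1e5
  attempts); an optional shift switches one uniformly chosen lineage alive
  at a given age (and its descendants) to post-shift rates.  Stopping rule
  is either a fixed root age or a tip-count target (the present then sits
  at the would-be next event, keeping terminal branches positive).
* **Collapse** — every maximal clade whose stem crosses the collapse age
  becomes a tip carrying its extant richness; total richness is conserved
  exactly.
* **Recovery trees** — a pure-birth backbone stopped at the target tip
  count, rescaled to root height 100, with tip richness drawn from the
  survival-conditioned geometric law (the exact conditioned clade-size
  distribution, cross-validated against the Gillespie simulator by
  chi-square in the suite).  The shifted clade is the internal edge closest
  to the requested tip count, deeper stems preferred on ties.

What a green test establishes: the estimators are consistent and the exact
tests match enumeration oracles *under the model's own assumptions*.  What
it does not: robustness to among-lineage rate variation beyond a single
shift, to richness measurement error, to non-ultrametric input, or to the
taxonomic-sampling biases of real richness data.

## Limitations

* The richness-only likelihood discards branching-time information; on real
  trees this sacrifices power relative to fits that include the
  reconstructed-process term.
* The single-replicate sampling sd of the fixed-rate estimate at 50 clades
  (true r = 0.05) is about 0.006, so individual fits routinely miss by
  >10%; consistency is assessed on replicate means.
* Polytomies are read and flagged but shifts are only placed on existing
  branches; no attempt is made to resolve them.
* The Pratt zero-handling variant is exposed but untuned; all headline
  results use drop-zeros.
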