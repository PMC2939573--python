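# sisterdiv

Comparative tests of whether gall induction — the insect habit of
reprogramming plant tissue into a gall to feed in — raises or lowers net
diversification, for researchers doing sister-clade comparative analyses in
phylogenetics.  The package implements, as a tested pipeline:

* **ERM bipartition tests** — under an Equal Rates Markov null every split
  of `n` species between two sisters is equiprobable, so the tail
  probability that a focal clade holds at least `k` of `n` species is
  `(n−k)/(n−1)`; each galler/non-galler pair is tested against both
  directional alternatives at a Bonferroni-corrected `α/2 = 0.025`.
* **Matched-pair contrast tests** — raw, proportional `(a−b)/(a+b)` and
  log-ratio `ln(a/b)` richness contrasts, with significance dispatched on
  the number `m` of nonzero contrasts: exact sign-permutation enumeration
  (`m ≤ 10`), exact Wilcoxon signed-rank by enumeration on tie-averaged
  ranks (`11 ≤ m ≤ 19`), normal approximation with tie and continuity
  corrections (`m ≥ 20`); plus the exact tail-doubled binomial sign test.
* **Host-breadth test** — host range measured as the age (Ma) of the host
  plants' most recent common ancestor; one-tailed exact signed-rank test of
  the prior expectation that gallers are more host-specific.
* **Birth–death rate-shift fitting** on richness trees (ultrametric trees
  whose tips carry extant species counts): the stem-age taxonomic
  likelihood `P(n | t) = (1−β)β^{n−1}` with
  `β = (e^{rt}−1)/(e^{rt}−ε)`, a fixed single-rate model, a
  one-shift flexible model with LRT, and a MEDUSA-style stepwise-AIC
  multi-shift search (cutoff 4, free extinction per class).
* **Synthetic data** — seeded generators for uniform ERM splits, rate-biased
  sister tables, Gillespie birth–death trees (with optional subtree rate
  shifts) and their collapse to richness trees.

The 13-row galler/non-galler comparison table (species numbers, host-MRCA
ages, printed reference probabilities) ships with the package; the original
study's phylogenies are not machine-readable, so the rate-shift machinery is
validated by parameter recovery on simulated trees instead.

## Worked example

```
$ sisterdiv reproduce --out results/table1
```

prints (abridged):

```
- pairs analysed: 13
- galler more diverse in 7 of 13 pairs (exact two-tailed binomial p = 1)
- log-ratio diversity contrasts: W+ = 50, n = 13, wilcoxon_exact, two-tailed p = 0.7869
- host specificity (ages): 6 nonzero differences, 6 favoring gallers more host-specific; one-tailed exact p = 0.01562

## ERM cells significant after Bonferroni (alpha/2)

- Maskellia (non-galler tail): p = 0.00229
- Apiomorpha (galler tail): p = 0.0197
```

Read: gallers are no more likely than their sisters to be the more diverse
clade overall (7 of 13, binomial p = 1; signed-rank p = 0.79), but the
extremes are informative — *Apiomorpha* is significantly **more** diverse
than its sister under the ERM null (p = 3/152 ≈ 0.020) and *Maskellia*
significantly **less** (its sister's tail p = 2/875 ≈ 0.0023) — and every
resolvable host-range difference favors gallers being the more
host-specific clade (exact one-tailed p = 1/64).  Discrepancy flags against
two unreproducible printed source values are part of the report (see
`docs/methods.md`).

Other entry points: `sisterdiv erm | contrasts | hosts | rateshift | medusa
| simulate`, and the numbered drivers under `analysis/` (01 sister
comparisons, 02 test calibration on ERM-null tables, 03 rate-shift
parameter recovery) which write their tables under `results/`.

As a library:

```python
from sisterdiv import (read_sister_table, packaged_table1_path,
                       erm_table_report, host_specificity_test)
table = read_sister_table(packaged_table1_path())
results, n_galler_more = erm_table_report(table)   # 13 results, 7
host = host_specificity_test(table)                # p = 0.015625
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged table through the ERM machinery, the headline
bipartition tail probabilities of the analysis (the *Apiomorpha*,
*Maskellia*, Cerataphidini, Euurina, *Micronematus*, *Kladothrips* and
fig-wasp comparisons), each rounded as its reference value is printed, and
writes them as JSON.  The quantities are exact and deterministic; `--seed`
is accepted for interface uniformity.
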