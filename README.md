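# famclust

Familial-clustering inference over population genealogies.

`famclust` answers the question a linked genealogy–disease-registry resource
makes askable: *do cases of a rare disease occur in families more often than
chance predicts?*  It is aimed at genetic epidemiologists who have (or can
simulate) a multigenerational pedigree with per-individual sex, birth year,
birth place and affection status, and who want the classic population-based
toolkit for familial aggregation:

- **Genealogical Index of Familiality (GIF).**  For a case set *C*, the GIF
  is 10⁵ × the mean Malécot kinship φ over all unordered case pairs, where
  φ(i, j) is the probability that one gene sampled from *i* and one from *j*
  are identical by descent.  Significance is empirical: the case GIF is
  compared with GIFs of control sets matched per-case on sex, birth year
  (±5 y), birth place and genealogical informativeness, with one-sided
  p = (1 + #{control GIF ≥ case GIF}) / (1 + n sets).  The **dGIF** zeroes
  the contribution of pairs closer than 3 meioses (keeping the pair count),
  isolating aggregation beyond the nuclear family, and the GIF decomposes
  exactly into per-genetic-distance contributions (1 = parent–offspring,
  2 = siblings/grandparental, 3 = avuncular, 4 = first cousins, 6 = second
  cousins).
- **Familial relative risks.**  Cohort-specific incidence rates (sex ×
  5-year birth interval × in-/out-of-state birth) give expected case counts
  among the union of first-, second- and third-degree relatives of the
  cases (each person counted once); RR = observed/expected, with a
  one-tailed Poisson p and small-sample test-inversion confidence intervals
  (mid-P by default, exact central Garwood as an option).
- **High-risk pedigree scan.**  Every founder whose descendants include ≥2
  cases defines a (possibly overlapping) pedigree; observed cases are tested
  against the sum of cohort rates over all descendants with a one-tailed
  Poisson test, without multiplicity correction.  Cases also partition into
  non-overlapping clusters (connected components of positive kinship).
- **Synthetic genealogies.**  A forward-time simulator (non-overlapping
  generations, within-generation couples, immigrant spouses, Poisson
  offspring) with a null phenotype model and a founder-seeded dominant-style
  carrier model whose `familial_multiplier` injects a target degree-1
  relative risk, empirically calibrated by pilot simulation.

Exact kinship is available both as a memoized pairwise recursion (handles
inbreeding loops) and as the vectorised tabular relationship matrix; a
Monte-Carlo gene-dropping estimator serves as an independent oracle.

## Worked example

```python
import famclust as fc
from dataclasses import replace

# carrier risk ratio as resolved by fc.calibrate_clustered_model(
#     fc.clustered_study_model(13.0), n_pilot=40, seed=101)   (~30 s)
model = replace(fc.clustered_study_model(13.0), carrier_risk_ratio=176.1234)

g = fc.simulate_genealogy(replace(fc.CLUSTERED_SIM_PARAMS, seed=7))
cases = fc.assign_phenotypes_clustered(g, model, seed=8)
probands = fc.informative_cases(g, min_generations=3)

res = fc.gif_test(g, probands, n_sets=1000, seed=9)
rates = fc.build_rate_table(g, cases)
report = fc.familial_rr_report(g, cases, rates)
calls = fc.high_risk_scan(g, cases, rates, alpha=0.05)
```

prints (via the formatting in the repository's example):

```
genealogy: 8021 individuals; cases: 28; informative probands: 9
case GIF 911.46 vs mean control GIF 172.68 (p = 0.01499)
case dGIF 564.24 vs mean control dGIF 131.71 (p = 0.008991)
degree  n_rel  obs    exp     RR  95% CI         p
     1    104   11   0.32  34.68  18.24-60.28  6.1e-14
     2    204    8   0.63  12.64   5.87-24.01  3.6e-07
     3    437    4   1.37   2.91   0.92- 7.02  0.051
founder pedigrees with >=2 case descendants: 20; high-risk: 14
non-overlapping case cluster sizes: [5, 5, 4, 4, 3, 1, 1, 1]
```

Reading it: the 9 informative probands are five times more related to one
another than their matched controls are (GIF 911 vs 173), the excess
survives removal of close pairs (dGIF p ≈ 0.009), first- and second-degree
relatives of cases carry strongly elevated risk (single-replicate RRs are
noisy; their mean across 200 replicates recovers the injected 13), and the
scan flags the founder families in which the cases concentrate.

The same analyses are available from the shell:

```bash
famclust simulate --config sim.yaml --seed 1 --out ped.tsv --cases-out cases.txt
famclust validate ped.tsv
famclust kinship ped.tsv --ids I000123,I000456
famclust gif ped.tsv --cases cases.txt --n-sets 1000 --seed 2
famclust rr ped.tsv --cases cases.txt
famclust scan ped.tsv --cases cases.txt --alpha 0.05
```

Pedigree files are tab- or whitespace-delimited with columns
`id father_id mother_id sex(M/F) birth_year birth_place affected(0/1)`
(`0` = missing parent; header optional).  The simulate config mirrors
`SimParams` and `PhenotypeModel`:

```yaml
simulation:  {n_founders: 110, n_generations: 5, mean_offspring: 2.6}
phenotype:   {baseline_rate: 0.008, familial_multiplier: 6.0}
```

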