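# phylorecomb

Phylogenetic comparative analysis of recombination rates in plants.

Across species, genome-wide recombination rates (centimorgans of genetic
map per megabase of genome) are not independent data points: closely
related species tend to have similar rates, and life-history traits such
as growth habit (herb, shrub, tree) shift them. `phylorecomb` is a
toolkit for asking, with the phylogeny properly accounted for, whether
recombination rate carries phylogenetic signal, whether it correlates
with heterozygosity (*H*<sub>e</sub> at SSR loci), and whether life-forms
differ — at the genome-wide scale and, via population-genetic estimators,
within genes.

It provides:

- **Rate assembly** — corrected genetic-map lengths (terminal-crossover
  correction), C-value → Mb conversion (1 pg = 978 Mb), inclusion filters
  (≥ 60% map coverage, ≥ 5 SSR loci), and a paired test supporting the
  pooling of domesticated species with wild relatives.
- **Trees** — Newick I/O, BLADJ-style age calibration (even interpolation
  of undated nodes between dated ones), Brownian-motion covariance
  V<sub>ij</sub> = depth of MRCA(i, j) and the derived correlation matrix.
- **Phylogenetic signal** — Felsenstein independent contrasts, Blomberg's
  K (K = 1 under pure Brownian motion), and a tip-reshuffling permutation
  test on the variance of standardized contrasts.
- **Models** — the uncorrected Gaussian GLM and two phylogeny-corrected
  GEE/GLS fits of log rate on *H*<sub>e</sub> and life-form,
  β̂ = (XᵀR⁻¹X)⁻¹XᵀR⁻¹y, the second splitting conifer trees from
  angiosperm trees; fitted group means; Kruskal–Wallis comparisons.
- **Within-gene estimators** — biallelic/parsimony-informative site
  filtering, θ<sub>π</sub> and θ<sub>W</sub>, the Hudson–Kaplan minimum
  number of recombination events R<sub>m</sub> (four-gamete test +
  optimal interval stabbing), and a Monte-Carlo two-locus
  composite-likelihood estimator of ρ = 4N<sub>e</sub>r with ρ/θ.
- **Synthetic data** — Yule trees, (bivariate) Brownian traits,
  clade-structured life-forms, species tables that back-solve exactly to
  known rates, and a coalescent-with-recombination haplotype simulator —
  every pipeline input with known ground truth.

## Worked example

```python
from phylorecomb import synthetic, run_comparative_analysis

tree = synthetic.yule_tree(81, 1.0, seed=7)
records, truth = synthetic.species_table_fixture(tree, seed=8)
report = run_comparative_analysis(records, tree, n_perm=999, seed=9)
print(report.to_text())
```

```
phylorecomb comparative analysis (v0.1.0)
species retained: 81 (excluded: 0)

Phylogenetic signal of log recombination rate:
  K = 0.6416   P = 0.001   (contrast-variance null, 999 perms)
  observed PIC variance = 0.2382   null mean = 3.243

PIC correlation (log rate vs He, through origin): -0.1011

Model [uncorrected]
           estimate     se   p_value
intercept    -2.211 0.3171 9.387e-10
he            1.707 0.4941  0.000901
herb        -0.6831 0.1504 2.025e-05
shrub       -0.8621 0.1589  6.43e-07

Model [phylo_corrected_1]
           estimate      se   p_value
intercept     -1.66   0.266 2.176e-08
he           0.4949  0.2925   0.09469
herb        -0.9225 0.06483 2.974e-23
shrub       -0.7713  0.0907 1.084e-12
...
Fitted group means (log rate at intercept scale):
life_form  fitted_log_rate     se
     tree            -1.66  0.266
     herb           -2.583 0.2777
    shrub           -2.432 0.2888
```

Reading the output: the trait was generated with strong phylogenetic
structure, and the permutation test detects it — the observed variance of
the standardized contrasts (0.238) is far below the reshuffled-null mean
(3.24), giving P = 0.001 with 999 permutations. The generating model used
an He slope of 0.8 and life-form effects herb −0.9 and shrub −0.7 around
a tree intercept of −1.5; the phylogeny-corrected fit recovers them
(0.49 ± 0.29, −0.92 ± 0.06, −0.77 ± 0.09, intercept −1.66 ± 0.27), while
the uncorrected model is pulled off target by the clade structure. Group
means are intercept + level coefficient: herbs sit 0.92 log units below
trees.

The same stages are available from the shell:

```sh
phylorecomb simulate-tree --n-tips 81 --seed 1 --out tree.nwk
phylorecomb simulate-table --tree tree.nwk --seed 2 --out species.tsv
phylorecomb run-all --table species.tsv --tree tree.nwk --seed 3 --out-dir results/
phylorecomb simulate-haplotypes --n 30 --theta 10 --rho 20 --out gene1.fasta
```

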