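# sexlinkage

Detection and validation of sex-linked markers from population
genotype data, identification of the sex chromosome, and
quantification of sex-chromosome turnover on a dated phylogeny.

The package is aimed at population geneticists working on taxa with
homomorphic sex chromosomes (fish, amphibians, reptiles), where sex
chromosomes cannot be identified cytogenetically and must instead be
inferred from sexed population samples — typically RADseq genotypes —
and then placed in a phylogenetic context to study how often lineages
switch the chromosome pair (or heterogamety system) used for sex
determination.

## What it computes

**Sex-linkage screens.** Three rule-based screens, each run in both
XY and ZW orientation (sexes swapped):

1. *allele frequency* — a locus with a fully penetrant Y-specific SNP
   has X-allele frequency ≈ 1 in females and ≈ 0.5 in males; a locus
   is flagged when freq(X) ≥ 0.95 in the homogametic sex and
   0.4 ≤ freq(X) ≤ 0.6 in the heterogametic sex;
2. *heterozygosity* — homozygous in every homogametic individual and
   heterozygous in ≥ ½ of heterogametic individuals;
3. *sex-limited tags* — RADtags absent from the homogametic sex and
   present in ≥ ½ of the heterogametic sex.

Loci first pass the standard retention filters (call rate ≥ 75% in
both sexes, minor-allele frequency ≥ 0.05, observed heterozygosity
≤ 0.75).

**Permutation validation.** Screens always return false positives, so
each observed marker count is compared with an empirical null built by
permuting sex labels across samples (1000 permutations by default,
screens re-run each time); a marker set is credible only when the
observed count strictly exceeds the null's 99th percentile.

**Sex-chromosome identification.** Validated markers are located on
chromosome-assigned scaffolds via filtered best BLAST hits (e-value
< 1e-20 and ≥ 5 orders of magnitude below the next hit).  A chromosome
is identified when it gathers ≥ 10 sex-linked markers and more than
the 99th percentile of the per-chromosome counts of 1000 random
same-size marker subsets drawn from the full catalogue.

**Turnover phylogenetics.** Chromosome states evolve on a dated
ultrametric tree under a K-state Mk model (generator Q; ER/SYM/ARD
constraints compared by AIC, likelihood by Felsenstein pruning with
per-branch e^{Qt}).  Stochastic character mapping samples full
histories conditional on probabilistic tip states; turnovers are
branches whose endpoint majority states differ across maps.  From the
event list the package computes the turnover rate
(events / total branch length, per Myr), exact binomial tests on
heterogamety preservation, and a gene-resampling null for chromosome
recruitment (N genes drawn without replacement per replicate, tallied
per chromosome) plus an OLS regression of recruitment counts on gene
counts.

**Synthetic data.** `sexlinkage.simulate` generates every input with
truth labels: XY/ZW/no-system populations with Y-specific SNPs,
sex-limited tags, X-hemizygous loci (which mimic the opposite system —
the "pseudo-ZW" confound), multiple Y haplotypes, genotyping error and
missingness; Yule trees and Mk character histories with the true event
list.

A curated 28-species Ranidae (true frog) turnover table ships with the
package (`sexlinkage.fixtures`): 13 turnover events — 8 interspecific,
3 intraspecific, 2 homologous XY→ZW — with per-species chromosome
states over Chr01/Chr02/Chr03/Chr05/Chr08.

## Worked example

Run the full synthetic pipeline end to end (simulate → filter →
screen → permutation-validate → assign → turnover analysis):

```python
from sexlinkage import pipeline

summary = pipeline.run({"seed": 7, "outdir": "demo_run"})
print("identified:", summary["assignment"]["identified"])
print("screens:", summary["screens"])
t = summary["turnover"]
print("turnovers:", t["total"], "preserving XY:", t["preserving_heterogamety"])
print("p(>=11/13 | p0=0.5) =", round(t["heterogamety_p_equal"], 5))
print("recruitment p(Chr05) =", round(t["recruitment_p_chr05"], 4))
```

prints

```
identified: Chr05
screens: {'freq_XY': 59, 'het_XY': 59, 'sex_limited_XY': 20, 'freq_ZW': 20, 'het_ZW': 19, 'sex_limited_ZW': 0}
turnovers: 13 preserving XY: 11
p(>=11/13 | p0=0.5) = 0.01123
recruitment p(Chr05) = 0.005
```

Reading the output: the simulated XY population (default: 20 M / 20 F,
2000 loci, 5% sex-linked, Chr05 as the true sex chromosome) yields 59
markers from each SNP screen and 20 sex-limited tags in XY
orientation; the 20 X-hemizygous confound loci also produce a
*validated* ZW signal — exactly the failure mode the orientation
comparison and chromosome assignment are there to resolve — and the
assignment stage correctly identifies Chr05 and nothing else.  The
turnover block summarises the packaged Ranidae history: 13 events, 11
keeping male heterogamety (exact binomial tail 0.011 against an
equal-probability null), and Chr05 recruited more often than the
gene-resampling null expects (p ≈ 0.005).

The same pipeline is available from the shell:

```bash
sexlinkage run-all --seed 7 --outdir demo_run
sexlinkage fixture-report     # the Ranidae turnover summary as JSON
```

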