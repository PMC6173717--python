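# Methods

## Scope and data model

The package analyses sexed population samples genotyped at biallelic
loci (RADseq-style), plus tag presence/absence, tabular alignment
hits, and a dated phylogeny with per-tip sex-chromosome state
probabilities.  Genotypes are coded 0/1/2 (alt-allele dosage) with a
missing token; all per-sex fractions are computed over non-missing
calls, reflecting the fact that genotype matrices from
reduced-representation data are never complete.

## Locus filters

A SNP is retained when its call rate is at least 0.75 within males
*and* within females, its pooled minor-allele frequency is at least
0.05, and its observed heterozygosity (share of non-missing calls
that are heterozygous) is at most 0.75.  The heterozygosity ceiling
removes over-merged paralogous stacks, which masquerade as
universally heterozygous loci.  Thresholds stated as minima are
inclusive; the MAF is pooled across sexes (a per-sex MAF would
discard fully sex-linked loci whose minor allele lives only in the
heterogametic sex).  The three rules are mutually independent
statistics, so the retained set does not depend on application order;
this is asserted on random simulations.  One documented hazard is
deliberate: when the heterogametic sex exceeds 75% of samples, a
fully sex-linked locus (heterozygous in every heterogametic
individual) violates the heterozygosity ceiling and is removed — the
filter is correct for paralogs but destructive for extreme sex
skews, and the test suite pins this behaviour.

## Sex-linkage screens

All three screens are stated for XY; ZW swaps the sex roles.

* **Allele frequency**: the X allele is operationalised as the major
  allele among homogametic-sex calls (exact ties break toward the
  reference allele; with the default symmetric band the tie-break
  cannot change a decision).  Flag when freq(X) ≥ 0.95 in the
  homogametic sex and 0.4 ≤ freq(X) ≤ 0.6 in the heterogametic sex.
* **Heterozygosity**: zero heterozygous calls among homogametic
  individuals ("all" is strict) and a heterozygote fraction ≥ 0.5
  among heterogametic individuals, both over non-missing calls; the
  ≥ 0.5 comparison on the observed denominator implements "at least
  half" for odd counts.
* **Sex-limited tags**: present in zero homogametic individuals and
  in ≥ 0.5 of heterogametic individuals.

A locus with no callable individuals in either sex is unevaluable:
never flagged, counted separately.

The screens are implemented once as vectorised kernels in which the
sex assignment enters only through matrix products with a 0/1
male-mask matrix.  A batch of 1000 permuted labelings therefore costs
a handful of (loci × samples) · (samples × 1000) multiplies, and the
single-dataset screen functions share the same kernels, so null and
observed counts cannot drift apart.

Exactness on clean data has one caveat worth stating: with finite
samples an autosomal Hardy–Weinberg locus is occasionally
all-homozygous in one sex by chance, which satisfies the
heterozygosity screen (measured: roughly one false positive per ~13
noise-free datasets of 2000 loci at 20 M/20 F).  The frequency screen
(0.95 condition) and the tag screen (exact zero presence against
noise-free full presence) admit no such chance positives.  This is
why the screens are never interpreted without the permutation null
below, and why the test suite asserts exact truth recovery for the
frequency/tag screens but recall-plus-pooled-precision (≥ 99.5%) for
the heterozygosity screens.

## Permutation validation

Sex labels are shuffled across samples without replacement (M/F
counts preserved), all six screens re-run per permutation, and the
six null series built from the same 1000 shuffles.  The decision rule
reads "outside the 99th percentile" conservatively: PASS requires the
observed count to *strictly exceed* the linear-interpolation 99th
percentile of the null series; ties fail.  When the permutation count
cannot resolve the requested percentile (e.g. 99th with < 100
permutations) the exact-rank ("higher") percentile is used and a
warning logged.  Each permutation consumes an independent child seed
spawned from the master seed.

The subsampling diagnostics experiment re-runs validated screening on
nested designs — balanced 19/19 down to 5/5, male skew 18/9, female
skew 9/18, and a two-Y-haplotype design 6+6 males / 12 females —
selecting samples in stored order (and by truth haplotype where
required) so the experiment is deterministic given the matrices.

## Chromosome assignment

Each validated marker contributes to at most one chromosome: the
chromosome of the scaffold of its single retained best hit (best hit
kept only when e-value < 1e-20 and, given competitors, ≥ 5 orders of
magnitude below the runner-up).  The per-chromosome null redraws
`set_size` markers uniformly without replacement from the full
catalogue 1000 times; its per-chromosome mean is hypergeometric
(set_size × mappable-on-chromosome / catalogue), which the tests
verify against the closed form.  Identification requires an observed
count ≥ 10 *and* strictly above the 99th percentile of that
chromosome's null; the 10-marker floor applies to the observed set
only, not to null replicates.  If several chromosomes pass, all are
reported and the result flagged ambiguous rather than forced unique.

## Mk model and stochastic mapping

States are chromosome identities (default K = 5: Chr01, Chr02, Chr03,
Chr05, Chr08; K = 10 supported).  Tip uncertainty is a probability
row; rows sum to one in storage, and enter the pruning pass rescaled
to maximum one, i.e. as ambiguity indicators — a fully unknown tip
contributes likelihood 1, so a tree of unknown tips has lnL = 0 under
a uniform root prior.

The likelihood uses Felsenstein pruning with per-branch matrix
exponentials (scipy `expm`; rows are checked to sum to 1 within
1e-10) and per-node rescaling for underflow.  The root prior defaults
to uniform (configurable).  Rates are optimised on the log scale with
L-BFGS-B from log-spaced multi-starts (default 10; bounds 1e-8 to 1e3
per Myr); ER/SYM/ARD are compared by AIC = 2p − 2 lnL.  A 1-D profile
likelihood interval is provided for the ER rate (lnL drop of
χ²₀.₉₅,₁/2).

Stochastic mapping draws node states (tips included) by the standard
conditional pass — root from prior × partial likelihood, then
root-to-tip from P(edge)ᵢⱼ × Lⱼ — and branch histories from the
endpoint-conditioned CTMC: rejection sampling (with the first jump
forced through a truncated exponential when the endpoints differ),
falling back to uniformization (number of virtual jumps from the
Poisson–R^n mixture, bridge states from R-power weights) after 100
failed attempts, with fallback use logged.  The two samplers are
checked against each other distributionally, and per-node map
frequencies against exact marginal posteriors from an independent
up-down pass.

Turnovers are counted as consensus endpoint changes: for each branch
the majority state at its two ends across maps; a differing majority
is an event, a tied majority an unresolved branch (reported, not
counted).  Within-branch round trips are invisible to any
endpoint-based count, so simulated-truth comparisons use the net
endpoint change of the true history.  Known intraspecific or
homologous events from other evidence are appended as extra events.
The turnover rate is events / total branch length (per Myr of
independent evolution), with its reciprocal reported.

Heterogamety preservation is tested with the exact binomial upper
tail P(X ≥ k | n, p₀), at p₀ = 0.5 (equal transition probabilities)
and p₀ = 0.75 (drift-biased expectation).  For the packaged 11-of-13
history these are 0.0112 and 0.333; the package reports the exact
values it computes.

## Recruitment null and regression

Each replicate draws N genes (N = number of recruitment events)
uniformly without replacement from the pooled genome
(`multivariate_hypergeometric`) and tallies chromosomes; the
upper-tail probability per chromosome is reported raw and with the
(r + 1)/(n + 1) correction.  Default 1000 replicates (100 available
via configuration).  Events with an unknown derived chromosome count
toward N but not toward any chromosome's observed tally, so the
observed total may be below N.  The companion regression is ordinary
least squares of recruitment counts on per-chromosome gene counts
with the slope t-test and R².

The packaged gene-count table is a synthetic stand-in (13
chromosomes, ~23k genes, counts decreasing with chromosome rank) and
is labelled synthetic in its filename and docstrings; real analyses
should substitute annotation counts.

## The Ranidae fixture

`fixtures.load_ranidae_turnovers()` returns a curated 13-event
turnover history across 28 Ranidae species (8 interspecific from
stochastic mapping, 3 intraspecific — R. japonica, R. pipiens,
P. porosus — and 2 homologous XY→ZW in G. rugosa), per-species
chromosome states, and the implied tip probability matrix (equal mass
over a species' described chromosomes; uniform for unknowns).  The
two near-root events sit where the ancestral state is ambiguous;
several placements are possible and the most parsimonious is encoded
(one event to Chr03 on the Pelophylax stem, one fully unknown on the
Rana stem).  Species-to-chromosome assignments beyond those the
source survey names in running text are schematic placeholders chosen
to be consistent with its published per-chromosome species tallies;
this is declared in the fixture metadata, and files are
checksum-verified on load.

## Synthetic data: what it does and does not emulate

The population simulator reproduces the *signal structure* screens
rely on — fully penetrant Y-specific SNPs (haplotype-specific when
several Y lineages are requested), sex-limited tags, X-hemizygous
loci producing a deterministic pseudo-ZW pattern (every homogametic
individual heterozygous for a paternal-X allele), Hardy–Weinberg
autosomal loci at uniform(0.05, 0.5) allele frequencies, independent
per-genotype miscalls (to a uniformly chosen other value) and
missingness, tag dropout at the missing rate.  It does *not* emulate
linkage disequilibrium between loci, population structure, shared
read-depth artefacts, partial penetrance or sex reversal, or a
realistic site-frequency spectrum (the flat MAF distribution is a
neutral default, not a claim about any real dataset).  Passing tests
therefore demonstrate correctness of the decision rules and their
calibration under exchangeability — not robustness to structured
artefacts, which the permutation null addresses only partially in
real data.

Locus-class counts use floor rounding at each split with remainders
assigned to the autosomal class, making class sizes deterministic.
Trees come from a hand-rolled Yule (pure-birth) simulation rescaled
to the requested root age — ultrametric by construction and
newick-deterministic under a seed; character histories from forward
CTMC simulation with the full event list returned as truth.

## Problem sizes and numerical choices

Default analysis sizes follow the source protocol (1000 permutations,
1000 random subsets, 1000 stochastic maps, 1000 resampling
replicates).  The verification suites use: 200 signal-free
simulations (10/10, 2000 loci) for type-I calibration against a ≤ 3%
empirical pass bound; 50 noise-free 19/19 simulations for power; 50
end-to-end 20/20 replicates for identification; 50 replicates of
200-tip trees for ER-rate profile-interval coverage (≥ 90% at the
95% level); exhaustive-enumeration likelihood checks on all packaged
≤ 5-tip tree shapes at K ∈ {2, 3} with |Δ lnL| < 1e-8; Monte-Carlo
agreement bounds at 3 standard errors.  Matrix exponentials are
clipped at zero and row-normalised only after verifying row sums
within 1e-10; partial likelihoods are max-rescaled per node with the
log-scale accumulated; Monte-Carlo p-values carry the add-one
correction alongside the raw fraction.

## Known limitations

* Homologous turnovers (same chromosome, same system) are invisible
  to state-based mapping; they enter only as curated extra events.
* Consensus turnover placement undercounts when several events occur
  on one branch or a branch's majority is tied.
* The ER profile interval is one-dimensional; SYM/ARD uncertainty is
  reported only through AIC comparison.
* The screens' decision thresholds are those of the source protocol;
  they are configurable but the defaults are not tuned per dataset.
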