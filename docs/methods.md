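# Methods

`soycross` implements an analysis chain for germplasm panels of fully
homozygous inbred lines: multi-environment trial statistics, haplotype-block
marker construction, a heritability-restricted two-stage multi-locus
association scan, QTL-allele matrices with subpopulation allele accounting,
and in-silico cross design by recombinant-inbred-line simulation.  This note
records the models, the numerical choices, and what the synthetic data do
and do not establish.

## Trial model and variance components

Plot values follow the two-way random model with replicates nested in
environments,

    y_ijk = mu + g_i + e_j + r(e)_jk + (ge)_ij + eps_ijk,

all terms random.  `quantstats.estimate_components` solves the variance
components by the method of moments from the expected mean squares of the
balanced ANOVA computed on cell means (mild imbalance is absorbed through
the mean cell size; strongly unbalanced designs are out of scope):

    E[MS_error] = s2,   E[MS_GxE] = s2 + r*s2_gt,   E[MS_G] = s2 + r*s2_gt + r*t*s2_g.

Negative solutions are truncated at zero and flagged.  Entry-mean
heritability is

    h2 = s2_g / (s2_g + s2/r)                      (single environment)
    h2 = s2_g / (s2_g + s2_gt/t + s2/(t*r))        (combined over environments)

and GCV% = 100*sqrt(s2_g)/mean.  The genotype term is tested against the
GxE mean square (random-model expectation), GxE against the residual.  A
statsmodels type-I ANOVA serves as an independent oracle in the tests; the
implementation itself does not depend on it.

## SNPLDB construction

Because the lines are homozygous, two-locus haplotypes are observed
directly, and the raw disequilibrium for a marker pair is D = p_AB − p_A·p_B
over lines non-missing at both markers, normalized by its frequency bound
(D′).  Blocks are built per chromosome by greedy left-to-right extension: a
block absorbs the next marker while *every* pairwise D′ among its members
stays ≥ 0.7 and the physical span stays ≤ 200 kb.  The all-pairs criterion
makes the partition deterministic and order-independent given sorted
markers; the span cap prevents chromosome-scale blocks in high-LD panels
and is configurable because block-capping conventions differ between LDB
methods.  Haplotypes rarer than 1% are merged into the nearest common
haplotype by Hamming distance (ties toward the more frequent target), and
lines with missing calls inside a block take the most frequent compatible
haplotype, so every accession has a complete allele assignment downstream.

## Restricted two-stage multi-locus scan

Population structure is corrected with the top k = 10 eigenvectors of the
genetic-similarity matrix, where similarity is the share of blocks at which
two accessions carry the same haplotype.  Stage 1 is a single-locus prescan
on accession means: per block, the (k_hap − 1)-df partial F-test of the
haplotype term over intercept + eigenvectors, survivors at p ≤ 0.05.
Stage 2 is forward-addition / backward-elimination stepwise OLS over the
survivors at the same α = 0.05, with two deterministic tie-breaks (smaller
p, then larger partial R², then lower genomic coordinate).

The *restriction*: an addition is rejected — and forward selection halts —
if either the joint marker R² (covariates partialled out) or the sum of
per-QTL partial R² would exceed the trait's combined-environment h².  The
second clause is what guarantees Σ per-QTL R² ≤ 100·h² even under
collinearity or suppression among blocks.  Per-QTL R² is the partial
(drop-one) share of the total sum of squares in the final model; allele
effects are the fitted haplotype coefficients converted to
frequency-weighted sum-to-zero coding, so that

    genotypic value = population mean + Σ_q effect_q(allele carried),

the exact form the cross simulator consumes.

QTL×environment classification is a separate plot-level pass: each selected
QTL receives a marker×environment partial F-test in a model holding
environment, covariates and all selected markers; stage-1 survivors outside
the main model may enter through their interaction term alone (forward at
α = 0.05).  Interaction R² is measured against the within-environment
centered plot sum of squares, and the interaction scan's running total of
main + interaction R² is capped at (s2_g + s2_gt)/(s2_g + s2_gt/t +
s2/(t·r)) — a declared convention, since no standard one exists for
bounding interaction shares.  With one environment everything is
`main_only` and interaction fields stay undefined.

## QTL-allele matrix and allele dynamics

The matrix holds, per accession and QTL, the carried haplotype and its
signed effect; the sum-to-zero coding makes the mean predicted value equal
the population mean.  For a contrast of an early subpopulation set against
a late one, an allele is *present* in a side iff at least one of its
accessions carries it; inherited/emerged/excluded counts follow from set
intersection and difference, split by effect sign with effect ≥ 0 counted
positive (zero is grouped with positive because near-zero effects are sign-
unstable under refitting).  The identities `inherited + emerged = early
total` and `inherited + excluded = late total` hold by construction and are
asserted on every synthetic run.

Candidate screening intersects gene models with the block interval expanded
by 50 kb on both sides (closed interval at both ends) and tests
independence of the block assignment against each in-gene SNP with a
Pearson chi-square (no continuity correction) at α = 0.05; genes without an
in-gene SNP are reported untestable rather than significant.

## Cross simulation

Progeny of a biparental cross are produced by single-seed descent from the
F2: each generation applies two independent meioses of the current plant,
until the line is homozygous at every QTL locus, with a hard cap of 50
generations after which residual heterozygous loci are resolved by a fair
coin (expected residual heterozygosity 2^-49 per locus makes the coin
practically unreachable; whether real pipelines discard or resolve such
lines is immaterial at that rate).

Meiosis uses the no-interference Poisson model: crossover count ~
Poisson(L/100) on a chromosome of L cM with positions uniform on (0, L) — a
homogeneous Poisson process.  The simulator samples gametes locus-by-locus
through the exact Markov restriction of that process: uniform start strand,
strand switch between consecutive loci d cM apart with the Haldane
probability (1 − exp(−2d/100))/2.  This is identical in distribution at
the QTL loci to placing explicit crossovers and reading them off, and
vectorizes across progeny; the explicit position sampler is retained for
crossover-count calibration, and the Haldane–Waddington RIL closed form
2r/(1+2r) is used as a test oracle only, never in the simulator.

Only QTL loci are simulated: genotypic value depends on nothing else, so
simulating the full marker set would add cost without changing any
predicted value.  Loci where both parents carry the same allele are fixed
without simulation.  QTL genetic positions come from the map, defaulting to
physical position × 1 cM/Mb.  Each cross draws from a stream keyed by the
master seed and the sorted parent pair, so whole-panel runs are reproducible
and independent of enumeration order, and (P1,P2) equals (P2,P1) exactly.

A cross's *recombination potential* for a trait is the nearest-rank 95th
percentile (sorted ascending, element ceil(0.95·n)) of its progeny
genotypic-value distribution; parental predicted values are recorded
alongside so transgression is visible directly.

## Cross design

`enumerate_crosses` simulates each of the n(n−1)/2 crosses once over the
union of both traits' QTL loci, so both traits are predicted on the same
progeny population.  Group summaries count pairs with both parents in a set
(within) or one in each of two disjoint sets (between).  The two-trait
strategies follow fixed pool sizes — primary-first: top 100 by the lead
trait re-ranked by the other, keep 10; balance: intersect both traits' top
2000 and keep the 10 with the smallest sum of within-trait ranks.  The
balance ordering is a declared convention (rank sum, ties to the second
trait's rank, then pair id): "most common crosses among the two top lists"
does not itself define an order.  All sorts are stable with documented tie
breaks.

## Synthetic data

`synthdata` generates the panel the analysis assumes rather than a
coalescent-realistic genome: markers come in founder blocks of 5
consecutive sites (10 kb apart, blocks spread over 20 chromosomes of
100 cM at 1 cM/Mb), each accession drawing one of ≤ 4 founder haplotypes
per block, with per-subpopulation Dirichlet frequencies (concentration 15
around a shared base) providing both within-block LD and structure.
Planted QTLs sit on distinct blocks with frequency-weighted sum-to-zero
effects scaled to equal per-QTL genetic SD (`allele_effect_sd`, trait
units); a polygenic background of 50 additional blocks carries 25% of the
genetic variance by default, so the planted QTLs explain h² × 0.75 of the
line-mean variance.  Environment effects are fixed, centered shifts (SD
half the genotypic SD); replicate effects are small (10% of the error SD);
the residual SD is solved from the combined-environment h² formula so the
realized entry-mean heritability lands on the target (recorded in the truth
set, typically within ±0.05).  A fraction of QTLs receive
environment-interaction effects, centered both across environments (no
main-effect leakage) and across haplotypes.

What passing on these data shows: the pipeline recovers block boundaries,
variance components, planted allele effects and cross potentials when its
own assumptions (block LD, additivity, homozygosity, no interference) hold
exactly.  What it does not show: behaviour under coalescent LD decay,
epistasis, dominance from residual heterozygosity, crossover interference,
genotyping error beyond random missingness, or strongly unbalanced trials.

## Problem sizes and determinism

The analysis scripts run the panel at 300 accessions × 2,000 markers with
2 environments × 4 replicates, and the whole-panel cross design at 200
progeny per cross; tests use the same generator at smaller marker counts,
and the acceptance script a 50-accession panel for the catalogue stage.
Every random step flows from an explicit seed (`numpy` Generator /
SeedSequence); per-cross streams are keyed by (master seed, sorted pair),
so all reported numbers are exactly reproducible.

## Known limitations

- Stepwise selection at α = 0.05 over prescreened survivors admits
  occasional noise blocks whose apparent R² reaches ~1% at n = 300; the
  heritability cap bounds the total but not each term.
- Method-of-moments components assume balanced or mildly unbalanced data;
  REML/BLUP refinements are out of scope.
- The block rule is one deterministic member of the LDB family; methods
  differing in cap or extension rule will partition boundaries differently
  without changing the downstream contract (blocks in, alleles out).
- Gene screening demonstrates the interval/chi-square machinery; on
  simulated panels the annotation is synthetic and carries no biology.
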