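# Methods

## Screen model

The simulator treats a pooled knockout screen as exponential selection on
guide abundances.  Guide *i* targeting gene *g* in background
*b* ∈ {WT, MUT} has expected read fraction at day *t*

f_i(t) ∝ a_i · exp(u_i · s_{g,b} · t),

where a_i ~ LogNormal(0, σ_lib) is the initial library abundance
(default σ_lib = 0.3), u_i ~ Uniform(0.7, 1) is a per-guide knockout
efficiency that scales the gene effect (so within-gene guide variation is
present and the quartile filter and significance tests must tolerate it),
and s_{g,b} is the planted per-day log-fitness of losing *g* in background
*b*.  Non-targeting guides and unplanted genes have s = 0.  Fractions are
renormalised per sample — so strong dropout of one gene set inflates
everything else, the composition effect real screens show — and counts are
drawn negative-binomial with mean fraction × depth and a single global size
parameter (default 10; var = m + m²/10), the standard overdispersion model
for pooled screens.  Defaults: five time points per arm, WT harvested at
day 21 and the mutant at day 27 (mutant arms run longer in practice; the
final days are per-background parameters), duplicate samples, and depth
expressed as expected reads per sample (the benchmark configurations use
500 reads per guide).

The day-1 WT samples are the shared baseline: both the "WT" and "MUT"
contrasts divide by WT day 1, and "MUT\*" divides the mutant final day by
the WT final day.

## CRISPR score and the three pipelines

CS is the unweighted gene mean of per-guide log2 ratios; each side of the
ratio is the arithmetic mean of the side's replicate samples (one log-ratio
per guide, not a mean of per-replicate ratios — the replicate-averaged
variant is less noisy at low counts).  Before the pseudocount (default 0.5)
is added, the abundance table is rescaled by one global scalar so its grand
mean equals the grand mean of a reads-per-million table.  A single global
factor preserves every cross-sample ratio — hence the CS — whatever
normalisation produced the table, while giving the pseudocount a fixed,
interpretable weight of 0.5 RPM.

The three pipelines share the CS definition and differ in normalisation ×
null: A = RPM + one-sample t-test of the guide log-ratios against 0;
B = median-of-ratios size factors + two-sided rank-sum against the
non-targeting guides; C = control-scaled (per-sample non-targeting total) +
permutation null of random same-size guide sets with the add-one estimator
p = (1 + #{|CS_null| ≥ |CS_obs|})/(1 + n_perm).  Spanning parametric,
rank-based and resampling nulls is what the ≥2-of-3 consensus exploits:
their false positives are largely disjoint, their true positives are not.
Note that A normalises by total depth and therefore sees composition
shifts (a neutral gene in a screen with many dropouts drifts mildly
positive), while B and C anchor on majority/control guides and do not;
this is intentional pipeline diversity.  Benjamini–Hochberg adjustment is
applied within each (comparison, pipeline) family, and classification uses
adjusted p-values by default.

## Class assignment and the "static" class

depleted: CS < −0.5 and p < 0.05; enriched: CS > 0.5 and p < 0.05;
static: |CS| ≤ 0.5.  The static class is meant to capture genes that do
*not significantly change*, so by default it carries no significance
requirement; requiring p < 0.05 *and* a small CS would define a
"significantly nonzero yet small" class that a true null gene almost never
enters, making the two trends that involve a static comparison practically
unreachable.  The stricter reading is available as
`static_requires_significance=True`.  Threshold comparisons are strict
inequalities throughout.

## Quartile-separation filter

Per-guide Z-scores are computed from fraction-normalised abundances across
*all* samples (row mean 0, sd 1 with the n−1 denominator; zero-variance
rows get Z = 0 plus a flag).  A surviving candidate must have Q3 of its
guides' Z-scores over the mutant final samples strictly below Q1 over the
WT day-1 samples and below Q1 over the WT final samples; quartiles use
linear interpolation between order statistics (type 7).  This is the stage
that removes WT-advantage genes — genes depleted in MUT\* only because the
WT denominator grew — because their mutant-final abundance matches WT
day 1 rather than sitting below it.  The filter is evaluated only for
trend-consensus survivors; since it is a per-gene predicate, evaluating it
late changes nothing but cost.

## Amplicon allele model

Alleles are single indel events: |offset| from the cut site is geometric
(default p = 0.5, so ≈98% of alleles fall within ±5 bp — consistent with
the tight cut-site clustering Cas9 produces), lengths are geometric
(support ≥ 1), insertions carry random sequence, and a planted fraction
(default 0.7) is frameshift.  Initial frequencies are Dirichlet(1) over
alleles, sharing the pool with an unedited allele (default 15%); the same
initial pool seeds both backgrounds, as when one edited culture is split.
Frequencies evolve deterministically as f_t ∝ f_0 · w^t with w = w(frame
class, background) per day, and reads are multinomial per sample (default
50,000 reads — typical demultiplexed MiSeq amplicon depth — 3 time points
at days 0/7/14, duplicates).

Frame classification is pure indel arithmetic: net inserted-minus-deleted
length mod 3.  Substitution-only alleles are classed WT — a nonsense
substitution would be loss-of-function biologically, but that is not
derivable from indel arithmetic; this is a documented limitation.  An
allele's location is the affected position nearest the cut site (deletions
spanning it get 0), with |·|-ties broken toward the negative side — an
arbitrary but documented convention.  Cut-site clustering QC reports both
the read-weighted and the allele-level fraction within the window (default
±5 bp) because "fraction of mutations" is ambiguous between the two.

Trajectories are restricted to frameshift alleles with nonzero first-time-
point frequency in every replicate of both groups; fold changes are
computed per replicate and then averaged, so the first entry is exactly 1.
The WT-vs-KO trend test is a two-sided Welch t-test of per-allele fold
changes at a chosen time point ("t-test" alone underdetermines the
variant; Welch is the robust default, with Student's and a paired-by-allele
variant as options).  Under neutral dynamics the test runs slightly
conservative (measured type-I ≈ 0.03 at α = 0.05): the fold-change of each
allele carries a Jensen bias that grows with its sampling noise, identical
in both groups — so it cancels from the group difference but inflates the
within-group spread the t-test uses.  The paired variant removes it.

## Validation statistics

Competition series are normalised per replicate to the initial time point
and compared by one-sided two-sample t-tests per day (treated < control);
the normalisation anchor day, where every value is 1, is reported with
p = NaN.  Cell lines are MMR-deficient iff MSI *and* MMR-mutated,
MMR-proficient iff MSS *and* not mutated; everything else is excluded, so
the grouping is a strict partition.  Sensitivity distributions are compared
with a two-sided two-sample Kolmogorov–Smirnov test, exact when both
groups have ≤ 25 lines, asymptotic otherwise.

## Benchmark configurations and what they show

The test suite and `scripts/acceptance.py` use desk-scale problem sizes
chosen to exercise every stage: 1000 genes × 4 guides + 100 non-targeting
controls at 500 reads/guide, with 20 planted synthetic-lethal genes
(s_mut = −0.2/day), 50 essentials (−0.25/day in both arms) and 30
WT-advantage genes (+0.1/day in WT) — the last group existing precisely to
attack the MUT\* contrast and be caught by the quartile filter; fully
neutral screens over 20 seeds for null calibration; 1000 neutral and 200
selected amplicon simulations at 138 tracked LoF alleles for the trend
test's error rates; and 1000 random alleles against a brute-force
translation oracle for the frame classifier.

What passing does and does not show: the generators are faithful to the
selection-plus-counting structure of these assays but idealised — no PCR
jackpotting or sequencing error, no guide-level off-target fitness
effects, a single global dispersion, haploid copy number by construction,
and expression values that are a clean threshold rather than an RNA-seq
quantification.  Recovery rates measured here are therefore upper bounds
on real-data performance; the calibration properties (uniform null
p-values, partitioning rules, exact identities) transfer directly.
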