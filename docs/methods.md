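# Methods

## Data model

Genotypes are ternary minor-allele counts (0/1/2) with a distinct missing
sentinel; disease status is binary (0 control, 1 case). Category counts
used by the tests are always the *theoretical* ranges — three genotypes,
two classes — not the observed ones, so the dimensions of a contingency
table never depend on which categories happened to occur, and the
empty-cell degrees-of-freedom reduction below is well defined.

In the PLINK-style ped/map dialect the minor allele is the rarer allele
in the file's pooled counts, ties broken lexicographically; `0 0` is a
missing genotype and phenotype codes 1/2 map to control/case.

## The G² conditional-independence test

For variables A, B and a (possibly empty) conditioning set C, observed
counts are tabulated per configuration (stratum) of C over the samples
with no missing value in any involved variable (complete-case deletion
*per test*, which maximises usable data when missingness is scattered).
Expected counts come from each stratum's own margins,
`E_ijk = row_ik · col_jk / N_k`; an empty stratum contributes zero
expectation. The statistic is `G² = 2 Σ O ln(O/E)` with `0·ln 0 ≡ 0`
(a cell with `O > 0` always has `E > 0` under margin-based expectations).

Degrees of freedom are `(Cat(A)−1)(Cat(B)−1)·∏ Cat(Cᵢ)` minus the raw
number of empty cells in the observed table, floored at zero. The raw
count is subtracted without any per-stratum cap. One consequence worth
knowing: a *binary* variable that perfectly copies the class label
leaves four empty cells in its 2×3 table, driving df to zero — the test
is then declared unable to assert anything, despite an enormous
statistic. Real three-category SNPs with all genotypes present are
unaffected; the edge case matters only for degenerate synthetic columns.

A test is **reliable** only if df ≥ 1 after the reduction and the table
averages at least five samples per cell (`reliability_factor`,
configurable) — the usual heuristic in constraint-based structure
learning. Unreliable tests report p = 1 and never assert dependence;
during backward pruning they also never assert independence, so they can
neither admit nor remove a SNP. At 2,000 samples this caps the blanket
at four members (a fifth conditioning variable would need 2,430
samples), which doubles as a tractability guard.

## The blanket search

Forward phase: every SNP outside `MB(T)` is scored by its G² against `T`
conditioned on the *entire* current blanket (incremental-association
style); the maximal reliable, significant score is admitted. Ties break
by smaller p-value, then input order. The batch implementation tabulates
all candidates with one `bincount` over a mixed-radix cell code and is
unit-tested for exact agreement with the scalar test.

Backward phase (after every admission, and once more at the end): members
are scanned most-recently-admitted first; for each member Y the nonempty
subsets of `MB(T)∖{Y}` up to `max_cond_size` (default 3) are enumerated
size-ascending, and the first reliable test with p ≥ α removes Y
immediately. The freshly admitted SNP is protected during the
interleaved sweep (preventing a pathological admit-then-remove of the
same variable); the final sweep protects nothing. Excluding the empty
conditioning set means a singleton blanket is never pruned: a lone
member's marginal admission already justified it, and joint effects are
only ever judged jointly.

Both phases are deterministic functions of the current blanket, so an
oscillation (two near-equivalent SNPs alternately displacing each other)
would repeat forever; the loop therefore terminates when a previously
visited blanket state recurs, recording a `stop` event. This was
observed in practice on simulated data where two noise SNPs each
rendered the other removable.

### Significance policy

Every test uses α = 0.05 by default, **uncorrected**, in both phases.
The method's false-positive control is structural, not threshold-based:
an admitted spurious SNP is pruned as soon as any conditioning subset
fails to reject its independence, which happens with probability ≈ 1−α
per witnessing subset. A Bonferroni option (α scaled by the SNP count in
forward tests only) is provided for screens where the cost of any
spurious report outweighs power; our null-data experiments show it keeps
the mean blanket size below 0.07 on 100-SNP datasets with no associated
SNP. With the uncorrected default, null data typically yields a single
spurious singleton (unprunable by construction) — the trade-off to keep
in mind when the existence of *any* signal is itself in question.

The uncorrected default is deliberate: at realistic effect sizes
(marginal G² noncentrality ~15 at 2,000 samples) a Bonferroni threshold
over 100 SNPs sits almost exactly at the critical value, halving the
probability of ever admitting a true locus, while leaving the backward
phase — the component designed to handle false positives — with nothing
to do.

## Disease models and calibration

Three two-locus models define disease odds over the 3×3 genotype grid at
loci A and B, with baseline α₀ > 0 and genotypic effect θ > −1
(multiplier 1+θ):

| model | odds(g_A, g_B) | character |
|---|---|---|
| 1 | α₀(1+θ)^(g_A+g_B) | multiplicative: independent additive log-odds |
| 2 | α₀(1+θ)^(g_A·g_B) | epistatic: risk only when both loci carry a disease allele |
| 3 | α₀(1+θ)^𝟙[g_A≥1 ∧ g_B≥1] | threshold: plateau, extra alleles add nothing |

Penetrance is odds/(1+odds). Given a marginal effect λ, a disease-locus
MAF and a target prevalence (0.1 throughout the shipped grids),
`calibrate` solves the two-equation system

1. Σ penetrance(g_A,g_B)·P(g_A)P(g_B) = prevalence (loci unlinked, HWE),
2. odds_marg(Aa) / odds_marg(AA) = 1 + λ, where
   odds_marg(g) is the marginal disease odds at one locus,

by nested Brent root-finding (α₀ inner on a log scale, θ outer with
geometric bracket expansion), verifying both residuals to 1e-10. λ is
thus a *marginal odds ratio* per first disease allele — the standard
operational definition for these models. λ = 0 collapses to the exact
null (θ = 0, α₀ = prevalence/(1−prevalence)).

Case and control genotype distributions follow by Bayes inversion:
P(g|case) ∝ penetrance·P(g_A)P(g_B), P(g|control) ∝ (1−penetrance)·
P(g_A)P(g_B); the mixture identity (prevalence-weighted average returns
the population table) is asserted to 1e-10 in tests.

## Linkage disequilibrium and simulation

Each disease locus is latent and observed through one genotyped marker.
The marker's MAF equals the disease MAF and the haplotype disequilibrium
takes the coupling phase, `D = +√(r²·p(1−p)·p(1−p))` — the unique
convention under which r² = 1 makes the marker an exact copy and r²
remains the single free parameter. Each of a sample's two disease-locus
alleles independently emits a marker allele with the conditional
probabilities implied by the four haplotype frequencies, so the
genotype-level squared correlation equals the configured r² (verified
empirically in tests). The repulsion phase at r² < 1 would be an equally
defensible convention; results at r² = 1 are unaffected.

A simulated study draws each sample's latent disease-genotype pair from
the status-conditional table (cases first, then controls), emits the two
markers, fills the remaining columns with independent HWE noise SNPs
whose MAFs are drawn once per SNP from Uniform(0, 0.5) (monomorphic
draws possible and handled by the df/reliability machinery), and places
the two disease markers at random column positions so detection cannot
exploit ordering. All randomness flows from a single seed; datasets are
bit-for-bit reproducible. Default sizes: 100 markers, 1,000 cases,
1,000 controls.

What the generator does **not** emulate: LD among background markers
(each noise SNP is independent), haplotype blocks, population
stratification, genotyping error or missingness, more than two disease
loci. Passing power numbers therefore speak to the detector's behaviour
under clean, exchangeable nulls, not to robustness against confounding
structure in real cohorts.

## QC filters

Three rules, each seeing the survivors of the previous one, a SNP being
attributed to the first rule that removes it: (1) non-polymorphic
(≤ 1 distinct non-missing genotype); (2) more than `max_missing`
(default 5, strict inequality) missing calls; (3) Hardy-Weinberg
chi-square (1 df, allele frequency estimated from the data) p below
`hwe_alpha` (default 1e-6), computed in **controls only** — cases are
expected to deviate at true disease loci, and a stringent threshold
avoids discarding genuine signals. Monomorphic input returns p = 1 by
convention. The filter is idempotent and never alters retained values.

## Power evaluation

A detection is scored **strict** when it equals the two planted markers
exactly and **relaxed** when both are found with at most `max_fp`
(default 2) false positives. The mean false-positive count is reported
both over relaxed successes and over all datasets — both conventions are
found in the literature, and they differ exactly when power is low.
Per-dataset seeds are `master + index (mod 2³¹)`, making grid cells
reproducible and parallelisable.

## Problem sizes and runtime

The shipped acceptance run uses the study-scale conditions — 50 datasets
per grid cell, 100 markers, 1,000/1,000 samples — and completes in well
under a minute on one CPU; the full test suite (including 1,000-replicate
null calibration and 200 pure-noise detector runs) takes about half a
minute. The batch forward scan is what makes this cheap: one pass over
the genotype matrix per forward sweep.

## Known limitations

* Power under the purely multiplicative model (model 1) is markedly
  lower than under models 2 and 3 at equal λ. The cause is structural:
  with two additive-effect loci, each member's conditional dependence on
  the disease given the other is no stronger than its marginal one, so
  each backward sweep re-runs a ~70%-power test on every true member and
  the removal risk compounds across sweeps, while second admissions pay
  a higher-df conditional test for no gain in signal. Blanket searches
  with interleaved pruning are simply at their weakest when there is no
  epistasis to exploit; single-locus scans are the better tool there.
* A singleton blanket cannot be pruned, so on data with no true signal
  the uncorrected default typically reports one spurious SNP (use the
  Bonferroni option when that matters).
* The empty-cell df reduction makes tests involving a *binary* perfect
  copy of the class label unreliable (df ≤ 0); see the G² section.
* The asymptotic χ² calibration was verified at N = 2,000; very small
  strata are guarded by the reliability heuristic rather than by exact
  tests.
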