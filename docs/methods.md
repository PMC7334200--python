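# Methods

## Scope and data model

The package analyses single-nucleotide de novo mutations (DNMs) from trio
sequencing relative to gene structure. All coordinates are 0-based half-open
internally; GTF input is converted on read and BED is consumed natively. DNM
tables are TSV (chrom, pos, ref, alt, condition, dataset), 1-based on disk.

Gene structures are collapsed to **meta-exons** (union of all transcripts'
exon intervals, minus UTR intervals) and **meta-introns** (gaps between
retained meta-exons). Filters, applied in order: non-autosomal genes (when an
autosome list is given), overlapping genes (every member of an overlap
cluster is dropped — overlap would make exon/intron labels ambiguous),
single-exon genes, and genes left without an internal exon after removing
the first and last meta-exon. Each internal meta-exon anchors one analysis
window of width L = 2001 centered on the exon's middle position; for
even-length exons the floor of the midpoint is used (the choice is arbitrary
but must be deterministic). Windows running past a chromosome end are
dropped. Window positions are labelled central-exon / other-exon / intron /
intergenic by intersecting with all retained genes' intervals; flanks are
retained even where they reach neighbouring genes, and the excess statistic
uses central-exon sites only, with everything else as background.

## Context models

A context scheme is (k, h, mode): `direct` estimates P(alt | k-mer) as
mutation count over forward-strand genomic k-mer abundance; `decomposed`
multiplies a core h-mer probability by independent per-flank-position
correction factors, each a count ratio marginalised over the remaining flank
positions; `mono` is the 12-parameter single-nucleotide model and `cpg` its
18-parameter variant splitting C and G by CpG status (C followed by G, G
preceded by C, read on the forward strand). k-mers are counted on the
forward strand only and mutations are used as reported; strand collapsing
appears only in the 9-class spectrum display. Parameter counts are 4^k·3
(direct) and 4^h·3·(1+3(k−h)) (decomposed).

Numerical conventions: contexts containing N, and sites whose context runs
off the chromosome, contribute frequency 0 and are excluded from abundance;
zero-abundance or zero-count contexts get probability 0 — no pseudocounts,
matching the estimator's plain count-ratio definition. With h = k the
decomposition reduces bitwise to the direct estimate (same division, empty
product). Composite probabilities with any zero denominator are set to 0.
Recurrent mutations at one site all enter model estimation; only the
likelihood comparison (below) reduces them to one per site.

## Exon-centered profile and permutation test

Site frequencies f_l = Σ_a P(a | context_l) are rescaled per window to sum
to one; the window's observed total n_s is redistributed as n̂_s^l =
f^resc_l·n_s, making Σ_l n̂_s^l = n_s an identity (checked to 1e−9 relative,
it holds to machine precision). A mutation falling inside several
overlapping windows is counted in each. Windows with an all-zero frequency
vector are excluded and counted.

The permutation test redraws each window's n_s mutations multinomially over
its L sites with probabilities f^resc, independently across windows, all
from one seeded generator. Because the test statistic is the total count
landing in the central-exon site set, its exact marginal is
Binomial(n_s, p_s) with p_s the rescaled frequency mass on those sites; the
implementation draws that binomial directly — distributionally identical to
the full multinomial and far cheaper. The effect size is
100·(obs − mean_perm)/mean_perm (the permutation mean, not the analytic
expectation, is the denominator); the error is one permutation s.d. on the
same scale; the one-sided empirical p counts permutations ≥ the observation
(≤ for deficits), with ties included and a floor of 1/n_permutations so p is
never 0. The side-adaptive p is what is reported; the fixed upper-tail
probability `p_upper` is also returned because it — not the side-adaptive
value, which concentrates below 0.5 under the null — is the quantity that is
uniform when the data come from the profiling model itself. Null calibration
tests use `p_upper`.

Consequence stratification restricts observed central-exon mutations to
synonymous (identical amino acid under the standard genetic code on the
annotated strand) or nonsynonymous (any amino-acid change, including stop
gain/loss), and at central-exon coding sites sums Eq.-style frequencies only
over the alternates of the chosen class; flank sites keep their full
frequency. The two stratified frequencies partition the full one at every
coding site. Central-exon sites outside an annotated CDS contribute zero to
either stratum.

## Model comparison

Every window site (stacked, repeats kept) is interrogated for its observed
state; a mutated site contributes log P(alt | context), an unmutated one
log(1 − Σ_a P(a | context)). Sites whose context is unreadable under the
*largest* compared scheme are excluded from all schemes, so likelihoods are
comparable; recurrent sites are reduced to one mutation chosen at random
with a recorded seed. Models are estimated on the full mutation set and
evaluated on the same data — in-sample, a circularity shared with the
analysis design this package follows; AIC = 2·params − 2·lnL ranks schemes.
A mutated site with zero modelled probability makes the comparison fail
loudly; an explicit probability floor can be supplied (default off).

## Chromatin analysis

Per gene, the feature ratio is (exonic bases with signal > 0)/(intronic
bases with signal > 0); genes with zero covered bases in either compartment,
or without any observed exonic-or-intronic mutation, are excluded (never a
NaN). Expected exonic counts use P_e = L_e/(L_e + L_i) with the L's the
summed all-alternate frequencies over the gene's exonic/intronic sites, and
n̂_e = P_e·n. Genes are grouped into equal-count bins by ratio (quantile
binning stabilises per-bin totals; the grouping rule is otherwise
unconstrained), the per-bin difference is 100·(Σn_e − Σn̂_e)/Σn̂_e, and the
correlation against the bin-median ratio is an iteratively re-weighted
least-squares fit with weights proportional to the inverse within-bin ratio
variance (bins whose member genes disagree about their ratio count less);
with equal weights it reduces exactly to OLS. r is the sign-consistent root
of the weighted R², p the two-sided slope t-test. Zero variances fall back
to equal weights with a warning; a constant x is rejected. The exact
weighting scheme of the somatic study this mirrors is not recoverable, so
inverse-variance weighting is one defensible reading and is kept
configurable through the variance argument.

Nucleosome peaks are strict local maxima (plateaus resolve to their
midpoint) accepted greedily by height, ties to the left, subject to a 150-bp
minimum separation; each peak emits the 147 positions within 73 bp of the
peak coordinate ("146 bp flanking, 73 per side" is off by one as stated;
the inclusive 147-bp region is emitted and documented). Peak calls are
invariant under translation and positive rescaling of the signal.

## Absolute rates

μ = N_obs/(N_site·N_gen). Exonic sites are the central-exon positions of
all stacked windows, the intronic proxy is every remaining window site (the
published site totals confirm this partition); N_gen — the number of
gametogeneses, two per trio — is an explicit input rather than being derived.

## Synthetic data: what it emulates, what it does not

The generator produces the statistical structure the analysis assumes, at
desk scale. Genes (single transcript, CDS covering every exon, length padded
to a codon multiple so frames are unambiguous, random strand) are packed
without overlap with intergenic gaps long enough that windows never cross
chromosome ends. Exon sequence comes from a first-order Markov chain whose
C→G transition is boosted by the configured CpG enrichment and whose
transition matrix is calibrated (fixed-point on the stationary distribution)
so exonic GC hits its target; introns and intergenic sequence are i.i.d. at
a lower GC. A Markov chain replaced the initially considered
rejection-sampling scheme because a 2× CpG enrichment is an exponentially
rare event for i.i.d. 160-bp draws.

Mutations are drawn per site as Binomial(N_gen, f·m) with f the generating
model's total site frequency and m the exonic multiplier at internal-exon
sites — a Bernoulli-per-gametogenesis approximation that is adequate while
f·m ≪ 1 (it errors if f·m > 1). Alternates follow the model's per-alternate
probabilities. Defaults emulate the pooled-study conditions: 11,237 trios, a
mean per-site per-gametogenesis rate of ~1.2e−8 (aggregate density
~2.5e−4/site, matching ~6.8e5 DNMs over a ~2.7-Gb autosomal genome), 1.7%
ASD probands, transition-biased rates with ~15× CpG C>T hypermutability and
lognormal per-context jitter (σ = 0.4) so the process is genuinely 3-mer
dependent. Disease ascertainment keeps diseased probands' exonic
nonsynonymous mutations with probability 1 and all their other mutations
with probability 1/boost, i.e. a relative nonsynonymous enrichment equal to
the boost. Chromatin tracks: H3K36me3-like coverage covers integer numbers
of exonic/intronic bases per gene whose ratio reproduces the configured
target (exactly when the rounding is exact and noise is zero, optionally
lognormally dispersed across genes); the nucleosome signal is a raised
cosine of configurable period whose maxima are the recorded truth peaks.

Not emulated: read-level sequencing and calling artifacts, parental age and
sex effects, multi-transcript genes with conflicting frames, selection on
the mutations themselves, and realistic genome/exome proportions — exons are
~8% of the synthetic genome versus ~1–2% of a mammalian genome. Passing
tests therefore demonstrate the *correctness and calibration of the
machinery* (estimators converge on their own generative assumptions; the
permutation test is uniform under the null; injected effects are recovered),
not the empirical values of any real cohort.

Two consequences of the scaled-down world are worth recording. First, an
aggressive ascertainment boost inflates per-window totals enough to drive a
*deficit* in the synonymous stratum (the same arithmetic that produces a
small synonymous deficit alongside a ~10% nonsynonymous excess in real
ascertained cohorts); the ascertainment demonstrations therefore use a mild
boost (1.3). Second, overlapping windows double-count sites with perfectly
correlated mutation draws, so the binomial-coverage check of the rate
estimator uses configurations whose introns (mean 2500 bp) keep adjacent
windows disjoint, restoring the exact binomial sampling model.

## Problem sizes and tolerances

Test and acceptance runs use a ~1.3-Mb genome with 160 genes (~560 windows,
~1.1M window sites) and cohorts sized to yield ≳20,000 genic mutations where
an analysis needs them; null calibration uses 220 replicate simulations with
100 permutations each (KS uniformity at α = 0.01); effect recovery uses 1000
permutations and a ±2-permutation-s.d. band; the rate-coverage check uses
100 replicates against exact (Clopper–Pearson) 95% intervals. Conservation
identities are asserted at 1e−9 relative tolerance; oracle equivalences
(decomposition with h = k, brute-force recounts) are exact.

## Known limitations

In-sample likelihood comparison (shared with the design being reproduced);
no smoothing or shrinkage for sparse large-k contexts, so 7-mer direct
models are unusable at small mutation counts (use the decomposition); the
consequence classifier covers the synonymous-versus-higher dichotomy only,
not a full consequence hierarchy; the IRLS weighting is one reading of an
under-specified procedure; meta-intron definitions leave three-exon genes
without intronic sites for the per-gene chromatin ratio, excluding them
there.
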