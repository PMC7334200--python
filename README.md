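# exindnm

Exon-versus-intron germline de novo mutation (DNM) rate analysis with
k-mer sequence-context models.

## The problem

Population genetics routinely uses intronic sites as a neutral yardstick for
exonic constraint, which presumes that the *mutation* rate does not itself
depend on whether a site is exonic or intronic. Exons are GC- and CpG-rich,
so their raw per-site DNM density is higher than introns' for purely
compositional reasons; and cohorts ascertained for disease carry an excess of
functional (nonsynonymous) exonic variants. Separating genuine rate
differences from these two confounders requires (i) a sequence-context
mutation model and (ii) a consequence-stratified, permutation-calibrated
comparison of observed and expected mutation burdens around internal exons.
This package implements that analysis as a reusable, fully testable pipeline,
exercised end to end on synthetic genomes with known ground truth.

## The model

Per-site mutation probabilities are conditioned on the reference base H_r and
its flanking sequence **X** ((k−1)/2 bases per side):

    P(H_a | H_r, X) = N(H_a, H_r, X) / G(H_r, X)

with N the genome-wide DNM count in that k-mer context and G the genomic
abundance of the reference k-mer. For large k the table is approximated by a
composite-likelihood decomposition around a core h-mer,

    P(H_a | H_r, X) ≈ P(H_a | H_r) · Π_i  P_i(H_a | H_r, x_i) / P(H_a | H_r),

where each marginal P_i conditions on a single flank position. The direct
model has 4^k·3 free parameters; the decomposition has 4^h·3·(1 + 3(k−h)).

For the exon/intron comparison, 2001-nt windows are stacked on the middle
position of every internal meta-exon. Site l of window s has frequency
f_l = Σ_a P(H_a | H_r^l, X^l), rescaled to sum to one over the window; the
window's n_s observed mutations are redistributed as n̂_s^l = f_l^resc · n_s,
so expected totals match observed totals by construction. The exonic excess
is the percent deviation of the observed central-exon count from its
permutation mean (1000 multinomial redistributions per window), with an
empirical one-sided p-value floored at 1/n_permutations. Context schemes are
ranked by AIC = 2·(parameters) − 2·(full-site log-likelihood); per-gene
chromatin analysis relates the exon/intron coverage ratio of a feature (e.g.
H3K36me3) to the gene-level exonic mutation deviation via inverse-variance
weighted least squares; absolute rates are μ = N_obs / (N_site · N_gen) with
N_gen the number of gametogeneses (two per trio).

## Worked example

`examples/01_simulate_and_profile.py` simulates a ~1.3-Mb genome with 160
multi-exon genes, draws ~23,000 DNMs from a CpG-boosted 3-mer process with a
10% exonic rate multiplier, and runs the exon-centered analysis:

```
genome: 1,271,042 bp, 160 genes, 561 exon-centered windows
simulated DNMs: 22,990 (exonic multiplier 1.1)
stacked windows: observed total 20860 == expected total 20860 (conserved by construction)
exonic excess: +9.8% +- 1.8% (empirical one-sided p = 0.001)
```

The injected +10% exonic rate surfaces as a +9.8% ± 1.8% excess over the
context-model expectation, significant at the permutation floor p = 0.001.
The other examples cover model estimation and the mutation spectrum (`02`),
AIC-based scheme selection (`03`), and the chromatin and absolute-rate
analyses (`04`). A thin CLI (`exin-dnm simulate|annotate|signature|profile|
compare|chromatin|rate|run-all`) wraps the same library functions for shell
use; `exin-dnm run-all --config run.yaml` executes the whole pipeline with
one seed and writes TSV reports tagged with the config hash.

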