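"""Estimate k-mer context mutation models and the 9-class spectrum.

Fits the direct 3-mer model (counts over genomic k-mer abundance), a
composite-likelihood 5-mer decomposition with a 3-mer core, and prints the
strand-collapsed mutation spectrum with its CpG hypermutability.
"""

import numpy as np

import exindnm as ed

cfg = ed.SimulationConfig(seed=5, n_genes=80, n_trios=26000)
genome, annotation = ed.simulate_genome(cfg)
truth = ed.default_true_model(mean_rate=4e-7)
dnms = ed.simulate_dnms(genome, annotation, cfg, truth)
print(f"{len(dnms):,} simulated DNMs on a "
      f"{sum(genome.length(c) for c in genome.chrom_names):,} bp genome")

m3 = ed.estimate_direct(dnms, genome, 3)
m5 = ed.estimate_direct(dnms, genome, 5)
m53 = ed.estimate_decomposed(dnms, genome, 5, 3)
print(f"3-mer model: {ed.parameter_count(m3.scheme)} parameters, "
      f"{int(m3.counts.sum())} mutations used")
print(f"5-mer decomposed (h=3): {ed.parameter_count(m53.scheme)} parameters "
      f"vs {ed.parameter_count(m5.scheme)} for the exact 5-mer")

# agreement between the exact 5-mer rates and the composite-likelihood ones
seen = (m5.probs.ravel() > 0) & (m53.probs.ravel() > 0)
r = np.corrcoef(np.log(m5.probs.ravel()[seen]),
                np.log(m53.probs.ravel()[seen]))[0, 1]
print(f"log-rate agreement, exact vs decomposed 5-mer: r = {r:.3f}")

spectrum = ed.mutation_spectrum(dnms, genome)
spectrum["rate"] /= spectrum["rate"].sum()
print("\nabundance-corrected spectrum (normalised):")
print(spectrum[["class", "count", "rate"]].to_string(index=False))
cpg = spectrum.set_index("class")
print(f"\n-> CpG transitions are "
      f"{cpg.loc['C>T_CpG', 'rate'] / cpg.loc['C>T', 'rate']:.1f}x the non-CpG "
      "C>T rate, the generator's deamination-like signature.")
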