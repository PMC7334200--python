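"""Chromatin-feature analysis and absolute mutation-rate estimates.

Generates an exon-enriched H3K36me3-like coverage track and a phased
nucleosome signal, calls nucleosome peaks, relates per-gene exonic mutation
enrichment to the chromatin ratio across bins, and estimates exonic and
intronic per-site per-generation mutation rates.
"""

import numpy as np

import exindnm as ed

cfg = ed.SimulationConfig(seed=14, n_genes=160, n_trios=26000,
                          track_params=ed.TrackParams(h3k36me3_ratio_sd=0.4))
genome, annotation = ed.simulate_genome(cfg)
genes, _ = ed.build_gene_models(annotation)
windows = ed.extract_windows(genes, {c: genome.length(c) for c in genome.chrom_names})
truth = ed.default_true_model(mean_rate=4e-7)
dnms = ed.simulate_dnms(genome, annotation, cfg, truth, genes=genes)
h3k, nuc, track_truth = ed.simulate_tracks(genome, genes, cfg)

peaks = ed.call_nucleosome_peaks(nuc)
n_true = sum(len(v) for v in track_truth["nucleosome_peaks"].values())
print(f"nucleosome peaks: called {len(peaks)}, truth {n_true} "
      f"(period {track_truth['nucleosome_period']} bp)")

model = ed.estimate_direct(dnms, genome, 3)
gt = ed.gene_enrichment_table(genes, h3k, dnms, genome, model)
bins = ed.binned_difference(gt, n_bins=20)
r, p = ed.irls_correlation(bins["median_ratio"].to_numpy(),
                           bins["difference_pct"].to_numpy(),
                           bins["ratio_var"].to_numpy())
print(f"binned gene analysis: {len(gt)} genes in 20 bins; "
      f"exonic-excess vs H3K36me3 ratio: r = {r:+.3f}, p = {p:.3g}")
print("-> the mutation process ignores the chromatin track, so the correlation")
print("   is typically non-significant (as for any null, ~5% of seeds will")
print("   cross p = 0.05 by chance).")

rates = ed.rates_from_windows(windows, dnms, n_gen=cfg.n_gametogeneses)
print("\nabsolute rates (per site per gametogenesis):")
print(rates.to_string(index=False))
mu = rates.set_index("compartment")["mu"]
print(f"-> exonic/intronic rate ratio {mu['exonic'] / mu['intronic']:.2f}: exons are "
      "more mutable purely through their GC/CpG-rich composition.")
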