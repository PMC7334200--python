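"""Rank context schemes by AIC over all window sites.

Data are simulated from a 3-mer truth; the comparison evaluates each
scheme's full-site log-likelihood (mutated sites contribute log P(alt),
unmutated ones log(1 - total rate)) on one common site set and penalises
parameters via AIC = 2k - 2 lnL.
"""

import exindnm as ed
from exindnm.context import ContextScheme

cfg = ed.SimulationConfig(seed=20, n_genes=160, n_trios=26000)
genome, annotation = ed.simulate_genome(cfg)
genes, _ = ed.build_gene_models(annotation)
windows = ed.extract_windows(genes, {c: genome.length(c) for c in genome.chrom_names})
truth = ed.default_true_model(mean_rate=4e-7)
dnms = ed.simulate_dnms(genome, annotation, cfg, truth, genes=genes)

schemes = [ContextScheme.parse(s) for s in ("mono", "cpg", "3", "5")]
table = ed.compare_models(windows, dnms, genome, schemes,
                          n_permutations=200, seed=3)
cols = ["model", "excess_pct", "sd_pct", "p_value", "loglik", "n_param", "aic", "best"]
print(table[cols].round(3).to_string(index=False))
best = table.loc[table["best"], "model"].iloc[0]
print(f"\n-> the generating scheme ({best}) attains the minimum AIC: the "
      "likelihood gain of the 5-mer scheme does not pay for its extra parameters,")
print("   and the 1-mer model's huge apparent exonic excess disappears once "
      "trinucleotide composition is modelled.")
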