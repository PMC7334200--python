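"""End-to-end orchestration: simulate -> annotate -> model -> profile ->
compare -> chromatin -> rates, with one config, one seed, TSV outputs.

Every output table starts with a '#' line carrying the seed and a hash of
the configuration, so identical config + seed give identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as eio
from .annotation import (MappabilityMask, build_gene_models, extract_windows,
                         filter_windows_by_mappability, windows_to_bed)
from .chromatin import (CoverageTrack, binned_difference, call_nucleosome_peaks,
                        gene_enrichment_table, irls_correlation, peaks_to_bed)
from .context import ContextScheme, estimate, mutation_spectrum
from .genome import GenomeSequence
from .profile import (build_profile, exonic_excess_test,
                      stratify_by_consequence, window_frequencies,
                      window_observed_counts)
from .rates import rates_from_windows
from .selection import compare_models
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger("exindnm")


@dataclass
class RunConfig:
    """Inputs and knobs for a full pipeline run."""

    outdir: str
    fasta: str | None = None
    gtf: str | None = None
    dnms: str | None = None
    mask: str | None = None
    h3k36me3: str | None = None
    nucleosome: str | None = None
    simulate: dict | None = None      # SimulationConfig fields; generates inputs
    schemes: list[str] = field(default_factory=lambda: ["mono", "cpg", "3", "5"])
    model_scheme: str = "3"
    width: int = 2001
    n_permutations: int = 1000
    n_bins: int = 20
    stratify: str | None = None       # 'synonymous' or 'nonsynonymous'
    n_gen: int = 22474
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        fields = {k: v for k, v in self.__dict__.items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the result bundle.

    Any stage failure aborts with the stage name and cause.  Returns a
    mapping of stage name to output path.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"seed={config.seed} config={config.hash()}"
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs: dict[str, Path] = {}

    stage = "simulate"
    try:
        if config.simulate is not None:
            sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
            paths = simulate_all(sim_cfg, outdir / "inputs")
            config.fasta = str(paths["fasta"])
            config.gtf = str(paths["gtf"])
            config.dnms = str(paths["dnms"])
            config.h3k36me3 = str(paths["h3k36me3"])
            config.nucleosome = str(paths["nucleosome"])
            logger.info("simulated inputs under %s", outdir / "inputs")
        for name in ("fasta", "gtf", "dnms"):
            path = getattr(config, name)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"missing input file for '{name}': {path}")

        stage = "annotate"
        genome = GenomeSequence.from_fasta(config.fasta)
        annotation = eio.read_gtf(config.gtf)
        genes, report = build_gene_models(annotation)
        logger.info("gene filters: %s", report)
        chrom_lengths = {c: genome.length(c) for c in genome.chrom_names}
        windows = extract_windows(genes, chrom_lengths, width=config.width)
        if config.mask:
            mask = MappabilityMask.from_bed(config.mask)
            n0 = len(windows)
            windows = filter_windows_by_mappability(windows, mask)
            logger.info("mappability filter retained %d/%d windows", len(windows), n0)
        windows_to_bed(windows, outdir / "windows.bed")
        outputs["windows"] = outdir / "windows.bed"

        stage = "signature"
        mutations = eio.read_dnms(config.dnms)
        model = estimate(mutations, genome, ContextScheme.parse(config.model_scheme))
        model.to_tsv(outdir / "model.tsv")
        outputs["model"] = outdir / "model.tsv"
        spectrum = mutation_spectrum(mutations, genome)
        eio.write_table(spectrum, outdir / "spectrum.tsv", tag)
        outputs["spectrum"] = outdir / "spectrum.tsv"

        stage = "profile"
        gene_by_id = {g.gene_id: g for g in genes}
        if config.stratify:
            freqs, observed = stratify_by_consequence(
                mutations, windows, gene_by_id, genome, model, config.stratify)
        else:
            freqs = window_frequencies(windows, genome, model)
            observed = window_observed_counts(windows, mutations)
        profile = build_profile(windows, freqs, observed)
        eio.write_table(profile.to_frame(), outdir / "profile.tsv", tag)
        outputs["profile"] = outdir / "profile.tsv"
        result = exonic_excess_test(windows, freqs, observed,
                                    n_permutations=config.n_permutations, seed=config.seed)
        summary = pd.DataFrame([{
            "dataset": "all", "stratum": config.stratify or "all",
            "excess_pct": result.excess_pct, "sd_pct": result.sd_pct,
            "p_value": result.p_value, "n_windows": profile.S,
        }])
        eio.write_table(summary, outdir / "excess.tsv", tag)
        outputs["excess"] = outdir / "excess.tsv"
        logger.info("exonic excess %.2f%% +- %.2f%%, p=%.4g",
                    result.excess_pct, result.sd_pct, result.p_value)

        stage = "compare"
        schemes = [ContextScheme.parse(s) for s in config.schemes]
        table = compare_models(windows, mutations, genome, schemes,
                               n_permutations=config.n_permutations, seed=config.seed)
        eio.write_table(table, outdir / "compare.tsv", tag)
        outputs["compare"] = outdir / "compare.tsv"

        stage = "chromatin"
        if config.h3k36me3:
            track = CoverageTrack.from_bedgraph(config.h3k36me3, chrom_lengths)
            gt = gene_enrichment_table(genes, track, mutations, genome, model)
            eio.write_table(gt, outdir / "gene_enrichment.tsv", tag)
            outputs["gene_enrichment"] = outdir / "gene_enrichment.tsv"
            if len(gt) >= config.n_bins:
                bins = binned_difference(gt, n_bins=config.n_bins)
                if bins["median_ratio"].nunique() > 1:
                    r, p = irls_correlation(bins["median_ratio"].to_numpy(),
                                            bins["difference_pct"].to_numpy(),
                                            bins["ratio_var"].to_numpy())
                    extra = f" r={r:.4f} p={p:.4g}"
                    logger.info("chromatin correlation r=%.3f p=%.3g", r, p)
                else:
                    extra = " (constant ratios; correlation skipped)"
                eio.write_table(bins, outdir / "binned_difference.tsv", tag + extra)
                outputs["binned_difference"] = outdir / "binned_difference.tsv"
        if config.nucleosome:
            track = CoverageTrack.from_bedgraph(config.nucleosome, chrom_lengths)
            peaks = call_nucleosome_peaks(track)
            peaks_to_bed(peaks, outdir / "nucleosome_peaks.bed")
            outputs["nucleosome_peaks"] = outdir / "nucleosome_peaks.bed"

        stage = "rate"
        rates = rates_from_windows(windows, mutations, n_gen=config.n_gen)
        eio.write_table(rates, outdir / "rates.tsv", tag)
        outputs["rates"] = outdir / "rates.tsv"
    except Exception as exc:
        logger.error("stage '%s' failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs
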