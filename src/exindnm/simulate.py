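"""Synthetic genomes, annotations, de novo mutations and chromatin tracks.

The generator produces the statistical structure the exon/intron analysis
assumes, at desk scale:

* multi-exon protein-coding genes with elevated exonic GC and CpG content
  (exon sequence from a first-order Markov chain with a boosted C->G
  transition; introns and intergenic sequence i.i.d. at a lower GC),
* de novo mutations drawn site-wise from a configurable k-mer context model,
  with an optional rate multiplier at internal-exon sites and optional
  disease-ascertainment enrichment of exonic nonsynonymous variants,
* an exon-enriched H3K36me3-like coverage track and a phased nucleosome
  signal with known peak positions.

Every draw flows through one seeded generator, so outputs are byte-identical
under a fixed seed.  Per-site mutation draws are Bernoulli per gametogenesis
(at most one mutation per site per transmission), an adequate approximation
at per-site rates far below one.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (NONCODING, OTHER_EXON, GeneModel, build_gene_models,
                         classify_consequence, genome_label_arrays)
from .chromatin import CoverageTrack
from .context import ContextModel, ContextScheme, state_ref_base
from .genome import BASES, GenomeSequence, decode

HEALTHY, ASD = "healthy", "ASD"


@dataclass
class TrackParams:
    """Chromatin-track generation knobs."""

    h3k36me3_ratio: float = 2.0       # per-gene exon/intron covered-base ratio
    h3k36me3_ratio_sd: float = 0.0    # lognormal sigma of the per-gene ratio
    h3k36me3_depth: float = 5.0       # coverage value at covered bases
    h3k36me3_noise: float = 0.0       # s.d. of additive noise on covered bases
    nucleosome_period: int = 185      # bp between phased nucleosome peaks
    nucleosome_amplitude: float = 2.0
    nucleosome_noise: float = 0.0


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic world.

    Defaults emulate the pooled trio study: 11,237 trios, an autosomal
    mutation process with CpG>TpG hypermutability around a mean per-site
    per-gametogenesis rate of ~1.2e-8, internal exons ~160 bp with elevated
    GC/CpG, and a 1.7% ASD proband fraction.
    """

    seed: int = 0
    n_chromosomes: int = 2
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (4, 7)        # inclusive range
    exon_length: tuple[float, float] = (160.0, 40.0)    # mean, sd
    intron_length: tuple[float, float] = (900.0, 250.0)
    intergenic_length: tuple[float, float] = (3000.0, 800.0)
    exonic_gc: float = 0.52
    intronic_gc: float = 0.40
    cpg_enrichment: float = 2.0       # exonic CpG boost over the i.i.d. expectation
    exonic_multiplier: float = 1.0    # mutation-rate multiplier at internal-exon sites
    n_trios: int = 11237
    condition_mix: dict = field(default_factory=lambda: {HEALTHY: 0.983, ASD: 0.017})
    ascertainment_boost: float = 1.0  # relative oversampling of exonic nonsynonymous
    minus_strand_fraction: float = 0.5
    track_params: TrackParams = field(default_factory=TrackParams)

    def __post_init__(self) -> None:
        if isinstance(self.track_params, dict):
            self.track_params = TrackParams(**self.track_params)
        if abs(sum(self.condition_mix.values()) - 1.0) > 1e-9:
            raise ValueError("condition_mix fractions must sum to 1")
        if self.exonic_multiplier < 0:
            raise ValueError("exonic_multiplier must be >= 0")
        if self.exons_per_gene[0] < 3:
            raise ValueError("need >= 3 exons per gene so internal exons exist")

    @property
    def n_gametogeneses(self) -> int:
        return 2 * self.n_trios

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "track_params" in raw:
            raw["track_params"] = TrackParams(**raw["track_params"])
        for key in ("exons_per_gene", "exon_length", "intron_length", "intergenic_length"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# the generating mutation process
# --------------------------------------------------------------------------

def default_true_model(mean_rate: float = 1.2e-8, seed: int = 1234,
                       context_sd: float = 0.4, cpg_boost: float = 15.0,
                       transition_weight: float = 3.0) -> ContextModel:
    """A heterogeneous 3-mer generating process.

    Transitions outweigh transversions, CpG C>T (and its reverse-strand
    image G>A after C) is strongly boosted, and every (context, alternate)
    rate carries lognormal jitter so the process is genuinely 3-mer
    dependent.  Rates are scaled so the context-averaged per-site total
    equals ``mean_rate`` (per gametogenesis).
    """
    rng = np.random.default_rng(seed)
    scheme = ContextScheme(3, 3, "direct")
    n = scheme.n_states
    refs = state_ref_base(scheme)
    weights = np.empty((n, 3))
    transitions = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T
    for s in range(n):
        ref = int(refs[s])
        left = (s // 16) % 4
        right = s % 4
        alts = [b for b in range(4) if b != ref]
        for j, a in enumerate(alts):
            w = transition_weight if transitions[ref] == a else 1.0
            if ref == 1 and right == 2 and a == 3:   # CpG: C>T
                w *= cpg_boost
            if ref == 2 and left == 1 and a == 0:    # CpG on the other strand: G>A
                w *= cpg_boost
            weights[s, j] = w
    weights *= rng.lognormal(0.0, context_sd, size=weights.shape)
    weights *= mean_rate / weights.sum(axis=1).mean()
    return ContextModel(scheme, weights)


def uniform_true_model(p: float, k: int = 1) -> ContextModel:
    scheme = ContextScheme(1, 1, "mono") if k == 1 else ContextScheme(k, k, "direct")
    return ContextModel(scheme, np.full((scheme.n_states, 3), p))


# --------------------------------------------------------------------------
# genome + annotation
# --------------------------------------------------------------------------

def _iid_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


_EXON_CHAIN_CACHE: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}


def _exon_chain(gc: float, cpg_enrichment: float) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix with a boosted C->G step, calibrated so the chain's
    stationary composition hits the target GC.  Cached per (gc, enrichment)."""
    key = (round(gc, 6), round(cpg_enrichment, 6))
    if key in _EXON_CHAIN_CACHE:
        return _EXON_CHAIN_CACHE[key]
    gc_eff = gc
    for _ in range(60):
        p = np.array([(1 - gc_eff) / 2, gc_eff / 2, gc_eff / 2, (1 - gc_eff) / 2])
        trans = np.tile(p, (4, 1))
        boosted = min(cpg_enrichment * p[2], 0.9)
        trans[1] = p * (1 - boosted) / (1 - p[2])
        trans[1, 2] = boosted
        vals, vecs = np.linalg.eig(trans.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi = np.abs(pi) / np.abs(pi).sum()
        err = gc - (pi[1] + pi[2])
        if abs(err) < 1e-9:
            break
        gc_eff = min(max(gc_eff + err, 0.02), 0.98)
    _EXON_CHAIN_CACHE[key] = (trans, pi)
    return trans, pi


def _markov_exon_sequence(rng: np.random.Generator, n: int, gc: float,
                          cpg_enrichment: float) -> np.ndarray:
    """First-order Markov chain at the target stationary GC with the C->G
    transition boosted by ``cpg_enrichment``."""
    trans, pi = _exon_chain(gc, cpg_enrichment)
    cum = trans.cumsum(axis=1)
    out = np.empty(n, dtype=np.uint8)
    out[0] = rng.choice(4, p=pi)
    u = rng.random(n)
    for i in range(1, n):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return out


def _positive_int(rng: np.random.Generator, mean: float, sd: float, minimum: int) -> int:
    return max(minimum, int(round(rng.normal(mean, sd))))


def simulate_genome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeSequence, pd.DataFrame]:
    """Generate a genome and its annotation.

    Genes are placed without overlap, separated by intergenic gaps long
    enough that 2001-nt windows never cross a chromosome end.  Each gene is
    a single transcript whose CDS covers every exon; exon lengths are
    adjusted so the CDS length is a multiple of three, making reading frames
    unambiguous.  Returns (genome, annotation) with the annotation in
    0-based half-open pyranges layout (Chromosome, Feature, Start, End,
    Strand, Frame, gene_id, transcript_id).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1

    sequences: dict[str, str] = {}
    records = []
    gene_counter = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        parts: list[np.ndarray] = []
        cursor = 0
        margin = _positive_int(rng, *config.intergenic_length, 1200)
        parts.append(_iid_sequence(rng, margin, config.intronic_gc))
        cursor += margin
        for _ in range(per_chrom[ci]):
            gene_counter += 1
            gid = f"gene{gene_counter}"
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exon_lens = [_positive_int(rng, *config.exon_length, 30) for _ in range(n_exons)]
            total = sum(exon_lens)
            exon_lens[-1] += (-total) % 3  # CDS length to a codon boundary
            intron_lens = [_positive_int(rng, *config.intron_length, 80)
                           for _ in range(n_exons - 1)]
            exon_ivs = []
            for i, elen in enumerate(exon_lens):
                parts.append(_markov_exon_sequence(rng, elen, config.exonic_gc,
                                                   config.cpg_enrichment))
                exon_ivs.append((cursor, cursor + elen))
                cursor += elen
                if i < n_exons - 1:
                    ilen = intron_lens[i]
                    parts.append(_iid_sequence(rng, ilen, config.intronic_gc))
                    cursor += ilen
            gene_start, gene_end = exon_ivs[0][0], exon_ivs[-1][1]
            tid = f"{gid}.t1"
            records.append((chrom, "sim", "gene", gene_start, gene_end, strand, ".", gid, ""))
            records.append((chrom, "sim", "transcript", gene_start, gene_end, strand, ".", gid, tid))
            order = exon_ivs if strand == "+" else exon_ivs[::-1]
            cum = 0
            frames = {}
            for s, e in order:
                frames[(s, e)] = cum % 3
                cum += e - s
            for s, e in exon_ivs:
                records.append((chrom, "sim", "exon", s, e, strand, ".", gid, tid))
                records.append((chrom, "sim", "CDS", s, e, strand, str(frames[(s, e)]), gid, tid))
            gap = _positive_int(rng, *config.intergenic_length, 1200)
            parts.append(_iid_sequence(rng, gap, config.intronic_gc))
            cursor += gap
        sequences[chrom] = decode(np.concatenate(parts)) if parts else ""

    annotation = pd.DataFrame(
        records,
        columns=["Chromosome", "Source", "Feature", "Start", "End", "Strand",
                 "Frame", "gene_id", "transcript_id"],
    )
    return GenomeSequence(sequences), annotation


# --------------------------------------------------------------------------
# mutations
# --------------------------------------------------------------------------

def simulate_dnms(
    genome: GenomeSequence,
    annotation: pd.DataFrame,
    config: SimulationConfig,
    true_model: ContextModel | None = None,
    rng: np.random.Generator | None = None,
    genes: list[GeneModel] | None = None,
) -> pd.DataFrame:
    """Draw de novo mutations from the generating context model.

    Per site, the mutation count over ``n_gametogeneses`` transmissions is
    binomial with per-transmission probability f_site (times the exonic
    multiplier at internal-exon sites); the alternate allele is drawn
    proportionally to the model's per-alternate probabilities.  Each
    mutation is assigned a proband condition; for diseased probands,
    mutations that are not exonic nonsynonymous are kept with probability
    1/ascertainment_boost, producing the relative enrichment of functional
    exonic variants seen in disease-ascertained cohorts.

    Returns a table (chrom, pos, ref, alt, condition, dataset, consequence),
    with the consequence filled for internal-exon mutations and 'noncoding'
    elsewhere.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if true_model is None:
        true_model = default_true_model()
    if genes is None:
        genes, _ = build_gene_models(annotation)
    gene_by_id = {g.gene_id: g for g in genes}
    chrom_lengths = {c: genome.length(c) for c in genome.chrom_names}
    labels = genome_label_arrays(genes, chrom_lengths)
    # map internal-exon positions to their gene
    exon_gene: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        for s, e in g.meta_exons:
            exon_gene.setdefault(g.chrom, []).append((s, e, g.gene_id))
    for iv in exon_gene.values():
        iv.sort()

    conditions = list(config.condition_mix)
    cond_p = np.array([config.condition_mix[c] for c in conditions])
    n_gen = config.n_gametogeneses

    rows = []
    for chrom in genome.chrom_names:
        codes = genome.codes(chrom)
        states = true_model.state_track(codes)
        alt_probs = true_model.site_alt_probs(states)  # (n, 3)
        f = alt_probs.sum(axis=1)
        mult = np.where(labels[chrom] == OTHER_EXON, config.exonic_multiplier, 1.0)
        p = f * mult
        if (p > 1).any():
            raise ValueError("per-site mutation probability exceeds 1 after multiplier")
        counts = rng.binomial(n_gen, p)
        hit = np.flatnonzero(counts)
        pos = np.repeat(hit, counts[hit])
        if len(pos) == 0:
            continue
        # alternate allele ~ model probabilities at the site
        probs = alt_probs[pos]
        cum = probs.cumsum(axis=1)
        u = rng.random(len(pos)) * cum[:, -1]
        alt_j = (u[:, None] >= cum).sum(axis=1)
        refs = codes[pos]
        alt_codes = np.array([[b for b in range(4) if b != r] for r in range(4)])
        alts = alt_codes[refs, alt_j]
        cond = rng.choice(len(conditions), size=len(pos), p=cond_p)

        ivs = exon_gene.get(chrom, [])
        starts = np.array([s for s, _, _ in ivs]) if ivs else np.empty(0, dtype=int)
        keep_u = rng.random(len(pos))
        for i in range(len(pos)):
            psite = int(pos[i])
            ref_b, alt_b = BASES[refs[i]], BASES[alts[i]]
            consequence = NONCODING
            if ivs:
                k = np.searchsorted(starts, psite, side="right") - 1
                if k >= 0 and ivs[k][0] <= psite < ivs[k][1]:
                    consequence = classify_consequence(
                        chrom, psite, ref_b, alt_b, gene_by_id[ivs[k][2]], genome)
            condition = conditions[cond[i]]
            if (condition != HEALTHY and config.ascertainment_boost > 1.0
                    and consequence != "nonsynonymous"
                    and keep_u[i] >= 1.0 / config.ascertainment_boost):
                continue
            rows.append((chrom, psite, ref_b, alt_b, condition, "sim", consequence))

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "condition",
                                     "dataset", "consequence"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# --------------------------------------------------------------------------
# chromatin tracks
# --------------------------------------------------------------------------

def simulate_tracks(
    genome: GenomeSequence,
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CoverageTrack, CoverageTrack, dict]:
    """H3K36me3-like and nucleosome-like coverage tracks plus truth metadata.

    H3K36me3: per gene, exonic and intronic bases are covered in integer
    numbers whose ratio reproduces the configured exon-to-intron target
    (exactly, when the target times the intronic count is integral and noise
    is zero).  Nucleosome: a phased raised cosine with the configured period;
    its maxima are the true peak positions.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    tp = config.track_params
    h3k = {c: np.zeros(genome.length(c)) for c in genome.chrom_names}
    ratios = {}
    for gene in genes:
        arr = h3k[gene.chrom]
        target = tp.h3k36me3_ratio
        if tp.h3k36me3_ratio_sd > 0:
            target *= float(np.exp(rng.normal(0.0, tp.h3k36me3_ratio_sd)))
        le = gene.exonic_length()
        li = gene.intronic_length()
        if li == 0:
            continue
        n_i = min(li, int(np.floor(le / target))) if target > 0 else li
        n_e = int(round(target * n_i))
        if n_i == 0 or n_e == 0 or n_e > le:
            continue
        ratios[gene.gene_id] = n_e / n_i
        _cover_first(arr, gene.meta_exons, n_e, tp.h3k36me3_depth, tp.h3k36me3_noise, rng)
        _cover_first(arr, gene.meta_introns, n_i, tp.h3k36me3_depth, tp.h3k36me3_noise, rng)

    nuc = {}
    peaks = {}
    for chrom in genome.chrom_names:
        n = genome.length(chrom)
        x = np.arange(n)
        signal = tp.nucleosome_amplitude * (1 + np.cos(2 * np.pi * x / tp.nucleosome_period))
        if tp.nucleosome_noise > 0:
            signal = np.clip(signal + rng.normal(0, tp.nucleosome_noise, size=n), 0, None)
        nuc[chrom] = signal
        peaks[chrom] = [int(p) for p in range(0, n, tp.nucleosome_period) if 0 < p < n - 1]

    truth = {
        "h3k36me3_gene_ratios": ratios,
        "nucleosome_peaks": peaks,
        "nucleosome_period": tp.nucleosome_period,
    }
    return CoverageTrack(h3k), CoverageTrack(nuc), truth


def _cover_first(arr: np.ndarray, intervals: list[tuple[int, int]], n_bases: int,
                 depth: float, noise: float, rng: np.random.Generator) -> None:
    remaining = n_bases
    for s, e in intervals:
        if remaining <= 0:
            break
        take = min(remaining, e - s)
        if noise > 0:
            arr[s:s + take] = np.clip(depth + rng.normal(0, noise, size=take), 0, None)
        else:
            arr[s:s + take] = depth
        remaining -= take


# --------------------------------------------------------------------------
# full dataset to disk
# --------------------------------------------------------------------------

def simulate_all(
    config: SimulationConfig,
    outdir: str | Path,
    true_model: ContextModel | None = None,
) -> dict[str, Path]:
    """Generate and write a complete synthetic dataset.

    Writes FASTA, GTF, a DNM TSV, two bedGraph tracks and a truth JSON
    (configured model file, multiplier, peak positions).  Deterministic
    under ``config.seed``.
    """
    from . import io as eio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if true_model is None:
        true_model = default_true_model()
    genome, annotation = simulate_genome(config, rng)
    genes, _ = build_gene_models(annotation)
    dnms = simulate_dnms(genome, annotation, config, true_model, rng, genes=genes)
    h3k, nuc, truth = simulate_tracks(genome, genes, config, rng)

    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "genes.gtf",
        "dnms": outdir / "dnms.tsv",
        "model": outdir / "true_model.tsv",
        "h3k36me3": outdir / "h3k36me3.bedGraph",
        "nucleosome": outdir / "nucleosome.bedGraph",
        "truth": outdir / "truth.json",
    }
    genome.to_fasta(paths["fasta"])
    eio.write_gtf(annotation, paths["gtf"])
    eio.write_dnms(dnms, paths["dnms"])
    true_model.to_tsv(paths["model"])
    h3k.to_bedgraph(paths["h3k36me3"])
    nuc.to_bedgraph(paths["nucleosome"])
    truth_out = dict(truth)
    truth_out["exonic_multiplier"] = config.exonic_multiplier
    truth_out["seed"] = config.seed
    truth_out["config"] = _config_to_jsonable(config)
    with open(paths["truth"], "w") as fh:
        json.dump(truth_out, fh, indent=1)
    return paths


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))
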