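"""Gene models, internal-exon windows, mappability filtering, consequence calls.

Gene structures from a GTF-style annotation are collapsed into *meta-exons*
(the union of all transcripts' exon intervals, minus UTRs) and *meta-introns*
(the gaps between retained meta-exons).  The first and last meta-exon of each
gene are removed, so a gene's model holds only *internal* exons — the anchors
for the stacked, exon-centered analysis windows.

Coordinates are 0-based half-open throughout.  GTF input is converted on read
(see :mod:`exindnm.io`); BED is native.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome import GenomeSequence

# per-position window labels
INTERGENIC, INTRON, OTHER_EXON, CENTRAL_EXON = 0, 1, 2, 3
LABEL_NAMES = {
    INTERGENIC: "intergenic",
    INTRON: "intron",
    OTHER_EXON: "other_exon",
    CENTRAL_EXON: "central_exon",
}

SYNONYMOUS, NONSYNONYMOUS, NONCODING = "synonymous", "nonsynonymous", "noncoding"


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    if not intervals:
        return []
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(
    intervals: list[tuple[int, int]], remove: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set difference of merged half-open interval lists."""
    remove = merge_intervals(remove)
    out = []
    for s, e in intervals:
        cur = s
        for rs, re in remove:
            if re <= cur or rs >= e:
                continue
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


@dataclass
class GeneModel:
    """A gene reduced to internal meta-exons and the meta-introns between them.

    ``cds_intervals``/``cds_frames`` describe the coding sequence of one
    transcript (genomic order; frames are the codon phase of each interval's
    first base in transcription order).  They are populated from annotations
    that provide unambiguous frames, such as the synthetic generator's output.
    """

    gene_id: str
    chrom: str
    strand: str
    meta_exons: list[tuple[int, int]]
    meta_introns: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    cds_frames: list[int] = field(default_factory=list)
    _cds_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def span(self) -> tuple[int, int]:
        return self.meta_exons[0][0], self.meta_exons[-1][1]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.meta_exons)

    def intronic_length(self) -> int:
        return sum(e - s for s, e in self.meta_introns)

    # ---- coding-sequence machinery -------------------------------------
    def _cds(self, genome: GenomeSequence):
        """Spliced CDS string (transcription orientation) and per-interval
        cumulative offsets (transcription order)."""
        if self._cds_cache is None:
            if not self.cds_intervals:
                raise ValueError(f"gene {self.gene_id} has no CDS intervals")
            ivs = sorted(self.cds_intervals)
            if self.strand == "-":
                ivs = ivs[::-1]
            parts, offsets, cum = [], [], 0
            for s, e in ivs:
                seq = genome.fetch(self.chrom, s, e)
                if self.strand == "-":
                    seq = str(Seq(seq).reverse_complement())
                parts.append(seq)
                offsets.append(cum)
                cum += e - s
            self._cds_cache = ("".join(parts), ivs, offsets)
        return self._cds_cache

    def cds_index(self, pos: int, genome: GenomeSequence) -> int | None:
        """0-based index of a genomic position within the spliced CDS, or None."""
        _, ivs, offsets = self._cds(genome)
        for (s, e), off in zip(ivs, offsets):
            if s <= pos < e:
                return off + (pos - s if self.strand == "+" else e - 1 - pos)
        return None


@dataclass
class Window:
    """A width-L window centered on the middle position of an internal exon."""

    chrom: str
    start: int
    center: int
    width: int
    site_labels: np.ndarray  # uint8, one of the label codes, length == width
    source_gene_id: str

    @property
    def end(self) -> int:
        return self.start + self.width

    def label_mask(self, label: int) -> np.ndarray:
        return self.site_labels == label


@dataclass
class MappabilityMask:
    """Excluded (unreliable-mappability) regions, merged per chromosome."""

    regions: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        self.regions = {c: merge_intervals(iv) for c, iv in self.regions.items()}
        self._starts = {c: np.array([s for s, _ in iv]) for c, iv in self.regions.items()}
        self._ends = {c: np.array([e for _, e in iv]) for c, iv in self.regions.items()}

    @classmethod
    def from_bed(cls, path: str | Path) -> "MappabilityMask":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], comment="#")
        regions: dict[str, list[tuple[int, int]]] = {}
        for chrom, sub in df.groupby("chrom"):
            regions[str(chrom)] = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
        return cls(regions)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self.regions or not self.regions[chrom]:
            return False
        starts, ends = self._starts[chrom], self._ends[chrom]
        i = np.searchsorted(starts, end, side="left")
        return bool(i > 0 and ends[i - 1] > start) or bool(i < len(starts) and starts[i] < end)


# --------------------------------------------------------------------------
# gene model construction
# --------------------------------------------------------------------------

_UTR_FEATURES = {"UTR", "utr", "five_prime_utr", "three_prime_utr", "5UTR", "3UTR"}


def _drop_malformed(df: pd.DataFrame) -> pd.DataFrame:
    bad = df["End"] <= df["Start"]
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} malformed interval record(s) (end <= start)")
    return df[~bad]


def build_gene_models(
    annotation: pd.DataFrame,
    autosome_names: list[str] | None = None,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Build filtered per-gene meta-exon/meta-intron models.

    Filters, in order: non-autosomal genes; overlapping genes (all members of
    an overlap cluster discarded); genes without introns (single merged exon);
    genes with no internal exon after removing the first/last meta-exon.

    Parameters
    ----------
    annotation
        pyranges-style records with columns Chromosome, Feature, Start, End,
        Strand, Frame, gene_id, transcript_id (0-based half-open).
    autosome_names
        Chromosomes to keep; ``None`` keeps all.

    Returns
    -------
    (genes, report) where report counts genes removed at each filter step.
    """
    df = _drop_malformed(annotation.copy())
    report: dict[str, int] = {}

    exon_df = df[df["Feature"] == "exon"]
    gene_ids = list(dict.fromkeys(exon_df["gene_id"]))
    report["total_genes"] = len(gene_ids)

    spans = {}
    for gid, sub in exon_df.groupby("gene_id", sort=False):
        chroms = sub["Chromosome"].unique()
        if len(chroms) != 1:
            warnings.warn(f"gene {gid} spans multiple chromosomes; discarded")
            continue
        spans[gid] = (str(chroms[0]), int(sub["Start"].min()), int(sub["End"].max()),
                      str(sub["Strand"].iloc[0]))

    if autosome_names is not None:
        keep = {g for g, (c, *_rest) in spans.items() if c in autosome_names}
        report["removed_non_autosomal"] = len(spans) - len(keep)
        spans = {g: v for g, v in spans.items() if g in keep}
    else:
        report["removed_non_autosomal"] = 0

    # discard all genes in overlap clusters
    overlapping: set[str] = set()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, (chrom, s, e, _strand) in spans.items():
        by_chrom.setdefault(chrom, []).append((s, e, gid))
    for ivs in by_chrom.values():
        ivs.sort()
        for (s1, e1, g1), (s2, e2, g2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                overlapping.update((g1, g2))
    report["removed_overlapping"] = len(overlapping)
    spans = {g: v for g, v in spans.items() if g not in overlapping}

    genes: list[GeneModel] = []
    n_intronless = n_no_internal = 0
    for gid, (chrom, _s, _e, strand) in spans.items():
        sub = df[df["gene_id"] == gid]
        exons = merge_intervals(
            list(zip(sub.loc[sub["Feature"] == "exon", "Start"].astype(int),
                     sub.loc[sub["Feature"] == "exon", "End"].astype(int))))
        utrs = list(zip(sub.loc[sub["Feature"].isin(_UTR_FEATURES), "Start"].astype(int),
                        sub.loc[sub["Feature"].isin(_UTR_FEATURES), "End"].astype(int)))
        exons = subtract_intervals(exons, utrs)
        if len(exons) < 2:
            n_intronless += 1
            continue
        internal = exons[1:-1]
        if not internal:
            n_no_internal += 1
            continue
        introns = [(internal[i][1], internal[i + 1][0]) for i in range(len(internal) - 1)]
        cds_iv, frames = _pick_cds(sub, strand)
        genes.append(GeneModel(gid, chrom, strand, internal, introns, cds_iv, frames))
    report["removed_intronless"] = n_intronless
    report["removed_no_internal_exon"] = n_no_internal
    report["retained"] = len(genes)
    return genes, report


def _pick_cds(gene_records: pd.DataFrame, strand: str):
    """CDS intervals/frames of the transcript with the longest total CDS."""
    cds = gene_records[gene_records["Feature"] == "CDS"]
    if cds.empty:
        return [], []
    best, best_len = None, -1
    for tid, sub in cds.groupby("transcript_id"):
        length = int((sub["End"] - sub["Start"]).sum())
        if length > best_len:
            best, best_len = sub, length
    ivs = sorted(zip(best["Start"].astype(int), best["End"].astype(int)))
    # phase of the first base of each interval, in transcription order
    order = ivs if strand == "+" else ivs[::-1]
    phases, cum = [], 0
    for s, e in order:
        phases.append(cum % 3)
        cum += e - s
    if strand == "-":
        phases = phases[::-1]
    return ivs, phases


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------

def genome_label_arrays(
    genes: list[GeneModel], chrom_lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Dense per-chromosome site labels: internal meta-exons of retained genes
    -> OTHER_EXON, their meta-introns -> INTRON, everything else INTERGENIC."""
    labels = {c: np.zeros(n, dtype=np.uint8) for c, n in chrom_lengths.items()}
    for gene in genes:
        arr = labels[gene.chrom]
        for s, e in gene.meta_introns:
            arr[s:e] = INTRON
        for s, e in gene.meta_exons:
            arr[s:e] = OTHER_EXON
    return labels


def exon_middle(start: int, end: int) -> int:
    """Middle position of a half-open exon; floor of the midpoint for even lengths."""
    return (start + end - 1) // 2


def extract_windows(
    genes: list[GeneModel],
    chrom_lengths: dict[str, int],
    width: int = 2001,
) -> list[Window]:
    """One window per internal meta-exon, centered on the exon's middle position.

    Windows that would extend past a chromosome end are dropped (count logged
    via warning).  Per-position labels come from intersecting the window with
    all retained genes' meta-exon/meta-intron intervals; positions inside the
    anchoring exon are relabelled CENTRAL_EXON.
    """
    if width % 2 != 1:
        raise ValueError("window width must be odd")
    half = width // 2
    global_labels = genome_label_arrays(genes, chrom_lengths)
    windows: list[Window] = []
    n_dropped = 0
    for gene in genes:
        arr = global_labels[gene.chrom]
        for s, e in gene.meta_exons:
            center = exon_middle(s, e)
            w_start, w_end = center - half, center + half + 1
            if w_start < 0 or w_end > chrom_lengths[gene.chrom]:
                n_dropped += 1
                continue
            labels = arr[w_start:w_end].copy()
            lo, hi = max(s, w_start), min(e, w_end)
            labels[lo - w_start:hi - w_start] = CENTRAL_EXON
            windows.append(Window(gene.chrom, w_start, center, width, labels, gene.gene_id))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} window(s) extending past chromosome ends")
    return windows


def filter_windows_by_mappability(
    windows: list[Window], mask: MappabilityMask
) -> list[Window]:
    """Remove windows overlapping any excluded region by >= 1 bp."""
    kept = [w for w in windows if not mask.overlaps(w.chrom, w.start, w.end)]
    return kept


def windows_to_bed(windows: list[Window], path: str | Path) -> None:
    rows = []
    for w in windows:
        n_central = int((w.site_labels == CENTRAL_EXON).sum())
        rows.append((w.chrom, w.start, w.end, f"{w.source_gene_id}|center={w.center}|central_exon={n_central}"))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# consequence classification
# --------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# standard genetic code, precomputed for per-site speed ('*' = stop)
from Bio.Data.CodonTable import standard_dna_table as _std_table

_CODON_AA = dict(_std_table.forward_table)
for _stop in _std_table.stop_codons:
    _CODON_AA[_stop] = "*"


def translate_codon(codon: str) -> str:
    return _CODON_AA[codon]


def classify_consequence(
    chrom: str, pos: int, ref: str, alt: str, gene: GeneModel, genome: GenomeSequence
) -> str:
    """Synonymous / nonsynonymous / noncoding call for a SNV inside a gene.

    CDS positions are translated with the standard genetic code on the
    annotated strand; any amino-acid change (including stop gain/loss) is
    nonsynonymous.  Positions outside the CDS are noncoding.
    """
    genome_base = genome.fetch(chrom, pos, pos + 1)
    if genome_base != ref:
        raise ValueError(
            f"ref allele {ref} at {chrom}:{pos} disagrees with genome base {genome_base}")
    if chrom != gene.chrom:
        raise ValueError("mutation chromosome does not match gene")
    idx = gene.cds_index(pos, genome) if gene.cds_intervals else None
    if idx is None:
        return NONCODING
    cds_seq, _, _ = gene._cds(genome)
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"gene {gene.gene_id}: CDS length not a multiple of 3 (ambiguous frame)")
    codon_i, off = divmod(idx, 3)
    codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
    alt_cds = alt if gene.strand == "+" else _COMPLEMENT[alt]
    new_codon = codon[:off] + alt_cds + codon[off + 1:]
    if translate_codon(codon) == translate_codon(new_codon):
        return SYNONYMOUS
    return NONSYNONYMOUS


def site_alternate_classes(
    gene: GeneModel, genome: GenomeSequence, chrom: str, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """For each genomic position, classify all three alternate alleles.

    Returns ``(coding, synonymous)``: ``coding`` is an (n,) boolean marking
    positions inside the gene's CDS; ``synonymous`` is an (n, 3) boolean, True
    where the j-th alternate (alternates of the reference base in alphabetical
    order) yields an identical amino acid.  Rows of non-coding positions are
    all-False.
    """
    from .genome import BASES

    coding = np.zeros(len(positions), dtype=bool)
    syn = np.zeros((len(positions), 3), dtype=bool)
    if not gene.cds_intervals:
        return coding, syn
    cds_seq, _, _ = gene._cds(genome)
    for row, pos in enumerate(positions):
        idx = gene.cds_index(int(pos), genome)
        if idx is None:
            continue
        coding[row] = True
        codon_i, off = divmod(idx, 3)
        codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
        ref = genome.fetch(chrom, int(pos), int(pos) + 1)
        aa_ref = translate_codon(codon)
        alts = [b for b in BASES if b != ref]
        for j, alt in enumerate(alts):
            alt_cds = alt if gene.strand == "+" else _COMPLEMENT[alt]
            new_codon = codon[:off] + alt_cds + codon[off + 1:]
            syn[row, j] = translate_codon(new_codon) == aa_ref
    return coding, syn
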