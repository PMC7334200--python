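"""Chromatin-feature vs exonic-mutation-enrichment analysis.

Per gene, the exonic enrichment of a chromatin feature (H3K36me3 read
coverage, nucleosome density) is the ratio of exonic to intronic bases
covered by reads.  The gene's expected exonic mutation count is n̂_e = P_e·n
with P_e = L_e / (L_e + L_i), the L's being the summed per-site mutation
frequencies (all three alternates) over the gene's exonic and intronic
sites.  Genes are grouped into equal-count bins by their feature ratio and
the per-bin relative difference (Σn_e − Σn̂_e)/Σn̂_e · 100 is related to the
bin-median ratio by an iteratively re-weighted least-squares correlation in
which a bin's weight is the inverse of its within-bin ratio variance.

Nucleosome peak positions are local maxima of the coverage signal separated
by at least 150 bp; each peak spans 73 bp to each side of the peak
coordinate (a 147-position inclusive region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .annotation import GeneModel
from .context import ContextModel
from .genome import GenomeSequence


@dataclass
class CoverageTrack:
    """Piecewise-constant non-negative signal, held densely per chromosome."""

    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.values[chrom] = arr

    @classmethod
    def from_bedgraph(cls, path: str | Path, chrom_lengths: dict[str, int]) -> "CoverageTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
        for _, row in df.iterrows():
            chrom = str(row["chrom"])
            if chrom in values:
                values[chrom][int(row["start"]):int(row["end"])] = float(row["value"])
        return cls(values)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.values.items():
                if len(arr) == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(arr)]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


@dataclass
class GeneEnrichment:
    """Per-gene chromatin ratio and observed/expected exonic mutation counts."""

    gene_id: str
    exonic_covered: int
    intronic_covered: int
    ratio: float
    n: int
    n_e: int
    n_hat_e: float
    p_e: float


# --------------------------------------------------------------------------
# nucleosome peak calling
# --------------------------------------------------------------------------

def call_nucleosome_peaks(
    track: CoverageTrack,
    min_separation: int = 150,
    half_window: int = 73,
) -> pd.DataFrame:
    """Local-maxima peak calling with a minimum pairwise separation.

    A candidate is a strict local maximum; plateaus resolve to their
    midpoint.  Candidates are accepted greedily by height (ties: leftmost)
    subject to pairwise distance >= ``min_separation``.  Peak calls are
    invariant under translating or positively rescaling the signal.

    Returns a DataFrame (chrom, start, end, peak) where [start, end) spans
    ``half_window`` positions each side of the peak coordinate.
    """
    rows = []
    for chrom, arr in track.values.items():
        for p in _local_maxima_with_min_sep(arr, min_separation):
            rows.append((chrom, max(0, p - half_window),
                         min(len(arr), p + half_window + 1), p))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "peak"])


def _local_maxima_with_min_sep(arr: np.ndarray, min_sep: int) -> list[int]:
    n = len(arr)
    if n < 3:
        return []
    candidates: list[tuple[float, int]] = []
    i = 1
    while i < n - 1:
        if arr[i] > arr[i - 1]:
            j = i
            while j + 1 < n and arr[j + 1] == arr[i]:
                j += 1
            if j < n - 1 and arr[j + 1] < arr[i]:  # plateau (or point) is a strict max
                candidates.append((float(arr[i]), (i + j) // 2))
            i = j + 1
        else:
            i += 1
    # greedy by height, ties -> leftmost
    candidates.sort(key=lambda t: (-t[0], t[1]))
    accepted: list[int] = []
    for _, p in candidates:
        if all(abs(p - q) >= min_sep for q in accepted):
            accepted.append(p)
    return sorted(accepted)


def peaks_to_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# gene-level enrichment
# --------------------------------------------------------------------------

def gene_feature_enrichment(gene: GeneModel, track: CoverageTrack) -> float | None:
    """Exon-to-intron ratio of bases covered by reads; None if either
    compartment has zero covered bases (gene excluded, never NaN)."""
    arr = track.values[gene.chrom]
    exonic = sum(int((arr[s:e] > 0).sum()) for s, e in gene.meta_exons)
    intronic = sum(int((arr[s:e] > 0).sum()) for s, e in gene.meta_introns)
    if exonic == 0 or intronic == 0:
        return None
    return exonic / intronic


def expected_exonic_mutations(
    gene: GeneModel,
    genome: GenomeSequence,
    model: ContextModel,
    n_observed: int,
    rate_track: np.ndarray | None = None,
) -> tuple[float, float]:
    """(n̂_e, P_e) for a gene: P_e = L_e / (L_e + L_i) from summed per-site
    mutation frequencies; n̂_e = P_e · n_observed."""
    if rate_track is None:
        states = model.state_track(genome.codes(gene.chrom))
        rate_track = model.site_rates(states)
    l_e = sum(float(rate_track[s:e].sum()) for s, e in gene.meta_exons)
    l_i = sum(float(rate_track[s:e].sum()) for s, e in gene.meta_introns)
    if l_e + l_i == 0:
        raise ValueError(f"gene {gene.gene_id}: zero total mutation frequency")
    p_e = l_e / (l_e + l_i)
    return p_e * n_observed, p_e


def gene_enrichment_table(
    genes: list[GeneModel],
    track: CoverageTrack,
    mutations: pd.DataFrame,
    genome: GenomeSequence,
    model: ContextModel,
) -> pd.DataFrame:
    """Per-gene table for the binned analysis.

    Excludes genes with zero covered bases in either compartment and genes
    without any observed exonic or intronic mutation.
    """
    rate_tracks = {}
    by_chrom = {str(c): sub["pos"].to_numpy(dtype=np.int64)
                for c, sub in mutations.groupby("chrom", sort=False)}
    rows = []
    for gene in genes:
        ratio = gene_feature_enrichment(gene, track)
        if ratio is None:
            continue
        pos = by_chrom.get(gene.chrom, np.empty(0, dtype=np.int64))
        n_e = sum(int(((pos >= s) & (pos < e)).sum()) for s, e in gene.meta_exons)
        n_i = sum(int(((pos >= s) & (pos < e)).sum()) for s, e in gene.meta_introns)
        n = n_e + n_i
        if n == 0:
            continue
        if gene.chrom not in rate_tracks:
            states = model.state_track(genome.codes(gene.chrom))
            rate_tracks[gene.chrom] = model.site_rates(states)
        n_hat_e, p_e = expected_exonic_mutations(
            gene, genome, model, n, rate_tracks[gene.chrom])
        rows.append((gene.gene_id, ratio, n, n_e, n_hat_e, p_e))
    return pd.DataFrame(rows, columns=["gene_id", "ratio", "n", "n_e", "n_hat_e", "p_e"])


def binned_difference(gene_table: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """Equal-count bins of genes by chromatin ratio; per-bin exonic mutation
    difference in percent from the bin totals, with the bin-median ratio as
    x-value and the within-bin ratio variance for downstream weighting."""
    if len(gene_table) < n_bins:
        raise ValueError(f"fewer genes ({len(gene_table)}) than bins ({n_bins})")
    df = gene_table.sort_values("ratio").reset_index(drop=True)
    df["bin"] = pd.qcut(df.index, n_bins, labels=False)
    rows = []
    for b, sub in df.groupby("bin"):
        sum_e, sum_hat = sub["n_e"].sum(), sub["n_hat_e"].sum()
        rows.append({
            "bin": int(b),
            "median_ratio": float(sub["ratio"].median()),
            "ratio_var": float(sub["ratio"].var(ddof=1)) if len(sub) > 1 else 0.0,
            "n_genes": len(sub),
            "sum_n_e": float(sum_e),
            "sum_n_hat_e": float(sum_hat),
            "difference_pct": 100.0 * (sum_e - sum_hat) / sum_hat if sum_hat > 0 else np.nan,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# robust correlation
# --------------------------------------------------------------------------

def irls_correlation(
    x: np.ndarray,
    y: np.ndarray,
    x_variances: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Weighted linear correlation between bin ratios and bin differences.

    Weights are proportional to the inverse within-bin variance of the
    chromatin ratio (points from noisier bins count less); the weighted
    least-squares fit is iterated until the coefficients change by less than
    ``tol`` in relative terms.  Returns (r, p): r is the sign-consistent
    square root of the weighted R², p the two-sided p-value of the slope's
    t-statistic.  With equal weights this reduces exactly to OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 bins")
    if np.ptp(x) == 0:
        raise ValueError("bin ratios are constant; correlation undefined")
    if x_variances is None:
        weights = np.ones_like(x)
    else:
        v = np.asarray(x_variances, dtype=float)
        if (v <= 0).all():
            warnings.warn("all bin variances are zero; falling back to equal weights")
            weights = np.ones_like(x)
        else:
            pos = v[v > 0]
            v = np.where(v > 0, v, pos.min())
            weights = 1.0 / v
    weights = weights / weights.mean()

    X = sm.add_constant(x, has_constant="add")
    params = None
    for _ in range(max_iter):
        fit = sm.WLS(y, X, weights=weights).fit()
        if params is not None:
            denom = np.maximum(np.abs(params), 1e-300)
            if np.max(np.abs(fit.params - params) / denom) < tol:
                params = fit.params
                break
        params = fit.params
    slope = fit.params[1]
    r = float(np.sign(slope) * np.sqrt(max(fit.rsquared, 0.0)))
    p = float(fit.pvalues[1])
    return r, p


def coverage_compartment_report(
    genes: list[GeneModel], track: CoverageTrack
) -> dict[str, float]:
    """Thin optional report: two-sided rank-sum comparison of per-gene exonic
    vs intronic covered fractions."""
    ex_frac, in_frac = [], []
    for gene in genes:
        arr = track.values[gene.chrom]
        le, li = gene.exonic_length(), gene.intronic_length()
        if le == 0 or li == 0:
            continue
        ex_frac.append(sum(int((arr[s:e] > 0).sum()) for s, e in gene.meta_exons) / le)
        in_frac.append(sum(int((arr[s:e] > 0).sum()) for s, e in gene.meta_introns) / li)
    stat, p = sps.mannwhitneyu(ex_frac, in_frac, alternative="two-sided")
    return {"n_genes": len(ex_frac), "exonic_mean": float(np.mean(ex_frac)),
            "intronic_mean": float(np.mean(in_frac)), "u_stat": float(stat),
            "p_value": float(p)}
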