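"""Exon-centered observed/expected mutation profiles and the exonic-excess test.

Each internal-exon-centered window s carries n_s observed mutations.  Under a
context model, site l of the window has mutation frequency

    f_l = sum_a P(a | ref_l, context_l),

rescaled to sum to one across the window; the window's expected profile is
n_s * f^resc, so the expected total equals the observed total by
construction.  The excess of mutations at central-exon sites relative to the
model is assessed by redistributing each window's n_s mutations over its
sites according to f^resc (1000 permutations by default): the effect size is
the percent deviation of the observed central-exon count from the
permutation mean, and the empirical one-sided p-value is the fraction of
permutations at least as extreme, floored at 1/n_permutations.

Redistribution is multinomial per window; since the test statistic is the
count landing in the central-exon site set, its marginal is Binomial(n_s,
p_s) with p_s the rescaled frequency mass on those sites, which is what is
drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import (CENTRAL_EXON, NONSYNONYMOUS, OTHER_EXON, SYNONYMOUS,
                         GeneModel, Window, site_alternate_classes)
from .context import ContextModel
from .genome import GenomeSequence


@dataclass
class StackedProfile:
    """Per-position observed and expected counts over S stacked windows."""

    L: int
    S: int
    observed: np.ndarray
    expected: np.ndarray
    exon_density: np.ndarray
    n_windows_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        half = self.L // 2
        return pd.DataFrame({
            "offset": np.arange(-half, half + 1),
            "observed": self.observed,
            "expected": self.expected,
            "exon_density": self.exon_density,
        })


@dataclass
class PermutationResult:
    """Exonic-excess effect size with permutation-based error and p-value.

    ``p_value`` is one-sided on the side of the observed deviation (floored
    at 1/n_permutations); ``p_upper`` is the fixed upper-tail probability
    P(permuted >= observed), the quantity that is uniform under the null.
    """

    observed_exonic: float
    expected_exonic: float
    excess_pct: float
    sd_pct: float
    p_value: float
    p_upper: float
    n_permutations: int
    seed: int


# --------------------------------------------------------------------------
# frequencies
# --------------------------------------------------------------------------

def _rate_tracks(genome: GenomeSequence, model: ContextModel,
                 chroms: set[str]) -> dict[str, np.ndarray]:
    tracks = {}
    for chrom in chroms:
        states = model.state_track(genome.codes(chrom))
        tracks[chrom] = model.site_rates(states)
    return tracks


def site_frequencies(window: Window, genome: GenomeSequence,
                     model: ContextModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-position frequencies f_l and their window-rescaled form.

    Raises on an all-zero window (no readable context anywhere): such windows
    must be excluded upstream.
    """
    states = model.state_track(genome.codes(window.chrom))[window.start:window.end]
    f = model.site_rates(states)
    total = f.sum()
    if total == 0:
        raise ValueError("window has zero total mutation frequency")
    return f, f / total


def window_frequencies(windows: list[Window], genome: GenomeSequence,
                       model: ContextModel) -> list[np.ndarray]:
    """Unnormalised f_l vectors for many windows (rate track computed once
    per chromosome)."""
    tracks = _rate_tracks(genome, model, {w.chrom for w in windows})
    return [tracks[w.chrom][w.start:w.end] for w in windows]


def stratified_window_frequencies(
    windows: list[Window],
    genes: dict[str, GeneModel],
    genome: GenomeSequence,
    model: ContextModel,
    consequence: str,
) -> list[np.ndarray]:
    """f_l vectors where central-exon coding sites sum only the alternates
    producing the chosen consequence class; all other sites keep the full f_l.

    At a coding site the synonymous- and nonsynonymous-restricted frequencies
    partition the full frequency.
    """
    if consequence not in (SYNONYMOUS, NONSYNONYMOUS):
        raise ValueError(f"consequence must be synonymous or nonsynonymous, got {consequence}")
    freqs = window_frequencies(windows, genome, model)
    state_cache: dict[str, np.ndarray] = {}
    for i, (w, f) in enumerate(zip(windows, freqs)):
        if w.chrom not in state_cache:
            state_cache[w.chrom] = model.state_track(genome.codes(w.chrom))
        central = w.label_mask(CENTRAL_EXON)
        pos = np.arange(w.start, w.end)[central]
        gene = genes[w.source_gene_id]
        coding, syn = site_alternate_classes(gene, genome, w.chrom, pos)
        alt_probs = model.site_alt_probs(state_cache[w.chrom][pos])
        mask = syn if consequence == SYNONYMOUS else (coding[:, None] & ~syn)
        f = f.copy()
        f[central] = (alt_probs * mask).sum(axis=1)
        # central non-coding sites contribute nothing to either class
        f[np.flatnonzero(central)[~coding]] = 0.0
        freqs[i] = f
    return freqs


def _mutations_by_chrom(mutations: pd.DataFrame) -> dict[str, np.ndarray]:
    return {str(c): sub["pos"].to_numpy(dtype=np.int64)
            for c, sub in mutations.groupby("chrom", sort=False)}


def window_observed_counts(
    windows: list[Window], mutations: pd.DataFrame,
    restrict_central_to: pd.DataFrame | None = None,
) -> list[np.ndarray]:
    """Per-window per-position observed mutation counts.

    A mutation lying in several (overlapping) windows is counted in each.
    If ``restrict_central_to`` is given, mutations at central-exon sites are
    counted only if they also appear in that subset (used for
    consequence-stratified profiles); flank mutations are always counted.
    """
    by_chrom = _mutations_by_chrom(mutations)
    central_by_chrom = (None if restrict_central_to is None
                        else _mutations_by_chrom(restrict_central_to))
    out = []
    for w in windows:
        pos = by_chrom.get(w.chrom, np.empty(0, dtype=np.int64))
        inside = pos[(pos >= w.start) & (pos < w.end)]
        counts = np.bincount(inside - w.start, minlength=w.width).astype(float)
        if central_by_chrom is not None:
            central = w.label_mask(CENTRAL_EXON)
            cpos = central_by_chrom.get(w.chrom, np.empty(0, dtype=np.int64))
            cin = cpos[(cpos >= w.start) & (cpos < w.end)]
            ccounts = np.bincount(cin - w.start, minlength=w.width).astype(float)
            counts[central] = ccounts[central]
        out.append(counts)
    return out


# --------------------------------------------------------------------------
# profile stacking
# --------------------------------------------------------------------------

def build_profile(
    windows: list[Window],
    freqs: list[np.ndarray],
    observed_counts: list[np.ndarray],
) -> StackedProfile:
    """Stack observed and expected per-position counts over windows.

    Windows whose frequency vector is all zero are excluded (counted in
    ``n_windows_excluded``); windows with no observed mutation contribute
    zero to both profiles.
    """
    if not windows:
        raise ValueError("no windows")
    L = windows[0].width
    observed = np.zeros(L)
    expected = np.zeros(L)
    exon = np.zeros(L)
    n_excluded = 0
    n_used = 0
    for w, f, obs in zip(windows, freqs, observed_counts):
        total_f = f.sum()
        if total_f == 0:
            n_excluded += 1
            continue
        n_used += 1
        exon += (w.site_labels == CENTRAL_EXON) | (w.site_labels == OTHER_EXON)
        n_s = obs.sum()
        observed += obs
        if n_s > 0:
            expected += f * (n_s / total_f)
    return StackedProfile(L, n_used, observed, expected, exon / max(n_used, 1), n_excluded)


def bin_profile(values: np.ndarray, bin_size: int = 25) -> np.ndarray:
    """Non-overlapping bin means from the window start; the final partial bin
    is averaged over its actual length."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = len(values)
    edges = np.arange(0, n + bin_size, bin_size)
    edges[-1] = min(edges[-1], n)
    if edges[-1] == edges[-2]:
        edges = edges[:-1]
    return np.array([values[s:e].mean() for s, e in zip(edges, edges[1:])])


# --------------------------------------------------------------------------
# permutation test
# --------------------------------------------------------------------------

def exonic_excess_test(
    windows: list[Window],
    freqs: list[np.ndarray],
    observed_counts: list[np.ndarray],
    n_permutations: int = 1000,
    seed: int = 0,
    exonic_label: int = CENTRAL_EXON,
) -> PermutationResult:
    """Permutation test of the central-exon mutation excess.

    Each permutation redraws every window's observed total multinomially over
    its sites with probabilities f^resc; the statistic is the summed count at
    central-exon sites (drawn via its exact binomial marginal).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n_s, p_s, obs_e = [], [], 0.0
    for w, f, obs in zip(windows, freqs, observed_counts):
        total_f = f.sum()
        if total_f == 0:
            continue
        mask = w.label_mask(exonic_label)
        n_s.append(obs.sum())
        p_s.append(f[mask].sum() / total_f)
        obs_e += obs[mask].sum()
    n_s = np.asarray(n_s, dtype=np.int64)
    p_s = np.asarray(p_s)

    rng = np.random.default_rng(seed)
    perm = rng.binomial(n_s[None, :], p_s[None, :],
                        size=(n_permutations, len(n_s))).sum(axis=1)
    mean_e = perm.mean()
    if mean_e == 0:
        raise ValueError("permutation mean exonic count is zero")
    excess = 100.0 * (obs_e - mean_e) / mean_e
    sd = 100.0 * perm.std(ddof=0) / mean_e
    p_upper = (perm >= obs_e).mean()
    if excess > 0:
        p = p_upper
    else:
        p = (perm <= obs_e).mean()
    p = max(p, 1.0 / n_permutations)
    return PermutationResult(float(obs_e), float(mean_e), float(excess), float(sd),
                             float(p), float(max(p_upper, 1.0 / n_permutations)),
                             n_permutations, seed)


def stratify_by_consequence(
    mutations: pd.DataFrame,
    windows: list[Window],
    genes: dict[str, GeneModel],
    genome: GenomeSequence,
    model: ContextModel,
    consequence: str,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Inputs for a consequence-stratified excess test / profile.

    Returns (stratified frequency vectors, observed count vectors) where
    observed central-exon mutations are restricted to the chosen class (their
    ``consequence`` column must be filled; an unlabeled exonic mutation
    raises) and central-exon expected frequencies sum only the alternates of
    that class.
    """
    if "consequence" not in mutations.columns:
        raise ValueError("mutations need a 'consequence' column for stratification")
    central = _central_site_lookup(windows)
    exonic = np.array(
        [(str(c), int(p)) in central
         for c, p in zip(mutations["chrom"], mutations["pos"])], dtype=bool)
    if exonic.any() and mutations.loc[exonic, "consequence"].isna().any():
        raise ValueError("unlabeled exonic mutation")
    restrict = mutations[exonic & (mutations["consequence"] == consequence).to_numpy()]
    freqs = stratified_window_frequencies(windows, genes, genome, model, consequence)
    observed = window_observed_counts(windows, mutations, restrict_central_to=restrict)
    return freqs, observed


def _central_site_lookup(windows: list[Window]) -> set[tuple[str, int]]:
    sites: set[tuple[str, int]] = set()
    for w in windows:
        for off in np.flatnonzero(w.label_mask(CENTRAL_EXON)):
            sites.add((w.chrom, w.start + int(off)))
    return sites
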