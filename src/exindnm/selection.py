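"""Context-model comparison by full-site log-likelihood and AIC.

Every site of every stacked window is interrogated for its observed state —
mutated (to a specific alternate) or not mutated.  For a model M the
log-likelihood is the sum over sites of log P_M(observed state): a mutated
site contributes log P(alt | context), an unmutated one
log(1 - sum_a P(a | context)).  Models are ranked by
AIC = 2 * n_parameters - 2 * log-likelihood.

The site set is held identical across compared schemes: sites whose context
is unreadable under the largest scheme are excluded from all of them, so the
likelihoods are comparable.  At a site carrying more than one reported
mutation, one is chosen at random (seeded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Window
from .context import (ContextModel, ContextScheme, alt_index, estimate,
                      parameter_count, state_ref_base)
from .genome import GenomeSequence, encode
from .profile import exonic_excess_test, window_frequencies, window_observed_counts


@dataclass
class SiteStateData:
    """Observed state of every window site (stacked; repeats kept).

    ``chrom_index``/``pos`` address each site; ``alt`` is -1 for unmutated
    sites, otherwise the alternate-base code; ``valid`` marks sites with
    readable context at the largest compared scheme.
    """

    chroms: list[str]
    chrom_index: np.ndarray
    pos: np.ndarray
    alt: np.ndarray
    valid: np.ndarray
    seed: int

    @property
    def total_sites(self) -> int:
        return int(self.valid.sum())


def build_site_data(
    windows: list[Window],
    mutations: pd.DataFrame,
    genome: GenomeSequence,
    max_k: int,
    seed: int = 0,
) -> SiteStateData:
    """Collect per-site observed states over all windows.

    Recurrent sites (several mutations at one genomic position) are resolved
    to one mutation chosen at random with the given seed; the choice applies
    to every stacked copy of the site.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted({w.chrom for w in windows})
    cindex = {c: i for i, c in enumerate(chroms)}

    # one mutation per site
    site_alt: dict[tuple[str, int], int] = {}
    for (chrom, pos), sub in mutations.groupby(["chrom", "pos"]):
        alts = list(sub["alt"])
        pick = alts[rng.integers(len(alts))] if len(alts) > 1 else alts[0]
        site_alt[(str(chrom), int(pos))] = int(encode(pick)[0])

    n = sum(w.width for w in windows)
    chrom_index = np.empty(n, dtype=np.int32)
    pos = np.empty(n, dtype=np.int64)
    alt = np.full(n, -1, dtype=np.int8)
    valid = np.empty(n, dtype=bool)

    from .context import kmer_state_track
    ktracks = {c: kmer_state_track(genome.codes(c), max_k) for c in chroms}

    i = 0
    for w in windows:
        width = w.width
        sl = slice(i, i + width)
        chrom_index[sl] = cindex[w.chrom]
        p = np.arange(w.start, w.end)
        pos[sl] = p
        valid[sl] = ktracks[w.chrom][p] >= 0
        i += width
    # mutated states: locate every stacked copy of each mutated site
    if site_alt:
        lookup: dict[str, dict[int, int]] = {}
        for (c, p), a in site_alt.items():
            lookup.setdefault(c, {})[p] = a
        for c, sub in lookup.items():
            if c not in cindex:
                continue
            idx_c = np.flatnonzero(chrom_index == cindex[c])
            order = np.argsort(pos[idx_c], kind="stable")
            sorted_pos = pos[idx_c][order]
            for p, a in sub.items():
                lo = np.searchsorted(sorted_pos, p, side="left")
                hi = np.searchsorted(sorted_pos, p, side="right")
                if hi > lo:
                    alt[idx_c[order[lo:hi]]] = a
    return SiteStateData(chroms, chrom_index, pos, alt, valid, seed)


def site_loglikelihood(
    data: SiteStateData,
    model: ContextModel,
    genome: GenomeSequence,
    probability_floor: float | None = None,
) -> tuple[float, int]:
    """Log-likelihood of the observed site states under a model.

    Returns ``(loglik, n_zero_prob)`` where the second element counts mutated
    sites whose modeled probability is zero (each contributes -inf unless a
    ``probability_floor`` is supplied).  Raises if any context's alternate
    probabilities sum above one.
    """
    model.validate()
    refs = state_ref_base(model.scheme)
    probs = model.probs
    not_rate = np.log1p(-np.clip(probs.sum(axis=1), 0, 1))  # log(1 - f) per state

    loglik = 0.0
    n_zero = 0
    for ci, chrom in enumerate(data.chroms):
        mask = (data.chrom_index == ci) & data.valid
        if not mask.any():
            continue
        track = model.state_track(genome.codes(chrom))
        states = track[data.pos[mask]]
        alts = data.alt[mask]
        if (states < 0).any():
            # unreadable under this (smaller) scheme despite the common mask:
            # cannot happen for nested k-mer schemes, guard anyway
            raise ValueError("site with unreadable context in common site set")
        unmut = alts < 0
        loglik += not_rate[states[unmut]].sum()
        mstates = states[~unmut]
        malts = alts[~unmut].astype(np.int64)
        j = alt_index(refs[mstates], malts)
        p = probs[mstates, j]
        zero = p == 0
        n_zero += int(zero.sum())
        if probability_floor is not None:
            p = np.maximum(p, probability_floor)
            loglik += np.log(p).sum()
        else:
            loglik += np.log(p[~zero]).sum()
            if zero.any():
                loglik = -np.inf
    return float(loglik), n_zero


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, 2 * n_params - 2 * loglik."""
    return 2.0 * n_params - 2.0 * loglik


def compare_models(
    windows: list[Window],
    mutations: pd.DataFrame,
    genome: GenomeSequence,
    schemes: list[ContextScheme],
    n_permutations: int = 1000,
    seed: int = 0,
    probability_floor: float | None = None,
) -> pd.DataFrame:
    """Rank context schemes on the same windows, mutations and site set.

    For each scheme: the exonic excess (permutation test), the full-site
    log-likelihood, the parameter count and the AIC.  The minimum-AIC scheme
    is flagged.  A mutated site with zero modeled probability fails loudly
    unless ``probability_floor`` is set.
    """
    # effective context width: the CpG model reads one neighbor, i.e. width 3
    max_k = max(3 if s.mode == "cpg" else s.k for s in schemes)
    data = build_site_data(windows, mutations, genome, max_k, seed=seed)
    rows = []
    for scheme in schemes:
        model = estimate(mutations, genome, scheme)
        loglik, n_zero = site_loglikelihood(data, model, genome, probability_floor)
        if not np.isfinite(loglik):
            raise ValueError(
                f"scheme {scheme.label}: {n_zero} mutated site(s) with zero modeled "
                "probability; set probability_floor to proceed")
        freqs = window_frequencies(windows, genome, model)
        observed = window_observed_counts(windows, mutations)
        res = exonic_excess_test(windows, freqs, observed,
                                 n_permutations=n_permutations, seed=seed)
        n_par = parameter_count(scheme)
        rows.append({
            "model": scheme.label,
            "excess_pct": res.excess_pct,
            "sd_pct": res.sd_pct,
            "p_value": res.p_value,
            "loglik": loglik,
            "n_param": n_par,
            "aic": aic(loglik, n_par),
            "n_zero_prob_sites": n_zero,
        })
    table = pd.DataFrame(rows)
    table["best"] = table["aic"] == table["aic"].min()
    return table
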