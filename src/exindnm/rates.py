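"""Absolute per-site, per-generation mutation rate estimation.

μ = N_obs / (N_site · N_gen), with N_gen the number of gametogeneses (two
per trio).  Exonic rates use central-exon window sites; the intronic proxy
is every remaining site of the stacked windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CENTRAL_EXON, Window


@dataclass
class RateInput:
    """Counts entering the rate quotient; all non-negative, denominators > 0."""

    n_obs: int
    n_site: int
    n_gen: int

    def __post_init__(self) -> None:
        if self.n_obs < 0 or self.n_site < 0 or self.n_gen < 0:
            raise ValueError("negative count")
        if self.n_site == 0 or self.n_gen == 0:
            raise ValueError("N_site and N_gen must be positive")


def mutation_rate(inp: RateInput) -> float:
    """Per-site per-generation mutation rate μ = N_obs / (N_site · N_gen)."""
    return inp.n_obs / (inp.n_site * inp.n_gen)


def rates_from_windows(
    windows: list[Window],
    mutations: pd.DataFrame,
    n_gen: int,
) -> pd.DataFrame:
    """Exonic and intronic rate estimates from stacked windows.

    Exonic sites are the central-exon labelled positions of all windows
    (stacked, i.e. counted per window); intronic sites are the rest of each
    window.  Observed mutations are attributed the same way.
    """
    by_chrom = {str(c): sub["pos"].to_numpy(dtype=np.int64)
                for c, sub in mutations.groupby("chrom", sort=False)}
    n_site = {"exonic": 0, "intronic": 0}
    n_obs = {"exonic": 0, "intronic": 0}
    for w in windows:
        central = w.label_mask(CENTRAL_EXON)
        n_site["exonic"] += int(central.sum())
        n_site["intronic"] += int(w.width - central.sum())
        pos = by_chrom.get(w.chrom, np.empty(0, dtype=np.int64))
        inside = pos[(pos >= w.start) & (pos < w.end)]
        if len(inside):
            is_central = central[inside - w.start]
            n_obs["exonic"] += int(is_central.sum())
            n_obs["intronic"] += int((~is_central).sum())
    rows = []
    for comp in ("exonic", "intronic"):
        inp = RateInput(n_obs[comp], n_site[comp], n_gen)
        rows.append((comp, inp.n_obs, inp.n_site, inp.n_gen, mutation_rate(inp)))
    return pd.DataFrame(rows, columns=["compartment", "n_obs", "n_site", "n_gen", "mu"])
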