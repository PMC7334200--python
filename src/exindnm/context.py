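"""k-mer sequence-context mutation models.

The central object is a table of per-site, per-alternate mutation
probabilities conditioned on the reference base and its flanking sequence:

    P(alt | ref, context) = N(alt, ref, context) / G(ref, context)

where N counts genome-wide observed de novo mutations with that k-mer
context and G is the genomic abundance of the reference k-mer.  For large k
the table is estimated by a composite-likelihood decomposition: a core h-mer
probability times independent per-flank-position correction factors

    P(a | r, X) ~= P(a | r) * prod_i  P_i(a | r, x_i) / P(a | r)

with the marginals P_i obtained by summing counts over all flanking
sequences that agree at position i.

Conventions: k-mers are counted on the forward strand only and mutations are
used as reported (no strand collapsing) — strand folding appears only in the
9-class spectrum display.  Contexts containing N, and zero-abundance or
zero-count contexts, get probability 0; no pseudocounts are applied.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BASES, GenomeSequence, decode, encode

# CpG-aware mono model states (forward strand; CpG = C followed by G / G preceded by C)
CPG_STATE_NAMES = ["A", "C", "C_CpG", "G", "G_CpG", "T"]
_CPG_REF_BASE = np.array([0, 1, 1, 2, 2, 3])


@dataclass(frozen=True)
class ContextScheme:
    """Context scheme: total length k, core length h, estimation mode.

    mode 'direct' requires h == k; 'decomposed' h < k; 'mono' is k == 1;
    'cpg' is the mononucleotide model with C/G split by CpG status.
    """

    k: int = 3
    h: int | None = None
    mode: str = "direct"

    def __post_init__(self) -> None:
        h = self.k if self.h is None else self.h
        object.__setattr__(self, "h", h)
        if self.mode not in {"direct", "decomposed", "mono", "cpg"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k % 2 != 1 or h % 2 != 1:
            raise ValueError("k and h must be odd")
        if not 1 <= h <= self.k:
            raise ValueError("need 1 <= h <= k")
        if self.mode == "direct" and h != self.k:
            raise ValueError("direct mode requires h == k")
        if self.mode == "decomposed" and h > self.k:
            raise ValueError("decomposed mode requires h <= k")
        if self.mode in {"mono", "cpg"} and self.k != 1:
            raise ValueError(f"{self.mode} mode requires k == 1")

    @property
    def g(self) -> int:
        return self.k - self.h

    @property
    def n_states(self) -> int:
        return 6 if self.mode == "cpg" else 4 ** self.k

    @property
    def label(self) -> str:
        if self.mode == "mono":
            return "1-mer"
        if self.mode == "cpg":
            return "CpG"
        if self.mode == "decomposed" and self.g > 0:
            return f"{self.k}-mer(h={self.h})"
        return f"{self.k}-mer"

    @classmethod
    def parse(cls, text: str) -> "ContextScheme":
        """Parse 'mono', 'cpg', '3', or '7:3' (k:h decomposed)."""
        text = text.strip().lower()
        if text in {"mono", "1", "1-mer"}:
            return cls(1, 1, "mono")
        if text == "cpg":
            return cls(1, 1, "cpg")
        if ":" in text:
            k, h = (int(t) for t in text.split(":"))
            return cls(k, h, "decomposed")
        return cls(int(text), None, "direct")


def parameter_count(scheme: ContextScheme) -> int:
    """Number of free parameters: f(k) = 4^k * 3 for the direct approach,
    g(k, h) = f(h) * (1 + 3 (k - h)) for the decomposition, 12 for the
    mononucleotide model and 18 for its CpG-split variant."""
    if scheme.mode == "mono":
        return 12
    if scheme.mode == "cpg":
        return 18
    if scheme.mode == "direct" or scheme.g == 0:
        return 4 ** scheme.k * 3
    return 4 ** scheme.h * 3 * (1 + 3 * scheme.g)


# --------------------------------------------------------------------------
# per-position context-state tracks
# --------------------------------------------------------------------------

def kmer_state_track(codes: np.ndarray, k: int) -> np.ndarray:
    """State code (base-4 big-endian k-mer) at each position of a chromosome;
    -1 where the centered k-mer runs off the sequence or contains N."""
    if k % 2 != 1:
        raise ValueError("k must be odd")
    n = len(codes)
    half = k // 2
    track = np.full(n, -1, dtype=np.int64)
    if n < k:
        return track
    c = codes.astype(np.int64)
    m = n - k + 1
    st = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        seg = c[j:j + m]
        bad |= seg == 4
        st = st * 4 + np.where(seg == 4, 0, seg)
    track[half:half + m] = np.where(bad, -1, st)
    return track


def cpg_state_track(codes: np.ndarray) -> np.ndarray:
    """Six-state track (A, C, C_CpG, G, G_CpG, T); -1 where the base is N or
    where CpG status is unreadable (chromosome edge / N neighbor)."""
    n = len(codes)
    track = np.full(n, -1, dtype=np.int64)
    track[codes == 0] = 0
    track[codes == 3] = 5
    is_c = codes == 1
    is_g = codes == 2
    next_g = np.zeros(n, dtype=bool)
    next_g[:-1] = codes[1:] == 2
    next_ok = np.zeros(n, dtype=bool)
    next_ok[:-1] = codes[1:] != 4
    prev_c = np.zeros(n, dtype=bool)
    prev_c[1:] = codes[:-1] == 1
    prev_ok = np.zeros(n, dtype=bool)
    prev_ok[1:] = codes[:-1] != 4
    track[is_c & next_ok & ~next_g] = 1
    track[is_c & next_ok & next_g] = 2
    track[is_g & prev_ok & ~prev_c] = 3
    track[is_g & prev_ok & prev_c] = 4
    return track


def state_track_for_scheme(codes: np.ndarray, scheme: ContextScheme) -> np.ndarray:
    if scheme.mode == "cpg":
        return cpg_state_track(codes)
    return kmer_state_track(codes, scheme.k)


def state_ref_base(scheme: ContextScheme) -> np.ndarray:
    """Reference (center) base code for every state of a scheme."""
    if scheme.mode == "cpg":
        return _CPG_REF_BASE.copy()
    states = np.arange(4 ** scheme.k, dtype=np.int64)
    return (states // 4 ** (scheme.k // 2)) % 4


def alt_index(ref_code: np.ndarray, alt_code: np.ndarray) -> np.ndarray:
    """Rank of the alternate among the reference base's three alternates
    (alphabetical order)."""
    return alt_code - (alt_code > ref_code)


def alt_base_codes(ref_code: int) -> list[int]:
    return [b for b in range(4) if b != ref_code]


# --------------------------------------------------------------------------
# the model container
# --------------------------------------------------------------------------

@dataclass
class ContextModel:
    """Mutation probability table for a context scheme.

    ``probs``, ``counts`` have shape (n_states, 3); ``abundance`` (n_states,).
    Alternate index j refers to the j-th non-reference base in alphabetical
    order.  Invariants: probs >= 0 and each row sums to <= 1.
    """

    scheme: ContextScheme
    probs: np.ndarray
    counts: np.ndarray | None = None
    abundance: np.ndarray | None = None
    n_skipped_mutations: int = 0
    _probs_ext: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.scheme.n_states, 3):
            raise ValueError(
                f"probs must have shape ({self.scheme.n_states}, 3), got {self.probs.shape}")
        if (self.probs < 0).any():
            raise ValueError("negative probabilities")

    def validate(self) -> None:
        if (self.probs.sum(axis=1) > 1 + 1e-12).any():
            raise ValueError("some context's alternate probabilities sum to > 1")

    def _ext(self) -> np.ndarray:
        # row n_states is an all-zero sentinel so state -1 indexes to 0 rates
        if self._probs_ext is None:
            self._probs_ext = np.vstack([self.probs, np.zeros((1, 3))])
        return self._probs_ext

    def site_rates(self, states: np.ndarray) -> np.ndarray:
        """Total mutation frequency f_l = sum_a P(a | state) per site; 0 for
        invalid (-1) states."""
        return self._ext()[states].sum(axis=1)

    def site_alt_probs(self, states: np.ndarray) -> np.ndarray:
        """(n, 3) per-alternate probabilities; zero rows for invalid states."""
        return self._ext()[states]

    def state_track(self, codes: np.ndarray) -> np.ndarray:
        return state_track_for_scheme(codes, self.scheme)

    # ---- TSV round trip -------------------------------------------------
    def state_names(self) -> list[str]:
        if self.scheme.mode == "cpg":
            return list(CPG_STATE_NAMES)
        k = self.scheme.k
        return [decode(np.array([(s // 4 ** (k - 1 - j)) % 4 for j in range(k)], dtype=np.uint8))
                for s in range(4 ** k)]

    def to_frame(self) -> pd.DataFrame:
        names = self.state_names()
        refs = state_ref_base(self.scheme)
        rows = []
        for s in range(self.scheme.n_states):
            for j, ac in enumerate(alt_base_codes(int(refs[s]))):
                rows.append((
                    names[s], BASES[ac],
                    0.0 if self.counts is None else float(self.counts[s, j]),
                    0 if self.abundance is None else int(self.abundance[s]),
                    float(self.probs[s, j]),
                ))
        return pd.DataFrame(rows, columns=["context", "alt", "count", "abundance", "probability"])

    def to_tsv(self, path: str | Path) -> None:
        sch = self.scheme
        with open(path, "w") as fh:
            fh.write(f"# scheme=k:{sch.k};h:{sch.h};mode:{sch.mode}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContextModel":
        with open(path) as fh:
            header = fh.readline().strip()
            body = fh.read()
        fields = dict(part.split(":") for part in header.lstrip("# ").split("=")[1].split(";"))
        scheme = ContextScheme(int(fields["k"]), int(fields["h"]), fields["mode"])
        df = pd.read_csv(_io.StringIO(body), sep="\t")
        probs = np.zeros((scheme.n_states, 3))
        counts = np.zeros((scheme.n_states, 3))
        abundance = np.zeros(scheme.n_states, dtype=np.int64)
        names = {n: i for i, n in enumerate(cls(scheme, probs).state_names())}
        refs = state_ref_base(scheme)
        for _, row in df.iterrows():
            s = names[row["context"]]
            j = alt_index(refs[s], np.int64(BASES.index(row["alt"])))
            probs[s, j] = row["probability"]
            counts[s, j] = row["count"]
            abundance[s] = row["abundance"]
        return cls(scheme, probs, counts, abundance)


def uniform_model(scheme: ContextScheme, p: float) -> ContextModel:
    """Model giving every (context, alternate) pair probability ``p``."""
    return ContextModel(scheme, np.full((scheme.n_states, 3), p))


# --------------------------------------------------------------------------
# estimation
# --------------------------------------------------------------------------

def count_kmer_abundance(
    genome: GenomeSequence,
    k: int,
    restrict: dict[str, list[tuple[int, int]]] | None = None,
) -> np.ndarray:
    """Forward-strand count of every k-mer in the genome (or in the given
    regions); k-mers containing N are skipped.  A k-mer is attributed to its
    center position."""
    if k % 2 != 1:
        raise ValueError("k must be odd")
    if not genome.chrom_names or all(genome.length(c) == 0 for c in genome.chrom_names):
        raise ValueError("empty genome")
    counts = np.zeros(4 ** k, dtype=np.int64)
    for chrom in genome.chrom_names:
        track = kmer_state_track(genome.codes(chrom), k)
        if restrict is not None:
            if chrom not in restrict:
                continue
            mask = np.zeros(len(track), dtype=bool)
            for s, e in restrict[chrom]:
                mask[s:e] = True
            track = track[mask]
        valid = track[track >= 0]
        counts += np.bincount(valid, minlength=4 ** k)
    return counts


def abundance_to_dict(counts: np.ndarray, k: int) -> dict[str, int]:
    """Nonzero abundance entries keyed by k-mer string (for small k / tests)."""
    out = {}
    for s in np.nonzero(counts)[0]:
        kmer = decode(np.array([(s // 4 ** (k - 1 - j)) % 4 for j in range(k)], dtype=np.uint8))
        out[kmer] = int(counts[s])
    return out


def _mutation_state_counts(
    mutations: pd.DataFrame, genome: GenomeSequence, scheme: ContextScheme
) -> tuple[np.ndarray, int]:
    """Tally mutations into (state, alt) cells; returns (counts, n_skipped)."""
    counts = np.zeros((scheme.n_states, 3), dtype=np.int64)
    n_skipped = 0
    for chrom, sub in mutations.groupby("chrom", sort=False):
        chrom = str(chrom)
        codes = genome.codes(chrom)
        track = state_track_for_scheme(codes, scheme)
        pos = sub["pos"].to_numpy(dtype=np.int64)
        ref = encode("".join(sub["ref"]))
        alt = encode("".join(sub["alt"]))
        if (codes[pos] != ref).any():
            bad = pos[codes[pos] != ref][0]
            raise ValueError(f"mutation ref allele mismatch at {chrom}:{bad}")
        if (ref == alt).any():
            raise ValueError("mutation with alt == ref")
        states = track[pos]
        ok = states >= 0
        n_skipped += int((~ok).sum())
        j = alt_index(ref[ok].astype(np.int64), alt[ok].astype(np.int64))
        np.add.at(counts, (states[ok], j), 1)
    return counts, n_skipped


def estimate_direct(
    mutations: pd.DataFrame, genome: GenomeSequence, k: int
) -> ContextModel:
    """Direct estimate: P(a | context) = N(a, context) / G(context).

    Mutations whose centered k-mer is unreadable (chromosome edge or N) are
    skipped and counted in ``n_skipped_mutations``; a reference-allele
    mismatch with the genome raises.
    """
    scheme = ContextScheme(k, k, "direct") if k > 1 else ContextScheme(1, 1, "mono")
    abundance = count_kmer_abundance(genome, k)
    counts, n_skipped = _mutation_state_counts(mutations, genome, scheme)
    probs = np.divide(counts, abundance[:, None],
                      out=np.zeros_like(counts, dtype=float), where=abundance[:, None] > 0)
    return ContextModel(scheme, probs, counts, abundance, n_skipped)


def estimate_cpg(mutations: pd.DataFrame, genome: GenomeSequence) -> ContextModel:
    """CpG-aware mononucleotide model: 6 reference states x 3 alternates."""
    scheme = ContextScheme(1, 1, "cpg")
    abundance = np.zeros(6, dtype=np.int64)
    for chrom in genome.chrom_names:
        track = cpg_state_track(genome.codes(chrom))
        valid = track[track >= 0]
        abundance += np.bincount(valid, minlength=6)
    counts, n_skipped = _mutation_state_counts(mutations, genome, scheme)
    probs = np.divide(counts, abundance[:, None],
                      out=np.zeros_like(counts, dtype=float), where=abundance[:, None] > 0)
    return ContextModel(scheme, probs, counts, abundance, n_skipped)


def estimate_decomposed(
    mutations: pd.DataFrame, genome: GenomeSequence, k: int, h: int
) -> ContextModel:
    """Composite-likelihood estimate over the full k-mer state space.

    The core h-mer probability P(a | core) and the per-flank-position
    marginals P_i(a | core, x_i) are obtained by summing the full k-mer
    mutation counts and abundances over the appropriate flank sets; the
    composite probability multiplies the per-position correction factors.
    Any zero denominator yields probability 0.  With h == k the result is
    identical to the direct estimate at k.
    """
    if h > k:
        raise ValueError("decomposition requires h <= k")
    scheme = ContextScheme(k, h, "decomposed")
    abundance = count_kmer_abundance(genome, k)
    counts, n_skipped = _mutation_state_counts(
        mutations, genome, ContextScheme(k, k, "direct") if k > 1 else ContextScheme(1, 1, "mono"))

    g = k - h
    if g == 0:
        probs = np.divide(counts, abundance[:, None],
                          out=np.zeros_like(counts, dtype=float), where=abundance[:, None] > 0)
        return ContextModel(scheme, probs, counts, abundance, n_skipped)

    side = g // 2  # flank digits per side (k, h odd => g even)
    states = np.arange(4 ** k, dtype=np.int64)
    digits = [(states // 4 ** (k - 1 - j)) % 4 for j in range(k)]
    core = np.zeros(4 ** k, dtype=np.int64)
    for j in range(side, side + h):
        core = core * 4 + digits[j]
    flank_positions = list(range(side)) + list(range(side + h, k))  # 5' then 3'

    n_core = np.zeros((4 ** h, 3), dtype=np.int64)
    g_core = np.zeros(4 ** h, dtype=np.int64)
    np.add.at(n_core, core, counts)
    np.add.at(g_core, core, abundance)
    p_core = np.divide(n_core, g_core[:, None],
                       out=np.zeros_like(n_core, dtype=float), where=g_core[:, None] > 0)

    probs = p_core[core].copy()
    core_nonzero = p_core[core] > 0
    for j in flank_positions:
        n_i = np.zeros((4 ** h, 4, 3), dtype=np.int64)
        g_i = np.zeros((4 ** h, 4), dtype=np.int64)
        np.add.at(n_i, (core, digits[j]), counts)
        np.add.at(g_i, (core, digits[j]), abundance)
        p_i = np.divide(n_i, g_i[:, :, None],
                        out=np.zeros_like(n_i, dtype=float), where=g_i[:, :, None] > 0)
        marg = p_i[core, digits[j]]  # (4^k, 3)
        factor = np.divide(marg, p_core[core],
                           out=np.zeros_like(marg), where=core_nonzero)
        probs *= factor
    return ContextModel(scheme, probs, counts, abundance, n_skipped)


def estimate(
    mutations: pd.DataFrame, genome: GenomeSequence, scheme: ContextScheme
) -> ContextModel:
    """Dispatch on scheme mode."""
    if scheme.mode == "cpg":
        return estimate_cpg(mutations, genome)
    if scheme.mode == "mono" or (scheme.mode == "direct"):
        return estimate_direct(mutations, genome, scheme.k)
    return estimate_decomposed(mutations, genome, scheme.k, scheme.h)


# --------------------------------------------------------------------------
# 9-class whole-genome spectrum
# --------------------------------------------------------------------------

SPECTRUM_CLASSES = [
    "C>A", "C>A_CpG", "C>G", "C>G_CpG", "C>T", "C>T_CpG", "T>A", "T>C", "T>G",
]


def mutation_spectrum(mutations: pd.DataFrame, genome: GenomeSequence) -> pd.DataFrame:
    """Abundance-corrected 9-class mutation spectrum.

    The six strand-collapsed substitution classes (purine references folded
    onto their pyrimidine complements), with the three C>* classes split into
    CpG and non-CpG.  Each class count is divided by the genomic abundance of
    its reference context (C classes: forward-strand C plus G sites of the
    matching CpG status; T classes: T plus A sites).
    """
    cpg_ab = np.zeros(6, dtype=np.int64)
    for chrom in genome.chrom_names:
        track = cpg_state_track(genome.codes(chrom))
        valid = track[track >= 0]
        cpg_ab += np.bincount(valid, minlength=6)
    abundance = {
        "C": int(cpg_ab[1] + cpg_ab[3]),       # non-CpG C + non-CpG G
        "C_CpG": int(cpg_ab[2] + cpg_ab[4]),
        "T": int(cpg_ab[5] + cpg_ab[0]),       # T + A
    }

    counts = {c: 0 for c in SPECTRUM_CLASSES}
    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    for chrom, sub in mutations.groupby("chrom", sort=False):
        codes = genome.codes(str(chrom))
        track = cpg_state_track(codes)
        pos = sub["pos"].to_numpy(dtype=np.int64)
        ref = encode("".join(sub["ref"])).astype(np.int64)
        alt = encode("".join(sub["alt"])).astype(np.int64)
        states = track[pos]
        for r, a, st in zip(ref, alt, states):
            is_cpg = st in (2, 4)
            if r in (2, 0):  # G or A: fold to complement
                r, a = comp[r], comp[a]
            name = f"{BASES[r]}>{BASES[a]}"
            if r == 1 and is_cpg:
                name += "_CpG"
            counts[name] += 1

    rows = []
    for cls in SPECTRUM_CLASSES:
        ab = abundance["C_CpG" if cls.endswith("_CpG") else cls[0]]
        rows.append((cls, counts[cls], ab, counts[cls] / ab if ab else 0.0))
    return pd.DataFrame(rows, columns=["class", "count", "abundance", "rate"])
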