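"""Readers and writers for the standard formats the pipeline consumes.

GTF is parsed with pyranges (converted to 0-based half-open on read); FASTA
goes through Biopython (see :mod:`exindnm.genome`); BED, bedGraph and the
package's TSV tables go through pandas.  DNM tables are TSV with a header
(chrom, pos, ref, alt, condition, dataset[, consequence]); positions are
1-based in files and 0-based in memory.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pyranges as pr

GTF_COLUMNS = ["Chromosome", "Source", "Feature", "Start", "End", "Strand",
               "Frame", "gene_id", "transcript_id"]


def read_gtf(path: str | Path) -> pd.DataFrame:
    """GTF records as a pyranges-layout DataFrame (0-based half-open)."""
    df = pr.read_gtf(str(path), as_df=True)
    for col in GTF_COLUMNS:
        if col not in df.columns:
            df[col] = "." if col != "transcript_id" else ""
    return df[GTF_COLUMNS]


def write_gtf(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write pyranges-layout records back to GTF (1-based inclusive on disk)."""
    df = annotation.copy()
    if "Score" not in df.columns:
        df["Score"] = "."
    pr.PyRanges(df).to_gtf(str(path))


def read_dnms(path: str | Path) -> pd.DataFrame:
    """DNM TSV -> DataFrame with 0-based positions."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DNM table {path} lacks columns {sorted(missing)}")
    df["pos"] = df["pos"].astype(int) - 1
    for col, default in (("condition", "unknown"), ("dataset", "unknown")):
        if col not in df.columns:
            df[col] = default
    return df


def write_dnms(dnms: pd.DataFrame, path: str | Path) -> None:
    out = dnms.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=["chrom", "start", "end"], usecols=[0, 1, 2],
                       dtype={"chrom": str})


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """TSV with an optional leading '#' metadata line (seed, config hash)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
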