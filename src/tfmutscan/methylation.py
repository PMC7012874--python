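"""CpG methylation summaries over TF-binding region sets.

Bisulfite data arrive as per-CpG records (1-based position of the C,
methylated fraction, read coverage).  Records below a coverage floor are
excluded; each surviving record is classified methylated when its fraction is
at or above a threshold (strictly below -> unmethylated); all records falling
in a region set are pooled into one overall methylated rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .catalog import snv_positions_0based
from .intervals import Genome, RegionSet, merge_within

__all__ = [
    "MethylationRecord",
    "MethylationSummary",
    "read_methylation",
    "write_methylation",
    "find_cpg_sites",
    "summarize_methylation",
]

METH_COLUMNS = ["chrom", "pos", "meth_fraction", "coverage"]


@dataclass(frozen=True)
class MethylationRecord:
    """One CpG data point (pos = 1-based position of the C)."""

    chrom: str
    pos: int
    meth_fraction: float
    coverage: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.meth_fraction <= 1.0):
            raise ValueError(f"meth_fraction {self.meth_fraction} outside [0,1]")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")


@dataclass
class MethylationSummary:
    """Pooled methylated rate over a region set."""

    fraction: float               # NaN when no usable record
    n_methylated: int
    n_unmethylated: int
    n_excluded_coverage: int
    missing: bool

    @property
    def n_used(self) -> int:
        return self.n_methylated + self.n_unmethylated


def read_methylation(path) -> pd.DataFrame:
    """Read a bedGraph-like TSV: chrom, pos (1-based), meth_fraction, coverage."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=METH_COLUMNS)
    bad = (df["meth_fraction"] < 0) | (df["meth_fraction"] > 1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} record(s) with meth_fraction "
                         "outside [0,1]")
    df["pos"] = df["pos"].astype(np.int64)
    df["coverage"] = df["coverage"].astype(np.int64)
    return df


def write_methylation(df: pd.DataFrame, path, header: Optional[str] = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        df[METH_COLUMNS].to_csv(fh, sep="\t", header=False, index=False,
                                float_format="%.4f")


def find_cpg_sites(
    genome: Genome, regions: Optional[RegionSet] = None
) -> Dict[str, np.ndarray]:
    """1-based positions of every C followed by G, optionally within regions."""
    out: Dict[str, np.ndarray] = {}
    if regions is None:
        span = {c: [(0, genome.lengths[c])] for c in genome.sequences}
    else:
        merged = merge_within(regions, 0)
        span = {}
        for chrom, g in merged.df.groupby("chrom", sort=True):
            span[str(chrom)] = list(zip(g["start"], g["end"]))
    for chrom, blocks in span.items():
        codes = genome.codes(chrom)
        cg = (codes[:-1] == 1) & (codes[1:] == 2)
        pos0 = np.nonzero(cg)[0]
        keep = np.zeros(len(pos0), dtype=bool)
        for s, e in blocks:
            keep |= (pos0 >= s) & (pos0 < e)
        if keep.any():
            out[chrom] = pos0[keep] + 1  # 1-based C position
    return out


def summarize_methylation(
    records: pd.DataFrame,
    regions: RegionSet,
    min_coverage: int = 10,
    meth_threshold: float = 0.52,
) -> MethylationSummary:
    """Overall methylated rate of a region set.

    Records with coverage < ``min_coverage`` are excluded; a surviving record
    is methylated iff ``meth_fraction >= meth_threshold`` (strictly below the
    threshold is unmethylated).  All records overlapping the region set are
    pooled into methylated / (methylated + unmethylated).
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    if not (0.0 <= meth_threshold <= 1.0):
        raise ValueError("meth_threshold must be in [0,1]")
    merged = merge_within(regions, 0).by_chrom()
    n_excl = 0
    n_meth = 0
    n_unmeth = 0
    for chrom, g in records.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        starts = merged[chrom]["start"].to_numpy()
        ends = merged[chrom]["end"].to_numpy()
        p0 = snv_positions_0based(g)
        j = np.searchsorted(starts, p0, side="right") - 1
        inside = (j >= 0) & (p0 < ends[np.maximum(j, 0)])
        sub = g[inside]
        low = sub["coverage"] < min_coverage
        n_excl += int(low.sum())
        ok = sub[~low]
        meth = ok["meth_fraction"] >= meth_threshold
        n_meth += int(meth.sum())
        n_unmeth += int((~meth).sum())
    used = n_meth + n_unmeth
    return MethylationSummary(
        fraction=(n_meth / used) if used else float("nan"),
        n_methylated=n_meth,
        n_unmethylated=n_unmeth,
        n_excluded_coverage=n_excl,
        missing=used == 0,
    )
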