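"""Genomic interval data model and interval algebra.

All internal coordinates are 0-based, half-open ``[start, end)`` (BED
convention).  VCF positions are 1-based; the single conversion point is
:func:`tfmutscan.catalog.snv_positions_0based` — no other code subtracts 1.

The algebra here (merge-within-distance, slop, subtract, closest, overlap
counting) is the substrate for every downstream analysis: TF-binding peak
sets, shuffled null region sets, blacklist masks and motif-match sets are
all :class:`RegionSet` objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "Genome",
    "read_bed",
    "write_bed",
    "merge_within",
    "slop",
    "center_windows",
    "intersect_count",
    "subtract",
    "closest_distance",
    "overlaps_any",
    "NO_TARGET",
]

# Sentinel distance for points on chromosomes with no target interval.
NO_TARGET = -1

_COLUMNS = ["chrom", "start", "end", "score", "strand"]

# Base -> code used throughout: A=0, C=1, G=2, T=3, anything else (N) = 4.
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional peak score."""

    chrom: str
    start: int
    end: int
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(
                f"zero/negative length interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.score is not None and self.score < 0:
            raise ValueError(f"negative score: {self.score}")

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """An ordered collection of :class:`GenomicInterval`.

    Backed by a :class:`pandas.DataFrame` with columns
    ``chrom, start, end, score, strand`` so that the algebra can operate on
    numpy arrays per chromosome.
    """

    def __init__(
        self,
        df: Optional[pd.DataFrame] = None,
        name: str = "",
        provenance: str = "",
        validate: bool = True,
    ) -> None:
        if df is None:
            df = pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                    "score": pd.Series(dtype=float),
                    "strand": pd.Series(dtype=str),
                }
            )
        df = df.copy()
        if "score" not in df.columns:
            df["score"] = np.nan
        if "strand" not in df.columns:
            df["strand"] = "."
        df = df[_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["score"] = df["score"].astype(float)
        if validate and len(df):
            bad = (df["start"] < 0) | (df["start"] >= df["end"])
            if bad.any():
                i = int(np.nonzero(bad.to_numpy())[0][0])
                r = df.iloc[i]
                raise ValueError(
                    f"invalid interval {r.chrom}:{r.start}-{r.end} at row {i}"
                )
        self.df = df
        self.name = name
        self.provenance = provenance

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], name: str = "", provenance: str = ""
    ) -> "RegionSet":
        rows = [
            (
                iv.chrom,
                iv.start,
                iv.end,
                np.nan if iv.score is None else iv.score,
                iv.strand,
            )
            for iv in intervals
        ]
        df = pd.DataFrame(rows, columns=_COLUMNS) if rows else None
        return cls(df, name=name, provenance=provenance)

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        start: Sequence[int],
        end: Sequence[int],
        score: Optional[Sequence[float]] = None,
        strand: Optional[Sequence[str]] = None,
        name: str = "",
        provenance: str = "",
        validate: bool = True,
    ) -> "RegionSet":
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chrom, dtype=object),
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
                "score": np.nan if score is None else np.asarray(score, dtype=float),
                "strand": "." if strand is None else np.asarray(strand, dtype=object),
            }
        )
        return cls(df, name=name, provenance=provenance, validate=validate)

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for r in self.df.itertuples(index=False):
            score = None if pd.isna(r.score) else float(r.score)
            yield GenomicInterval(r.chrom, int(r.start), int(r.end), score, r.strand)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    @property
    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())

    @property
    def chroms(self) -> List[str]:
        return sorted(self.df["chrom"].unique())

    def sorted(self) -> "RegionSet":
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        out = RegionSet(df, name=self.name, provenance=self.provenance, validate=False)
        return out

    def by_chrom(self) -> Dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.df.groupby("chrom", sort=True)}

    def with_name(self, name: str) -> "RegionSet":
        out = RegionSet(self.df, name=name, provenance=self.provenance, validate=False)
        return out

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegionSet({self.name!r}, n={len(self)}, bp={self.total_bp})"


class Genome:
    """A reference genome: per-chromosome sequences plus a gap/blacklist mask.

    Sequences are uppercase strings over A/C/G/T/N.  Base-code arrays and
    per-base cumulative counts are cached lazily; downstream modules (spectra,
    motif scanning, simulation) share them through this object.
    """

    def __init__(
        self,
        sequences: Mapping[str, str],
        gap_mask: Optional[RegionSet] = None,
    ) -> None:
        self.sequences: Dict[str, str] = {c: s.upper() for c, s in sequences.items()}
        self.lengths: Dict[str, int] = {c: len(s) for c, s in self.sequences.items()}
        if gap_mask is None:
            gap_mask = RegionSet(name="gap_mask")
        for iv in gap_mask:
            if iv.chrom not in self.lengths:
                raise ValueError(f"gap mask on unknown chromosome {iv.chrom!r}")
            if iv.end > self.lengths[iv.chrom]:
                raise ValueError(f"gap interval {iv} beyond chromosome end")
        self.gap_mask = gap_mask
        self._codes: Dict[str, np.ndarray] = {}
        self._cumcounts: Dict[str, np.ndarray] = {}
        self._context_ids: Dict[str, np.ndarray] = {}

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path, gap_bed=None) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        mask = read_bed(gap_bed, name="gap_mask") if gap_bed else None
        return cls(seqs, gap_mask=mask)

    def to_fasta(self, path, line_width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")

    # -- sequence access ---------------------------------------------------
    def fetch(self, chrom: str, start: int, end: int) -> str:
        self._check(chrom, start, end)
        return self.sequences[chrom][start:end]

    def codes(self, chrom: str) -> np.ndarray:
        """uint8 base codes (A=0,C=1,G=2,T=3,N=4) for a chromosome."""
        if chrom not in self._codes:
            seq = self.sequences[chrom]
            self._codes[chrom] = _BASE_CODE[np.frombuffer(seq.encode("ascii"), np.uint8)]
        return self._codes[chrom]

    def base_cumcounts(self, chrom: str) -> np.ndarray:
        """(4, L+1) cumulative A/C/G/T counts; counts in [a,b) = C[:,b]-C[:,a]."""
        if chrom not in self._cumcounts:
            c = self.codes(chrom)
            onehot = np.zeros((4, len(c) + 1), dtype=np.uint32)
            for b in range(4):
                onehot[b, 1:] = np.cumsum(c == b, dtype=np.uint32)
            self._cumcounts[chrom] = onehot
        return self._cumcounts[chrom]

    def _check(self, chrom: str, start: int = 0, end: Optional[int] = None) -> None:
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end is not None and (start < 0 or end > self.lengths[chrom]):
            raise ValueError(
                f"{chrom}:{start}-{end} outside [0,{self.lengths[chrom]}]"
            )

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths.values()))

    def non_gap_bp(self) -> int:
        return self.total_bp - merge_within(self.gap_mask, 0).total_bp


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path, name: str = "", on_error: str = "warn") -> RegionSet:
    """Read a BED3/BED5/BED6 file into a :class:`RegionSet`.

    Coordinates are taken as 0-based half-open.  Column 5, if present and not
    '.', is parsed as the score (peak height).  Malformed lines (too few
    columns, non-integer coordinates, start >= end) are rejected; each
    rejection is recorded with its 1-based line number on the returned set's
    ``parse_errors`` attribute and summarized in a warning (or raised when
    ``on_error='raise'``).
    """
    if on_error not in ("warn", "raise"):
        raise ValueError("on_error must be 'warn' or 'raise'")
    chroms: List[str] = []
    starts: List[int] = []
    ends: List[int] = []
    scores: List[float] = []
    strands: List[str] = []
    errors: List[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                errors.append((lineno, "fewer than 3 columns"))
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                errors.append((lineno, "non-integer coordinates"))
                continue
            if start < 0 or start >= end:
                errors.append((lineno, f"start >= end ({start} >= {end})"))
                continue
            score = np.nan
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    errors.append((lineno, f"bad score {fields[4]!r}"))
                    continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            scores.append(score)
            strands.append(strand)
    if errors:
        msg = f"{path}: rejected {len(errors)} BED line(s): " + "; ".join(
            f"line {ln}: {why}" for ln, why in errors[:5]
        )
        if on_error == "raise":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    rs = RegionSet.from_arrays(
        chroms, starts, ends, scores, strands,
        name=name or Path(str(path)).stem, provenance=f"read_bed({path})",
    )
    rs.parse_errors = errors  # type: ignore[attr-defined]
    return rs


def write_bed(regions: RegionSet, path, header: Optional[str] = None) -> None:
    """Write BED3 (no scores/strands), BED5, or BED6 depending on content."""
    df = regions.df
    has_score = bool(len(df)) and df["score"].notna().any()
    has_strand = bool(len(df)) and (df["strand"] != ".").any()
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        for i, r in enumerate(df.itertuples(index=False)):
            cols = [r.chrom, str(int(r.start)), str(int(r.end))]
            if has_score or has_strand:
                score = "." if pd.isna(r.score) else format(r.score, "g")
                cols += [f"{regions.name or 'region'}_{i}", score]
            if has_strand:
                cols.append(r.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Algebra
# ---------------------------------------------------------------------------

def merge_within(regions: RegionSet, max_gap: int) -> RegionSet:
    """Union intervals separated by a gap of at most ``max_gap`` bp.

    The gap between ``[a,b)`` and ``[c,d)`` with ``c >= b`` is ``c - b``; the
    pair is merged when ``gap <= max_gap`` (so ``max_gap=0`` merges touching
    and overlapping intervals).  The merged score is the max of member scores.
    Output is sorted by (chrom, start) and non-overlapping.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not len(regions):
        return RegionSet(name=regions.name)
    out_c: List[str] = []
    out_s: List[int] = []
    out_e: List[int] = []
    out_sc: List[float] = []
    for chrom, g in regions.sorted().df.groupby("chrom", sort=True):
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        scores = g["score"].to_numpy()
        cur_s, cur_e, cur_sc = int(starts[0]), int(ends[0]), scores[0]
        for s, e, sc in zip(starts[1:], ends[1:], scores[1:]):
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, int(e))
                if not np.isnan(sc):
                    cur_sc = sc if np.isnan(cur_sc) else max(cur_sc, sc)
            else:
                out_c.append(str(chrom)); out_s.append(cur_s)
                out_e.append(cur_e); out_sc.append(cur_sc)
                cur_s, cur_e, cur_sc = int(s), int(e), sc
        out_c.append(str(chrom)); out_s.append(cur_s)
        out_e.append(cur_e); out_sc.append(cur_sc)
    return RegionSet.from_arrays(
        out_c, out_s, out_e, out_sc,
        name=regions.name, provenance=f"merge_within(d={max_gap})", validate=False,
    )


def slop(regions: RegionSet, genome: Genome, flank: int) -> RegionSet:
    """Extend every interval by ``flank`` bp on both sides, clamped to the
    chromosome bounds."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    df = regions.df.copy()
    for chrom in df["chrom"].unique():
        if chrom not in genome.lengths:
            raise KeyError(f"chromosome {chrom!r} not in genome")
    lens = df["chrom"].map(genome.lengths).to_numpy()
    df["start"] = np.maximum(df["start"].to_numpy() - flank, 0)
    df["end"] = np.minimum(df["end"].to_numpy() + flank, lens)
    return RegionSet(df, name=regions.name,
                     provenance=f"slop(flank={flank})", validate=False)


def _counts_in_intervals(
    positions0: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Counts of sorted 0-based positions falling in each [start, end)."""
    return (
        np.searchsorted(positions0, ends, side="left")
        - np.searchsorted(positions0, starts, side="left")
    )


def intersect_count(regions: RegionSet, catalog) -> tuple:
    """Per-interval SNV counts plus the overlapping records.

    A 1-based SNV position ``p`` overlaps ``[start, end)`` iff
    ``start <= p-1 < end``.  Returns ``(counts, hits)`` where ``counts`` is an
    int array aligned with ``regions.df`` rows and ``hits`` is the DataFrame
    of SNV records overlapping at least one interval.
    """
    from .catalog import snv_positions_0based

    counts = np.zeros(len(regions), dtype=np.int64)
    snvs = catalog.snvs if hasattr(catalog, "snvs") else catalog
    if not len(regions) or not len(snvs):
        return counts, snvs.iloc[0:0] if len(snvs) else snvs
    hit_mask = np.zeros(len(snvs), dtype=bool)
    pos_by_chrom = {}
    for chrom, g in snvs.groupby("chrom", sort=False):
        p0 = snv_positions_0based(g)
        order = np.argsort(p0, kind="mergesort")
        pos_by_chrom[chrom] = (p0[order], g.index.to_numpy()[order])
    idx_lookup = {i: k for k, i in enumerate(snvs.index)}
    for chrom, g in regions.df.groupby("chrom", sort=False):
        if chrom not in pos_by_chrom:
            continue
        p0, orig_idx = pos_by_chrom[chrom]
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        lo = np.searchsorted(p0, starts, side="left")
        hi = np.searchsorted(p0, ends, side="left")
        counts[g.index.to_numpy()] = hi - lo
        for a, b in zip(lo, hi):
            for j in orig_idx[a:b]:
                hit_mask[idx_lookup[j]] = True
    return counts, snvs.loc[hit_mask]


def center_windows(regions: RegionSet, flank: int,
                   genome: Optional[Genome] = None) -> RegionSet:
    """Fixed-width windows anchored at peak centers: [center-flank, center+flank].

    The center is ``floor((start+end)/2)``; windows are clamped to the
    chromosome when a genome is given.  Scores are preserved.  This is the
    region over which peak-proximal mutation models are defined (as opposed
    to :func:`slop`, which extends the original peak boundaries).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    df = regions.df.copy()
    centers = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    starts = np.maximum(centers - flank, 0)
    ends = centers + flank + 1
    if genome is not None:
        lens = df["chrom"].map(genome.lengths).to_numpy()
        ends = np.minimum(ends, lens)
    df["start"] = starts
    df["end"] = ends
    return RegionSet(df, name=regions.name,
                     provenance=f"center_windows(flank={flank})",
                     validate=False)


def subtract(a: RegionSet, b: RegionSet) -> RegionSet:
    """Portions of ``a`` not covered by ``b`` (bedtools subtract semantics).

    Fragment rows inherit the score and strand of their source interval.
    """
    if not len(a) or not len(b):
        return RegionSet(a.df, name=a.name, validate=False)
    bm = merge_within(b, 0).by_chrom()
    out_rows = []
    for r in a.df.itertuples(index=False):
        if r.chrom not in bm:
            out_rows.append((r.chrom, r.start, r.end, r.score, r.strand))
            continue
        g = bm[r.chrom]
        bs = g["start"].to_numpy()
        be = g["end"].to_numpy()
        keep = (be > r.start) & (bs < r.end)
        cur = int(r.start)
        for s, e in zip(bs[keep], be[keep]):
            if s > cur:
                out_rows.append((r.chrom, cur, int(s), r.score, r.strand))
            cur = max(cur, int(e))
        if cur < r.end:
            out_rows.append((r.chrom, cur, int(r.end), r.score, r.strand))
    df = pd.DataFrame(out_rows, columns=_COLUMNS) if out_rows else None
    return RegionSet(df, name=a.name, provenance="subtract", validate=False)


def overlaps_any(regions: RegionSet, mask: RegionSet) -> np.ndarray:
    """Boolean per interval of ``regions``: >= 1 bp overlap with ``mask``."""
    out = np.zeros(len(regions), dtype=bool)
    if not len(regions) or not len(mask):
        return out
    mm = merge_within(mask, 0).by_chrom()
    for chrom, g in regions.df.groupby("chrom", sort=False):
        if chrom not in mm:
            continue
        ms = mm[chrom]["start"].to_numpy()
        me = mm[chrom]["end"].to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        # interval overlaps some [ms, me) iff exists j: ms[j] < end and me[j] > start
        j = np.searchsorted(me, starts, side="right")
        ok = (j < len(ms)) & (ms[np.minimum(j, len(ms) - 1)] < ends)
        out[g.index.to_numpy()] = ok
    return out


def closest_distance(
    points: Mapping[str, np.ndarray], targets: RegionSet
) -> Dict[str, np.ndarray]:
    """Distance from each 0-based point to the nearest target interval.

    For a point ``p`` and interval ``[start, end)`` the distance is
    ``max(0, start - p, p - (end - 1))`` — 0 when the point lies inside, else
    the bp gap to the nearest covered base.  Points on chromosomes with no
    target get :data:`NO_TARGET` (-1).
    """
    if not len(targets):
        raise ValueError("targets is empty")
    tm = merge_within(targets, 0).by_chrom()
    out: Dict[str, np.ndarray] = {}
    for chrom, pts in points.items():
        pts = np.asarray(pts, dtype=np.int64)
        if chrom not in tm:
            out[chrom] = np.full(len(pts), NO_TARGET, dtype=np.int64)
            continue
        starts = tm[chrom]["start"].to_numpy()
        ends = tm[chrom]["end"].to_numpy()
        # nearest interval is either the one starting after p or ending before
        j = np.searchsorted(starts, pts, side="right")
        d_right = np.where(j < len(starts),
                           starts[np.minimum(j, len(starts) - 1)] - pts,
                           np.iinfo(np.int64).max)
        jl = j - 1
        d_left = np.where(jl >= 0,
                          pts - (ends[np.maximum(jl, 0)] - 1),
                          np.iinfo(np.int64).max)
        d = np.minimum(np.maximum(d_left, 0), np.maximum(d_right, 0))
        # inside: start <= p < end for the left neighbor
        inside = (jl >= 0) & (pts < ends[np.maximum(jl, 0)])
        d[inside] = 0
        out[chrom] = d
    return out
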