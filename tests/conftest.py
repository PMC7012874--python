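"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every operation from first principles
(per-bp bitmasks, double loops, string slicing) so they share no code with
the implementation they check.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pytest

from tfmutscan.intervals import Genome, GenomicInterval, RegionSet


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def random_genome(
    seed: int,
    lengths: Optional[Dict[str, int]] = None,
    gc: float = 0.45,
    gap: Optional[List[Tuple[str, int, int]]] = None,
) -> Genome:
    """A small i.i.d. test genome, independent of the simulate module."""
    rng = np.random.default_rng(seed)
    lengths = lengths or {"chr1": 50_000, "chr2": 30_000}
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {}
    for chrom, L in lengths.items():
        codes = rng.choice(4, size=L, p=p)
        seq = np.frombuffer(b"ACGT", dtype=np.uint8)[codes].copy()
        if gap:
            for c, s, e in gap:
                if c == chrom:
                    seq[s:e] = ord("N")
        seqs[chrom] = seq.tobytes().decode()
    mask = None
    if gap:
        mask = RegionSet.from_arrays(
            [g[0] for g in gap], [g[1] for g in gap], [g[2] for g in gap],
            name="gap_mask")
    return Genome(seqs, gap_mask=mask)


def random_regions(
    seed: int, genome: Genome, n: int, min_len: int = 10, max_len: int = 400
) -> RegionSet:
    rng = np.random.default_rng(seed)
    chroms, starts, ends = [], [], []
    names = sorted(genome.lengths)
    for _ in range(n):
        c = names[rng.integers(len(names))]
        L = int(rng.integers(min_len, max_len + 1))
        s = int(rng.integers(0, genome.lengths[c] - L))
        chroms.append(c)
        starts.append(s)
        ends.append(s + L)
    return RegionSet.from_arrays(chroms, starts, ends,
                                 score=rng.random(n), name="rand")


def random_snvs(seed: int, genome: Genome, n: int,
                sample_id: str = "S0") -> pd.DataFrame:
    """SNVs at random non-N positions, ref matching the genome."""
    rng = np.random.default_rng(seed)
    rows = []
    names = sorted(genome.lengths)
    while len(rows) < n:
        c = names[rng.integers(len(names))]
        p0 = int(rng.integers(0, genome.lengths[c]))
        ref = genome.sequences[c][p0]
        if ref == "N":
            continue
        alt = "ACGT"[int(rng.integers(4))]
        if alt == ref:
            continue
        rows.append((c, p0 + 1, ref, alt, sample_id, 0.4, 2.0))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sample_id", "vaf",
                       "caller_count"])


@pytest.fixture(scope="session")
def toy_genome() -> Genome:
    return random_genome(7)


@pytest.fixture(scope="session")
def gapped_genome() -> Genome:
    return random_genome(
        11, lengths={"chr1": 100_000},
        gap=[("chr1", 40_000, 50_000)])


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_merge(
    intervals: List[Tuple[str, int, int]], max_gap: int
) -> List[Tuple[str, int, int]]:
    """O(n^2) union-find pairwise merge."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci != cj:
                continue
            gap = max(si, sj) - min(ei, ej)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    # NOTE: pairwise closure is not transitive-complete after one pass;
    # iterate until stable by recomputing group extents
    groups: Dict[int, List[int]] = {}
    for i in range(len(intervals)):
        groups.setdefault(find(i), []).append(i)
    merged = [
        (intervals[g[0]][0],
         min(intervals[i][1] for i in g),
         max(intervals[i][2] for i in g))
        for g in groups.values()
    ]
    # repeat until fixed point (chains of merges)
    if len(merged) < len(intervals):
        again = brute_merge(merged, max_gap)
        if len(again) < len(merged):
            return sorted(again)
    return sorted(merged)


def brute_subtract_coverage(
    a: RegionSet, b: RegionSet, genome: Genome
) -> Dict[str, np.ndarray]:
    """Per-bp boolean coverage of a \\ b."""
    cov = {c: np.zeros(L, dtype=bool) for c, L in genome.lengths.items()}
    for iv in a:
        cov[iv.chrom][iv.start:iv.end] = True
    for iv in b:
        cov[iv.chrom][iv.start:iv.end] = False
    return cov


def coverage_of(rs: RegionSet, genome: Genome) -> Dict[str, np.ndarray]:
    cov = {c: np.zeros(L, dtype=bool) for c, L in genome.lengths.items()}
    for iv in rs:
        cov[iv.chrom][iv.start:iv.end] = True
    return cov


def brute_counts(regions: RegionSet, snvs: pd.DataFrame) -> np.ndarray:
    """O(n*m) double loop over intervals and SNVs."""
    counts = np.zeros(len(regions), dtype=int)
    rows = list(regions.df.itertuples(index=False))
    for s in snvs.itertuples(index=False):
        p0 = s.pos - 1
        for i, r in enumerate(rows):
            if r.chrom == s.chrom and r.start <= p0 < r.end:
                counts[i] += 1
    return counts


def brute_closest(points: Dict[str, np.ndarray], targets: RegionSet
                  ) -> Dict[str, np.ndarray]:
    """Exhaustive min-scan over all targets."""
    tl = list(targets.df.itertuples(index=False))
    out = {}
    for chrom, pts in points.items():
        dists = []
        for p in pts:
            best = None
            for t in tl:
                if t.chrom != chrom:
                    continue
                d = max(0, t.start - p, p - (t.end - 1))
                best = d if best is None else min(best, d)
            dists.append(-1 if best is None else best)
        out[chrom] = np.array(dists)
    return out


_RC = str.maketrans("ACGT", "TGCA")
_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]


def brute_classify(chrom: str, pos: int, ref: str, alt: str,
                   genome: Genome) -> Optional[str]:
    """Independent string-based 96-class labeler."""
    seq = genome.sequences[chrom]
    p0 = pos - 1
    assert seq[p0] == ref
    if p0 == 0 or p0 == len(seq) - 1:
        return None
    tri = seq[p0 - 1 : p0 + 2]
    if "N" in tri or "N" in alt:
        return None
    if ref in "AG":
        tri = tri.translate(_RC)[::-1]
        alt = alt.translate(_RC)
        ref = tri[1]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def brute_pwm_scores(seq: str, lodds: np.ndarray) -> np.ndarray:
    """All-window plus-strand log-odds scores; NaN where a window has N."""
    L = lodds.shape[1]
    out = np.full(max(len(seq) - L + 1, 0), np.nan)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(len(out)):
        w = seq[i : i + L]
        if "N" in w:
            continue
        out[i] = sum(lodds[idx[b], j] for j, b in enumerate(w))
    return out
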