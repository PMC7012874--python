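"""Shuffled null region sets and composition-matched backgrounds.

The empirical null for regional mutation rates is built by repositioning the
observed peak set uniformly at random across the mappable genome (the
complement of the gap/blacklist exclusion mask), preserving each interval's
length.  Placement is exactly uniform over all allowed start positions, which
guarantees zero overlap with the exclusion mask by construction and keeps the
procedure deterministic per seed.

Composition matching reproduces the post-hoc selection of shuffles whose
A/C/G/T fractions match the target set: base-fraction columns are z-scored
across the shuffle population and a shuffle is kept iff every base's z-score
lies within ``sd_window`` of the target's z-score under the same column
mean/sd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import Genome, RegionSet, merge_within, subtract

__all__ = [
    "ShuffleConfig",
    "CompositionVector",
    "shuffle_regions",
    "shuffle_starts",
    "composition_vector",
    "composition_matrix",
    "select_composition_matched",
    "allowed_blocks",
]


@dataclass
class ShuffleConfig:
    """Configuration of the shuffle-based null."""

    n_iterations: int = 1000
    seed: int = 0
    preserve_chromosome: bool = False
    exclude: Optional[RegionSet] = None
    allow_overlap_within_iteration: bool = True

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class CompositionVector:
    """A/C/G/T fractions over a region set's sequence (N excluded)."""

    a: float
    c: float
    g: float
    t: float

    def __post_init__(self) -> None:
        total = self.a + self.c + self.g + self.t
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.c, self.g, self.t])

    @property
    def gc(self) -> float:
        return self.c + self.g


def allowed_blocks(
    genome: Genome, exclude: Optional[RegionSet]
) -> Dict[str, np.ndarray]:
    """Gap-free placement blocks per chromosome as (n, 2) start/end arrays."""
    whole = RegionSet.from_arrays(
        list(genome.lengths), [0] * len(genome.lengths),
        list(genome.lengths.values()), validate=False,
    )
    mask_parts = [genome.gap_mask]
    if exclude is not None:
        mask_parts.append(exclude)
    mask = RegionSet.from_arrays(
        np.concatenate([m.df["chrom"].to_numpy() for m in mask_parts]),
        np.concatenate([m.df["start"].to_numpy() for m in mask_parts]),
        np.concatenate([m.df["end"].to_numpy() for m in mask_parts]),
        validate=False,
    ) if sum(len(m) for m in mask_parts) else RegionSet()
    free = subtract(whole, mask).sorted()
    out: Dict[str, np.ndarray] = {c: np.empty((0, 2), dtype=np.int64)
                                  for c in genome.lengths}
    for chrom, g in free.df.groupby("chrom", sort=True):
        out[str(chrom)] = g[["start", "end"]].to_numpy(dtype=np.int64)
    return out


class _PlacementSampler:
    """Uniform sampler over allowed start positions for a given length."""

    def __init__(self, blocks: Dict[str, np.ndarray],
                 chrom_subset: Optional[Sequence[str]] = None) -> None:
        chroms = sorted(blocks) if chrom_subset is None else list(chrom_subset)
        self.chroms = chroms
        self.block_chrom: List[str] = []
        starts, ends = [], []
        for c in chroms:
            for s, e in blocks[c]:
                self.block_chrom.append(c)
                starts.append(s)
                ends.append(e)
        self.block_start = np.asarray(starts, dtype=np.int64)
        self.block_end = np.asarray(ends, dtype=np.int64)
        self._cache: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}

    def capacity(self, length: int) -> Tuple[np.ndarray, int]:
        if length not in self._cache:
            cap = np.maximum(self.block_end - self.block_start - length + 1, 0)
            cum = np.concatenate([[0], np.cumsum(cap)])
            self._cache[length] = (cum, int(cum[-1]))
        return self._cache[length]

    def sample(self, length: int, n: int, rng: np.random.Generator
               ) -> Tuple[List[str], np.ndarray]:
        cum, total = self.capacity(length)
        if total <= 0:
            raise ValueError(
                f"no gap-free stretch can hold an interval of length {length}"
            )
        u = rng.integers(0, total, size=n)
        bi = np.searchsorted(cum, u, side="right") - 1
        starts = self.block_start[bi] + (u - cum[bi])
        chroms = [self.block_chrom[i] for i in bi]
        return chroms, starts


def shuffle_starts(
    regions: RegionSet,
    genome: Genome,
    config: ShuffleConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized placement of all iterations at once.

    Returns ``(chrom_idx, starts, lengths)``: ``chrom_idx`` and ``starts``
    have shape ``(n_iterations, n_intervals)``; ``chrom_idx`` indexes
    ``sorted(genome.lengths)``; ``lengths`` has shape ``(n_intervals,)``.
    """
    rng = np.random.default_rng(config.seed)
    blocks = allowed_blocks(genome, config.exclude)
    chrom_names = sorted(genome.lengths)
    chrom_index = {c: i for i, c in enumerate(chrom_names)}
    lengths = regions.lengths()
    n_int = len(lengths)
    n_iter = config.n_iterations
    chrom_out = np.empty((n_iter, n_int), dtype=np.int32)
    start_out = np.empty((n_iter, n_int), dtype=np.int64)
    if config.preserve_chromosome:
        samplers = {c: _PlacementSampler(blocks, [c]) for c in chrom_names}
        src_chroms = regions.df["chrom"].to_numpy()
        for j in range(n_int):
            smp = samplers[src_chroms[j]]
            cs, ss = smp.sample(int(lengths[j]), n_iter, rng)
            chrom_out[:, j] = [chrom_index[c] for c in cs]
            start_out[:, j] = ss
    else:
        sampler = _PlacementSampler(blocks)
        # group intervals by length so draws vectorize
        for L in np.unique(lengths):
            cols = np.nonzero(lengths == L)[0]
            cs, ss = sampler.sample(int(L), n_iter * len(cols), rng)
            ci = np.fromiter((chrom_index[c] for c in cs), dtype=np.int32,
                             count=len(cs))
            chrom_out[:, cols] = ci.reshape(n_iter, len(cols))
            start_out[:, cols] = ss.reshape(n_iter, len(cols))
    return chrom_out, start_out, lengths


def shuffle_regions(
    regions: RegionSet, genome: Genome, config: ShuffleConfig
) -> List[RegionSet]:
    """One shuffled :class:`RegionSet` per iteration.

    Each output interval keeps the length (and score) of its source interval;
    no output interval overlaps the exclusion mask; placement is uniform over
    allowed positions and deterministic given ``config.seed``.
    """
    chrom_idx, starts, lengths = shuffle_starts(regions, genome, config)
    chrom_names = np.array(sorted(genome.lengths), dtype=object)
    scores = regions.df["score"].to_numpy()
    out = []
    for it in range(config.n_iterations):
        rs = RegionSet.from_arrays(
            chrom_names[chrom_idx[it]], starts[it], starts[it] + lengths,
            scores, name=f"{regions.name}_shuffle{it}", validate=False,
        )
        out.append(rs)
    return out


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def composition_vector(regions: RegionSet, genome: Genome) -> CompositionVector:
    """Pooled A/C/G/T fractions over all intervals (N bases excluded)."""
    counts = np.zeros(4, dtype=np.int64)
    for chrom, g in regions.df.groupby("chrom", sort=False):
        cc = genome.base_cumcounts(str(chrom))
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        counts += (cc[:, ends].astype(np.int64) - cc[:, starts].astype(np.int64)).sum(axis=1)
    total = counts.sum()
    if total == 0:
        raise ValueError("region set covers no non-N sequence")
    f = counts / total
    return CompositionVector(*f)


def composition_matrix(
    region_sets: Sequence[RegionSet], genome: Genome
) -> np.ndarray:
    """(n_sets, 4) A/C/G/T fraction matrix."""
    return np.array([composition_vector(rs, genome).as_array()
                     for rs in region_sets])


def select_composition_matched(
    shuffles: Sequence[RegionSet],
    target: RegionSet,
    genome: Optional[Genome] = None,
    sd_window: float = 2.0,
    comps: Optional[np.ndarray] = None,
    target_comp: Optional[np.ndarray] = None,
) -> Tuple[List[int], "np.ndarray"]:
    """Select shuffles whose base composition matches the target.

    Each base column of the shuffle composition matrix is z-normalized with
    the shuffle population's mean/sd; the target's composition is z-scored
    under the same mean/sd.  A shuffle is selected iff for every base
    ``|z(shuffle) - z(target)| <= sd_window``.  Zero-variance columns are
    ignored with a warning.  ``comps``/``target_comp`` allow supplying
    precomputed composition rows (rows of A/C/G/T fractions).

    Returns ``(selected_indices, z_table)`` where the z-table has one row per
    shuffle plus a final row for the target.
    """
    if sd_window <= 0:
        raise ValueError("sd_window must be > 0")
    if comps is None:
        if genome is None:
            raise ValueError("need a genome (or precomputed comps)")
        comps = composition_matrix(shuffles, genome)
    comps = np.asarray(comps, dtype=float)
    if comps.shape[0] < 10:
        raise ValueError("need >= 10 shuffles for a meaningful z-score")
    if target_comp is None:
        if genome is None:
            raise ValueError("need a genome (or precomputed target_comp)")
        target_comp = composition_vector(target, genome).as_array()
    mean = comps.mean(axis=0)
    sd = comps.std(axis=0, ddof=0)
    usable = sd > 0
    if not usable.all():
        warnings.warn(
            f"zero variance in base column(s) {np.nonzero(~usable)[0].tolist()}; "
            "ignored for matching", stacklevel=2,
        )
    z = np.zeros_like(comps)
    zt = np.zeros(4)
    z[:, usable] = (comps[:, usable] - mean[usable]) / sd[usable]
    zt[usable] = (np.asarray(target_comp, dtype=float)[usable] - mean[usable]) / sd[usable]
    ok = (np.abs(z[:, usable] - zt[usable]) <= sd_window).all(axis=1)
    z_table = np.vstack([z, zt])
    return list(np.nonzero(ok)[0]), z_table
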