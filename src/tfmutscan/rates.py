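"""Regional mutation rates and shuffle-based empirical enrichment tests.

The central statistic is the SNV (or indel) rate per megabase over a region
set, pooled across the cohort.  Significance comes from an empirical null:
the same rate computed on each of ``n_iterations`` shuffled copies of the
region set.  Two p-values are reported:

* ``p_raw`` — the plain fraction of null rates >= observed (this is the
  quantity whose value 0 is conventionally reported as "empirical FDR = 0");
* ``p_add_one`` — ``(1 + #null >= observed) / (n_iterations + 1)``, which can
  never be 0 and is exactly uniform under the null, so it is the version used
  for calibration and multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import MutationCatalog, snv_positions_0based
from .intervals import (
    Genome,
    RegionSet,
    closest_distance,
    intersect_count,
    merge_within,
    NO_TARGET,
)
from .randomization import ShuffleConfig, shuffle_starts

__all__ = [
    "EnrichmentResult",
    "QuartileResult",
    "mutation_rate",
    "enrichment_test",
    "normalized_rate_by_cohort",
    "quartile_rates",
    "breakpoint_distance_distribution",
    "bh_adjust",
]

QUARTILE_LABELS = ["low", "low-medium", "medium-high", "high"]


@dataclass
class EnrichmentResult:
    """Observed rate vs the shuffle null for one region set."""

    region_set_name: str
    observed_rate: float
    null_rates: np.ndarray
    fold: float
    p_raw: float
    p_add_one: float
    n_iterations: int
    which: str = "snv"

    @property
    def null_mean(self) -> float:
        return float(self.null_rates.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_rates.std(ddof=1)) if len(self.null_rates) > 1 else 0.0

    def to_row(self) -> Dict[str, float]:
        return {
            "region_set": self.region_set_name,
            "which": self.which,
            "observed_rate_per_mb": self.observed_rate,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "fold": self.fold,
            "p_raw": self.p_raw,
            "p_add_one": self.p_add_one,
            "n_iterations": self.n_iterations,
        }


@dataclass
class QuartileResult:
    """Peak-height quartiles (low -> high) with per-quartile SNV rates."""

    quartiles: List[RegionSet]
    rates: List[float]
    labels: List[str] = field(default_factory=lambda: list(QUARTILE_LABELS))


def mutation_rate(
    regions: RegionSet, catalog: MutationCatalog, which: str = "snv"
) -> float:
    """Pooled mutation rate per Mb over a region set.

    ``regions`` should be merged (non-overlapping) so base pairs are not
    double-counted in the denominator.
    """
    bp = regions.total_bp
    if bp == 0:
        raise ValueError("region set covers 0 bp")
    if which not in ("snv", "indel"):
        raise ValueError("which must be 'snv' or 'indel'")
    df = catalog.snvs if which == "snv" else catalog.indels
    counts, _ = intersect_count(regions, df)
    return float(counts.sum()) / bp * 1e6


def _null_counts(
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    lengths: np.ndarray,
    positions: Mapping[str, np.ndarray],
    chrom_names: Sequence[str],
) -> np.ndarray:
    """Total mutation count per shuffle iteration (vectorized)."""
    n_iter, n_int = chrom_idx.shape
    counts = np.zeros(n_iter, dtype=np.int64)
    flat_chrom = chrom_idx.ravel()
    flat_start = starts.ravel()
    flat_len = np.tile(lengths, n_iter)
    iter_of = np.repeat(np.arange(n_iter), n_int)
    for ci, chrom in enumerate(chrom_names):
        sel = flat_chrom == ci
        if not sel.any():
            continue
        pos = positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        s = flat_start[sel]
        e = s + flat_len[sel]
        c = np.searchsorted(pos, e, side="left") - np.searchsorted(pos, s, side="left")
        np.add.at(counts, iter_of[sel], c)
    return counts


def enrichment_test(
    regions: RegionSet,
    catalog: MutationCatalog,
    genome: Genome,
    config: ShuffleConfig,
    which: str = "snv",
) -> EnrichmentResult:
    """Empirical enrichment of the regional mutation rate over a shuffle null.

    The observed rate is compared with the rate of each of
    ``config.n_iterations`` length-preserving shuffles of the region set
    (ties count as >= observed).  The full null vector is retained.
    """
    observed = mutation_rate(regions, catalog, which=which)
    chrom_idx, starts, lengths = shuffle_starts(regions, genome, config)
    positions = catalog.positions_by_chrom(which=which)
    chrom_names = sorted(genome.lengths)
    counts = _null_counts(chrom_idx, starts, lengths, positions, chrom_names)
    total_bp = int(lengths.sum())
    null_rates = counts / total_bp * 1e6
    n_ge = int((null_rates >= observed).sum())
    n = config.n_iterations
    null_mean = float(null_rates.mean())
    if observed == 0:
        fold = 0.0
    elif null_mean == 0:
        fold = float("inf")
    else:
        fold = observed / null_mean
    return EnrichmentResult(
        region_set_name=regions.name,
        observed_rate=observed,
        null_rates=null_rates,
        fold=fold,
        p_raw=n_ge / n,
        p_add_one=(1 + n_ge) / (n + 1),
        n_iterations=n,
        which=which,
    )


def normalized_rate_by_cohort(
    regions: RegionSet,
    catalogs: Mapping[str, MutationCatalog],
    genome: Genome,
) -> pd.DataFrame:
    """Per-sample regional rate normalized by that sample's genome-wide rate.

    For each sample, the ratio (rate at regions) / (genome-wide rate) is
    computed over the non-gap genome; a cohort's value is the distribution of
    these ratios (returned per sample; take the median per cohort for the
    cross-cancer comparison).  Samples with zero genome-wide mutations are
    excluded with a warning.
    """
    import warnings

    bp_regions = regions.total_bp
    if bp_regions == 0:
        raise ValueError("region set covers 0 bp")
    bp_genome = genome.non_gap_bp()
    rows = []
    for cohort, catalog in catalogs.items():
        counts, _ = intersect_count(regions, catalog.snvs)
        per_sample_region = (
            intersect_count(regions, catalog.snvs)[1]
            .groupby("sample_id").size() if len(catalog.snvs) else pd.Series(dtype=int)
        )
        per_sample_total = catalog.snvs.groupby("sample_id").size()
        for sample in sorted(catalog.samples):
            total = int(per_sample_total.get(sample, 0))
            if total == 0:
                warnings.warn(
                    f"sample {sample!r} ({cohort}) has zero genome-wide "
                    "mutations; excluded", stacklevel=2,
                )
                continue
            n_reg = int(per_sample_region.get(sample, 0))
            rate_reg = n_reg / bp_regions * 1e6
            rate_gen = total / bp_genome * 1e6
            rows.append((cohort, sample, n_reg, total,
                         rate_reg, rate_gen, rate_reg / rate_gen))
    return pd.DataFrame(
        rows,
        columns=["cancer_type", "sample_id", "n_in_regions", "n_total",
                 "rate_regions_per_mb", "rate_genome_per_mb", "normalized_rate"],
    )


def quartile_rates(
    regions: RegionSet, catalog: MutationCatalog, which: str = "snv"
) -> QuartileResult:
    """Split peaks into four equal-count groups by score and rate each group.

    Peaks are sorted by score ascending (ties broken by genomic order) and
    split into quartiles low -> high; group sizes differ by at most 1.
    """
    if len(regions) < 4:
        raise ValueError("need >= 4 scored intervals for quartiles")
    df = regions.df
    if df["score"].isna().any():
        raise ValueError("all intervals must carry a score")
    genomic = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    ordered = genomic.sort_values("score", kind="mergesort")
    groups = np.array_split(np.arange(len(ordered)), 4)
    quartiles, rates_ = [], []
    for g in groups:
        sub = RegionSet(ordered.iloc[g], name=regions.name, validate=False)
        quartiles.append(sub)
        rates_.append(mutation_rate(sub, catalog, which=which))
    return QuartileResult(quartiles, rates_)


def breakpoint_distance_distribution(
    catalog: MutationCatalog,
    breakpoints: Mapping[str, RegionSet],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Distance from each SNV to its sample's nearest breakpoint.

    ``breakpoints`` maps sample_id -> breakpoint region set.  Returns
    (per-SNV table, per-sample quantile summary); SNVs of samples without
    breakpoints get the sentinel distance -1 and are flagged.
    """
    rows = []
    for sample, g in catalog.snvs.groupby("sample_id", sort=True):
        bp = breakpoints.get(str(sample))
        if bp is None or not len(bp):
            dist = {c: np.full(len(sub), NO_TARGET)
                    for c, sub in g.groupby("chrom")}
            flagged = True
        else:
            pts = {str(c): snv_positions_0based(sub)
                   for c, sub in g.groupby("chrom")}
            dist = closest_distance(pts, bp)
            flagged = False
        for (c, sub) in g.groupby("chrom"):
            for pos, d in zip(sub["pos"], dist[str(c)]):
                rows.append((sample, str(c), int(pos), int(d), flagged))
    table = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "distance", "no_breakpoints"]
    )
    ok = table[~table["no_breakpoints"] & (table["distance"] != NO_TARGET)]
    summary = (
        ok.groupby("sample_id")["distance"]
        .quantile([0.25, 0.5, 0.75]).unstack()
        .rename(columns={0.25: "q25", 0.5: "median", 0.75: "q75"})
        if len(ok) else pd.DataFrame(columns=["q25", "median", "q75"])
    )
    return table, summary


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
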