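"""Peak-centered mutation-density profiles.

For every region the signed offsets of nearby mutations to the peak center
are collected; offsets are pooled over regions, histogrammed in fixed-width
bins and smoothed with a Gaussian kernel.  A mutation lying within the window
of two peaks contributes one offset per peak (pooled-offset semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .catalog import MutationCatalog, snv_positions_0based
from .intervals import RegionSet

__all__ = ["ProfileCurve", "aggregate_profile", "profile_contrast"]


@dataclass
class ProfileCurve:
    """Smoothed mutation density vs distance to peak center."""

    bin_centers: np.ndarray   # bp offsets, symmetric about 0
    raw_counts: np.ndarray    # unsmoothed per-bin offset counts
    density: np.ndarray       # smoothed, in the units given by `mode`
    window: int
    bin: int
    bandwidth: float
    mode: str                 # "count" or "frequency"
    n_pairs: int              # pooled (region, mutation) offset pairs
    is_flat_zero: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset_bp": self.bin_centers,
             "raw_count": self.raw_counts,
             "density": self.density}
        )


def peak_centers(regions: RegionSet) -> pd.DataFrame:
    df = regions.df
    centers = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    return pd.DataFrame({"chrom": df["chrom"].to_numpy(), "center": centers})


def pooled_offsets(
    regions: RegionSet, catalog, window: int
) -> np.ndarray:
    """Signed offsets (mutation - center) pooled over regions, |offset|<=window."""
    snvs = catalog.snvs if hasattr(catalog, "snvs") else catalog
    cen = peak_centers(regions)
    out = []
    pos_by_chrom: Dict[str, np.ndarray] = {
        str(c): np.sort(snv_positions_0based(g))
        for c, g in snvs.groupby("chrom", sort=False)
    }
    for chrom, g in cen.groupby("chrom", sort=False):
        pos = pos_by_chrom.get(str(chrom))
        if pos is None:
            continue
        for c in g["center"].to_numpy():
            lo = np.searchsorted(pos, c - window, side="left")
            hi = np.searchsorted(pos, c + window, side="right")
            if hi > lo:
                out.append(pos[lo:hi] - c)
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def aggregate_profile(
    regions: RegionSet,
    catalog,
    window: int = 5000,
    bin: int = 100,
    bandwidth: float = 100.0,
    mode: str = "count",
) -> ProfileCurve:
    """Aggregate mutation density around peak centers.

    The peak center is ``floor((start+end)/2)``.  Bins are centered on
    multiples of ``bin`` from -window to +window (so window=5000, bin=100
    gives 101 bins); smoothing is a Gaussian kernel with the given bandwidth
    (bp).  ``mode='frequency'`` normalizes the smoothed curve to sum 1.
    """
    if window <= 0 or bin <= 0:
        raise ValueError("window and bin must be > 0")
    if mode not in ("count", "frequency"):
        raise ValueError("mode must be 'count' or 'frequency'")
    offsets = pooled_offsets(regions, catalog, window)
    centers = np.arange(-window, window + 1, bin)
    edges = np.arange(-window - bin / 2, window + bin, bin)
    raw, _ = np.histogram(offsets, bins=edges)
    flat = len(offsets) == 0
    smoothed = gaussian_filter1d(
        raw.astype(float), sigma=bandwidth / bin, mode="constant", cval=0.0
    )
    if mode == "frequency" and smoothed.sum() > 0:
        smoothed = smoothed / smoothed.sum()
    return ProfileCurve(
        bin_centers=centers,
        raw_counts=raw,
        density=smoothed,
        window=window,
        bin=bin,
        bandwidth=bandwidth,
        mode=mode,
        n_pairs=int(len(offsets)),
        is_flat_zero=flat,
    )


def profile_contrast(
    curve_a: ProfileCurve, curve_b: ProfileCurve
) -> pd.DataFrame:
    """Per-bin ratio and difference of two identically binned curves.

    The ratio is NaN where curve_b is zero.
    """
    if (curve_a.window, curve_a.bin) != (curve_b.window, curve_b.bin) or len(
        curve_a.bin_centers
    ) != len(curve_b.bin_centers):
        raise ValueError("profiles have mismatched binning")
    a = curve_a.density
    b = curve_b.density
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, a / np.where(b > 0, b, 1.0), np.nan)
    return pd.DataFrame(
        {"offset_bp": curve_a.bin_centers,
         "ratio": ratio,
         "difference": a - b}
    )
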