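"""PWM scanning for motif-alone control regions.

A "motif alone" region carries the TF's recognition sequence (e.g., the
androgen response element) without ChIP-seq evidence of bound protein; such
regions control for nucleotide composition in the rate and signature
analyses.  Scanning is log-odds (base 2) over both strands with the score
threshold expressed as a fraction of the maximum achievable score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import Genome, RegionSet, overlaps_any

__all__ = ["PWM", "read_jaspar", "scan_pwm", "motif_alone_regions", "are_pwm"]

_BASES = "ACGT"


@dataclass
class PWM:
    """A position weight matrix (rows A, C, G, T; one column per position)."""

    name: str
    matrix: np.ndarray                     # 4 x L counts or probabilities
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("matrix must be 4 x L")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if abs(self.background.sum() - 1) > 1e-6:
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def probabilities(self) -> np.ndarray:
        """Column-normalized probabilities with background-split pseudocount."""
        m = self.matrix + self.pseudocount * self.background[:, None]
        p = m / m.sum(axis=0, keepdims=True)
        return p

    def log_odds(self) -> np.ndarray:
        """log2(p / background) per base and position."""
        return np.log2(self.probabilities() / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probabilities().argmax(axis=0))


def read_jaspar(path) -> List[PWM]:
    """Read PWMs from a JASPAR-format PFM file (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            mat = np.array([m.counts[b] for b in _BASES], dtype=float)
            out.append(PWM(name=m.name or m.matrix_id or "pwm", matrix=mat))
    return out


def are_pwm() -> PWM:
    """Built-in toy androgen-response-element PWM.

    The ARE is a 15-bp palindrome of two AGAACA hexamer half-sites separated
    by a 3-bp spacer (AGAACAnnnTGTTCT); the spacer columns are uniform.
    """
    consensus = "AGAACA" + "NNN" + "TGTTCT"
    mat = np.ones((4, 15))  # 1 pseudo-observation everywhere
    for j, b in enumerate(consensus):
        if b != "N":
            mat[_BASES.index(b), j] = 20.0
    return PWM(name="ARE", matrix=mat)


def scan_pwm(
    genome: Genome, pwm: PWM, score_threshold: float = 0.8
) -> RegionSet:
    """Scan both strands of a genome for PWM matches.

    Windows score >= ``score_threshold * max_score`` are reported with strand
    and score.  Windows containing N are skipped.  A window matching on both
    strands (palindrome) is reported once with strand '.'.
    """
    if not (0 < score_threshold <= 1):
        raise ValueError("score_threshold must be in (0, 1]")
    lod = pwm.log_odds()
    L = pwm.length
    # minus-strand scan = plus-strand scan of the reverse-complemented matrix
    lod_rc = lod[::-1, ::-1]
    cutoff = score_threshold * pwm.max_score()
    rows = []
    for chrom in sorted(genome.sequences):
        c = genome.codes(chrom)
        n = len(c)
        if n < L:
            continue
        nw = n - L + 1
        valid = np.ones(nw, dtype=bool)
        score_p = np.zeros(nw)
        score_m = np.zeros(nw)
        for j in range(L):
            cj = c[j : j + nw]
            bad = cj == 4
            if bad.any():
                valid &= ~bad
            cj_safe = np.where(bad, 0, cj)
            score_p += lod[cj_safe, j]
            score_m += lod_rc[cj_safe, j]
        hit_p = valid & (score_p >= cutoff)
        hit_m = valid & (score_m >= cutoff)
        both = hit_p & hit_m
        for i in np.nonzero(both)[0]:
            rows.append((chrom, i, i + L, max(score_p[i], score_m[i]), "."))
        for i in np.nonzero(hit_p & ~both)[0]:
            rows.append((chrom, i, i + L, score_p[i], "+"))
        for i in np.nonzero(hit_m & ~both)[0]:
            rows.append((chrom, i, i + L, score_m[i], "-"))
    rows.sort(key=lambda r: (r[0], r[1]))
    if not rows:
        return RegionSet(name=f"{pwm.name}_matches")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "strand"])
    return RegionSet(df, name=f"{pwm.name}_matches",
                     provenance=f"scan_pwm(threshold={score_threshold})",
                     validate=False)


def motif_alone_regions(matches: RegionSet, bound: RegionSet) -> RegionSet:
    """Motif matches with no overlap with the bound (ChIP-seq) peak set.

    Whole-match removal: any match overlapping a bound peak by >= 1 bp is
    dropped entirely.
    """
    if not len(bound):
        return RegionSet(matches.df, name=f"{matches.name}_alone", validate=False)
    keep = ~overlaps_any(matches, bound)
    return RegionSet(matches.df[keep], name=f"{matches.name}_alone",
                     provenance="motif_alone_regions", validate=False)
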