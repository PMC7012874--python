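"""96-channel trinucleotide mutational spectra and cosine-similarity analysis.

Every SNV is assigned to one of 96 classes defined by the pyrimidine-collapsed
substitution (C>A, C>G, C>T, T>A, T>C, T>G) and the 5'/3' flanking bases on
the pyrimidine strand.  When the reference base is a purine, the substitution
and its context are reverse-complemented before classification, so a catalog
and its strand-complemented image yield identical spectra.

Class order is fixed and lexicographic: substitution class first
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' base, then 3' base, each A<C<G<T.
Index of class = 16*substitution + 4*five_prime + three_prime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .catalog import MutationCatalog, snv_positions_0based
from .intervals import Genome, RegionSet

__all__ = [
    "SUBSTITUTIONS",
    "CLASS_LABELS",
    "SpectrumVector",
    "SimilarityMatrix",
    "ClusterResult",
    "classify_snv",
    "classify_catalog",
    "spectrum",
    "min_mutation_filter",
    "cosine_similarity",
    "similarity_matrix",
    "cluster_spectra",
    "compare_to_reference",
    "cpg_fraction",
    "context_ids",
    "class_to_context",
    "toy_reference_signatures",
    "read_reference_signatures",
    "write_spectra_tsv",
    "ReferenceMismatchError",
]

BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
# alt base for each substitution index, on the pyrimidine strand
_ALT_PYR = "AGTACG"  # C>A, C>G, C>T, T>A, T>C, T>G
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

CLASS_LABELS: List[str] = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]

# map (pyrimidine ref base, alt base on pyr strand) -> substitution index
_SUB_INDEX = {("C", "A"): 0, ("C", "G"): 1, ("C", "T"): 2,
              ("T", "A"): 3, ("T", "C"): 4, ("T", "G"): 5}


class ReferenceMismatchError(ValueError):
    """The genome base at an SNV position does not equal the record's ref."""


@dataclass
class SpectrumVector:
    """96-channel mutation-type counts for one region set / cohort."""

    counts: np.ndarray
    label: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("counts must have shape (96,)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        n = self.n_mutations
        if n == 0:
            return np.zeros(96)
        return self.counts / n

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CLASS_LABELS, name=self.label)


@dataclass
class SimilarityMatrix:
    """Pairwise cosine similarities between labelled spectra."""

    labels: List[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class ClusterResult:
    similarity: SimilarityMatrix
    linkage: np.ndarray
    leaf_order: List[str]
    flat: Dict[str, int]


# ---------------------------------------------------------------------------
# Context machinery
# ---------------------------------------------------------------------------

def context_ids(genome: Genome, chrom: str) -> np.ndarray:
    """Per-position collapsed trinucleotide context id (int16), cached.

    Context id = 16*pyr + 4*five + three where pyr is 0 for C / 1 for T on
    the pyrimidine strand and five/three are flank base codes on that strand.
    Positions whose base or either flank is N, and chromosome-edge positions,
    get -1.
    """
    cache = genome._context_ids
    if chrom in cache:
        return cache[chrom]
    c = genome.codes(chrom).astype(np.int16)
    n = len(c)
    out = np.full(n, -1, dtype=np.int16)
    if n >= 3:
        mid = c[1:-1]
        left = c[:-2]
        right = c[2:]
        valid = (mid < 4) & (left < 4) & (right < 4)
        pyr_mid = (mid == 1) | (mid == 3)  # C or T
        # pyrimidine strand flanks: as-is for C/T, reverse-complement for A/G
        pyr = np.where(pyr_mid, (mid == 3).astype(np.int16),
                       (mid == 0).astype(np.int16))  # G->C(0), A->T(1)
        five = np.where(pyr_mid, left, 3 - right)
        three = np.where(pyr_mid, right, 3 - left)
        ids = (16 * pyr + 4 * five + three).astype(np.int16)
        out[1:-1] = np.where(valid, ids, -1)
    cache[chrom] = out
    return out


def class_to_context(class_idx: int) -> int:
    """Context id (0..31) in which a 96-class mutation can occur."""
    sub = class_idx // 16
    return 16 * (sub // 3) + class_idx % 16


def classify_snv(snv, genome: Genome) -> Optional[int]:
    """Class index (0..95) of one SNV, or None if a flank is N / at an edge.

    Raises :class:`ReferenceMismatchError` when the genome base at the SNV
    position differs from the record's ref allele.
    """
    chrom, pos, ref, alt = snv.chrom, snv.pos, snv.ref, snv.alt
    seq = genome.sequences[chrom]
    p0 = pos - 1
    base = seq[p0]
    if base != ref:
        raise ReferenceMismatchError(
            f"{chrom}:{pos} genome has {base}, record says {ref}"
        )
    if p0 == 0 or p0 == len(seq) - 1:
        return None
    left, right = seq[p0 - 1], seq[p0 + 1]
    if "N" in (left, right, ref, alt):
        return None
    if ref in "AG":  # collapse to pyrimidine strand
        ref, alt = _COMP[ref], _COMP[alt]
        left, right = _COMP[right], _COMP[left]
    sub = _SUB_INDEX[(ref, alt)]
    return 16 * sub + 4 * BASES.index(left) + BASES.index(right)


def classify_catalog(
    snvs: pd.DataFrame, genome: Genome, strict: bool = True
) -> Tuple[np.ndarray, int]:
    """Vectorized 96-class assignment for a SNV DataFrame.

    Returns ``(classes, n_skipped)`` where classes is -1 for skipped records
    (N flank or chromosome edge).  Reference mismatches raise when ``strict``.
    """
    snvs = snvs.reset_index(drop=True)
    classes = np.full(len(snvs), -1, dtype=np.int64)
    n_skipped = 0
    alt_codes_pyr = {("C", "A"): 0, ("C", "G"): 1, ("C", "T"): 2,
                     ("T", "A"): 3, ("T", "C"): 4, ("T", "G"): 5,
                     ("G", "T"): 0, ("G", "C"): 1, ("G", "A"): 2,
                     ("A", "T"): 3, ("A", "G"): 4, ("A", "C"): 5}
    for chrom, g in snvs.groupby("chrom", sort=False):
        codes = genome.codes(str(chrom))
        ctx = context_ids(genome, str(chrom))
        p0 = snv_positions_0based(g)
        refs = g["ref"].to_numpy()
        ref_codes = np.array([BASES.index(r) for r in refs])
        if strict:
            bad = codes[p0] != ref_codes
            if bad.any():
                i = int(np.nonzero(bad)[0][0])
                r = g.iloc[i]
                raise ReferenceMismatchError(
                    f"{chrom}:{r.pos} genome base != ref {r.ref}"
                )
        cids = ctx[p0]
        subs = np.array([alt_codes_pyr[(r, a)]
                         for r, a in zip(refs, g["alt"].to_numpy())])
        cls = 16 * subs + (cids % 16)
        cls[cids < 0] = -1
        n_skipped += int((cids < 0).sum())
        classes[g.index.to_numpy()] = cls
    return classes, n_skipped


def spectrum(
    snvs: pd.DataFrame, genome: Genome, label: str = ""
) -> SpectrumVector:
    """96-channel spectrum of a set of SNV records.

    Records whose flanking base is N or that sit at a chromosome edge are
    skipped and counted on ``n_skipped``.
    """
    if not len(snvs):
        return SpectrumVector(np.zeros(96, dtype=np.int64), label)
    snvs = snvs.reset_index(drop=True)
    classes, n_skipped = classify_catalog(snvs, genome)
    counts = np.bincount(classes[classes >= 0], minlength=96)
    return SpectrumVector(counts, label, n_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Similarity, filtering, clustering
# ---------------------------------------------------------------------------

def min_mutation_filter(
    spectra: Sequence[SpectrumVector], threshold: int = 480
) -> Tuple[List[SpectrumVector], List[str]]:
    """Drop spectra with fewer than ``threshold`` mutations (strict <).

    The default of 480 mutations is the published minimum for deciphering two
    mixed signatures with > 0.95 accuracy.  Returns (kept, removed_labels).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = [s for s in spectra if s.n_mutations >= threshold]
    removed = [s.label for s in spectra if s.n_mutations < threshold]
    return kept, removed


def cosine_similarity(a, b) -> float:
    """Cosine similarity of two spectra (or raw 96-vectors)."""
    va = a.frequencies if isinstance(a, SpectrumVector) else np.asarray(a, float)
    vb = b.frequencies if isinstance(b, SpectrumVector) else np.asarray(b, float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero spectrum")
    return float(va @ vb / (na * nb))


def similarity_matrix(spectra: Sequence[SpectrumVector]) -> SimilarityMatrix:
    labels = [s.label for s in spectra]
    n = len(spectra)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = cosine_similarity(spectra[i], spectra[j])
    return SimilarityMatrix(labels, m)


def cluster_spectra(
    spectra: Sequence[SpectrumVector],
    n_clusters: Optional[int] = None,
    cut_height: Optional[float] = None,
    linkage_method: str = "average",
) -> ClusterResult:
    """Hierarchical clustering of spectra on distance 1 - cosine.

    Average linkage by default.  Flat clusters are cut either to
    ``n_clusters`` groups or at ``cut_height`` on the 1-cosine scale
    (default: number of groups found at half the maximum merge height).
    """
    if len(spectra) < 2:
        raise ValueError("need >= 2 spectra to cluster")
    sim = similarity_matrix(spectra)
    dist = np.clip(1.0 - sim.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    leaves = hierarchy.leaves_list(Z)
    if n_clusters is not None:
        flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        t = cut_height if cut_height is not None else max(Z[-1, 2] / 2, 1e-12)
        flat = hierarchy.fcluster(Z, t=t, criterion="distance")
    return ClusterResult(
        similarity=sim,
        linkage=Z,
        leaf_order=[sim.labels[i] for i in leaves],
        flat={sim.labels[i]: int(flat[i]) for i in range(len(spectra))},
    )


def compare_to_reference(
    spec: SpectrumVector, reference: pd.DataFrame
) -> Tuple[pd.Series, str]:
    """Cosine similarity against each column of a 96 x K reference matrix.

    Columns must be probability vectors over the 96 classes (sum 1 +/- 1e-6),
    indexed by class label.  Returns (similarities sorted descending, best).
    """
    ref = reference.reindex(CLASS_LABELS)
    if ref.isna().any().any():
        missing = reference.index.symmetric_difference(CLASS_LABELS)
        raise ValueError(f"reference index must be the 96 class labels "
                         f"(mismatch: {list(missing)[:4]} ...)")
    sums = ref.sum(axis=0)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(f"reference column(s) not normalized: "
                         f"{dict(bad.round(4))}")
    sims = pd.Series(
        {col: cosine_similarity(spec, ref[col].to_numpy()) for col in ref},
        name="cosine",
    ).sort_values(ascending=False)
    return sims, str(sims.index[0])


def cpg_fraction(snvs: pd.DataFrame, genome: Genome) -> float:
    """Fraction of C>T records occurring at a CpG dinucleotide.

    Records must be C>T on the pyrimidine-collapsed strand (ref C alt T, or
    ref G alt A on the opposite strand).  A record is CpG when the 3'
    neighbor of the mutated C on the pyrimidine strand is G.
    """
    if not len(snvs):
        raise ValueError("no records")
    is_ct = ((snvs["ref"] == "C") & (snvs["alt"] == "T"))
    is_ga = ((snvs["ref"] == "G") & (snvs["alt"] == "A"))
    if not (is_ct | is_ga).all():
        raise ValueError("records must all be C>T (or G>A) substitutions")
    n_cpg = 0
    for r in snvs.itertuples(index=False):
        seq = genome.sequences[r.chrom]
        p0 = r.pos - 1
        if r.ref == "C":
            n_cpg += p0 + 1 < len(seq) and seq[p0 + 1] == "G"
        else:  # ref G: pyrimidine strand is the minus strand
            n_cpg += p0 - 1 >= 0 and seq[p0 - 1] == "C"
    return n_cpg / len(snvs)


# ---------------------------------------------------------------------------
# Reference signature I/O and bundled toys
# ---------------------------------------------------------------------------

def toy_reference_signatures() -> pd.DataFrame:
    """Two synthetic reference columns for testing the comparison machinery.

    ``deamination_like`` concentrates on C>T at CpG (spontaneous deamination
    of 5-methylcytosine); ``abasic_like`` concentrates on T>A at TpG plus
    C>G at CpG (the A-rule outcome of unrepaired abasic sites).  These are
    synthetic stand-ins, not COSMIC signatures.
    """
    deam = np.full(96, 0.2 / 92)
    abasic = np.full(96, 0.3 / 88)
    for five in BASES:
        deam[CLASS_LABELS.index(f"{five}[C>T]G")] = 0.8 / 4
        abasic[CLASS_LABELS.index(f"{five}[T>A]G")] = 0.4 / 4
        abasic[CLASS_LABELS.index(f"{five}[C>G]G")] = 0.3 / 4
    return pd.DataFrame(
        {"deamination_like": deam / deam.sum(), "abasic_like": abasic / abasic.sum()},
        index=CLASS_LABELS,
    )


def read_reference_signatures(path) -> pd.DataFrame:
    """Read a 96 x K reference signature TSV (first column: class label)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise ValueError(f"expected 96 rows, got {df.shape[0]}")
    return df


def write_spectra_tsv(spectra: Sequence[SpectrumVector], path,
                      header: Optional[str] = None) -> None:
    """Write spectra as a TSV: class, then per-spectrum count and frequency."""
    df = pd.DataFrame(index=pd.Index(CLASS_LABELS, name="mutation_class"))
    for s in spectra:
        df[f"{s.label}_count"] = s.counts
        df[f"{s.label}_freq"] = s.frequencies
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g")
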