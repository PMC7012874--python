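"""Somatic mutation catalogs: VCF I/O, filtering, and the in-memory model.

A catalog pools per-sample somatic calls (PCAWG-style: one VCF per sample,
listed in a manifest).  SNVs and indels are kept in separate DataFrames; the
VAF and the number of supporting callers travel in the ``VAF`` and
``CALLERS`` INFO fields of the interchange VCF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .intervals import RegionSet, overlaps_any

__all__ = [
    "SNVRecord",
    "IndelRecord",
    "MutationCatalog",
    "read_vcf",
    "write_vcf",
    "filter_catalog",
    "read_manifest",
    "snv_positions_0based",
]

SNV_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "vaf", "caller_count"]
INDEL_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id"]

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class SNVRecord:
    """A somatic single-nucleotide variant (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    vaf: Optional[float] = None
    caller_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref not in _VALID or self.alt not in _VALID:
            raise ValueError(f"ref/alt must be A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0,1]")


@dataclass(frozen=True)
class IndelRecord:
    """A small insertion/deletion; ref and alt allele lengths differ."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.ref) == len(self.alt):
            raise ValueError("indel alleles must differ in length")


def _empty_snvs() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
        "ref": pd.Series(dtype=str), "alt": pd.Series(dtype=str),
        "sample_id": pd.Series(dtype=str), "vaf": pd.Series(dtype=float),
        "caller_count": pd.Series(dtype=float),
    })


def _empty_indels() -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64),
        "ref": pd.Series(dtype=str), "alt": pd.Series(dtype=str),
        "sample_id": pd.Series(dtype=str),
    })


@dataclass
class MutationCatalog:
    """Cohort-level mutation catalog (SNVs + indels across samples)."""

    snvs: pd.DataFrame = field(default_factory=_empty_snvs)
    indels: pd.DataFrame = field(default_factory=_empty_indels)
    samples: Set[str] = field(default_factory=set)
    cancer_type: str = ""

    def __post_init__(self) -> None:
        self.snvs = self.snvs.reset_index(drop=True)
        self.indels = self.indels.reset_index(drop=True)
        for df in (self.snvs, self.indels):
            extra = set(df["sample_id"]) - self.samples
            if extra:
                self.samples |= extra

    @property
    def n_snvs(self) -> int:
        return len(self.snvs)

    @property
    def n_indels(self) -> int:
        return len(self.indels)

    def subset_samples(self, samples: Iterable[str]) -> "MutationCatalog":
        samples = set(samples)
        return MutationCatalog(
            self.snvs[self.snvs["sample_id"].isin(samples)],
            self.indels[self.indels["sample_id"].isin(samples)],
            samples, self.cancer_type,
        )

    def positions_by_chrom(self, which: str = "snv") -> Dict[str, np.ndarray]:
        """Sorted 0-based positions per chromosome, pooled over samples."""
        df = self.snvs if which == "snv" else self.indels
        return {
            str(c): np.sort(snv_positions_0based(g))
            for c, g in df.groupby("chrom", sort=True)
        }


def snv_positions_0based(df: pd.DataFrame) -> np.ndarray:
    """THE 1-based -> 0-based conversion point for mutation positions."""
    return df["pos"].to_numpy(dtype=np.int64) - 1


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(
    paths: Sequence,
    sample_ids: Optional[Sequence[str]] = None,
    cancer_type: str = "",
) -> MutationCatalog:
    """Read one or more per-sample VCFs into a :class:`MutationCatalog`.

    Multi-allelic records are split by ALT allele before classification.
    Equal-length substitutions of length 1 are SNVs; alleles of unequal
    length are indels; records containing N (or equal-length MNVs) are
    dropped and counted in a warning.
    """
    from cyvcf2 import VCF

    if isinstance(paths, (str, Path)):
        paths = [paths]
    if sample_ids is not None and len(sample_ids) != len(paths):
        raise ValueError("sample_ids must match paths")
    snv_rows, indel_rows = [], []
    n_dropped = 0
    for k, path in enumerate(paths):
        sid = sample_ids[k] if sample_ids else Path(str(path)).name.split(".")[0]
        vcf = VCF(str(path))
        for v in vcf:
            ref = v.REF.upper()
            vaf = v.INFO.get("VAF")
            callers = v.INFO.get("CALLERS")
            for alt in v.ALT:
                alt = alt.upper()
                if len(ref) == 1 and len(alt) == 1:
                    if ref in _VALID and alt in _VALID and ref != alt:
                        snv_rows.append(
                            (v.CHROM, v.POS, ref, alt, sid,
                             np.nan if vaf is None else float(vaf),
                             np.nan if callers is None else float(callers))
                        )
                    else:
                        n_dropped += 1
                elif len(ref) != len(alt):
                    if set(ref) <= _VALID and set(alt) <= _VALID:
                        indel_rows.append((v.CHROM, v.POS, ref, alt, sid))
                    else:
                        n_dropped += 1
                else:
                    n_dropped += 1
        vcf.close()
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} record(s) with N alleles or MNVs",
                      stacklevel=2)
    snvs = (pd.DataFrame(snv_rows, columns=SNV_COLUMNS)
            if snv_rows else _empty_snvs())
    indels = (pd.DataFrame(indel_rows, columns=INDEL_COLUMNS)
              if indel_rows else _empty_indels())
    samples = set(sample_ids) if sample_ids else (
        set(snvs["sample_id"]) | set(indels["sample_id"])
    )
    return MutationCatalog(snvs, indels, samples, cancer_type)


def write_vcf(catalog: MutationCatalog, path, sample_id: Optional[str] = None,
              contigs: Optional[Dict[str, int]] = None) -> None:
    """Write a site-only VCF (one sample's records, or the whole catalog).

    This is the package's interchange format: VAF and caller count are stored
    as the INFO fields ``VAF`` and ``CALLERS``.
    """
    snvs = catalog.snvs
    indels = catalog.indels
    if sample_id is not None:
        snvs = snvs[snvs["sample_id"] == sample_id]
        indels = indels[indels["sample_id"] == sample_id]
    rows = pd.concat([
        snvs.assign(_kind="snv"),
        indels.assign(vaf=np.nan, caller_count=np.nan, _kind="indel"),
    ]).sort_values(["chrom", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for c, ln in sorted(contigs.items()):
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,'
                 'Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=CALLERS,Number=1,Type=Integer,'
                 'Description="Number of supporting callers">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in rows.itertuples(index=False):
            info = []
            if not pd.isna(r.vaf):
                info.append(f"VAF={r.vaf:.4f}")
            if not pd.isna(r.caller_count):
                info.append(f"CALLERS={int(r.caller_count)}")
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                + (";".join(info) or ".") + "\n"
            )


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest TSV with columns sample_id, path, cancer_type."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {required}, got {list(df.columns)}")
    if "cancer_type" not in df.columns:
        df["cancer_type"] = ""
    return df


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_catalog(
    catalog: MutationCatalog,
    min_callers: int = 1,
    exclude_positions: Optional[RegionSet] = None,
) -> Tuple[MutationCatalog, Dict[str, int]]:
    """Apply the caller-support and known-position exclusion filters.

    ``exclude_positions`` generalizes a dbSNP-style mask: any SNV whose
    (0-based) position falls inside the set is removed.  Returns the filtered
    catalog plus a report of kept/removed counts per criterion.
    """
    snvs = catalog.snvs
    keep = np.ones(len(snvs), dtype=bool)
    report = {"input": len(snvs), "removed_callers": 0, "removed_excluded": 0}
    if min_callers > 1:
        cc = snvs["caller_count"]
        if cc.isna().any():
            raise ValueError(
                "caller_count missing for some records; set min_callers=1 "
                "to disable the caller-support filter"
            )
        fail = (cc < min_callers).to_numpy()
        report["removed_callers"] = int(fail.sum())
        keep &= ~fail
    if exclude_positions is not None and len(exclude_positions) and len(snvs):
        pos_rs = RegionSet.from_arrays(
            snvs["chrom"], snv_positions_0based(snvs),
            snv_positions_0based(snvs) + 1, validate=False,
        )
        inside = overlaps_any(pos_rs, exclude_positions)
        report["removed_excluded"] = int((keep & inside).sum())
        keep &= ~inside
    report["kept"] = int(keep.sum())
    out = MutationCatalog(
        snvs[keep], catalog.indels, set(catalog.samples), catalog.cancer_type
    )
    return out, report
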