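"""Synthetic genomes, peak sets, mutation catalogs and methylation tracks.

The generator emulates the statistical structure the analysis assumes so that
every pipeline stage can be tested by parameter recovery:

* an i.i.d. genome at a stated GC content with N-run gaps recorded in a mask;
* TF peak sets placed uniformly over the gap-free genome, 250 bp long, with
  log-normal peak heights written as BED scores;
* per-sample somatic SNVs as a Poisson process at a background rate
  (default 1 SNV/Mb, the typical burden of primary prostate cancer), with
  trinucleotide contexts drawn from a background 96-class signature;
* extra peak-proximal SNVs within +/- a stated window of peak centers
  (default 375 bp) so that the TOTAL rate there is ``fold`` x background,
  with contexts drawn from a planted peak signature and per-peak intensity
  proportional to height**coupling;
* a methylation track with one record per CpG (coverage noise, per-context
  beta-distributed methylated fractions, peak-set membership shifting the
  beta mean).

Mutations are placed by drawing a 96-class first and then a genomic site
whose reference trinucleotide matches that class (the genome itself is never
edited), so the one genome is shared by all samples as in a real cohort.
All generators are deterministic per seed, and a ground-truth table records
each mutation's origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import (
    INDEL_COLUMNS,
    MutationCatalog,
    SNV_COLUMNS,
    write_vcf,
)
from .intervals import Genome, RegionSet, merge_within, write_bed
from .randomization import allowed_blocks, _PlacementSampler
from .signatures import BASES, CLASS_LABELS, class_to_context, context_ids

__all__ = [
    "TFConfig",
    "SimulationConfig",
    "default_background_signature",
    "ar_like_signature",
    "prc2_like_signature",
    "uniform_signature",
    "simulate_genome",
    "simulate_peaks",
    "simulate_catalog",
    "simulate_methylation",
    "simulate_breakpoints",
    "write_dataset",
]

_ALT_PYR = "AGTACG"   # alt on the pyrimidine strand per substitution index
_COMP_CODE = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Planted signatures
# ---------------------------------------------------------------------------

def _label_mass(pairs: Mapping[str, float], rest: float) -> np.ndarray:
    """Probability vector with named class masses plus a flat remainder."""
    p = np.zeros(96)
    for label, mass in pairs.items():
        p[CLASS_LABELS.index(label)] = mass
    flat = np.isclose(p, 0.0)
    p[flat] = rest / flat.sum()
    return p / p.sum()


def default_background_signature() -> np.ndarray:
    """Genome-wide background: dominated by C>T at CpG (deamination-like),
    with a T>C component and a thin flat remainder."""
    pairs = {}
    for five in BASES:
        pairs[f"{five}[C>T]G"] = 0.125          # 0.50 total
        for three in "ACT":
            pairs[f"{five}[C>T]{three}"] = 0.015  # 0.18 total
        for three in BASES:
            pairs[f"{five}[T>C]{three}"] = 0.0125  # 0.20 total
    return _label_mass(pairs, rest=0.12)


def ar_like_signature() -> np.ndarray:
    """Peak signature mirroring TF-occupancy mutagenesis: mass on T>A at TpG
    and C>G at CpG purine-transversion classes."""
    pairs = {}
    for five in BASES:
        pairs[f"{five}[T>A]G"] = 0.10   # 0.40 total
        pairs[f"{five}[C>G]G"] = 0.075  # 0.30 total
    return _label_mass(pairs, rest=0.30)


def prc2_like_signature() -> np.ndarray:
    """Peak signature dominated by C>T at CpG (deamination at methylated
    CpGs, as at polycomb-bound sites)."""
    pairs = {f"{five}[C>T]G": 0.20 for five in BASES}
    return _label_mass(pairs, rest=0.20)


def uniform_signature() -> np.ndarray:
    return np.full(96, 1.0 / 96)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TFConfig:
    """One synthetic TF peak set and its planted mutational behavior."""

    name: str
    n_peaks: int = 100
    peak_length: int = 250
    length_jitter: int = 0
    enrichment_fold: float = 10.0
    # absolute added SNV/Mb/sample within the peak window; overrides the
    # (fold - 1) x background intensity when set (lets a study plant peak
    # mutations on a mutation-free background)
    peak_snv_per_mb: Optional[float] = None
    peak_signature: Optional[np.ndarray] = None   # default: ar_like
    height_coupling: float = 0.0
    meth_beta_mean: Optional[float] = None        # None -> background mean
    share_jaccard_with: Optional[Tuple[str, float]] = None

    def signature(self) -> np.ndarray:
        return (ar_like_signature() if self.peak_signature is None
                else np.asarray(self.peak_signature, dtype=float))


def _default_tfs() -> List[TFConfig]:
    return [
        TFConfig("AR_like", enrichment_fold=10.0,
                 peak_signature=ar_like_signature(), height_coupling=1.0,
                 meth_beta_mean=0.20),
        TFConfig("PRC2_like", enrichment_fold=5.0,
                 peak_signature=prc2_like_signature(), meth_beta_mean=0.85),
        TFConfig("CTRL_flat", enrichment_fold=1.0,
                 peak_signature=uniform_signature()),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults: 5 chromosomes x 2 Mb at GC 0.41, 100 x 250-bp peaks per TF,
    50 samples at a background of 1 SNV/Mb, 10-fold enrichment within
    +/-375 bp of AR-like peak centers.
    """

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 2_000_000 for i in range(1, 6)})
    gc_content: float = 0.41
    gap_fraction: float = 0.01
    n_gaps_per_chrom: int = 2
    n_samples: int = 50
    cancer_type: str = "SIM"
    background_rate: float = 1.0          # SNV per Mb per sample
    indel_background_rate: float = 0.1    # indel per Mb per sample
    peak_mutation_window: int = 375
    background_signature: np.ndarray = field(
        default_factory=default_background_signature)
    vaf_alpha: float = 8.0
    vaf_beta: float = 8.0
    vaf_scale: float = 0.5                # diploid heterozygous
    height_lognorm_mu: float = 3.0
    height_lognorm_sigma: float = 0.6
    meth_coverage_mean: float = 30.0
    meth_background_mean: float = 0.40
    meth_beta_concentration: float = 10.0
    n_background_cpgs: int = 20000
    tfs: List[TFConfig] = field(default_factory=_default_tfs)

    def __post_init__(self) -> None:
        sig = np.asarray(self.background_signature, dtype=float)
        if abs(sig.sum() - 1.0) > 1e-9:
            raise ValueError("background_signature must sum to 1")
        if self.background_rate < 0 or self.gap_fraction < 0:
            raise ValueError("rates/fractions must be >= 0")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0,1]")

    def rng_for(self, stage: str) -> np.random.Generator:
        """Independent deterministic stream per stage name."""
        import zlib

        ss = np.random.SeedSequence(
            [self.seed, zlib.crc32(stage.encode()) % (2**31)])
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> Genome:
    """An i.i.d. genome at the configured GC content with N-run gaps."""
    rng = config.rng_for("genome")
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: Dict[str, str] = {}
    gap_rows = []
    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        codes = rng.choice(4, size=L, p=p)
        seq = base_arr[codes]
        if config.gap_fraction > 0 and config.n_gaps_per_chrom > 0:
            gap_bp = int(round(config.gap_fraction * L))
            per_gap = max(gap_bp // config.n_gaps_per_chrom, 1)
            for _ in range(config.n_gaps_per_chrom):
                start = int(rng.integers(0, max(L - per_gap, 1)))
                seq[start : start + per_gap] = ord("N")
                gap_rows.append((chrom, start, start + per_gap))
        seqs[chrom] = seq.tobytes().decode("ascii")
    if gap_rows:
        gaps = RegionSet.from_arrays(
            [r[0] for r in gap_rows], [r[1] for r in gap_rows],
            [r[2] for r in gap_rows], name="gap_mask", validate=False)
        gaps = merge_within(gaps, 0)
    else:
        gaps = RegionSet(name="gap_mask")
    return Genome(seqs, gap_mask=gaps)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(
    config: SimulationConfig, genome: Genome
) -> Dict[str, RegionSet]:
    """Place each TF's peaks uniformly over the gap-free genome.

    Heights are log-normal and stored as BED scores.  A TF with
    ``share_jaccard_with=(other, J)`` copies enough of the other TF's peak
    placements that the realized bp Jaccard index of the two sets is ~J.
    """
    rng = config.rng_for("peaks")
    blocks = allowed_blocks(genome, None)
    sampler = _PlacementSampler(blocks)
    chrom_names = sorted(genome.lengths)
    out: Dict[str, RegionSet] = {}
    for tf in config.tfs:
        lengths = np.full(tf.n_peaks, tf.peak_length, dtype=np.int64)
        if tf.length_jitter:
            lengths = lengths + rng.integers(
                -tf.length_jitter, tf.length_jitter + 1, size=tf.n_peaks)
            lengths = np.maximum(lengths, 10)
        heights = rng.lognormal(config.height_lognorm_mu,
                                config.height_lognorm_sigma, size=tf.n_peaks)
        chroms: List[str] = []
        starts = np.empty(tf.n_peaks, dtype=np.int64)
        n_shared = 0
        if tf.share_jaccard_with is not None:
            other_name, jacc = tf.share_jaccard_with
            if other_name not in out:
                raise ValueError(
                    f"{tf.name} shares with {other_name!r}, which must be "
                    "defined earlier in config.tfs")
            other = out[other_name]
            n_shared = int(round(jacc / (1 + jacc) * (len(other) + tf.n_peaks)))
            n_shared = min(n_shared, len(other), tf.n_peaks)
            pick = rng.choice(len(other), size=n_shared, replace=False)
            odf = other.df.iloc[pick]
            chroms.extend(odf["chrom"].tolist())
            starts[:n_shared] = odf["start"].to_numpy()
            lengths[:n_shared] = (odf["end"] - odf["start"]).to_numpy()
        for j in range(n_shared, tf.n_peaks):
            cs, ss = sampler.sample(int(lengths[j]), 1, rng)
            chroms.append(cs[0])
            starts[j] = ss[0]
        rs = RegionSet.from_arrays(
            chroms, starts, starts + lengths, heights,
            name=tf.name, provenance=f"simulate_peaks(seed={config.seed})",
        ).sorted()
        out[tf.name] = rs
    return out


# ---------------------------------------------------------------------------
# Mutation catalog
# ---------------------------------------------------------------------------

class _ContextIndex:
    """Positions of every usable genomic site, bucketed by 32 collapsed
    trinucleotide contexts, over an arbitrary set of (chrom, start, end)
    spans."""

    def __init__(self, genome: Genome,
                 spans: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None):
        self.genome = genome
        buckets: Dict[int, List[Tuple[str, np.ndarray]]] = {i: [] for i in range(32)}
        if spans is None:
            spans = {c: [(0, genome.lengths[c])] for c in genome.sequences}
        for chrom, blocks in spans.items():
            ctx = context_ids(genome, chrom)
            for s, e in blocks:
                sub = ctx[s:e]
                valid = sub >= 0
                pos = np.nonzero(valid)[0] + s
                ids = sub[valid]
                order = np.argsort(ids, kind="mergesort")
                pos, ids = pos[order], ids[order]
                bounds = np.searchsorted(ids, np.arange(33))
                for cid in range(32):
                    chunk = pos[bounds[cid]:bounds[cid + 1]]
                    if len(chunk):
                        buckets[cid].append((chrom, chunk))
        self._flat: Dict[int, Tuple[List[str], np.ndarray, np.ndarray]] = {}
        for cid, parts in buckets.items():
            if not parts:
                self._flat[cid] = ([], np.empty(0, np.int64), np.empty(0, np.int64))
                continue
            names = [p[0] for p in parts]
            sizes = np.array([len(p[1]) for p in parts])
            cum = np.concatenate([[0], np.cumsum(sizes)])
            allpos = np.concatenate([p[1] for p in parts])
            self._flat[cid] = (names, cum, allpos)

    def sample(self, cid: int, n: int, rng: np.random.Generator
               ) -> List[Tuple[str, int]]:
        names, cum, allpos = self._flat[cid]
        if len(allpos) == 0:
            raise ValueError(
                f"no genomic site available for context {cid}; "
                "use a larger genome")
        u = rng.integers(0, len(allpos), size=n)
        part = np.searchsorted(cum, u, side="right") - 1
        return [(names[p], int(allpos[i])) for p, i in zip(part, u)]


def _alt_for(genome: Genome, chrom: str, pos0: int, class_idx: int) -> Tuple[str, str]:
    """(ref, alt) on the plus strand for a planted class at a matching site."""
    ref = genome.sequences[chrom][pos0]
    alt_pyr = _ALT_PYR[class_idx // 16]
    if ref in "CT":
        return ref, alt_pyr
    return ref, _COMP_CODE[alt_pyr]


def _draw_mutations(
    index: _ContextIndex,
    genome: Genome,
    signature: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> List[Tuple[str, int, str, str, int]]:
    """n mutations: (chrom, pos0, ref, alt, class_idx), contexts per signature."""
    if n == 0:
        return []
    classes = rng.choice(96, size=n, p=signature)
    out = []
    for k in np.bincount(classes, minlength=96).nonzero()[0]:
        count = int((classes == k).sum())
        sites = index.sample(class_to_context(int(k)), count, rng)
        for chrom, pos0 in sites:
            ref, alt = _alt_for(genome, chrom, pos0, int(k))
            out.append((chrom, pos0, ref, alt, int(k)))
    return out


def simulate_catalog(
    config: SimulationConfig,
    genome: Genome,
    peaks: Mapping[str, RegionSet],
) -> Tuple[MutationCatalog, pd.DataFrame]:
    """Per-sample SNV/indel catalog with planted peak enrichment.

    Background SNVs: Poisson(background_rate x non-gap Mb) per sample,
    contexts from the background signature, placed uniformly among matching
    sites.  Peak-proximal SNVs: within +/-peak_mutation_window of each peak
    center, added at (fold - 1) x background so the total rate there is
    fold x background; per-peak intensity scales with height**coupling
    (normalized to mean 1); contexts from the TF's peak signature.

    Returns (catalog, ground_truth) where ground_truth labels every SNV with
    its origin (``background`` or the TF name) and planted class.
    """
    rng = config.rng_for("catalog")
    # context indexes depend only on (genome, peaks, window): cache on the
    # genome object so repeated draws over one genome are cheap
    cache = genome.__dict__.setdefault("_sim_cache", {})
    if "bg" not in cache:
        cache["bg"] = _ContextIndex(genome)
    bg_index = cache["bg"]
    genome_mb = genome.non_gap_bp() / 1e6
    tf_by_name = {tf.name: tf for tf in config.tfs}

    # per-TF window spans and per-peak context indexes
    tf_windows: Dict[str, List[Tuple[str, int, int, float]]] = {}
    tf_peak_index: Dict[str, List[_ContextIndex]] = {}
    for name, rs in peaks.items():
        tf = tf_by_name[name]
        w = config.peak_mutation_window
        rows = []
        heights = rs.df["score"].to_numpy()
        coupling = tf.height_coupling
        if coupling > 0 and len(heights):
            factor = heights ** coupling
            factor = factor / factor.mean()
        else:
            factor = np.ones(len(rs))
        for i, r in enumerate(rs.df.itertuples(index=False)):
            center = (int(r.start) + int(r.end)) // 2
            s = max(center - w, 0)
            e = min(center + w + 1, genome.lengths[r.chrom])
            rows.append((r.chrom, s, e, float(factor[i])))
        tf_windows[name] = rows
        if tf.enrichment_fold > 1 or tf.peak_snv_per_mb:
            key = ("peak_idx", name, w, id(rs))
            if key not in cache:
                cache[key] = [
                    _ContextIndex(genome, {chrom: [(s, e)]})
                    for chrom, s, e, _ in rows
                ]
            tf_peak_index[name] = cache[key]

    snv_rows: List[tuple] = []
    indel_rows: List[tuple] = []
    truth_rows: List[tuple] = []
    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    for sample in samples:
        # background SNVs
        n_bg = rng.poisson(config.background_rate * genome_mb)
        for chrom, pos0, ref, alt, k in _draw_mutations(
                bg_index, genome, config.background_signature, n_bg, rng):
            vaf = float(rng.beta(config.vaf_alpha, config.vaf_beta)
                        * config.vaf_scale)
            snv_rows.append((chrom, pos0 + 1, ref, alt, sample, vaf, 2))
            truth_rows.append((sample, chrom, pos0 + 1, ref, alt,
                               "background", int(k)))
        # peak-proximal SNVs per TF
        for name, tf in tf_by_name.items():
            if name not in tf_peak_index:
                continue
            sig = tf.signature()
            if tf.peak_snv_per_mb is not None:
                added_per_bp = tf.peak_snv_per_mb / 1e6
            else:
                added_per_bp = ((tf.enrichment_fold - 1)
                                * config.background_rate / 1e6)
            windows = tf_windows[name]
            widths = np.array([e - s for _, s, e, _ in windows])
            factors = np.array([f for _, _, _, f in windows])
            lam = added_per_bp * float((widths * factors).sum())
            n_peakmut = rng.poisson(lam)
            if n_peakmut == 0:
                continue
            # peak chosen proportional to width x height-factor, then a class
            # from the peak signature, then a matching site inside that peak's
            # window (class redrawn if the window lacks the context)
            pweights = widths * factors
            pweights = pweights / pweights.sum()
            peak_pick = rng.choice(len(windows), size=n_peakmut, p=pweights)
            classes = rng.choice(96, size=n_peakmut, p=sig)
            for pi, k in zip(peak_pick, classes):
                idx = tf_peak_index[name][pi]
                k = int(k)
                c2 = pos0 = None
                for _try in range(50):
                    try:
                        c2, pos0 = idx.sample(class_to_context(k), 1, rng)[0]
                        break
                    except ValueError:
                        k = int(rng.choice(96, p=sig))
                if c2 is None:
                    raise ValueError(
                        f"peak window of {name} contains no usable context; "
                        "use a larger genome or window")
                ref, alt = _alt_for(genome, c2, pos0, k)
                vaf = float(rng.beta(config.vaf_alpha, config.vaf_beta)
                            * config.vaf_scale)
                snv_rows.append((c2, pos0 + 1, ref, alt, sample, vaf, 2))
                truth_rows.append((sample, c2, pos0 + 1, ref, alt, name, k))
        # background indels (1-bp deletions/insertions)
        n_ind = rng.poisson(config.indel_background_rate * genome_mb)
        for _ in range(n_ind):
            cid = int(rng.integers(0, 32))
            try:
                chrom, pos0 = bg_index.sample(cid, 1, rng)[0]
            except ValueError:
                continue
            seq = genome.sequences[chrom]
            if pos0 + 1 >= len(seq) or "N" in seq[pos0:pos0 + 2]:
                continue
            if rng.random() < 0.5:
                ref, alt = seq[pos0:pos0 + 2], seq[pos0]      # deletion
            else:
                ins = "ACGT"[int(rng.integers(0, 4))]
                ref, alt = seq[pos0], seq[pos0] + ins          # insertion
            indel_rows.append((chrom, pos0 + 1, ref, alt, sample))

    snvs = pd.DataFrame(snv_rows, columns=SNV_COLUMNS)
    indels = pd.DataFrame(indel_rows, columns=INDEL_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "origin",
                 "class_idx"],
    )
    truth["class_label"] = [CLASS_LABELS[int(i)] for i in truth["class_idx"]]
    catalog = MutationCatalog(snvs, indels, set(samples), config.cancer_type)
    return catalog, truth


# ---------------------------------------------------------------------------
# Methylation and breakpoints
# ---------------------------------------------------------------------------

def simulate_methylation(
    config: SimulationConfig,
    genome: Genome,
    peak_sets: Mapping[str, RegionSet],
) -> pd.DataFrame:
    """One record per CpG in peak regions plus a random background subset.

    Coverage is Poisson(meth_coverage_mean); the methylated fraction is Beta
    with mean given by the innermost peak set's configured mean (or the
    background mean) at the configured concentration.
    """
    from .methylation import find_cpg_sites

    rng = config.rng_for("methylation")
    tf_by_name = {tf.name: tf for tf in config.tfs}
    rows: List[tuple] = []
    seen: Dict[str, set] = {c: set() for c in genome.sequences}

    def add_records(sites: Mapping[str, np.ndarray], mean: float) -> None:
        conc = config.meth_beta_concentration
        a, b = mean * conc, (1 - mean) * conc
        for chrom, positions in sites.items():
            for pos in positions:
                if int(pos) in seen[chrom]:
                    continue
                seen[chrom].add(int(pos))
                cov = int(rng.poisson(config.meth_coverage_mean))
                frac = float(rng.beta(a, b))
                rows.append((chrom, int(pos), frac, cov))

    for name, rs in peak_sets.items():
        mean = tf_by_name[name].meth_beta_mean
        if mean is None:
            mean = config.meth_background_mean
        add_records(find_cpg_sites(genome, rs), mean)
    # background subset
    all_cpg = find_cpg_sites(genome)
    flat = [(c, p) for c, arr in all_cpg.items() for p in arr]
    if flat:
        take = min(config.n_background_cpgs, len(flat))
        pick = rng.choice(len(flat), size=take, replace=False)
        bg_sites: Dict[str, List[int]] = {}
        for i in pick:
            c, p = flat[i]
            bg_sites.setdefault(c, []).append(int(p))
        add_records({c: np.array(v) for c, v in bg_sites.items()},
                    config.meth_background_mean)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth_fraction",
                                     "coverage"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_breakpoints(
    config: SimulationConfig, genome: Genome, mean_per_sample: float = 20.0
) -> Dict[str, RegionSet]:
    """Per-sample structural-variant breakpoint positions (1-bp intervals)."""
    rng = config.rng_for("breakpoints")
    blocks = allowed_blocks(genome, None)
    sampler = _PlacementSampler(blocks)
    out: Dict[str, RegionSet] = {}
    for j in range(config.n_samples):
        n = max(int(rng.poisson(mean_per_sample)), 1)
        chroms, starts = sampler.sample(1, n, rng)
        out[f"S{j:03d}"] = RegionSet.from_arrays(
            chroms, starts, starts + 1, name=f"S{j:03d}_breakpoints",
            validate=False).sorted()
    return out


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

def write_dataset(config: SimulationConfig, outdir) -> Dict[str, object]:
    """Generate and write a complete synthetic dataset.

    Writes FASTA + gap BED, per-TF peak BED5, per-sample VCFs + manifest,
    methylation TSV and the ground-truth table, plus a ready-to-run pipeline
    config YAML.  Returns the in-memory objects.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    peaks = simulate_peaks(config, genome)
    catalog, truth = simulate_catalog(config, genome, peaks)
    meth = simulate_methylation(config, genome, peaks)

    genome.to_fasta(outdir / "genome.fa")
    write_bed(genome.gap_mask, outdir / "gaps.bed")
    peak_paths = {}
    for name, rs in peaks.items():
        path = outdir / f"peaks_{name}.bed"
        write_bed(rs, path)
        peak_paths[name] = str(path)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    manifest_rows = []
    for sample in sorted(catalog.samples):
        vp = vcf_dir / f"{sample}.vcf"
        write_vcf(catalog, vp, sample_id=sample, contigs=genome.lengths)
        manifest_rows.append((sample, str(vp), config.cancer_type))
    manifest = pd.DataFrame(manifest_rows,
                            columns=["sample_id", "path", "cancer_type"])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    meth_path = outdir / "methylation.tsv"
    from .methylation import write_methylation
    write_methylation(meth, meth_path, header=f"seed={config.seed}")
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)

    pipeline_cfg = {
        "genome_fasta": str(outdir / "genome.fa"),
        "gap_bed": str(outdir / "gaps.bed"),
        "peaks": [{"name": n, "path": p} for n, p in peak_paths.items()],
        "vcf_manifest": str(outdir / "manifest.tsv"),
        "methylation": str(meth_path),
        "params": {
            "seed": config.seed,
            "n_iterations": 1000,
            "merge_gap": 200,
            "flank": config.peak_mutation_window,
            "window": 5000,
            "bin": 100,
            "bandwidth": 100,
            "min_mutations": 480,
            "min_coverage": 10,
            "meth_threshold": 0.52,
            "sd_window": 2.0,
        },
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=False)
    return {
        "genome": genome,
        "peaks": peaks,
        "catalog": catalog,
        "truth": truth,
        "methylation": meth,
        "config_path": str(outdir / "config.yaml"),
    }
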