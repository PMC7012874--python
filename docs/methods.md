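# Methods

This note documents the models, conventions, parameters and design choices
behind tfmutscan, in the order an analysis flows through the package.

## Coordinates and data model

All internal computation is 0-based half-open (BED convention). VCF
positions are 1-based; the single conversion point is
`catalog.snv_positions_0based`. An SNV at 1-based position *p* overlaps
`[start, end)` iff `start ≤ p−1 < end`. Region sets are DataFrame-backed
(`chrom, start, end, score, strand`) with peak height carried as the BED
score column. Distance from a point to an interval is
`max(0, start − p, p − (end−1))` — zero inside, else base pairs to the
nearest covered base; points on chromosomes without targets get the
sentinel −1.

`merge_within(regions, d)` unions intervals whose edge gap is ≤ d
(`d = 200` reproduces the peak-merging step used to build a high-confidence
clinical binding-site set; note that HOMER's `-d` is center-distance-based,
whereas the edge-gap contract here is simpler and reproducible — at 250-bp
peaks the two differ only for peaks 200–450 bp apart). Merged scores take
the member maximum. Blacklist/gap filtering removes any peak with ≥1 bp
overlap rather than trimming it.

Two region-extension operations exist deliberately: `slop(regions, g, f)`
extends the original boundaries (the bedtools operation used to extend
binding regions), while `center_windows(regions, f)` builds fixed-width
`[center−f, center+f]` windows. The peak-proximal mutation model is defined
on center windows, so recovery analyses measure rates there; slop remains
the general-purpose extension.

## Shuffle null and composition matching

The empirical null repositions each interval uniformly at random over the
allowed genome (complement of the gap/blacklist exclusion), preserving its
length, independently per iteration (1000 by default). Placement samples an
integer uniformly over the exact set of allowed start positions (cumulative
capacities over gap-free blocks), which is exactly uniform, guarantees zero
exclusion overlap by construction, errors immediately when an interval
exceeds every gap-free stretch, and vectorizes across iterations — this is
why a 400-replicate calibration experiment runs in seconds. Shuffled
intervals within one iteration may overlap one another (matching the cited
tool's default); chromosome can optionally be preserved, but the default
shuffles genome-wide.

Composition matching selects, from a population of shuffles, those whose
pooled A/C/G/T fractions match a target set: each base column is z-scored
with the shuffle population's mean/sd, the target is z-scored under the
same mean/sd (the population defines the scale; the target is one point
measured against it), and a shuffle passes iff every base satisfies
|z_shuffle − z_target| ≤ 2 (the ±2 sd window). Zero-variance columns are
ignored with a warning.

## Rates and the two p-values

Rates pool mutations across samples: rate = Σ counts / total bp × 10⁶.
`p_raw = #{null ≥ obs}/N` reproduces the conventional "empirical FDR = 0"
report; `p_add_one = (1 + #{null ≥ obs})/(N+1)` is never zero, exactly
uniform on {1/(N+1), …, 1} under exchangeability, and is what the
calibration test and BH correction use. Ties count in favor of the null
(≥), so a zero-mutation catalog yields p_raw = 1 against an all-zero null.
Fold is observed/null-mean, defined as 0 when the observed rate is 0.

Cross-cohort comparison normalizes per sample: (rate at regions)/(sample's
genome-wide rate over the non-gap genome), reported per sample with the
cohort median as the headline value; zero-mutation samples are excluded
with a warning. Peak-height quartiles sort by score ascending (ties broken
by genomic order), split into four groups differing by ≤1 in size, and
rate each group.

## 96-class spectra

Classes are indexed `16·substitution + 4·five′ + three′` with substitutions
ordered C>A, C>G, C>T, T>A, T>C, T>G and bases A<C<G<T; labels are
`5'[ref>alt]3'` on the pyrimidine strand. Purine-reference records are
reverse-complemented (alleles and flanks) before classification, so a
catalog and its strand-mirrored image produce identical spectra. Records at
chromosome edges or with N flanks are skipped and counted; a genome/ref
mismatch is an error, not a skip. The TpG→ApG and CpG→GpG purine
transversions of the occupancy-mutagenesis signature collapse to the
`N[T>A]G` and `N[C>G]G` classes.

Spectra below 480 mutations are excluded from comparisons (strictly fewer:
479 is removed, 480 retained), the published minimum for >0.95 accuracy in
separating two mixed signatures. Similarity is cosine on frequency vectors;
clustering is scipy average linkage on 1 − cosine (configurable to
complete/single), with flat clusters cut either to a requested count or at
a height. Reference comparison accepts a 96×K probability-column matrix;
two synthetic toy columns (`deamination_like`: CpG C>T mass; `abasic_like`:
TpG T>A + CpG C>G mass) are bundled for tests — they are constructed
stand-ins, not published signatures.

## Profiles

For each peak, signed offsets of mutations within ±window of the center
(floor of the midpoint) are collected; offsets are pooled over peaks — a
mutation near two centers contributes once per center. The histogram uses
bins centered on multiples of the bin width (window 5000, bin 100 → 101
bins), smoothed with a Gaussian kernel (default bandwidth 100 bp, matching
the bin scale; the method is stated only as "smooth kernel density" in the
source analysis, so the kernel and bandwidth are package choices).
Smoothing uses zero-padding, so mass within ~3 bandwidths of the window
edge can leak; for bandwidth ≤ window/10 total mass is conserved to within
1%. Curves can be raw-count or normalized-to-1; the mode is recorded in the
output.

## Motif scanning

PWMs (JASPAR text via Bio.motifs, or built directly) are column-normalized
with a background-split pseudocount (default 0.8) and scored as log-odds
base 2 against the background. Both strands are scanned; the threshold is a
fraction of the maximum achievable score (no p-value calibration); windows
containing N are skipped; a window matching on both strands (palindrome) is
reported once with strand '.'. "Motif alone" control regions are matches
minus any match overlapping the bound peak set (whole-match removal). A
15-bp toy androgen-response-element PWM (AGAACA-nnn-TGTTCT) is built in for
tests.

## Methylation

Records are per-CpG (1-based C position, methylated fraction, coverage).
Records with coverage < 10 are excluded; a surviving record is methylated
iff fraction ≥ 0.52 (strictly below is unmethylated; 0.52 was the cell-line
median used as the threshold in the source analysis). All records
overlapping a region set pool into a single methylated/(methylated +
unmethylated) rate; zero usable records yield a flagged missing value
rather than 0.

## Synthetic data generator

The generator encodes the study conditions the analyses assume:

| parameter | default | meaning |
|---|---|---|
| chrom_lengths | 5 × 2 Mb | desk-scale genome |
| gc_content | 0.41 | human-like i.i.d. base composition |
| gap_fraction | 0.01 | N-run gaps recorded in the mask |
| n_samples | 50 | cohort size |
| background_rate | 1 SNV/Mb | typical primary prostate-cancer burden |
| peak_mutation_window | ±375 bp | span of peak-proximal enrichment |
| n_peaks / peak_length | 100 / 250 bp | per-TF peak set |
| peak heights | log-normal(3, 0.6) | BED score column |
| enrichment_fold | 10 (AR-like) | total in-window rate = fold × background |
| height_coupling | 1 (AR-like) | per-peak intensity ∝ height^coupling |
| VAF | Beta(8,8) × 0.5 | diploid heterozygous |
| methylation | Beta, mean 0.85/0.40/0.20 | PRC2-like / background / AR-like |

Background SNVs are a per-sample Poisson process over the non-gap genome
with trinucleotide contexts drawn from a background 96-class signature
(deamination-dominated: half its mass on CpG C>T, a T>C component, thin
flat remainder — concentrated enough that a ~10³-mutation cohort spectrum
matches it at cosine ≈ 0.99). Peak-proximal SNVs are added inside center
windows at intensity (fold − 1) × background — so the total in-window rate
is fold × background and the enrichment test's observed/null ratio
estimates the configured fold directly — or at an absolute per-Mb rate
(`peak_snv_per_mb`), which permits planted-only catalogs on a zero
background. Contexts come from the TF's planted signature (AR-like:
0.4 mass on N[T>A]G + 0.3 on N[C>G]G; PRC2-like: 0.8 on N[C>T]G).

Placement draws the mutation class first, then a uniformly chosen genomic
site whose reference trinucleotide matches it (per-context position
indexes; the genome is never edited), so one genome serves the whole
cohort as in real data. Every stage is deterministic per seed via named
sub-streams, and a ground-truth table records each mutation's origin and
planted class. Generated FASTA/BED/VCF/TSV round-trip losslessly through
the package's own readers.

What the generator does **not** emulate: real chromatin context (replication
timing, expression-coupled repair), mappability structure beyond simple N
gaps, sample-to-sample burden heterogeneity, subclonal VAF structure, and
realistic indel spectra (indels are 1-bp events at a flat rate). Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to those real-data complications.

## Problem sizes and numerical choices in the checks

Recovery checks run at desk scale: the default 10 Mb genome holds ~100 kb
of binding sites — the same genome fraction as the real analysis — but the
default cohort yields only ~40 peak-window mutations for the fold-10 set,
so a single fold estimate carries ~16% Poisson noise; fold-recovery checks
therefore report the median over a handful of independent replicates. The
signature-recovery check uses 200 peaks × fold 40 × 100 samples to clear
the 480-mutation floor with margin, and measures the background spectrum on
the remainder of the genome (outside peak windows), since at this scale
peak mutations are a non-negligible fraction of the whole catalog. The
null-calibration check uses a dense pooled catalog (expected ~200 mutations
per region set) so that counts are effectively continuous — with sparse
counts the add-one p is conservative purely through ties, which would
measure discreteness rather than calibration. The profile check uses a
planted-only catalog (zero background), matching its premise that all
mutations lie within ±375 bp of centers.

## Known limitations

* The enrichment null randomizes region placement, not mutations; it tests
  "is this region set unusually mutated for its size", conditional on the
  catalog.
* Composition matching is post-hoc selection of shuffles, not stratified
  sampling; with strongly atypical target composition few shuffles survive.
* Cohort-level rates pool samples and are dominated by hypermutated samples
  if present; use the per-sample normalized mode for cross-cohort claims.
* No transcriptional strand bias channels (96 classes, not 192), no de novo
  signature factorization (NMF) — observed spectra are compared directly.
* Indel handling is rate-only; indel contexts and lengths are not modeled.
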