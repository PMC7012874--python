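# tfmutscan

Regional somatic mutagenesis analysis at transcription-factor binding sites:
shuffle-based empirical enrichment of SNV/indel rates, 96-context mutational
signature spectra with cosine-similarity clustering, peak-centered
mutation-density profiles, peak-height quartile analysis, composition-matched
background selection, and CpG-methylation summaries — plus a synthetic-data
generator that plants known enrichment and signatures so every stage is
testable by parameter recovery.

## The problem

Bound transcription factors (e.g., the androgen receptor in prostate cancer)
can shield the DNA beneath them from repair machinery. If base- or
nucleotide-excision repair is blocked at occupied sites, somatic mutations
accumulate there at an elevated rate and with a distinctive spectrum — in
particular TpG→ApG and CpG→GpG purine transversions, the expected outcome of
unrepaired abasic sites ("A-rule" adenine insertion opposite the lesion).
Detecting this requires comparing mutation burdens in small region sets
(tens of kb of binding sites) against what random chromosomal regions of the
same size and composition would show, and comparing the mutation-type
spectrum at those sites against the rest of the genome.

## The statistics

**Empirical enrichment.** For a region set *R* and a pooled cohort catalog,
the observed rate is r(R) = #SNV(R) / |R| × 10⁶ (SNV/Mb). The null is built
by repositioning *R* uniformly at random over the mappable genome
(length-preserving, excluding gaps/blacklist) *N* times (default
N = 1000) and recomputing the rate each time. Two p-values are reported:
p_raw = #{null ≥ observed}/N (the quantity reported as "empirical FDR = 0"
when no null reaches the observed rate), and the add-one version
p₊ = (1 + #{null ≥ observed})/(N + 1), which is exactly uniform under the
null and is the version to use for calibration and BH correction.

**Signatures.** Each SNV is assigned to one of 96 classes
(pyrimidine-collapsed substitution × 5′ base × 3′ base). Spectra are
compared by cosine similarity cos(a,b) = a·b/(‖a‖‖b‖) and clustered by
average-linkage on distance 1 − cos. Spectra with fewer than 480 mutations
are excluded (the published minimum for >0.95 deciphering accuracy of two
mixed signatures).

**Profiles and quartiles.** Signed offsets of mutations to peak centers are
pooled over peaks, histogrammed in 100-bp bins over ±5 kb and smoothed with
a Gaussian kernel; peak sets are split into height quartiles to test whether
occupancy strength tracks mutation density.

## Worked example

Generate a synthetic cohort (5 × 2 Mb genome, 50 samples at ~1 SNV/Mb, three
TF peak sets: `AR_like` with 10-fold planted enrichment and a
purine-transversion signature, `PRC2_like` with 5-fold enrichment and a
CpG C>T signature, `CTRL_flat` with no enrichment), then run the full
pipeline:

```
$ tfmutscan simulate --outdir data --seed 1
$ tfmutscan all --config data/config.yaml --outdir results
```

`results/enrichment/enrichment.tsv` (SNV rows, abridged):

```
region_set  which  null_mean  fold      p_raw  p_add_one    n_iterations
AR_like     snv    54.4       11.0294   0      0.000999001  1000
CTRL_flat   snv    58.5673    0.676133  0.757  0.757243     1000
PRC2_like   snv    60.684     7.28477   0      0.000999001  1000
```

The planted 10-fold set is recovered at fold ≈ 11 with an empirical p of 0
over 1000 shuffles (no shuffled region set reached the observed rate); the
flat control sits at fold ≈ 0.7 with p ≈ 0.76. `results/methylation/
methylation.tsv` separates the peak families by methylation state exactly as
planted (fraction 0.99 at `PRC2_like`, 0.01 at `AR_like`, 0.22 in the
background-like control), and `results/enrichment/quartile_rates.tsv` shows
the height-coupled `AR_like` set rising from 0 to 1760 SNV/Mb from the
lowest to the highest height quartile.

Library use mirrors the CLI: `simulate_*` builds the dataset in memory,
`enrichment_test`, `spectrum`/`cluster_spectra`, `aggregate_profile`,
`quartile_rates` and `summarize_methylation` are the analysis entry points
(see `docs/methods.md`).

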