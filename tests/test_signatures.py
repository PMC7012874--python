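"""96-class spectrum extraction, cosine similarity, clustering, reference
comparison and CpG fraction."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_classify, random_genome, random_snvs
from tfmutscan.catalog import SNVRecord
from tfmutscan.intervals import Genome
from tfmutscan.signatures import (
    CLASS_LABELS,
    ReferenceMismatchError,
    SpectrumVector,
    classify_snv,
    cluster_spectra,
    compare_to_reference,
    cosine_similarity,
    cpg_fraction,
    min_mutation_filter,
    spectrum,
    toy_reference_signatures,
)

SNV_COLS = ["chrom", "pos", "ref", "alt", "sample_id", "vaf", "caller_count"]


def _df(rows):
    return pd.DataFrame(rows, columns=SNV_COLS)


class TestClassifySnv:
    def test_pyrimidine_direct(self):
        genome = Genome({"chr1": "TACAG"})  # context A·C·A at pos 3 (1-based)
        idx = classify_snv(SNVRecord("chr1", 3, "C", "A"), genome)
        assert CLASS_LABELS[idx] == "A[C>A]A"

    def test_purine_reverse_complemented(self):
        genome = Genome({"chr1": "ATGTC"})  # T·G·T; G>T == C>A at A_A
        idx = classify_snv(SNVRecord("chr1", 3, "G", "T"), genome)
        assert CLASS_LABELS[idx] == "A[C>A]A"

    def test_tpg_to_apg_transversion(self):
        # the TpG dinucleotide: T>A with 3' G, any 5' base
        genome = Genome({"chr1": "CCTGA"})
        idx = classify_snv(SNVRecord("chr1", 3, "T", "A"), genome)
        assert CLASS_LABELS[idx] == "C[T>A]G"

    def test_reference_mismatch_raises(self):
        genome = Genome({"chr1": "AACAA"})
        with pytest.raises(ReferenceMismatchError):
            classify_snv(SNVRecord("chr1", 3, "G", "T"), genome)

    def test_edge_and_n_flank_skipped(self):
        genome = Genome({"chr1": "CANCA"})
        assert classify_snv(SNVRecord("chr1", 1, "C", "T"), genome) is None
        assert classify_snv(SNVRecord("chr1", 4, "C", "T"), genome) is None


class TestSpectrum:
    def test_single_mutation_unit_mass(self):
        genome = Genome({"chr1": "TACAG"})
        s = spectrum(_df([("chr1", 3, "C", "A", "s", np.nan, np.nan)]), genome)
        assert s.n_mutations == 1
        assert s.frequencies[CLASS_LABELS.index("A[C>A]A")] == 1.0

    def test_matches_bruteforce_classifier_exactly(self):
        genome = random_genome(21, lengths={"chr1": 60_000, "chr2": 40_000})
        snvs = random_snvs(22, genome, 1000)
        s = spectrum(snvs, genome)
        want = np.zeros(96, dtype=int)
        skipped = 0
        for r in snvs.itertuples(index=False):
            lab = brute_classify(r.chrom, r.pos, r.ref, r.alt, genome)
            if lab is None:
                skipped += 1
            else:
                want[CLASS_LABELS.index(lab)] += 1
        assert s.counts.tolist() == want.tolist()
        assert s.n_skipped == skipped

    def test_strand_collapse_invariance(self):
        # spectrum of a catalog on the reverse-complemented genome with
        # complemented alleles at mirrored positions is identical
        genome = random_genome(23, lengths={"chr1": 20_000})
        snvs = random_snvs(24, genome, 300)
        rc = {"A": "T", "C": "G", "G": "C", "T": "A"}
        L = genome.lengths["chr1"]
        seq_rc = genome.sequences["chr1"].translate(
            str.maketrans("ACGT", "TGCA"))[::-1]
        genome_rc = Genome({"chr1": seq_rc})
        mirrored = snvs.copy()
        mirrored["pos"] = L - snvs["pos"] + 1
        mirrored["ref"] = [rc[b] for b in snvs["ref"]]
        mirrored["alt"] = [rc[b] for b in snvs["alt"]]
        a = spectrum(snvs, genome)
        b = spectrum(mirrored, genome_rc)
        assert a.counts.tolist() == b.counts.tolist()

    def test_multinomial_recovery_from_known_signature(self):
        from scipy.stats import chisquare
        from tfmutscan.simulate import (
            SimulationConfig, _ContextIndex, _draw_mutations)
        rng = np.random.default_rng(25)
        genome = random_genome(26, lengths={"chr1": 200_000})
        sig = np.full(96, 1 / 96)
        idx = _ContextIndex(genome)
        rows = [(c, p0 + 1, ref, alt, "s", np.nan, np.nan)
                for c, p0, ref, alt, _k in
                _draw_mutations(idx, genome, sig, 2000, rng)]
        s = spectrum(_df(rows), genome)
        # chi-square goodness of fit of counts vs the planted uniform
        assert chisquare(s.counts, f_exp=np.full(96, s.n_mutations / 96)
                         ).pvalue > 0.01


class TestMinMutationFilter:
    def test_479_removed_480_retained(self):
        lo = SpectrumVector(np.eye(96, dtype=int)[0] * 479, label="lo")
        hi = SpectrumVector(np.eye(96, dtype=int)[0] * 480, label="hi")
        kept, removed = min_mutation_filter([lo, hi], 480)
        assert [s.label for s in kept] == ["hi"]
        assert removed == ["lo"]

    def test_zero_threshold_identity(self):
        s = SpectrumVector(np.zeros(96, dtype=int), label="z")
        kept, removed = min_mutation_filter([s], 0)
        assert kept == [s] and removed == []


class TestCosine:
    def test_self_similarity_one(self):
        v = np.random.default_rng(0).random(96)
        s = SpectrumVector((v * 100).astype(int))
        assert cosine_similarity(s, s) == pytest.approx(1.0)

    def test_disjoint_support_zero(self):
        a = np.zeros(96); a[:48] = 1
        b = np.zeros(96); b[48:] = 1
        assert cosine_similarity(a, b) == 0.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(96), rng.random(96)
        want = float(np.dot(a, b) /
                     (np.sqrt((a ** 2).sum()) * np.sqrt((b ** 2).sum())))
        assert cosine_similarity(a, b) == pytest.approx(want, abs=1e-12)

    def test_scale_invariance_duplicated_catalog(self):
        counts = np.arange(96)
        assert cosine_similarity(
            SpectrumVector(counts), SpectrumVector(counts * 2)
        ) == pytest.approx(1.0)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestClusterSpectra:
    def test_two_orthogonal_families_recovered(self):
        rng = np.random.default_rng(2)
        x = np.zeros(96); x[:10] = 1 / 10
        y = np.zeros(96); y[50:60] = 1 / 10
        spectra = []
        for i in range(3):
            spectra.append(SpectrumVector(
                rng.multinomial(500, x), label=f"x{i}"))
        for i in range(3):
            spectra.append(SpectrumVector(
                rng.multinomial(500, y), label=f"y{i}"))
        res = cluster_spectra(spectra, n_clusters=2)
        groups = {}
        for lab, cl in res.flat.items():
            groups.setdefault(cl, set()).add(lab[0])
        assert sorted(map(tuple, groups.values())) == [("x",), ("y",)]

    def test_identical_spectra_single_cluster_distance_zero(self):
        s = SpectrumVector(np.arange(96), label="a")
        t = SpectrumVector(np.arange(96), label="b")
        res = cluster_spectra([s, t])
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.flat.values())) == 1

    def test_needs_two_spectra(self):
        with pytest.raises(ValueError):
            cluster_spectra([SpectrumVector(np.ones(96, dtype=int))])


class TestCompareToReference:
    def test_exact_column_match(self):
        ref = toy_reference_signatures()
        counts = (ref["abasic_like"].to_numpy() * 10000).round().astype(int)
        sims, best = compare_to_reference(SpectrumVector(counts), ref)
        assert best == "abasic_like"
        assert sims["abasic_like"] > 0.999

    def test_one_hot_reference_picks_argmax_class(self):
        cols = {}
        for k in (0, 40, 95):
            v = np.zeros(96); v[k] = 1.0
            cols[f"onehot{k}"] = v
        ref = pd.DataFrame(cols, index=CLASS_LABELS)
        counts = np.zeros(96, dtype=int); counts[40] = 7; counts[0] = 2
        _, best = compare_to_reference(SpectrumVector(counts), ref)
        assert best == "onehot40"

    def test_unnormalized_column_rejected(self):
        ref = toy_reference_signatures()
        ref["bad"] = ref["abasic_like"] * 2
        with pytest.raises(ValueError, match="bad"):
            compare_to_reference(SpectrumVector(np.ones(96, dtype=int)), ref)

    def test_toy_reference_recovery_at_480_mutations(self):
        # simulated catalogs from each toy column are matched back to it
        ref = toy_reference_signatures()
        rng = np.random.default_rng(3)
        correct = 0
        for _ in range(100):
            truth = rng.choice(ref.columns)
            counts = rng.multinomial(480, ref[truth].to_numpy())
            _, best = compare_to_reference(SpectrumVector(counts), ref)
            correct += best == truth
        assert correct >= 99


class TestCpgFraction:
    def test_cpg_and_non_cpg(self):
        genome = Genome({"chr1": "AACGA" + "AACAA"})
        cpg = _df([("chr1", 3, "C", "T", "s", np.nan, np.nan)])
        noncpg = _df([("chr1", 8, "C", "T", "s", np.nan, np.nan)])
        assert cpg_fraction(cpg, genome) == 1.0
        assert cpg_fraction(noncpg, genome) == 0.0

    def test_minus_strand_record(self):
        # G>A at a CpG seen from the plus strand: C at p0-1
        genome = Genome({"chr1": "AACGA"})
        ga = _df([("chr1", 4, "G", "A", "s", np.nan, np.nan)])
        assert cpg_fraction(ga, genome) == 1.0

    def test_planted_ninety_percent_recovered(self):
        genome = random_genome(31, lengths={"chr1": 100_000})
        seq = genome.sequences["chr1"]
        cpg_pos = [i for i in range(1, len(seq) - 1)
                   if seq[i] == "C" and seq[i + 1] == "G"]
        nonc_pos = [i for i in range(1, len(seq) - 1)
                    if seq[i] == "C" and seq[i + 1] != "G"]
        rng = np.random.default_rng(32)
        rows = []
        for p in rng.choice(cpg_pos, 900, replace=False):
            rows.append(("chr1", int(p) + 1, "C", "T", "s", np.nan, np.nan))
        for p in rng.choice(nonc_pos, 100, replace=False):
            rows.append(("chr1", int(p) + 1, "C", "T", "s", np.nan, np.nan))
        est = cpg_fraction(_df(rows), genome)
        assert est == pytest.approx(0.90, abs=0.001)

    def test_non_ct_records_rejected(self):
        genome = Genome({"chr1": "AACGA"})
        bad = _df([("chr1", 3, "C", "A", "s", np.nan, np.nan)])
        with pytest.raises(ValueError):
            cpg_fraction(bad, genome)
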