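import itertools
import math
from math import comb

import numpy as np
import pytest
from scipy import stats

from cleavecall.annotation_io import GenomeSequence, TranscriptModel
from cleavecall.degradome_quant import log2_compare
from cleavecall.feature_analysis import (
    IUPAC,
    MotifSpec,
    assign_region,
    bh_adjust,
    decap_abundance_shift,
    extract_window_sequences,
    halflife_group_compare,
    junction_distance_profile,
    kmer_differential_enrichment,
    metagene_profile,
    motif_positional_distribution,
    ranksum_test,
    scan_motif,
    set_overlap_test,
)
from cleavecall.site_caller import DecapCatalog, PipelineConfig

from conftest import make_profile

BASES = np.array(list("ACGT"))


def random_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def coding_tx(tid="t1", exons=((0, 500),), cds=(100, 400), strand="+", chrom="chr1"):
    return TranscriptModel(
        tid, "g_" + tid, chrom, strand, exons=[tuple(e) for e in exons], cds_span=cds,
        is_protein_coding=True,
    )


class TestAssignRegion:
    def test_plus_strand_regions(self):
        tx = coding_tx()
        assert assign_region(("chr1", "+", 50), tx) == "5UTR"
        assert assign_region(("chr1", "+", 200), tx) == "CDS"
        assert assign_region(("chr1", "+", 450), tx) == "3UTR"

    def test_intron_and_noncoding(self):
        tx = coding_tx(exons=((0, 100), (200, 300)), cds=(50, 250))
        assert assign_region(("chr1", "+", 150), tx) == "intron"
        nc = TranscriptModel("n1", "gn", "chr1", "+", exons=[(0, 100)])
        assert assign_region(("chr1", "+", 10), nc) == "noncoding-exon"

    def test_minus_strand_exhaustive_oracle(self):
        tx = coding_tx(exons=((0, 100), (200, 300)), cds=(50, 250), strand="-")
        # oracle: walk the spliced transcript base-by-base
        exonic = []
        for s, e in tx.exons:
            exonic.extend(range(s, e))
        exonic = exonic[::-1]  # minus strand: 5' end is the high coordinate
        cds_spliced = [i for i, g in enumerate(exonic) if 50 <= g < 250]
        lo, hi = min(cds_spliced), max(cds_spliced)
        for i, g in enumerate(exonic):
            expected = "5UTR" if i < lo else ("CDS" if i <= hi else "3UTR")
            assert assign_region(("chr1", "-", g), tx) == expected

    def test_partition_covers_every_exonic_base(self):
        tx = coding_tx(exons=((0, 120), (150, 400)), cds=(30, 350))
        seen = {"5UTR": 0, "CDS": 0, "3UTR": 0}
        for s, e in tx.exons:
            for g in range(s, e):
                seen[assign_region(("chr1", "+", g), tx)] += 1
        assert sum(seen.values()) == tx.length


class TestMetagene:
    def test_cds_midpoint_bin(self):
        tx = coding_tx(exons=((0, 500),), cds=(100, 300))  # 200-nt CDS
        prof = metagene_profile([(("chr1", "+", 200), "t1")], {"t1": tx})
        assert prof.bins["CDS"][50] == 1
        assert prof.n_sites_assigned == 1

    def test_conservation(self):
        rng = np.random.default_rng(0)
        tx = coding_tx()
        sites = [(("chr1", "+", int(p)), "t1") for p in rng.integers(0, 500, 200)]
        prof = metagene_profile(sites, {"t1": tx})
        assert sum(arr.sum() for arr in prof.bins.values()) == prof.n_sites_assigned
        assert prof.n_sites_assigned == 200

    def test_uniform_sites_within_4_sigma(self):
        rng = np.random.default_rng(1)
        tx = coding_tx(exons=((0, 10_000),), cds=(2000, 8000))
        n = 10_000
        sites = [
            (("chr1", "+", int(p)), "t1") for p in rng.integers(2000, 8000, n)
        ]
        prof = metagene_profile(sites, {"t1": tx})
        p = 1 / 100
        mu, sigma = n * p, math.sqrt(n * p * (1 - p))
        assert np.all(np.abs(prof.bins["CDS"] - mu) <= 4 * sigma)


class TestJunctionProfile:
    def _tx(self):
        # junction at spliced coordinate 499 (exon lengths 500 + 500)
        return coding_tx(exons=((0, 500), (600, 1100)), cds=(50, 1050))

    def test_distance_27(self):
        tx = self._tx()
        # spliced coord 473 -> distance 499 - 473 + 1 = 27
        prof = junction_distance_profile([(("chr1", "+", 473), "t1")], {"t1": tx})
        assert prof.counts[26] == 1
        assert prof.n_sites_in_window == 1

    def test_one_before_junction_distance_1(self):
        tx = self._tx()
        prof = junction_distance_profile([(("chr1", "+", 499), "t1")], {"t1": tx})
        assert prof.counts[0] == 1

    def test_51_excluded(self):
        tx = self._tx()
        prof = junction_distance_profile([(("chr1", "+", 449), "t1")], {"t1": tx})
        assert prof.n_sites_in_window == 0
        assert prof.n_sites_considered == 1

    def test_frequencies_sum_to_one(self):
        tx = self._tx()
        rng = np.random.default_rng(2)
        sites = [(("chr1", "+", int(p)), "t1") for p in rng.integers(60, 499, 300)]
        prof = junction_distance_profile(sites, {"t1": tx})
        if prof.n_sites_in_window:
            assert prof.distances.sum() == pytest.approx(1.0)

    def test_uniform_chi2(self):
        tx = self._tx()
        rng = np.random.default_rng(3)
        n = 10_000
        # uniform over the 50-nt window upstream of the junction
        sites = [(("chr1", "+", int(p)), "t1") for p in rng.integers(450, 500, n)]
        prof = junction_distance_profile(sites, {"t1": tx})
        assert prof.n_sites_in_window == n
        chi2 = ((prof.counts - n / 50) ** 2 / (n / 50)).sum()
        p = stats.chi2.sf(chi2, df=49)
        assert p > 0.001


class TestWindows:
    def test_default_window_length_40(self, small_sim):
        ds, _, _ = small_sim
        tx = {t.transcript_id: t for t in ds.truth.transcripts}
        sites = []
        for rec in ds.truth.planted_targets():
            m = tx[rec.transcript_id]
            sites.append(((m.chromosome, m.strand, rec.cleavage_genomic), rec.transcript_id))
        windows, dropped = extract_window_sequences(sites, ds.genome, tx)
        assert dropped == 0
        assert all(len(w) == 40 for w in windows.values())

    def test_minus_strand_hand_spliced_oracle(self):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 400)
        genome = GenomeSequence("g", {"chr1": seq})
        tx = coding_tx(exons=((0, 200), (250, 400)), cds=(20, 380), strand="-")
        from cleavecall.annotation_io import reverse_complement

        spliced = reverse_complement(seq[0:200] + seq[250:400])
        s = 100
        g = tx.transcript_to_genomic(s)
        windows, _ = extract_window_sequences(
            [(("chr1", "-", g), "t1")], genome, {"t1": tx}
        )
        assert windows[("chr1", "-", g)] == spliced[80:120]
        assert windows[("chr1", "-", g)][20] == spliced[100]

    def test_near_end_dropped(self):
        rng = np.random.default_rng(5)
        genome = GenomeSequence("g", {"chr1": random_seq(rng, 500)})
        tx = coding_tx()
        windows, dropped = extract_window_sequences(
            [(("chr1", "+", 10), "t1")], genome, {"t1": tx}
        )
        assert windows == {}
        assert dropped == 1


def brute_force_iupac_matches(seq, pattern):
    offs = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in IUPAC[c] for j, c in enumerate(pattern)):
            offs.append(i)
    return offs


class TestScanMotif:
    def test_examples(self):
        assert scan_motif(["CGGAG"]) == [[0]]
        assert scan_motif(["AGGAG"]) == [[]]
        assert scan_motif(["TGGTG"]) == [[0]]  # Y->T, W->T

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError):
            MotifSpec(iupac_pattern="YGGXZ")

    def test_brute_force_oracle_1000_random_40mers(self):
        rng = np.random.default_rng(6)
        spec = MotifSpec()
        seqs = [random_seq(rng, 40) for _ in range(1000)]
        got = scan_motif(seqs, spec)
        for seq, offs in zip(seqs, got):
            assert offs == brute_force_iupac_matches(seq, spec.iupac_pattern)

    def test_overlapping_matches(self):
        # two overlapping YGGWG instances: CGGAG at 0 and GGAGG? construct
        seq = "CGGTGGAGC"  # CGGTG at 0, TGGAG at 3
        assert scan_motif([seq]) == [[0, 3]]


class TestMotifDistribution:
    def test_single_inset_hit(self):
        spec = MotifSpec()
        # hit starting 2 nt 3' of the site base: offset hw + 2
        dist = motif_positional_distribution([[spec.window_halfwidth + 2]], spec)
        assert dist.inset_counts[spec.inset_halfwidth + 2] == 1
        assert dist.inset_fraction == 1.0
        assert dist.n_hits == 1

    def test_no_hits(self):
        dist = motif_positional_distribution([[], []])
        assert dist.coarse_counts.sum() == 0
        assert dist.inset_fraction == 0.0

    def test_histograms_conserve_hits(self):
        rng = np.random.default_rng(7)
        spec = MotifSpec()
        hits = [sorted(rng.integers(0, 36, rng.integers(0, 4)).tolist()) for _ in range(50)]
        dist = motif_positional_distribution(hits, spec)
        assert dist.coarse_counts.sum() == dist.n_hits

    def test_planted_offset_is_mode(self, small_sim):
        ds, _, _ = small_sim
        tx = {t.transcript_id: t for t in ds.truth.transcripts}
        spec = MotifSpec()
        sites = [
            ((tx[r.transcript_id].chromosome, tx[r.transcript_id].strand, r.cleavage_genomic), r.transcript_id)
            for r in ds.truth.planted_targets()
        ]
        windows, _ = extract_window_sequences(sites, ds.genome, tx, spec)
        hits = scan_motif(list(windows.values()), spec)
        dist = motif_positional_distribution(hits, spec)
        planted_offset = ds.config.motif_offsets[0]
        assert dist.inset_counts.argmax() == spec.inset_halfwidth + planted_offset
        assert dist.inset_fraction > 0.9


class TestKmerEnrichment:
    def test_hypergeometric_oracle(self):
        rng = np.random.default_rng(8)
        kmer = "ACGTG"
        targets = [kmer + random_seq(rng, 5) for _ in range(50)]
        targets += [random_seq(rng, 10).replace(kmer, "AAAAA") for _ in range(50)]
        controls = [kmer + random_seq(rng, 5) for _ in range(5)]
        controls += [random_seq(rng, 10).replace(kmer, "AAAAA") for _ in range(995)]
        table = kmer_differential_enrichment(targets, controls, k_min=5, k_max=5)
        row = table[table.kmer == kmer].iloc[0]
        t, c = int(row.target_count), int(row.control_count)
        M, N = 1100, 100
        n = t + c
        expected = sum(
            comb(n, k) * comb(M - n, N - k) for k in range(t, min(n, N) + 1)
        ) / comb(M, N)
        assert row.p == pytest.approx(expected, rel=1e-10)

    def test_exchangeable_null(self):
        rng = np.random.default_rng(9)
        seqs = [random_seq(rng, 20) for _ in range(40)]
        table = kmer_differential_enrichment(seqs, list(seqs), k_min=5, k_max=5)
        assert (table.q <= 0.05).sum() == 0

    def test_too_long_k_rejected(self):
        with pytest.raises(ValueError, match="k_max"):
            kmer_differential_enrichment(["ACGT"], ["ACGT"], k_min=5, k_max=7)

    def test_planted_motif_ranks_first(self, small_sim):
        ds, _, _ = small_sim
        tx = {t.transcript_id: t for t in ds.truth.transcripts}
        spec = MotifSpec()
        target_sites = [
            ((tx[r.transcript_id].chromosome, tx[r.transcript_id].strand, r.cleavage_genomic), r.transcript_id)
            for r in ds.truth.planted_targets()
        ]
        t_windows, _ = extract_window_sequences(target_sites, ds.genome, tx, spec)
        # controls: CDS midpoints of non-target transcripts
        control_sites = []
        for rec in ds.truth.records:
            if rec.class_label == "dne1_target":
                continue
            m = tx[rec.transcript_id]
            lo, hi = m.cds_transcript_interval()
            g = m.transcript_to_genomic((lo + hi) // 2)
            control_sites.append(((m.chromosome, m.strand, g), rec.transcript_id))
        c_windows, _ = extract_window_sequences(control_sites, ds.genome, tx, spec)
        table = kmer_differential_enrichment(
            list(t_windows.values()), list(c_windows.values()), k_min=5, k_max=5
        )
        top = table.iloc[0].kmer
        assert brute_force_iupac_matches(top, spec.iupac_pattern) == [0]


class TestBH:
    def test_matches_statsmodels_style_formula(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 37)
        q = bh_adjust(p)
        n = len(p)
        order = np.argsort(p)
        expected = np.empty(n)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = n - rank_from_end
            val = min(prev, p[idx] * n / rank)
            expected[idx] = val
            prev = val
        assert np.allclose(q, expected)


class TestSetOverlap:
    def test_disjoint_sets(self):
        uni = set(range(1000))
        res = set_overlap_test(set(range(10)), set(range(500, 520)), uni, 200, seed=0)
        assert res.observed == 0
        assert res.hypergeom_p == pytest.approx(1.0)
        assert res.fisher_odds < 1 or res.fisher_odds == 0.0

    def test_identical_sets_enumeration_oracle(self):
        uni = set("abcdefghijkl")  # |U| = 12
        a = set("abcde")
        res = set_overlap_test(a, a, uni, 100, seed=1)
        # oracle: enumerate all C(12,5) draws, count overlap >= 5
        hits = sum(
            1 for combo in itertools.combinations(sorted(uni), 5) if set(combo) == a
        )
        expected = hits / comb(12, 5)
        assert res.hypergeom_p == pytest.approx(expected, rel=1e-10)

    def test_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            set_overlap_test({"x"}, set(), {"a"}, 10, seed=0)

    def test_permutation_converges_to_hypergeometric(self):
        rng = np.random.default_rng(11)
        uni = set(range(200))
        a = set(rng.choice(200, 30, replace=False).tolist())
        b = set(rng.choice(200, 40, replace=False).tolist())
        res = set_overlap_test(a, b, uni, 10_000, seed=2)
        # P(overlap >= obs) under the null, versus Monte Carlo estimate
        se = math.sqrt(res.hypergeom_p * (1 - res.hypergeom_p) / 10_000)
        assert abs(res.permutation_p - res.hypergeom_p) <= 3 * se + 2e-4


def brute_force_ranksum_p(x, y):
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    m = len(x)
    obs = sum(ranks[:m])
    mu = m * sum(ranks) / len(pooled)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), m):
        total += 1
        w = sum(ranks[i] for i in combo)
        if abs(w - mu) >= abs(obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


class TestHalfLife:
    def test_medians(self):
        table = {f"a{i}": v for i, v in enumerate([10, 55, 100])}
        table.update({f"b{i}": v for i, v in enumerate([100, 108, 200])})
        res = halflife_group_compare(
            {"a0", "a1", "a2"}, {"b0", "b1", "b2"}, table
        )
        assert res.median_a == 55
        assert res.median_b == 108

    def test_identical_groups_p_one(self):
        table = {f"a{i}": float(v) for i, v in enumerate([3, 7, 11, 20])}
        table.update({f"b{i}": float(v) for i, v in enumerate([3, 7, 11, 20])})
        res = halflife_group_compare(
            {f"a{i}" for i in range(4)}, {f"b{i}" for i in range(4)}, table
        )
        assert res.p_value == pytest.approx(1.0)

    def test_exact_vs_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = rng.uniform(0, 10, 5).tolist()
            y = rng.uniform(2, 12, 6).tolist()
            assert ranksum_test(x, y) == pytest.approx(brute_force_ranksum_p(x, y))

    def test_short_fraction(self):
        table = {"a0": 30.0, "a1": 60.0, "a2": 90.0, "b0": 100.0, "b1": 120.0, "b2": 50.0}
        res = halflife_group_compare({"a0", "a1", "a2"}, {"b0", "b1", "b2"}, table)
        assert res.frac_short_a == pytest.approx(2 / 3)
        assert res.frac_short_b == pytest.approx(1 / 3)

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="insufficient"):
            halflife_group_compare({"a"}, {"b"}, {"a": 1.0, "b": 2.0})

    def test_power_under_location_shift(self):
        significant = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.lognormal(0, 0.5, 100)
            y = 2.0 * rng.lognormal(0, 0.5, 100)
            if ranksum_test(x.tolist(), y.tolist()) < 0.01:
                significant += 1
        assert significant >= 19

    def test_simulated_halflife_split(self, small_sim):
        ds, _, _ = small_sim
        table = dict(
            zip(ds.halflife.transcript_id, ds.halflife.halflife_min.astype(float))
        )
        targets = {r.transcript_id for r in ds.truth.planted_targets()}
        rest = set(table) - targets
        res = halflife_group_compare(targets, rest, table)
        assert res.median_a < res.median_b
        assert res.p_value < 0.01


class TestDecapShift:
    def _setup(self, xrn4_cpm, double_cpm, fc_wt_denom=1.0):
        tx = coding_tx(exons=((0, 500),), cds=(100, 400))
        cat = DecapCatalog(positions={("chr1", "+", 0)})
        xrn4 = make_profile({0: xrn4_cpm})
        double = make_profile({0: double_cpm}, genotype="dne1_xrn4")
        wt = make_profile({0: fc_wt_denom}, genotype="wild_type")
        fc_xw = log2_compare(xrn4, wt)
        fc_dw = log2_compare(double, wt)
        return cat, fc_xw, fc_dw, xrn4, double, [tx]

    def test_low_abundance_excluded(self):
        cat, fc_xw, fc_dw, xrn4, double, txs = self._setup(4.9, 4.9)
        out = decap_abundance_shift(cat, fc_xw, fc_dw, xrn4, double, txs, set())
        assert out["rest"]["n"] == 0

    def test_low_fc_excluded(self):
        # xrn4 9.0 vs wt 5.0 -> fc ~ 0.85 < 1
        cat, fc_xw, fc_dw, xrn4, double, txs = self._setup(9.0, 9.0, fc_wt_denom=5.0)
        out = decap_abundance_shift(cat, fc_xw, fc_dw, xrn4, double, txs, set())
        assert out["rest"]["n"] == 0

    def test_eligible_included(self):
        cat, fc_xw, fc_dw, xrn4, double, txs = self._setup(20.0, 20.0)
        out = decap_abundance_shift(cat, fc_xw, fc_dw, xrn4, double, txs, set())
        assert out["rest"]["n"] == 1

    def test_simulator_redistribution_shift(self):
        """Double-mutant decap spikes scaled x2 -> +1 log2 median shift."""
        from cleavecall.degradome_quant import cpm_normalize, merge_replicates
        from cleavecall.site_caller import build_decap_catalog
        from cleavecall.synthetic_data import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            seed=13,
            n_transcripts=60,
            depth=2_000_000,
            utr5_range=(80, 150),
            cds_range=(400, 800),
            utr3_range=(100, 200),
            decap_redistribution=2.0,
            decap_sigma=0.3,
            background_fraction=0.05,
        )
        ds = simulate_dataset(cfg)
        merged = {
            g: merge_replicates(
                [cpm_normalize(ds.profiles[(g, r)]) for r in (1, 2)]
            )
            for g in ("wild_type", "xrn4", "dne1_xrn4")
        }
        cap = cpm_normalize(ds.cap_pare)
        cat = build_decap_catalog(cap, ds.truth.transcripts, PipelineConfig())
        fc_xw = log2_compare(merged["xrn4"], merged["wild_type"])
        fc_dw = log2_compare(merged["dne1_xrn4"], merged["wild_type"])
        out = decap_abundance_shift(
            cat, fc_xw, fc_dw, merged["xrn4"], merged["dne1_xrn4"],
            ds.truth.transcripts,
            {r.transcript_id for r in ds.truth.planted_targets()},
        )
        for grp in ("target", "rest"):
            if out[grp]["n"] >= 5:
                shift = out[grp]["median_double"] - out[grp]["median_xrn4"]
                assert shift == pytest.approx(1.0, abs=0.1)
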