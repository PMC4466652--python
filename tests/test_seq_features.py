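"""Phase, Fisher oracle, conservation profile, k-mer Z-scores, clustering."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from cansplice.io_formats import AsEvent, ConservationTrack, ValidationError
from cansplice.seq_features import (
    ProfileWindows,
    classify_phase,
    cluster_kmers,
    conservation_profile,
    count_kmers,
    fisher_exact_greater,
    kmer_zscores,
    kmers_link,
    mean_flank_conservation,
    phase_enrichment,
)


def _se(eid, length, strand="+", chrom=None, flank=200):
    return AsEvent(eid, "SE", "g", chrom or eid, strand, flank, flank + length)


class TestPhase:
    @pytest.mark.parametrize("length,phase", [(90, 0), (91, 1), (92, 2),
                                              (3, 0), (1, 1)])
    def test_classify(self, length, phase):
        assert classify_phase(length) == phase

    def test_nonpositive_length_error(self):
        with pytest.raises(ValidationError):
            classify_phase(0)

    def test_identical_sets_no_enrichment(self):
        evs = [_se(f"e{i}", 60 + i) for i in range(12)]
        pt = phase_enrichment(evs, evs)
        assert pt.fisher_p >= 0.5
        assert sum(pt.target_counts) == len(evs)

    def test_non_se_rejected(self):
        ri = AsEvent("r1", "RI", "g", "c", "+", 0, 100)
        with pytest.raises(ValidationError, match="SE events only"):
            phase_enrichment([ri], [_se("e1", 90)])


def fisher_greater_oracle(a, b, c, d):
    """Exact-fraction hypergeometric tail by enumerating tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    total = Fraction(comb(n, c1))
    tail = Fraction(0)
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        if aa >= a:
            tail += Fraction(comb(r1, aa) * comb(r2, c1 - aa))
    return float(tail / total)


class TestFisherOracle:
    def test_stated_table(self):
        # target 8/10 phase-0 vs control 2/10
        p = fisher_exact_greater([[8, 2], [2, 8]])
        assert p == pytest.approx(fisher_greater_oracle(8, 2, 2, 8), abs=1e-12)

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, 4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            p = fisher_exact_greater([[a, b], [c, d]])
            assert p == pytest.approx(fisher_greater_oracle(a, b, c, d),
                                      abs=1e-12)

    def test_phase_enrichment_detects_planted_difference(self, rng):
        # 124 targets at 53% phase-0 vs 5000 controls at 42%: detection in
        # most replicates at alpha=0.05
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            t0 = rng.binomial(124, 0.53)
            c0 = rng.binomial(5000, 0.42)
            p = fisher_exact_greater([[t0, 124 - t0], [c0, 5000 - c0]])
            hits += p < 0.05
        assert hits / n_rep >= 0.6


class TestConservationProfile:
    def test_constant_track(self):
        ev = _se("e1", 120)
        track = ConservationTrack({"e1": np.full(520, 0.7)})
        prof = conservation_profile([ev], track)
        np.testing.assert_allclose(prof.concatenated(), 0.7)
        assert prof.upstream_intron.size == 150
        assert prof.exon_start.size == prof.exon_end.size == 50
        assert prof.downstream_intron.size == 150

    def test_single_plus_strand_event_identity(self, rng):
        ev = _se("e1", 100)
        scores = rng.random(500)
        track = ConservationTrack({"e1": scores})
        prof = conservation_profile([ev], track)
        np.testing.assert_allclose(prof.upstream_intron, scores[50:200])
        np.testing.assert_allclose(prof.exon_start, scores[200:250])
        np.testing.assert_allclose(prof.exon_end, scores[250:300])
        np.testing.assert_allclose(prof.downstream_intron, scores[300:450])

    def test_minus_strand_mirrors_plus(self, rng):
        scores = rng.random(500)
        fwd = conservation_profile(
            [_se("e1", 100, "+")], ConservationTrack({"e1": scores}))
        rev = conservation_profile(
            [_se("e1", 100, "-")], ConservationTrack({"e1": scores[::-1]}))
        np.testing.assert_allclose(rev.concatenated(), fwd.concatenated())

    def test_uncovered_events_error(self):
        track = ConservationTrack({"other": np.full(500, 0.5)})
        with pytest.raises(ValidationError, match="no events covered"):
            conservation_profile([_se("e1", 100)], track)

    def test_planted_flanks_more_conserved(self, small_bundle):
        b = small_bundle
        planted = [e for e in b.events
                   if e.event_id in b.truth.planted_shared and e.mode == "SE"]
        background = [e for e in b.events if e.mode == "SE"
                      and e.event_id not in b.truth.planted_shared][:60]
        mp = mean_flank_conservation(planted, b.conservation)
        mb = mean_flank_conservation(background, b.conservation)
        p = stats.mannwhitneyu(mp, mb, alternative="greater").pvalue
        assert p < 0.01


class TestKmerZscores:
    def test_count_conservation_and_small_z_on_identical_sets(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(50)]
        res = kmer_zscores(seqs, seqs)
        total = sum(m.observed_count for m in res)
        assert total == sum(len(s) - 4 for s in seqs)
        zs = [m.z_score for m in res if np.isfinite(m.z_score)]
        assert np.max(np.abs(zs)) < 3.5   # no systematic enrichment vs itself

    def test_single_window_hand_formula(self):
        # target one AAAAA window; background has known p for AAAAA
        background = ["AAAAA", "CCCCC", "GGGGG", "TTTTT"]
        res = {m.kmer: m for m in kmer_zscores(["AAAAA"], background)}
        p = 1 / 4
        e = p * 1
        z = (1 - e) / np.sqrt(e * (1 - p))
        assert res["AAAAA"].z_score == pytest.approx(z, abs=1e-12)
        assert res["AAAAA"].observed_count == 1

    def test_planted_word_has_top_z(self, rng):
        bg = ["".join(rng.choice(list("ACGT"), 405)) for _ in range(2000)]
        tgt = ["".join(rng.choice(list("ACGT"), 405)) for _ in range(200)]
        for i in rng.choice(len(tgt), 60, replace=False):
            s = list(tgt[i])
            pos = int(rng.integers(0, 401))
            s[pos:pos + 5] = "TGTGT"
            tgt[i] = "".join(s)
        res = kmer_zscores(tgt, bg)
        best = max(res, key=lambda m: m.z_score if np.isfinite(m.z_score) else -9e9)
        assert best.kmer == "TGTGT"
        assert best.z_score > 2.5

    def test_background_duplication_invariance(self, rng):
        bg = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(20)]
        tgt = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(5)]
        z1 = {m.kmer: m.z_score for m in kmer_zscores(tgt, bg)}
        z2 = {m.kmer: m.z_score for m in kmer_zscores(tgt, bg + bg)}
        for k in z1:
            if np.isfinite(z1[k]):
                assert z1[k] == pytest.approx(z2[k], abs=1e-9)

    def test_ambiguous_bases_skipped(self):
        # every window touching the N is dropped; only "ACGTA" at offset 5 counts
        counts, total = count_kmers(["ACGTNACGTA"], 5)
        assert total == 1
        assert counts == {"ACGTA": 1}

    def test_empty_input_error(self):
        with pytest.raises(ValidationError):
            kmer_zscores([], ["ACGTACGT"])


class TestClusterKmers:
    def _hits(self, kmers, z=3.0):
        from cansplice.seq_features import MotifResult
        return [MotifResult(k, 10, 1.0, z) for k in kmers]

    def test_offset_neighbors_cluster_together(self):
        clusters = cluster_kmers(self._hits(["TGTGT", "GTGTG"]))
        assert len(clusters) == 1
        assert set(clusters[0]["members"]) == {"TGTGT", "GTGTG"}

    def test_dissimilar_kmers_stay_separate(self):
        clusters = cluster_kmers(self._hits(["AAAAA", "CCCCC"]))
        assert len(clusters) == 2

    def test_matches_transitive_closure_oracle(self, rng):
        kmers = list({"".join(rng.choice(list("ACGT"), 5)) for _ in range(20)})
        clusters = cluster_kmers(self._hits(kmers))
        # brute-force transitive closure of the pairwise link relation
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(kmers)
        for a, b in itertools.combinations(kmers, 2):
            if kmers_link(a, b):
                g.add_edge(a, b)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(c["members"]) for c in clusters}
        assert got == expected

    def test_consensus_of_singleton_is_itself(self):
        (c,) = cluster_kmers(self._hits(["ACGTA"]))
        assert c["consensus"] == "ACGTA"
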