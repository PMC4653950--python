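"""Dyad scoring, fragment-length estimation, stable and first dyads."""

import numpy as np
import pandas as pd
import pytest

from nucleocyclic import nucleosome_map as nm, sequtil, synthetic_data as sd
from nucleocyclic.tss_model import RepresentativeTss, TssCluster


def reads_frame(fwd=(), rev=()):
    return pd.DataFrame(
        {
            "pos": list(fwd) + list(rev),
            "strand": ["+"] * len(fwd) + ["-"] * len(rev),
        }
    )


def make_rep(pos, strand="+"):
    cluster = TssCluster(strand, np.array([pos]), np.array([1.0]))
    return RepresentativeTss(pos, strand, cluster)


class TestDyadScores:
    def test_forward_read_midpoint(self):
        track = nm.compute_dyad_scores(reads_frame(fwd=[1000]), 2000)
        assert track.raw_fwd[1073] == 1 and track.raw_fwd.sum() == 1

    def test_reverse_read_midpoint(self):
        track = nm.compute_dyad_scores(reads_frame(rev=[1000]), 2000)
        assert track.raw_rev[927] == 1 and track.raw_rev.sum() == 1

    def test_constant_track_unchanged_by_smoothing(self):
        x = np.full(500, 3.0)
        assert np.allclose(nm.running_mean(x, 21), x)

    def test_smoothing_conserves_mass(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(2.0, 1000).astype(float)
        sm = nm.running_mean(x, 21)
        # away from the edges the 21-bp average redistributes mass exactly
        assert sm[300:700].sum() * 21 == pytest.approx(
            np.convolve(x, np.ones(21), "same")[300:700].sum()
        )

    def test_planted_dyad_peak_matches_convolution_oracle(self):
        # 50 jitter-free reads at one dyad: smoothed track must equal the
        # direct convolution of the raw counts, peaking exactly at the dyad
        dyad = 5000
        track = nm.compute_dyad_scores(
            reads_frame(fwd=[dyad - 73] * 25, rev=[dyad + 73] * 25), 10_000
        )
        raw = np.zeros(10_000)
        raw[dyad] = 25
        oracle = np.convolve(raw, np.ones(21) / 21, "same")
        assert np.allclose(track.smooth_fwd, oracle)
        assert int(np.argmax(track.smooth_fwd)) in range(dyad - 10, dyad + 11)

    def test_strand_symmetry_reflection(self):
        # reversing all reads' strands on the reflected genome reflects the track
        g = 4000
        fwd = [100, 900, 2500]
        rev = [700, 1600, 3999]
        track = nm.compute_dyad_scores(reads_frame(fwd, rev), g)
        reflected = nm.compute_dyad_scores(
            reads_frame(fwd=[g - 1 - y for y in rev], rev=[g - 1 - x for x in fwd]), g
        )
        assert np.allclose(track.raw_fwd[::-1], reflected.raw_rev)
        assert np.allclose(track.raw_rev[::-1], reflected.raw_fwd)


class TestFragmentLength:
    def test_zero_discrepancy_on_matching_profiles(self):
        # a genome whose A/T profile is flat makes v+ == v- for every L
        genome = "AC" * 5000
        reads = reads_frame(fwd=[200, 400, 600], rev=[1200, 1400, 1600])
        res = nm.estimate_fragment_length(reads, genome)
        assert res.discrepancy[res.optimal_length] == pytest.approx(0.0)
        # exact ties resolve to the smallest candidate
        assert res.optimal_length == 137

    def test_recovers_planted_length(self):
        cfg = sd.SimConfig(genome_length=100_000, n_promoters=10, seed=21,
                           core_length_true=150)
        anc, truth = sd.simulate_ancestor_genome(cfg)
        reads = sd.simulate_nucleosome_reads(truth, cfg, anc, "testes")
        res = nm.estimate_fragment_length(reads, anc)
        assert abs(res.optimal_length - 150) <= 1

    def test_strand_exchange_invariance(self, small_world):
        # relabeling strands on the reverse-complemented genome leaves the
        # discrepancy curve unchanged
        genome = small_world["strains"]["focal"]
        all_reads = small_world["reads"]["testes"]
        reads = pd.concat(
            [
                all_reads[all_reads["strand"] == "+"].iloc[:2000],
                all_reads[all_reads["strand"] == "-"].iloc[:2000],
            ],
            ignore_index=True,
        )
        g = len(genome)
        flipped_genome = sequtil.codes_to_seq(
            sequtil.revcomp_codes(sequtil.seq_to_codes(genome))
        )
        flipped = reads.copy()
        flipped["pos"] = g - 1 - flipped["pos"]
        flipped["strand"] = np.where(flipped["strand"] == "+", "-", "+")
        r1 = nm.estimate_fragment_length(reads, genome)
        r2 = nm.estimate_fragment_length(flipped, flipped_genome)
        for L in r1.discrepancy:
            assert r1.discrepancy[L] == pytest.approx(r2.discrepancy[L])

    def test_edge_reads_skipped_and_counted(self):
        # a forward read needs room downstream, a reverse read upstream
        genome = "ACGT" * 1000
        reads = reads_frame(fwd=[3998, 500], rev=[3, 600])
        res = nm.estimate_fragment_length(reads, genome)
        assert res.n_skipped == 2


class TestStableDyads:
    def _tracks_from_scores(self, scores):
        z = np.zeros_like(scores)
        return nm.DyadScoreTrack(scores, z, scores, z)

    def test_isolation_kills_close_pairs(self):
        s = np.zeros(2000)
        s[800] = 5.0
        s[950] = 4.0  # 150 bp apart: both eliminated
        peaks = nm.call_peaks(s)
        assert peaks.tolist() == [800, 950]
        iso = nm._isolated(peaks, 165)
        assert not iso.any()

    def test_duplicated_25mer_flank_removed(self, rng):
        # plant one 25-mer twice: a peak whose flank holds it must drop
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=6000))
        motif = "ACGTACGTACGTACGTACGTACGTA"
        seq = seq[:1000] + motif + seq[1025:4000] + motif + seq[4025:]
        scores = np.zeros(len(seq))
        scores[1010] = 5.0  # flank contains the first motif copy
        scores[2500] = 5.0  # clean flank
        tracks = {t: self._tracks_from_scores(scores) for t in ("a", "b", "c")}
        out = nm.select_stable_dyads(tracks, seq)
        cand = out["a"].candidates.set_index("pos")
        assert not cand.loc[1010, "passed_uniqueness"]
        assert cand.loc[2500, "passed_uniqueness"]
        assert out["a"].dyads.tolist() == [2500]

    def test_cross_tissue_proximity_filter(self):
        base = np.zeros(3000)
        base[1000] = 5.0
        shifted = np.zeros(3000)
        shifted[1020] = 5.0  # 20 bp away: outside the 10-bp tolerance
        seq = "ACGT" * 750
        tracks = {
            "a": self._tracks_from_scores(base),
            "b": self._tracks_from_scores(base),
            "c": self._tracks_from_scores(shifted),
        }
        out = nm.select_stable_dyads(tracks, seq)
        assert len(out["a"].dyads) == 0

    def test_filters_only_remove(self, small_world):
        out = nm.select_stable_dyads(
            small_world["tracks"], small_world["strains"]["focal"]
        )
        for res in out.values():
            peaks = set(res.candidates["pos"].tolist())
            assert set(res.dyads.tolist()) <= peaks

    def test_recall_and_precision_on_simulation(self, small_world):
        out = nm.select_stable_dyads(
            small_world["tracks"], small_world["strains"]["focal"]
        )
        planted = small_world["truth"].stable_dyads()
        for res in out.values():
            called = res.dyads
            d_planted = np.min(np.abs(planted[:, None] - called[None, :]), axis=1)
            d_called = np.min(np.abs(planted[:, None] - called[None, :]), axis=0)
            assert (d_planted <= 5).mean() > 0.90
            assert (d_called <= 5).mean() > 0.95

    def test_fewer_than_three_tissues_raises(self):
        t = self._tracks_from_scores(np.zeros(100))
        with pytest.raises(ValueError, match="three"):
            nm.select_stable_dyads({"a": t, "b": t}, "ACGT" * 25)


class TestFirstDyads:
    def _track(self, scores):
        z = np.zeros_like(scores)
        return nm.DyadScoreTrack(scores, z, scores, z)

    def test_argmax_in_window(self):
        s = np.zeros(2000)
        s[1100] = 5.0
        result, table = nm.locate_first_dyads([make_rep(1000)], self._track(s))
        assert result[0] == 1100 and table["pos"].tolist() == [1100]

    def test_minus_strand_window(self):
        s = np.zeros(2000)
        s[900] = 5.0
        result, _ = nm.locate_first_dyads([make_rep(1000, "-")], self._track(s))
        assert result[0] == 900

    def test_all_zero_window_undefined(self):
        result, table = nm.locate_first_dyads([make_rep(1000)], self._track(np.zeros(2000)))
        assert result[0] is None and len(table) == 0

    def test_shared_dyad_counted_once(self):
        s = np.zeros(2000)
        s[1100] = 5.0
        reps = [make_rep(1000), make_rep(1040)]
        result, table = nm.locate_first_dyads(reps, self._track(s))
        assert result[0] == result[1] == 1100
        assert len(table) == 1
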