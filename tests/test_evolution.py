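"""Ancestral parsimony, mutation-rate tracks, flux conservation, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleocyclic import evolution as ev, sequtil, synthetic_data as sd


def anchors(positions, strands=None):
    df = pd.DataFrame({"pos": positions})
    if strands is not None:
        df["strand"] = strands
    return df


class TestParsimony:
    @pytest.mark.parametrize(
        "triple,expected_anc,expected_status",
        [
            (("A", "A", "A"), "A", "no_mutation"),
            (("G", "A", "A"), "A", "mutated"),  # outgroup sides with sister
            (("A", "C", "A"), "A", "no_mutation"),  # outgroup sides with focal
            (("A", "C", "C"), "C", "mutated"),
            (("A", "C", "G"), None, "undetermined"),  # three-way disagreement
            (("A", "A", "G"), None, "undetermined"),  # outgroup matches neither
            (("N", "A", "A"), None, "excluded"),
        ],
    )
    def test_single_site_rules(self, triple, expected_anc, expected_status):
        anc, status = ev.infer_ancestral_base(*triple)
        assert anc == expected_anc and status == expected_status

    def test_statuses_partition_all_sites(self, small_world):
        s = small_world["strains"]
        calls = ev.infer_ancestral_calls(s["focal"], s["sister"], s["outgroup"])
        kinds = {"no_mutation", "mutated", "undetermined", "excluded"}
        assert set(np.unique(calls.status)) <= kinds
        assert len(calls.status) == len(s["focal"])

    def test_mutated_implies_determined_and_changed(self, small_world):
        s = small_world["strains"]
        calls = ev.infer_ancestral_calls(s["focal"], s["sister"], s["outgroup"])
        m = calls.mutated
        assert (calls.ancestor[m] >= 0).all()
        assert (calls.ancestor[m] != calls.focal[m]).all()

    def test_rate_matrix_recovery_within_3sd(self):
        # 2e5 iid sites evolved under the default matrices: the focal-branch
        # per-category counts among determined sites match the matrix entries
        rng = np.random.default_rng(17)
        anc_codes = rng.integers(0, 4, 200_000).astype(np.uint8)
        ancestor = sequtil.codes_to_seq(anc_codes)
        cfg = sd.SimConfig(seed=17)
        strains, _ = sd.evolve_strains(ancestor, cfg)
        calls = ev.infer_ancestral_calls(
            strains["focal"], strains["sister"], strains["outgroup"]
        )
        det = calls.determined
        m = cfg.branch_rates["focal"]
        for x in range(4):
            n_x = int(((calls.ancestor == x) & det).sum())
            for y in range(4):
                if x == y:
                    continue
                obs = int(((calls.ancestor == x) & (calls.focal == y) & det).sum())
                exp = n_x * m[x, y]
                assert abs(obs - exp) <= 3 * np.sqrt(exp * (1 - m[x, y])) + 1


class TestRateTracks:
    def _calls(self, anc_seq, focal_seq):
        anc = sequtil.seq_to_codes(anc_seq)
        foc = sequtil.seq_to_codes(focal_seq)
        status = np.where(anc == foc, "no_mutation", "mutated").astype(object)
        return ev.AncestralCalls(anc.astype(np.int8), foc.astype(np.int8), status)

    def test_rate_arithmetic(self):
        # 100 determined sites at one offset, 2 of them C->T
        anc = "C" * 100
        foc = "T" * 2 + "C" * 98
        calls = self._calls(anc, foc)
        track = ev.positional_mutation_rates(
            calls, anchors(np.arange(100), ["+"] * 100), half_width=0
        )
        assert track.rate("C->T")[0] == pytest.approx(0.02)
        assert track.totals[0] == 100

    def test_zero_rate_simulation_all_zero(self):
        cfg = sd.SimConfig(
            genome_length=30_000, n_promoters=5, seed=1,
            branch_rates={b: np.eye(4) for b in sd.BRANCHES},
        )
        anc, truth = sd.simulate_ancestor_genome(cfg)
        strains, _ = sd.evolve_strains(anc, cfg)
        calls = ev.infer_ancestral_calls(
            strains["focal"], strains["sister"], strains["outgroup"]
        )
        track = ev.positional_mutation_rates(
            calls, truth.tss[["pos", "strand"]], half_width=500
        )
        for c in ev.CATEGORIES:
            assert np.nansum(track.counts[c]) == 0

    def test_minus_strand_complements_categories(self):
        # an A->G change downstream of a minus-strand anchor reads as T->C
        anc = "A" * 401
        foc = "A" * 100 + "G" + "A" * 300
        calls = self._calls(anc, foc)
        plus = ev.positional_mutation_rates(calls, anchors([200], ["+"]), 100)
        minus = ev.positional_mutation_rates(calls, anchors([200], ["-"]), 100)
        assert plus.counts[(sequtil.A, sequtil.G)][100 - 100] == 1
        assert minus.counts[(sequtil.T, sequtil.C)][100 + 100] == 1

    def test_both_mode_complement_mirror_exact(self, small_world):
        s = small_world["strains"]
        calls = ev.infer_ancestral_calls(s["focal"], s["sister"], s["outgroup"])
        dyads = anchors(small_world["truth"].background_dyads)
        track = ev.positional_mutation_rates(calls, dyads, 200, mode="both")
        for (x, y) in ev.CATEGORIES:
            cx, cy = int(sequtil.COMPLEMENT[x]), int(sequtil.COMPLEMENT[y])
            assert np.allclose(
                track.rate((x, y)), track.rate((cx, cy))[::-1], equal_nan=True
            )

    def test_category_counts_sum_to_mutated_sites(self, small_world):
        s = small_world["strains"]
        calls = ev.infer_ancestral_calls(s["focal"], s["sister"], s["outgroup"])
        track = ev.positional_mutation_rates(
            calls, small_world["truth"].tss[["pos", "strand"]], 300
        )
        total_counts = sum(track.counts[c] for c in ev.CATEGORIES)
        # per-offset: categories partition the mutated sites
        reps = small_world["truth"].tss
        pos = reps["pos"].to_numpy()
        offs = np.arange(-300, 301)
        win_mut = calls.mutated[pos[:, None] + offs]
        strands = reps["strand"].to_numpy()
        win_mut[strands == "-"] = win_mut[strands == "-"][:, ::-1]
        assert np.array_equal(total_counts, win_mut.sum(axis=0).astype(float))


class TestFlux:
    def _track_from_counts(self, counts, totals, offsets):
        return ev.MutationRateTrack(offsets, counts, totals, "transcribed")

    def test_symmetric_rates_zero_net(self):
        offsets = np.arange(-5, 6)
        counts = {c: np.full(11, 3.0) for c in ev.CATEGORIES}
        track = self._track_from_counts(counts, np.full(11, 100.0), offsets)
        flux = ev.mutational_flux_summary(track, {"up": (-5, -1), "down": (1, 5)})
        assert np.allclose(flux.net_change.to_numpy(), 0.0)

    def test_flow_in_definition(self):
        offsets = np.arange(-5, 6)
        counts = {c: np.zeros(11) for c in ev.CATEGORIES}
        counts[(sequtil.C, sequtil.A)] = np.full(11, 1.0)
        track = self._track_from_counts(counts, np.full(11, 100.0), offsets)
        flux = ev.mutational_flux_summary(track, {"up": (-5, -1), "down": (1, 5)})
        assert flux.flow_in.loc["A", "up"] == pytest.approx(0.01)
        assert flux.flow_out.loc["C", "up"] == pytest.approx(0.01)
        assert flux.flow_in.loc["G", "up"] == 0.0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_conservation_holds_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        offsets = np.arange(-10, 11)
        counts = {c: rng.poisson(2.0, 21).astype(float) for c in ev.CATEGORIES}
        track = self._track_from_counts(counts, rng.integers(500, 600, 21).astype(float), offsets)
        flux = ev.mutational_flux_summary(track, {"up": (-10, -1), "down": (1, 10)})
        assert np.allclose(flux.net_change.sum(axis=0).to_numpy(), 0.0, atol=1e-15)


class TestContrasts:
    def test_identical_tracks_not_significant(self, rng):
        offsets = np.arange(-200, 201)
        counts = {c: rng.poisson(3.0, 401).astype(float) for c in ev.CATEGORIES}
        track = ev.MutationRateTrack(offsets, counts, np.full(401, 500.0), "transcribed")
        res = ev.mutation_dyad_vs_linker_test(track, track, "C->T")
        assert res.p_value == 0.5 and res.method == "degenerate"

    def test_unknown_category_raises(self, rng):
        offsets = np.arange(-200, 201)
        counts = {c: np.zeros(401) for c in ev.CATEGORIES}
        track = ev.MutationRateTrack(offsets, counts, np.full(401, 10.0), "transcribed")
        with pytest.raises(ValueError):
            ev.mutation_dyad_vs_linker_test(track, track, "C->C")

    def test_doubling_counts_preserves_p(self, rng):
        offsets = np.arange(-200, 201)
        c1 = {c: rng.poisson(3.0, 401).astype(float) for c in ev.CATEGORIES}
        c2 = {c: rng.poisson(3.0, 401).astype(float) for c in ev.CATEGORIES}
        t1 = ev.MutationRateTrack(offsets, c1, np.full(401, 500.0), "transcribed")
        t2 = ev.MutationRateTrack(offsets, c2, np.full(401, 500.0), "transcribed")
        p_ref = ev.mutation_dyad_vs_linker_test(t1, t2, "C->T").p_value
        d1 = ev.MutationRateTrack(
            offsets, {c: v * 2 for c, v in c1.items()}, np.full(401, 1000.0), "transcribed"
        )
        d2 = ev.MutationRateTrack(
            offsets, {c: v * 2 for c, v in c2.items()}, np.full(401, 1000.0), "transcribed"
        )
        assert ev.mutation_dyad_vs_linker_test(d1, d2, "C->T").p_value == pytest.approx(p_ref)

    def test_planted_downstream_ct_excess_significant(self, rng):
        offsets = np.arange(-500, 501)
        counts = {c: np.zeros(1001) for c in ev.CATEGORIES}
        counts[(sequtil.C, sequtil.T)] = np.where(
            offsets > 0, rng.poisson(8.0, 1001), rng.poisson(2.0, 1001)
        ).astype(float)
        counts[(sequtil.G, sequtil.A)] = rng.poisson(2.0, 1001).astype(float)
        track = ev.MutationRateTrack(offsets, counts, np.full(1001, 500.0), "transcribed")
        assert ev.ct_vs_ga_test(track).p_value < 0.01

    def test_flat_difference_degenerate_flagged(self):
        offsets = np.arange(-500, 501)
        counts = {c: np.full(1001, 2.0) for c in ev.CATEGORIES}
        track = ev.MutationRateTrack(offsets, counts, np.full(1001, 500.0), "transcribed")
        res = ev.ct_vs_ga_test(track)
        assert res.p_value == 0.5 and res.method == "degenerate"
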