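"""Nucleosome dyad-score tracks, core fragment length, stable and first dyads.

A single-end core read marks a dyad at the fragment midpoint: a forward
read anchored at x counts at x + (L-1)//2, a reverse read anchored at y
(the fragment's other end) at y - (L-1)//2, with L the assumed core length
(147 bp).  Raw counts per strand are smoothed with a 21-bp running average.

The mean core fragment length is re-estimated from sequence: for each
candidate L in 137..157 the A/T incidence vectors over the fragment
interior (30 bp trimmed at both ends, so MNase cleavage skew does not
contribute) are compared between forward-anchored and reverse-anchored
reads; the discrepancy — the mean squared difference — is minimal when the
imputed far end matches the real end-to-end distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from . import sequtil

CORE_LENGTH = 147
SMOOTH_WINDOW = 21
ISOLATION_BP = 165  # mean neighbor-dyad distance used as the isolation radius
UNIQUENESS_K = 25
CROSS_TISSUE_BP = 10
FIRST_DYAD_WINDOW = (50, 150)


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Edge-aware running average (divides by the in-range window size)."""
    num = uniform_filter1d(x.astype(float), size=window, mode="constant", cval=0.0)
    den = uniform_filter1d(np.ones_like(x, dtype=float), size=window, mode="constant")
    return num / den


@dataclass
class DyadScoreTrack:
    raw_fwd: np.ndarray
    raw_rev: np.ndarray
    smooth_fwd: np.ndarray
    smooth_rev: np.ndarray
    window: int = SMOOTH_WINDOW
    core_length: int = CORE_LENGTH

    def __len__(self) -> int:
        return len(self.raw_fwd)


def compute_dyad_scores(
    reads: pd.DataFrame,
    genome_length: int,
    core_length: int = CORE_LENGTH,
    window: int = SMOOTH_WINDOW,
) -> DyadScoreTrack:
    """Midpoint-count dyad scores per strand, smoothed over ``window`` bp."""
    half = (core_length - 1) // 2
    raw = {}
    for strand, sign in (("+", half), ("-", -half)):
        pos = reads.loc[reads["strand"] == strand, "pos"].to_numpy() + sign
        pos = pos[(pos >= 0) & (pos < genome_length)]
        raw[strand] = np.bincount(pos, minlength=genome_length).astype(float)
    return DyadScoreTrack(
        raw_fwd=raw["+"],
        raw_rev=raw["-"],
        smooth_fwd=running_mean(raw["+"], window),
        smooth_rev=running_mean(raw["-"], window),
        window=window,
        core_length=core_length,
    )


@dataclass
class FragmentLengthResult:
    optimal_length: int
    discrepancy: dict  # candidate L -> mean squared A/T incidence difference
    v_fwd: np.ndarray  # A/T incidence vector at the optimal L, forward reads
    v_rev: np.ndarray
    n_skipped: int  # reads too close to a contig end to evaluate


def estimate_fragment_length(
    reads: pd.DataFrame,
    genome: str,
    l_min: int = 137,
    l_max: int = 157,
    end_trim: int = 30,
) -> FragmentLengthResult:
    """Pick the core fragment length minimizing the strand discrepancy.

    Forward reads anchor the fragment start x (interior sampled ascending
    from x+30); reverse reads anchor the fragment end y, whose start is
    imputed as y-L+1 for each candidate L.  Ties go to the smaller L.
    """
    at = sequtil.at_mask(sequtil.seq_to_codes(genome))
    g = len(at)
    span = l_max - 2 * end_trim  # offsets sampled from each anchored end
    fwd = reads.loc[reads["strand"] == "+", "pos"].to_numpy()
    rev = reads.loc[reads["strand"] == "-", "pos"].to_numpy()
    if len(fwd) == 0 or len(rev) == 0:
        raise ValueError("need at least one read on each strand")
    ok_f = (fwd >= 0) & (fwd + end_trim + span - 1 < g)
    ok_r = (rev < g) & (rev - end_trim - span + 1 >= 0)
    n_skipped = int((~ok_f).sum() + (~ok_r).sum())
    fwd, rev = fwd[ok_f], rev[ok_r]
    offs = np.arange(end_trim, end_trim + span)
    profile_fwd = at[fwd[:, None] + offs].mean(axis=0)  # inward from start
    profile_rev = at[rev[:, None] - offs].mean(axis=0)  # inward from end
    discrepancy = {}
    for L in range(l_min, l_max + 1):
        k = L - 2 * end_trim
        v_f = profile_fwd[:k]
        # offsets y-L+31 .. y-30 ascending == inward profile reversed
        v_r = profile_rev[:k][::-1]
        discrepancy[L] = float(np.mean((v_f - v_r) ** 2))
    best = min(discrepancy, key=lambda L: (discrepancy[L], L))
    k = best - 2 * end_trim
    return FragmentLengthResult(
        optimal_length=best,
        discrepancy=discrepancy,
        v_fwd=profile_fwd[:k],
        v_rev=profile_rev[:k][::-1],
        n_skipped=n_skipped,
    )


def call_peaks(scores: np.ndarray, radius: int = CORE_LENGTH - 1) -> np.ndarray:
    """Positions whose score strictly exceeds every other score within
    ``radius`` bp; on a tie the leftmost position wins (it must strictly
    beat everything to its left, and only match to its right).  Zero is
    never a peak."""
    s = np.asarray(scores, dtype=float)
    n = len(s)
    pad = np.full(radius, -1.0)
    sp = np.concatenate([pad, s, pad])
    win = np.lib.stride_tricks.sliding_window_view(sp, radius)
    left = win[:n].max(axis=1)  # max s[x-radius .. x-1]
    right = win[radius + 1 : radius + 1 + n].max(axis=1)  # max s[x+1 .. x+radius]
    starts = np.flatnonzero((s > 0) & (s > left) & (s >= right))
    # a candidate marks the left edge of a run of equal values; report the
    # run's central position so flat-topped maxima stay unbiased
    peaks = np.empty(len(starts), dtype=np.int64)
    for i, x in enumerate(starts):
        k = 1
        while x + k < n and k < radius and s[x + k] == s[x]:
            k += 1
        peaks[i] = x + (k - 1) // 2
    return peaks


def _isolated(peaks: np.ndarray, radius: int) -> np.ndarray:
    """Mask of peaks with no other peak within ``radius`` bp (inclusive)."""
    if len(peaks) == 0:
        return np.zeros(0, dtype=bool)
    d_left = np.diff(peaks, prepend=peaks[0] - 2 * radius)
    d_right = np.diff(peaks, append=peaks[-1] + 2 * radius)
    return (d_left > radius) & (d_right > radius)


@dataclass
class StableDyadSet:
    dyads: np.ndarray  # final stable dyad positions for the tissue
    candidates: pd.DataFrame  # pos + pass/fail provenance of each filter


def select_stable_dyads(
    tracks: dict[str, DyadScoreTrack],
    genome: str,
    isolation: int = ISOLATION_BP,
    kmer: int = UNIQUENESS_K,
    proximity: int = CROSS_TISSUE_BP,
) -> dict[str, StableDyadSet]:
    """Stable dyads per tissue from forward-strand smoothed scores.

    Four filters, in order: (1) peaks = local score maxima within the core
    length; (2) isolation — drop peaks with another peak within 165 bp; (3)
    uniqueness — drop dyads whose +-165 bp flank contains a 25-mer occurring
    elsewhere in the genome; (4) cross-tissue — keep dyads with a surviving
    dyad within 10 bp in both other tissues.  Each filter only removes.
    """
    if len(tracks) < 3:
        raise ValueError("stable dyad calling needs three tissue tracks")
    codes = sequtil.seq_to_codes(genome)
    dup = sequtil.duplicated_kmer_mask(codes, k=kmer)
    dup_cum = np.concatenate(([0], np.cumsum(dup)))
    g = len(codes)

    def flank_has_duplicate(pos: np.ndarray) -> np.ndarray:
        lo = np.clip(pos - ISOLATION_BP, 0, len(dup))
        hi = np.clip(pos + ISOLATION_BP - kmer + 2, 0, len(dup))
        return (dup_cum[hi] - dup_cum[lo]) > 0

    prelim = {}
    for tissue, track in tracks.items():
        peaks = call_peaks(track.smooth_fwd, radius=track.core_length - 1)
        iso = _isolated(peaks, isolation)
        uniq = ~flank_has_duplicate(peaks)
        cand = pd.DataFrame(
            {"pos": peaks, "passed_isolation": iso, "passed_uniqueness": uniq}
        )
        prelim[tissue] = cand

    surviving = {
        t: c.loc[c["passed_isolation"] & c["passed_uniqueness"], "pos"].to_numpy()
        for t, c in prelim.items()
    }
    out = {}
    for tissue, cand in prelim.items():
        others = [surviving[t] for t in tracks if t != tissue]
        pos = cand["pos"].to_numpy()
        cross = np.ones(len(pos), dtype=bool)
        for arr in others:
            if len(arr) == 0:
                cross[:] = False
                continue
            i = np.searchsorted(arr, pos)
            near = np.full(len(pos), np.iinfo(np.int64).max)
            for j in (np.clip(i - 1, 0, len(arr) - 1), np.clip(i, 0, len(arr) - 1)):
                near = np.minimum(near, np.abs(pos - arr[j]))
            cross &= near <= proximity
        cand = cand.copy()
        cand["passed_cross_tissue"] = cross
        final = cand.loc[
            cand["passed_isolation"] & cand["passed_uniqueness"] & cross, "pos"
        ].to_numpy()
        out[tissue] = StableDyadSet(dyads=final, candidates=cand)
    return out


def locate_first_dyads(
    reps,
    track: DyadScoreTrack,
    window: tuple[int, int] = FIRST_DYAD_WINDOW,
) -> tuple[dict, pd.DataFrame]:
    """First downstream dyad per representative TSS.

    The dyad is the argmax of the smoothed forward-strand score in the
    strand-oriented window [+50, +150] downstream of the TSS (leftmost
    genomic position on ties); undefined (None) when all scores there are
    zero.  A dyad shared by several TSSs appears once in the returned
    unique table.
    """
    s = track.smooth_fwd
    g = len(s)
    lo_off, hi_off = window
    result = {}
    uniq: dict[int, str] = {}
    for i, rep in enumerate(reps):
        if rep.strand == "+":
            lo, hi = rep.pos + lo_off, rep.pos + hi_off + 1
        else:
            lo, hi = rep.pos - hi_off, rep.pos - lo_off + 1
        lo, hi = max(0, lo), min(g, hi)
        if hi <= lo or not np.any(s[lo:hi] > 0):
            result[i] = None
            continue
        pos = lo + int(np.argmax(s[lo:hi]))
        result[i] = pos
        uniq.setdefault(pos, rep.strand)
    table = pd.DataFrame(
        {"pos": list(uniq.keys()), "strand": list(uniq.values())}
    ).sort_values("pos", ignore_index=True)
    return result, table
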