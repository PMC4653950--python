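"""Nucleosome periodicity and consistency by windowed autocorrelation.

For each representative TSS the smoothed dyad-score track in the two
500-bp windows upstream and downstream is autocorrelated at lags 150..220;
the maximizing lag L* is the periodicity (nucleosome repeat length) and
R(L*) the consistency of the array.  TSSs are stratified into three groups
by downstream consistency; Group 1 (highest) is the "nucleocyclic" class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2

LAG_MIN = 150
LAG_MAX = 220
WINDOW = 500
SIDES = ("upstream", "downstream")


def autocorrelation_profile(
    s: np.ndarray, lag_min: int = LAG_MIN, lag_max: int = LAG_MAX
) -> pd.Series | None:
    """Normalized sample autocorrelation R(L) for L in [lag_min, lag_max].

    R(L) = sum_x (s[x]-m)(s[x-L]-m) / sum_x (s[x]-m)^2 over the whole
    window (mean-centered, full-window-variance denominator), so |R| <= 1.
    Returns None for a zero-variance window.
    """
    s = np.asarray(s, dtype=float)
    m = s.mean()
    d = s - m
    denom = float(np.sum(d * d))
    if denom == 0.0 or len(s) <= lag_max:
        return None
    lags = np.arange(lag_min, lag_max + 1)
    r = np.array([np.dot(d[L:], d[:-L]) for L in lags]) / denom
    return pd.Series(r, index=lags)


def periodicity_and_consistency(s: np.ndarray, lag_min=LAG_MIN, lag_max=LAG_MAX):
    """(L*, R(L*)) with ties broken to the smaller lag; None when undefined."""
    prof = autocorrelation_profile(s, lag_min, lag_max)
    if prof is None:
        return None
    best = int(prof.idxmax())  # idxmax returns the first (smallest) maximizer
    return best, float(prof.loc[best])


def tss_window(track_scores: np.ndarray, pos: int, strand: str, side: str, window: int = WINDOW):
    """Strand-oriented 501-point score window on one side of a TSS.

    Downstream runs 5'->3' from the TSS on the transcribed strand; None when
    the window leaves the track.
    """
    g = len(track_scores)
    downstream = (side == "downstream") == (strand == "+")
    lo, hi = (pos, pos + window + 1) if downstream else (pos - window, pos + 1)
    if lo < 0 or hi > g:
        return None
    w = track_scores[lo:hi]
    return w if strand == "+" else w[::-1]


def phasing_metrics(
    reps,
    tracks: dict[str, "DyadScoreTrack"],
    window: int = WINDOW,
    lag_min: int = LAG_MIN,
    lag_max: int = LAG_MAX,
) -> pd.DataFrame:
    """Tidy table (tss_id, tissue, side, periodicity, consistency, missing).

    Metrics are computed on the smoothed forward-strand score track of each
    tissue; a TSS whose window leaves the track, or whose window has zero
    variance, is flagged missing.
    """
    rows = []
    for tissue, track in tracks.items():
        s = track.smooth_fwd
        for i, rep in enumerate(reps):
            for side in SIDES:
                w = tss_window(s, rep.pos, rep.strand, side, window)
                res = periodicity_and_consistency(w, lag_min, lag_max) if w is not None else None
                rows.append(
                    {
                        "tss_id": i,
                        "tissue": tissue,
                        "side": side,
                        "periodicity": res[0] if res else np.nan,
                        "consistency": res[1] if res else np.nan,
                        "missing": res is None,
                    }
                )
    return pd.DataFrame(rows)


def group_tss_by_consistency(
    consistency: np.ndarray, k: int = 3, method: str = "tertile", seed: int = 0
) -> np.ndarray:
    """Group labels 1..k from downstream consistency (1 = most consistent).

    ``tertile`` (default) ranks the values and splits them into k strata of
    near-equal size (differing by at most 1); ties and all-equal inputs are
    resolved by position order, so the assignment is deterministic.
    ``kmeans`` clusters the 1-d values and orders centroids descending.
    Missing (NaN) values get label 0.
    """
    c = np.asarray(consistency, dtype=float)
    ok = ~np.isnan(c)
    n = int(ok.sum())
    if n < k:
        raise ValueError(f"need at least {k} non-missing consistency values")
    labels = np.zeros(len(c), dtype=int)
    idx = np.flatnonzero(ok)
    if method == "tertile":
        order = idx[np.argsort(-c[idx], kind="stable")]
        for grp, chunk in enumerate(np.array_split(order, k), start=1):
            labels[chunk] = grp
    elif method == "kmeans":
        centroids, assign = kmeans2(c[idx, None], k, minit="++", seed=seed)
        rank = np.argsort(-centroids[:, 0])
        remap = np.empty(k, dtype=int)
        remap[rank] = np.arange(1, k + 1)
        labels[idx] = remap[assign]
    else:
        raise ValueError(f"unknown grouping method: {method}")
    return labels
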