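"""Sequence composition around TSSs and dyads.

Windowed base counts and their upstream-minus-downstream asymmetry, the
two-sample incidence z-test, and per-offset incidence profiles with the
MNase-bias exclusion (offsets 70-74 bp upstream of dyads) and optional
both-strand complement averaging.

Offset 0 is the anchor base itself; the upstream window is [-500, -1] and
the downstream window [+1, +500] on the transcribed strand, so the anchor
is never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import sequtil
from .sequtil import AMBIG, BASES, COMPLEMENT
from .stats import RankSumResult, ranksum_one_tailed

WINDOW = 500
PROFILE_SMOOTH = 41
MNASE_EXCLUDE = (70, 74)  # bp upstream of dyads
DYAD_HALF = 30
LINKER_OFFSET = 100


@dataclass
class WindowComposition:
    """Counts in the 500-bp windows flanking one TSS (strand-oriented)."""

    up: dict  # base -> count; also "AA+TT", "CC+GG"
    down: dict
    asymmetry: dict  # up - down per key; negative = higher downstream


def _oriented_window(codes: np.ndarray, pos: int, strand: str, window: int):
    """(upstream, downstream) code arrays, 5'->3' on the transcribed strand."""
    g = len(codes)
    if pos - window < 0 or pos + window >= g:
        return None
    if strand == "+":
        up = codes[pos - window : pos]
        down = codes[pos + 1 : pos + window + 1]
    else:
        up = COMPLEMENT[codes[pos + 1 : pos + window + 1]][::-1]
        down = COMPLEMENT[codes[pos - window : pos]][::-1]
    return up, down


def _counts(codes: np.ndarray) -> dict:
    out = {b: int(np.sum(codes == i)) for i, b in enumerate(BASES)}
    same = codes[:-1] == codes[1:]
    at = (codes == sequtil.A) | (codes == sequtil.T)
    cg = (codes == sequtil.C) | (codes == sequtil.G)
    out["AA+TT"] = int(np.sum(same & at[:-1]))
    out["CC+GG"] = int(np.sum(same & cg[:-1]))
    return out


def window_base_counts(
    genome: str | np.ndarray, pos: int, strand: str, window: int = WINDOW
) -> WindowComposition | None:
    """Mono- and dinucleotide counts up/downstream of one TSS.

    Dinucleotides are counted with overlap (window-1 per side).  Returns
    None when either window is truncated by a contig edge.
    """
    codes = sequtil.seq_to_codes(genome) if isinstance(genome, str) else genome
    win = _oriented_window(codes, pos, strand, window)
    if win is None:
        return None
    up, down = (_counts(w) for w in win)
    asym = {k: up[k] - down[k] for k in up}
    return WindowComposition(up=up, down=down, asymmetry=asym)


def asymmetry_ztest(
    n1: int, m1: int, n2: int, m2: int, corrected: bool = False
) -> tuple[float, float]:
    """Two-sample z-test that base incidence is equal up- and downstream.

    Z = (n1/m1 - n2/m2) / sqrt(mu (1-mu) (1/n1 + 1/n2)) with
    mu = (n1+n2)/(m1+m2); two-sided p from the standard normal.  The
    denominator divides by the focal-base counts n_i; ``corrected=True``
    uses the conventional 1/m1 + 1/m2 instead.  With n1 or n2 zero the
    default form is undefined and (nan, nan) is returned.
    """
    if min(m1, m2) <= 0:
        raise ValueError("window totals must be positive")
    if not corrected and (n1 == 0 or n2 == 0):
        return float("nan"), float("nan")
    mu = (n1 + n2) / (m1 + m2)
    inv = (1 / n1 + 1 / n2) if not corrected else (1 / m1 + 1 / m2)
    var = mu * (1 - mu) * inv
    if var <= 0:
        return float("nan"), float("nan")
    z = (n1 / m1 - n2 / m2) / np.sqrt(var)
    return float(z), float(2.0 * norm.sf(abs(z)))


@dataclass
class IncidenceProfile:
    offsets: np.ndarray  # -half .. +half
    raw: pd.DataFrame  # per-base mean incidence; NaN at excluded offsets
    smoothed: pd.DataFrame  # 41-bp running average over available offsets
    mode: str  # "transcribed" or "both"
    n_anchors: int


def _nan_running_mean(values: np.ndarray, window: int) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    num = np.convolve(np.where(ok, v, 0.0), np.ones(window), mode="same")
    den = np.convolve(ok.astype(float), np.ones(window), mode="same")
    with np.errstate(invalid="ignore"):
        return num / den


def incidence_profile(
    anchors: pd.DataFrame,
    genome: str | np.ndarray,
    half_width: int = WINDOW,
    smooth: int = PROFILE_SMOOTH,
    mode: str = "transcribed",
    mnase_exclude: bool = False,
) -> IncidenceProfile:
    """Mean per-offset base incidence across anchors.

    ``anchors`` has columns pos (+ strand in transcribed mode).  In
    ``both`` mode the profile of each base at +d is averaged with its
    complement at -d, so complementary bases mirror exactly around the
    anchor.  With ``mnase_exclude`` the offsets 70-74 bp upstream of dyads
    are dropped before smoothing (cleavage-bias artifact) and rendered only
    by the smoothed curve.
    """
    codes = sequtil.seq_to_codes(genome) if isinstance(genome, str) else genome
    g = len(codes)
    pos = anchors["pos"].to_numpy()
    ok = (pos - half_width >= 0) & (pos + half_width < g)
    pos = pos[ok]
    if len(pos) == 0:
        raise ValueError("no usable anchors (empty set or all at contig edges)")
    offs = np.arange(-half_width, half_width + 1)
    win = codes[pos[:, None] + offs]
    if mode == "transcribed":
        strands = anchors["strand"].to_numpy()[ok]
        neg = strands == "-"
        if neg.any():
            win[neg] = COMPLEMENT[win[neg][:, ::-1]]
    elif mode != "both":
        raise ValueError(f"unknown mode: {mode}")
    valid = (win != AMBIG).sum(axis=0).astype(float)
    raw = {}
    for i, b in enumerate(BASES):
        with np.errstate(invalid="ignore"):
            raw[b] = (win == i).sum(axis=0) / valid
    raw = pd.DataFrame(raw, index=offs)
    if mnase_exclude:
        lo, hi = MNASE_EXCLUDE
        cut = (offs >= -hi) & (offs <= -lo)
        if mode == "both":
            cut |= (offs >= lo) & (offs <= hi)  # the mirrored strand's upstream
        raw[cut] = np.nan
    if mode == "both":
        flipped = raw.iloc[::-1].to_numpy()
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        averaged = {
            b: (raw[b].to_numpy() + flipped[:, BASES.index(comp[b])]) / 2.0
            for b in BASES
        }
        raw = pd.DataFrame(averaged, index=offs)
    smoothed = raw.apply(lambda col: _nan_running_mean(col.to_numpy(), smooth))
    return IncidenceProfile(
        offsets=offs, raw=raw, smoothed=smoothed, mode=mode, n_anchors=len(pos)
    )


def dyad_vs_linker_test(
    first_profile: np.ndarray | pd.Series,
    genome_profile: np.ndarray | pd.Series,
    offsets: np.ndarray,
    direction: str = "greater",
    dyad_half: int = DYAD_HALF,
    linker_offset: int = LINKER_OFFSET,
) -> RankSumResult:
    """Rank-sum contrast of dyad-window vs linker-window differences.

    The per-offset difference (first-dyad minus genome-wide profile) is
    collected over [-30, +30] around the dyad and over [70, 130] around the
    putative linker 100 bp downstream; offsets where either profile is
    missing are dropped.  ``direction`` states the one-tailed alternative
    for the dyad window relative to the linker window.
    """
    offsets = np.asarray(offsets)
    diff = np.asarray(first_profile, dtype=float) - np.asarray(
        genome_profile, dtype=float
    )
    dyad = diff[(offsets >= -dyad_half) & (offsets <= dyad_half)]
    linker = diff[
        (offsets >= linker_offset - dyad_half) & (offsets <= linker_offset + dyad_half)
    ]
    return ranksum_one_tailed(dyad, linker, alternative=direction)
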