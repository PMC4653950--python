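"""Ancestral bases, per-position mutation rates, and mutational flux.

The ancestor of the two focal strains is inferred by strict parsimony with
the outgroup: when the outgroup base matches the focal or the sister base,
that base is ancestral; three-way disagreements and outgroup-only matches
are undetermined, and any gap/ambiguous base excludes the site.  Mutations
are counted on the focal branch only (ancestor -> focal base), and rates
are normalized by all determined sites at each offset — not by
ancestor-X sites — so a mutation and its reverse are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from . import sequtil
from .sequtil import AMBIG, BASES, COMPLEMENT
from .stats import RankSumResult, ranksum_one_tailed

UNDETERMINED = -1
CATEGORIES = [(x, y) for x, y in permutations(range(4), 2)]  # 12 ordered pairs


def category_name(x: int, y: int) -> str:
    return f"{BASES[x]}->{BASES[y]}"


def parse_category(name: str) -> tuple[int, int]:
    try:
        x, y = name.split("->")
        pair = (BASES.index(x), BASES.index(y))
    except ValueError as exc:
        raise ValueError(f"not a base-change category: {name!r}") from exc
    if pair[0] == pair[1]:
        raise ValueError(f"not a base change: {name!r}")
    return pair


@dataclass
class AncestralCalls:
    """Per-site ancestral inference on focal-strain coordinates."""

    ancestor: np.ndarray  # base code, or -1 undetermined, -2 excluded
    focal: np.ndarray  # focal-strain base codes
    status: np.ndarray  # "no_mutation" | "mutated" | "undetermined" | "excluded"

    @property
    def mutated(self) -> np.ndarray:
        return self.status == "mutated"

    @property
    def determined(self) -> np.ndarray:
        return (self.status == "mutated") | (self.status == "no_mutation")


EXCLUDED = -2


def infer_ancestral_calls(focal, sister, outgroup) -> AncestralCalls:
    """Vectorized parsimony over aligned triples (strings or code arrays)."""
    f = sequtil.seq_to_codes(focal) if isinstance(focal, str) else np.asarray(focal)
    s = sequtil.seq_to_codes(sister) if isinstance(sister, str) else np.asarray(sister)
    o = sequtil.seq_to_codes(outgroup) if isinstance(outgroup, str) else np.asarray(outgroup)
    if not (len(f) == len(s) == len(o)):
        raise ValueError("aligned triple arrays must have equal length")
    anc = np.full(len(f), UNDETERMINED, dtype=np.int8)
    ok = (f < AMBIG) & (s < AMBIG) & (o < AMBIG)
    match = ok & ((o == f) | (o == s))
    anc[match] = o[match]
    anc[~ok] = EXCLUDED
    status = np.full(len(f), "undetermined", dtype=object)
    status[~ok] = "excluded"
    status[match & (anc == f)] = "no_mutation"
    status[match & (anc != f)] = "mutated"
    return AncestralCalls(ancestor=anc, focal=f.astype(np.int8), status=status)


def infer_ancestral_base(focal: str, sister: str, outgroup: str):
    """Single-site convenience wrapper; returns (ancestral base or None, status)."""
    calls = infer_ancestral_calls(focal, sister, outgroup)
    code = int(calls.ancestor[0])
    return (BASES[code] if code >= 0 else None), str(calls.status[0])


@dataclass
class MutationRateTrack:
    """Per-offset mutation counts and rates around a set of anchors."""

    offsets: np.ndarray
    counts: dict  # (x, y) -> array over offsets
    totals: np.ndarray  # determined sites per offset
    mode: str

    def rate(self, category: str | tuple[int, int]) -> np.ndarray:
        pair = parse_category(category) if isinstance(category, str) else category
        if pair not in self.counts:
            raise ValueError(f"unknown category {category!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0, self.counts[pair] / self.totals, np.nan)

    def rates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {category_name(*c): self.rate(c) for c in CATEGORIES}, index=self.offsets
        )


def positional_mutation_rates(
    calls: AncestralCalls,
    anchors: pd.DataFrame,
    half_width: int = 500,
    mode: str = "transcribed",
) -> MutationRateTrack:
    """Per-offset rates of each ordered base change around anchors.

    ``transcribed`` mode orients offsets 5'->3' on the anchor strand and
    complements base identities for minus-strand anchors; ``both`` mode
    (genome-wide dyads) averages each category with its complement at the
    mirrored offset, making complementary changes mirror exactly.
    """
    pos = anchors["pos"].to_numpy()
    g = len(calls.ancestor)
    ok = (pos - half_width >= 0) & (pos + half_width < g)
    pos = pos[ok]
    if len(pos) == 0:
        raise ValueError("no usable anchors")
    offs = np.arange(-half_width, half_width + 1)
    anc = calls.ancestor[pos[:, None] + offs]
    foc = calls.focal[pos[:, None] + offs].astype(np.int8)
    if mode == "transcribed":
        strands = anchors["strand"].to_numpy()[ok]
        neg = strands == "-"
        if neg.any():
            anc_neg = anc[neg][:, ::-1]
            foc_neg = foc[neg][:, ::-1]
            det = anc_neg >= 0
            anc_neg[det] = COMPLEMENT[anc_neg[det]]
            anc[neg] = anc_neg
            foc[neg] = COMPLEMENT[foc_neg].astype(np.int8)
    elif mode != "both":
        raise ValueError(f"unknown mode: {mode}")
    determined = anc >= 0
    totals = determined.sum(axis=0).astype(float)
    counts = {}
    for x, y in CATEGORIES:
        counts[(x, y)] = ((anc == x) & (foc == y)).sum(axis=0).astype(float)
    if mode == "both":
        comp = {c: (int(COMPLEMENT[c[0]]), int(COMPLEMENT[c[1]])) for c in CATEGORIES}
        sym_counts = {
            c: (counts[c] + counts[comp[c]][::-1]) for c in CATEGORIES
        }
        counts = sym_counts
        totals = totals + totals[::-1]
    return MutationRateTrack(offsets=offs, counts=counts, totals=totals, mode=mode)


@dataclass
class FluxSummary:
    """Region-pooled mutation rates, flows and net incidence change."""

    regions: dict  # name -> (lo, hi) inclusive offset bounds
    rates: pd.DataFrame  # index category, columns region
    flow_in: pd.DataFrame  # index base, columns region
    flow_out: pd.DataFrame
    net_change: pd.DataFrame  # flow_in - flow_out (= incidence change per base)


def mutational_flux_summary(
    track: MutationRateTrack,
    regions: dict | None = None,
) -> FluxSummary:
    """Pooled flux per region (default: upstream [-500,-1], downstream [1,500]).

    The rate of X->Y in a region is the pooled count over the region's
    offsets divided by the pooled determined-site total, so for every base
    Z the net incidence change equals flow-in(Z) - flow-out(Z) and the four
    net changes sum to zero exactly.
    """
    if regions is None:
        hw = int(track.offsets.max())
        regions = {"upstream": (-hw, -1), "downstream": (1, hw)}
    rate_rows = {}
    for name, (lo, hi) in regions.items():
        sel = (track.offsets >= lo) & (track.offsets <= hi)
        total = float(track.totals[sel].sum())
        rate_rows[name] = {
            category_name(*c): (track.counts[c][sel].sum() / total if total else np.nan)
            for c in CATEGORIES
        }
    rates = pd.DataFrame(rate_rows)
    flow_in = pd.DataFrame(
        {
            name: {
                BASES[z]: sum(
                    rate_rows[name][category_name(x, z)] for x in range(4) if x != z
                )
                for z in range(4)
            }
            for name in regions
        }
    )
    flow_out = pd.DataFrame(
        {
            name: {
                BASES[z]: sum(
                    rate_rows[name][category_name(z, y)] for y in range(4) if y != z
                )
                for z in range(4)
            }
            for name in regions
        }
    )
    return FluxSummary(
        regions=regions,
        rates=rates,
        flow_in=flow_in,
        flow_out=flow_out,
        net_change=flow_in - flow_out,
    )


def mutation_dyad_vs_linker_test(
    first_track: MutationRateTrack,
    genome_track: MutationRateTrack,
    category: str,
    direction: str = "greater",
    dyad_half: int = 30,
    linker_offset: int = 100,
) -> RankSumResult:
    """Dyad-vs-linker contrast of one mutation category's rate difference.

    Same machinery as the sequence-composition version: per-offset rate
    difference (first-dyad track minus genome-wide track) in the dyad
    window [-30, 30] versus the linker window [70, 130].
    """
    pair = parse_category(category)
    offs = first_track.offsets
    if not np.array_equal(offs, genome_track.offsets):
        raise ValueError("tracks must share offsets")
    diff = first_track.rate(pair) - genome_track.rate(pair)
    dyad = diff[(offs >= -dyad_half) & (offs <= dyad_half)]
    linker = diff[
        (offs >= linker_offset - dyad_half) & (offs <= linker_offset + dyad_half)
    ]
    return ranksum_one_tailed(dyad, linker, alternative=direction)


def ct_vs_ga_test(track: MutationRateTrack) -> RankSumResult:
    """Transcription-coupled-repair signature: C->T minus G->A, up vs down.

    d(x) = rate_{C->T}(x) - rate_{G->A}(x); one-tailed rank-sum that the
    upstream distribution {d(x): x<0} is smaller than the downstream one.
    """
    offs = track.offsets
    d = track.rate("C->T") - track.rate("G->A")
    up = d[offs < 0]
    down = d[offs > 0]
    return ranksum_one_tailed(up, down, alternative="less")


def smoothed_rate(track: MutationRateTrack, category: str, window: int = 41) -> np.ndarray:
    """41-bp running average of one category's rate (NaN-aware), for display."""
    from .seqcomp import _nan_running_mean

    return _nan_running_mean(track.rate(category), window)
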