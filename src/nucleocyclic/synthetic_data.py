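"""Synthetic genomes, tag libraries, nucleosome reads and strain histories.

The generator states one world and hands back its ground truth:

* an ancestor genome with planted promoters whose 500-bp upstream window is
  A/T-rich and whose 500-bp downstream window is C/G-rich;
* phased arrays of nucleosome dyads downstream of a configurable subset of
  promoters per tissue (first dyad ~ +100 bp, then one repeat length apart),
  fuzzy (randomly placed) nucleosomes downstream of the rest, and regularly
  spaced background arrays in intergenic space shared by all tissues;
* an A/T-composition envelope across every positioned nucleosome core
  (A/T depleted at the dyad with a weak ~10-bp periodic component), the
  canonical sequence preference of nucleosomes and the signal the
  fragment-length estimator needs;
* tag libraries with log-normal expression variation per tissue, expression
  boosted at promoters whose downstream array is phased in that tissue;
* strand-balanced single-end nucleosome core reads whose fragment ends are
  preferentially shifted onto A/T bases (MNase cleavage bias);
* substitution-only evolution of two descendant strains plus an outgroup
  under per-branch 4x4 substitution matrices, optionally modulated per site
  and per category.

Sites evolve independently; no indels are simulated, so the coordinate map
between strains is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import sequtil
from .sequtil import A, C, G, T

TISSUES = ("blastula", "testes", "liver")
BRANCHES = ("focal", "sister", "outgroup")


def substitution_matrix(total_rate: float, kappa: float = 2.0) -> np.ndarray:
    """4x4 per-site substitution probability matrix (rows = ancestral base).

    ``total_rate`` is the probability that a site substitutes at all on the
    branch; transitions are ``kappa`` times as likely as each transversion.
    Diagonal entries hold the stay probability.
    """
    m = np.zeros((4, 4))
    transver = total_rate / (kappa + 2.0)
    transit = kappa * transver
    pairs = {(A, G): transit, (G, A): transit, (C, T): transit, (T, C): transit}
    for x in range(4):
        for y in range(4):
            if x == y:
                continue
            m[x, y] = pairs.get((x, y), transver)
    np.fill_diagonal(m, 1.0 - m.sum(axis=1))
    return m


@dataclass
class SimConfig:
    """Stated world of the simulation.  All lengths in bp.

    Substitution rates default to ~1.7 % per descendant branch (half of the
    ~3.4 % SNP divergence between the two focal strains) and ~2.5 % on the
    outgroup branch.
    """

    genome_length: int = 500_000
    n_promoters: int = 150
    upstream_AT_fraction: float = 0.6
    downstream_CG_fraction: float = 0.6
    nucleosome_spacing: int = 180
    dyad_jitter_sd: float = 2.0
    core_length_true: int = 147
    fragment_length_sd: float = 5.0
    coverage: float = 50.0
    expression_log_sd: float = 1.0
    library_size: int = 1_000_000
    branch_rates: dict = field(
        default_factory=lambda: {
            "focal": substitution_matrix(0.017),
            "sister": substitution_matrix(0.017),
            "outgroup": substitution_matrix(0.025),
        }
    )
    phased_fraction: float = 1.0 / 3.0
    expression_phasing_boost: float = 1.0  # natural-log units
    mnase_at_weight: float = 3.0
    core_at_dip: float = 0.15
    core_at_period_amp: float = 0.08
    core_at_period: float = 10.2
    n_array: int = 3  # nucleosomes per phased downstream array
    first_dyad_offset: int = 100
    window: int = 500
    tag_decay: float = 0.5  # geometric decay of tag positions over +-10 bp
    silent_fraction: float = 0.15  # promoters without expression, per tissue
    seed: int = 0

    def validate(self) -> None:
        for name in ("upstream_AT_fraction", "downstream_CG_fraction", "phased_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 100 <= self.core_length_true <= 250:
            raise ValueError("core_length_true must be in [100, 250]")
        for branch, m in self.branch_rates.items():
            m = np.asarray(m)
            if m.shape != (4, 4):
                raise ValueError(f"branch {branch}: rate matrix must be 4x4")
            off = m.copy()
            np.fill_diagonal(off, 0.0)
            if (off < 0).any() or (off.sum(axis=1) > 1).any():
                raise ValueError(f"branch {branch}: off-diagonal rows must sum to <= 1")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Planted features of one simulated world (focal-strain coordinates)."""

    tss: pd.DataFrame  # pos, strand, phased_<tissue>, expr_<tissue>
    array_dyads: dict  # promoter index -> np.ndarray of phased array dyads
    fuzzy_dyads: dict  # tissue -> {promoter index -> np.ndarray}, downstream
    upstream_dyads: dict  # tissue -> {promoter index -> np.ndarray}, never phased
    background_dyads: np.ndarray  # shared across tissues
    substitutions: pd.DataFrame | None = None  # branch, pos, ancestral, derived
    coordinate_map: None = None  # identity (substitution-only evolution)

    def first_dyads(self, tissue: str) -> pd.DataFrame:
        """Planted first downstream dyads of promoters phased in ``tissue``."""
        rows = []
        phased = self.tss[f"phased_{tissue}"].to_numpy()
        for i, (pos, strand) in enumerate(
            zip(self.tss["pos"].to_numpy(), self.tss["strand"].to_numpy())
        ):
            if phased[i]:
                rows.append((self.array_dyads[i][0], strand))
        return pd.DataFrame(rows, columns=["pos", "strand"])

    def dyads_for_tissue(self, tissue: str) -> np.ndarray:
        parts = [self.background_dyads]
        phased = self.tss[f"phased_{tissue}"].to_numpy()
        for i in range(len(self.tss)):
            parts.append(self.array_dyads[i] if phased[i] else self.fuzzy_dyads[tissue][i])
            parts.append(self.upstream_dyads[tissue][i])
        return np.sort(np.concatenate(parts))

    def stable_dyads(self) -> np.ndarray:
        """Dyads planted at the same position in all three tissues."""
        always = [self.background_dyads]
        phased_all = np.ones(len(self.tss), dtype=bool)
        for t in TISSUES:
            phased_all &= self.tss[f"phased_{t}"].to_numpy()
        for i in np.flatnonzero(phased_all):
            always.append(self.array_dyads[i])
        return np.sort(np.concatenate(always))


def _promoter_layout(config: SimConfig, rng: np.random.Generator):
    g, n = config.genome_length, config.n_promoters
    slot = g // (n + 1)
    footprint = 2 * config.window + 200
    if slot < max(1001 + 2 * config.window // 5, footprint):
        raise ValueError(
            f"genome of {g} bp too short for {n} promoters at >1000 bp spacing"
        )
    jitter_max = max(1, min(slot // 10, (slot - 1001) // 2))
    pos = (np.arange(1, n + 1) * slot + rng.integers(-jitter_max, jitter_max + 1, n))
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    return pos.astype(np.int64), strand


def _apply_at_fraction(p: np.ndarray, lo: int, hi: int, at_frac: float) -> None:
    """Set window [lo, hi) base probabilities to the given A+T fraction."""
    p[lo:hi, A] = p[lo:hi, T] = at_frac / 2.0
    p[lo:hi, C] = p[lo:hi, G] = (1.0 - at_frac) / 2.0


def _overlay_core_profile(p: np.ndarray, dyads: np.ndarray, config: SimConfig) -> None:
    """Rescale A/T vs C/G probability around dyads by the core envelope."""
    half = 73
    offs = np.arange(-half, half + 1)
    taper = 0.5 * (1.0 + np.cos(np.pi * offs / half))
    delta = (
        -config.core_at_dip * taper
        + config.core_at_period_amp * np.cos(2 * np.pi * offs / config.core_at_period) * taper
    )
    g = len(p)
    for d in dyads:
        lo, hi = d - half, d + half + 1
        if lo < 0 or hi > g:
            continue
        at0 = p[lo:hi, A] + p[lo:hi, T]
        at1 = np.clip(at0 + delta, 0.05, 0.95)
        # split each pair evenly, preserving nothing but the A/T vs C/G balance
        p[lo:hi, A] = p[lo:hi, T] = at1 / 2.0
        p[lo:hi, C] = p[lo:hi, G] = (1.0 - at1) / 2.0


def simulate_ancestor_genome(config: SimConfig) -> tuple[str, GroundTruth]:
    """Draw the ancestor genome and its planted ground truth.

    Deterministic given ``config`` (including the seed).  Raises a sizing
    error when the genome cannot hold ``n_promoters`` at >1000 bp spacing.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])
    g = config.genome_length
    tss_pos, tss_strand = _promoter_layout(config, rng)
    n = config.n_promoters
    sign = np.where(tss_strand == "+", 1, -1)

    # phased status and expression per tissue; silent promoters are never
    # phased (phasing is transcription-coupled)
    phased = {}
    expr = {}
    for t in TISSUES:
        silent = rng.random(n) < config.silent_fraction
        phased[t] = (rng.random(n) < config.phased_fraction) & ~silent
        logx = rng.normal(0.0, config.expression_log_sd, n)
        logx = logx + config.expression_phasing_boost * phased[t]
        expr[t] = np.where(silent, 0.0, np.exp(logx))

    # planted dyads
    array_dyads = {}
    for i in range(n):
        first = tss_pos[i] + sign[i] * config.first_dyad_offset
        array_dyads[i] = first + sign[i] * config.nucleosome_spacing * np.arange(
            config.n_array
        )
    fuzzy_dyads = {t: {} for t in TISSUES}
    upstream_dyads = {t: {} for t in TISSUES}
    for t in TISSUES:
        for i in range(n):
            lo = 50 if sign[i] == 1 else -550
            offs = rng.integers(lo, lo + 501, config.n_array)
            fuzzy_dyads[t][i] = np.sort(tss_pos[i] + offs)
            # unphased upstream nucleosomes, leaving a ~150-bp depleted region
            up_lo = -550 if sign[i] == 1 else 150
            up_offs = rng.integers(up_lo, up_lo + 401, config.n_array)
            upstream_dyads[t][i] = np.sort(tss_pos[i] + up_offs)

    # intergenic background arrays, shared by all tissues
    zone = np.zeros(g, dtype=bool)
    for i in range(n):
        lo = max(0, tss_pos[i] - config.window - 200)
        hi = min(g, tss_pos[i] + config.window + config.n_array * config.nucleosome_spacing)
        zone[lo:hi] = True
    grid = np.arange(200, g - 200, config.nucleosome_spacing)
    background = grid[~zone[grid]]

    # per-site base probabilities
    p = np.full((g, 4), 0.25)
    for i in range(n):
        if sign[i] == 1:
            up = (tss_pos[i] - config.window, tss_pos[i])
            down = (tss_pos[i] + 1, tss_pos[i] + config.window + 1)
        else:
            up = (tss_pos[i] + 1, tss_pos[i] + config.window + 1)
            down = (tss_pos[i] - config.window, tss_pos[i])
        _apply_at_fraction(p, max(0, up[0]), min(g, up[1]), config.upstream_AT_fraction)
        _apply_at_fraction(
            p, max(0, down[0]), min(g, down[1]), 1.0 - config.downstream_CG_fraction
        )
    positioned = [background]
    any_phased = np.zeros(n, dtype=bool)
    for t in TISSUES:
        any_phased |= phased[t]
    for i in np.flatnonzero(any_phased):
        positioned.append(array_dyads[i])
    _overlay_core_profile(p, np.concatenate(positioned), config)

    u = rng.random(g)
    codes = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1).astype(np.uint8)

    tss = pd.DataFrame({"pos": tss_pos, "strand": tss_strand})
    for t in TISSUES:
        tss[f"phased_{t}"] = phased[t]
        tss[f"expr_{t}"] = expr[t]
    truth = GroundTruth(
        tss=tss,
        array_dyads=array_dyads,
        fuzzy_dyads=fuzzy_dyads,
        upstream_dyads=upstream_dyads,
        background_dyads=background,
    )
    return sequtil.codes_to_seq(codes), truth


def evolve_strains(
    ancestor: str,
    config: SimConfig,
    site_scale: dict | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Evolve focal, sister and outgroup strains from the ancestor.

    ``site_scale`` optionally holds per-site multipliers for specific
    categories: ``{branch: {(x_code, y_code): array_of_len_G}}``.  Each site
    substitutes independently; the returned table records every substitution
    (branch, pos, ancestral and derived code), which exactly reconstructs
    each descendant from the ancestor.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    anc = sequtil.seq_to_codes(ancestor)
    g = len(anc)
    strains = {}
    records = []
    for branch in BRANCHES:
        m = np.asarray(config.branch_rates[branch], dtype=float)
        derived = anc.copy()
        scales = (site_scale or {}).get(branch, {})
        for x in range(4):
            idx = np.flatnonzero(anc == x)
            if len(idx) == 0:
                continue
            targets = [y for y in range(4) if y != x]
            probs = np.empty((len(idx), 3))
            for j, y in enumerate(targets):
                probs[:, j] = m[x, y]
                if (x, y) in scales:
                    probs[:, j] = probs[:, j] * np.asarray(scales[(x, y)])[idx]
            cum = np.cumsum(probs, axis=1)
            if (cum[:, -1] > 1.0).any():
                raise ValueError(f"branch {branch}: scaled rates exceed 1 at some site")
            u = rng.random(len(idx))
            choice = (u[:, None] >= cum).sum(axis=1)  # 3 means "no substitution"
            hit = choice < 3
            ys = np.asarray(targets)[choice[hit]]
            pos = idx[hit]
            derived[pos] = ys
            records.append(
                pd.DataFrame(
                    {"branch": branch, "pos": pos, "ancestral": x, "derived": ys}
                )
            )
        strains[branch] = sequtil.codes_to_seq(derived)
    subs = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(columns=["branch", "pos", "ancestral", "derived"])
    )
    subs = subs.sort_values(["branch", "pos"], ignore_index=True)
    return strains, subs


def simulate_tag_library(
    truth: GroundTruth, config: SimConfig, rng: np.random.Generator | None = None
) -> dict[str, pd.DataFrame]:
    """Sample 5'-end tag counts per tissue (columns pos, strand, count).

    Each tissue's ``library_size`` tags fall on promoters in proportion to
    the planted expression, then spread over +-10 bp of the TSS with
    geometric decay.  Per-tissue totals equal the configured library size.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 303])
    n = len(truth.tss)
    if n == 0:
        raise ValueError("no planted TSSs")
    pos = truth.tss["pos"].to_numpy()
    strand = truth.tss["strand"].to_numpy()
    offsets = np.arange(-10, 11)
    w = config.tag_decay ** np.abs(offsets)
    w = w / w.sum()
    out = {}
    for t in TISSUES:
        expr = truth.tss[f"expr_{t}"].to_numpy()
        per_prom = rng.multinomial(config.library_size, expr / expr.sum())
        rows = []
        for i in np.flatnonzero(per_prom):
            per_off = rng.multinomial(per_prom[i], w)
            nz = np.flatnonzero(per_off)
            rows.append(
                pd.DataFrame(
                    {
                        "pos": pos[i] + offsets[nz],
                        "strand": strand[i],
                        "count": per_off[nz],
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        out[t] = df.sort_values(["strand", "pos"], ignore_index=True)
    return out


def _bias_ends(
    ends: np.ndarray, at: np.ndarray, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """Shift each end by -1/0/+1, weighted toward A/T bases."""
    if weight == 1.0:
        return ends
    cand = ends[:, None] + np.array([-1, 0, 1])
    cand = np.clip(cand, 0, len(at) - 1)
    w = np.where(at[cand], weight, 1.0)
    cum = np.cumsum(w, axis=1)
    u = rng.random(len(ends)) * cum[:, -1]
    pick = (u[:, None] >= cum).sum(axis=1)
    return cand[np.arange(len(ends)), pick]


def simulate_nucleosome_reads(
    truth: GroundTruth,
    config: SimConfig,
    genome: str,
    tissue: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample single-end nucleosome core read anchors for one tissue.

    Each planted dyad receives Poisson(``coverage``) fragments; fragment
    midpoints jitter around the dyad, lengths around ``core_length_true``,
    and both fragment ends are independently shifted (by at most 1 bp)
    toward A/T bases with weight ``mnase_at_weight``.  Each fragment is then
    sequenced from one end chosen with probability 0.5: a ``+`` read anchors
    at the fragment start, a ``-`` read at the fragment end (both the 5' end
    of the sequenced read on its own strand).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 404, hash(tissue) % (2**31)])
    at = sequtil.at_mask(sequtil.seq_to_codes(genome))
    g = len(at)
    dyads = truth.dyads_for_tissue(tissue)
    counts = rng.poisson(config.coverage, len(dyads))
    centers = np.repeat(dyads, counts)
    mids = np.rint(rng.normal(centers, config.dyad_jitter_sd)).astype(np.int64)
    lens = np.rint(
        rng.normal(config.core_length_true, config.fragment_length_sd, len(mids))
    ).astype(np.int64)
    lens = np.clip(lens, 100, 250)
    starts = mids - lens // 2
    ends = starts + lens - 1
    starts = _bias_ends(starts, at, config.mnase_at_weight, rng)
    ends = _bias_ends(ends, at, config.mnase_at_weight, rng)
    keep = (starts >= 0) & (ends < g) & (ends > starts)
    starts, ends = starts[keep], ends[keep]
    fwd = rng.random(len(starts)) < 0.5
    reads = pd.DataFrame(
        {
            "pos": np.where(fwd, starts, ends),
            "strand": np.where(fwd, "+", "-"),
        }
    )
    return reads.sort_values(["strand", "pos"], ignore_index=True)


def reconstruct_descendant(ancestor: str, subs: pd.DataFrame, branch: str) -> str:
    """Apply the recorded substitutions of one branch to the ancestor."""
    codes = sequtil.seq_to_codes(ancestor).copy()
    sel = subs[subs["branch"] == branch]
    codes[sel["pos"].to_numpy()] = sel["derived"].to_numpy()
    return sequtil.codes_to_seq(codes)
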