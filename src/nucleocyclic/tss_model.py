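"""TSS calling from 5'-end tag counts.

Tag counts are normalized to a 300,000-read library (one cell's worth of
mRNA, so ~1.0 means roughly one copy per cell), averaged across the three
tissues, clustered at a 20-bp gap above a 0.1 expression floor, and reduced
to representative TSSs spaced >500 bp apart.  Strands are processed
independently; all windows are oriented 5'->3' on the transcribed strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("blastula", "testes", "liver")

#: normalized library total: ~300,000 mRNA molecules per cell
TARGET_TOTAL = 300_000
MIN_EXPRESSION = 0.1
CLUSTER_GAP = 20
REPRESENTATIVE_SPACING = 500


def normalize_tags(tags: pd.DataFrame, target_total: float = TARGET_TOTAL) -> pd.DataFrame:
    """Scale raw per-position tag counts so they sum to ``target_total``.

    ``tags`` has columns pos, strand, count; the result replaces count with
    ``expr = count * target_total / total``.
    """
    total = float(tags["count"].sum())
    if total <= 0:
        raise ValueError("empty tag library: total raw count must be > 0")
    out = tags[["pos", "strand"]].copy()
    out["expr"] = tags["count"].to_numpy(dtype=float) * (target_total / total)
    return out


def merge_tissue_expression(tracks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Average normalized expression across tissues (absent position = 0)."""
    n = len(tracks)
    merged = (
        pd.concat(tracks.values(), ignore_index=True)
        .groupby(["strand", "pos"], as_index=False)["expr"]
        .sum()
    )
    merged["expr"] = merged["expr"] / n
    return merged.sort_values(["strand", "pos"], ignore_index=True)


@dataclass
class TssCluster:
    strand: str
    positions: np.ndarray  # sorted ascending (genomic)
    merged_expr: np.ndarray  # aligned with positions

    @property
    def peak(self) -> int:
        """Position of the highest merged expression (leftmost on ties)."""
        return int(self.positions[int(np.argmax(self.merged_expr))])

    @property
    def peak_expr(self) -> float:
        return float(self.merged_expr.max())


def call_tss_clusters(
    merged: pd.DataFrame,
    min_expr: float = MIN_EXPRESSION,
    gap: int = CLUSTER_GAP,
) -> list[TssCluster]:
    """Group positions with merged expression > ``min_expr`` into clusters.

    Neighbors <= ``gap`` bp apart join the same cluster; strands are
    clustered independently.
    """
    clusters: list[TssCluster] = []
    kept = merged[merged["expr"] > min_expr]
    for strand, sub in kept.groupby("strand"):
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        expr = sub["expr"].to_numpy()[order]
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > gap) + 1
        for chunk_pos, chunk_expr in zip(
            np.split(pos, breaks), np.split(expr, breaks)
        ):
            clusters.append(TssCluster(str(strand), chunk_pos, chunk_expr))
    clusters.sort(key=lambda c: (int(c.positions[0]), c.strand))
    return clusters


@dataclass
class RepresentativeTss:
    pos: int
    strand: str
    cluster: TssCluster
    expression: dict = field(default_factory=dict)  # tissue -> cluster sum
    breadth: dict = field(default_factory=dict)  # tissue -> bp
    active: dict = field(default_factory=dict)  # tissue -> bool
    group: int | None = None  # phasing group label (1 = nucleocyclic)


def select_representative_tss(
    clusters: list[TssCluster], spacing: int = REPRESENTATIVE_SPACING
) -> list[RepresentativeTss]:
    """Greedy selection of cluster peaks, pairwise > ``spacing`` bp apart.

    Candidates are per-cluster argmax positions, retained in descending
    merged-expression order (ties to the leftmost coordinate); a candidate
    within ``spacing`` bp of a retained one (either strand) is discarded.
    The result is maximal: no discarded candidate could be added back.
    """
    cands = [(c.peak_expr, c.peak, c) for c in clusters]
    cands.sort(key=lambda t: (-t[0], t[1]))
    kept_pos: list[int] = []
    reps: list[RepresentativeTss] = []
    for expr, pos, cluster in cands:
        if all(abs(pos - q) > spacing for q in kept_pos):
            kept_pos.append(pos)
            reps.append(RepresentativeTss(pos, cluster.strand, cluster))
    reps.sort(key=lambda r: r.pos)
    return reps


def cluster_breadth(cluster: TssCluster, tissue_track: pd.DataFrame) -> int:
    """Distance between the 5th- and 95th-percentile tag positions.

    The cumulative tag sum runs 5'->3' on the cluster's strand; each end is
    the first position whose cumulative sum reaches the percentile.  Returns
    0 for a cluster without tags in the tissue.
    """
    sub = tissue_track[tissue_track["strand"] == cluster.strand]
    expr = (
        sub.set_index("pos")["expr"].reindex(cluster.positions).fillna(0.0).to_numpy()
    )
    total = expr.sum()
    if total <= 0:
        return 0
    pos = cluster.positions
    if cluster.strand == "-":
        pos, expr = pos[::-1], expr[::-1]
    cum = np.cumsum(expr)
    p5 = pos[int(np.searchsorted(cum, 0.05 * total))]
    p95 = pos[int(np.searchsorted(cum, 0.95 * total))]
    return int(abs(int(p95) - int(p5)))


def attach_tissue_metrics(
    reps: list[RepresentativeTss],
    tissue_tracks: dict[str, pd.DataFrame],
    min_expr: float = MIN_EXPRESSION,
) -> list[RepresentativeTss]:
    """Fill per-tissue cluster expression, breadth and activity in place.

    Expression is the normalized tag sum over the cluster; a TSS is active
    in a tissue when that sum is >= ``min_expr`` (boundary inclusive).
    """
    for tissue, track in tissue_tracks.items():
        for strand, sub in track.groupby("strand"):
            by_pos = sub.set_index("pos")["expr"]
            for rep in reps:
                if rep.strand != strand:
                    continue
                expr = float(
                    by_pos.reindex(rep.cluster.positions).fillna(0.0).sum()
                )
                rep.expression[tissue] = expr
                rep.active[tissue] = expr >= min_expr
        for rep in reps:
            rep.expression.setdefault(tissue, 0.0)
            rep.active.setdefault(tissue, False)
            rep.breadth[tissue] = cluster_breadth(rep.cluster, track)
    return reps


def active_tss_sets(reps: list[RepresentativeTss], tissues=TISSUES):
    """Per-tissue active sets and the 7 Venn region counts.

    Region keys are membership strings in tissue order, e.g. "101" = active
    in the first and third tissue only.
    """
    sets = {t: {i for i, r in enumerate(reps) if r.active.get(t, False)} for t in tissues}
    venn = {}
    for code in range(1, 2 ** len(tissues)):
        bits = format(code, f"0{len(tissues)}b")
        members = set(range(len(reps)))
        for bit, t in zip(bits, tissues):
            members = members & sets[t] if bit == "1" else members - sets[t]
        venn[bits] = len(members)
    return sets, venn


def rep_table(reps: list[RepresentativeTss], tissues=TISSUES) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(reps):
        row = {"tss_id": i, "pos": r.pos, "strand": r.strand, "group": r.group}
        for t in tissues:
            row[f"expr_{t}"] = r.expression.get(t, 0.0)
            row[f"breadth_{t}"] = r.breadth.get(t, 0)
            row[f"active_{t}"] = r.active.get(t, False)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_strain_tss_distance(
    reps_a: list[RepresentativeTss],
    reps_b: list[RepresentativeTss],
    coordinate_map=None,
    thresholds=(0, 10, 50, 100),
):
    """Distance from each mapped strain-A representative to the nearest
    strain-B representative on the same strand.

    ``coordinate_map`` maps strain-A to strain-B coordinates: None means
    identity (substitution-only evolution); otherwise a callable or a dict.
    Returns (distances, cumulative fraction per threshold, n_excluded).
    """
    b_by_strand = {}
    for r in reps_b:
        b_by_strand.setdefault(r.strand, []).append(r.pos)
    b_by_strand = {s: np.sort(np.asarray(p)) for s, p in b_by_strand.items()}
    dists = []
    excluded = 0
    for r in reps_a:
        if coordinate_map is None:
            mapped = r.pos
        elif callable(coordinate_map):
            mapped = coordinate_map(r.pos)
        else:
            mapped = coordinate_map.get(r.pos)
        if mapped is None or r.strand not in b_by_strand:
            excluded += 1
            continue
        arr = b_by_strand[r.strand]
        i = np.searchsorted(arr, mapped)
        best = min(
            abs(mapped - arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)
        )
        dists.append(best)
    dists = np.asarray(dists, dtype=float)
    fractions = {
        t: float((dists <= t).mean()) if len(dists) else float("nan")
        for t in thresholds
    }
    return dists, fractions, excluded
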