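"""End-to-end orchestration: simulate -> TSS -> nucleosomes -> phasing ->
composition -> evolution -> correlation -> group contrasts.

The driver runs either on a synthetic world (a ``SimConfig``) or on real
inputs (FASTA genomes, BED tag and read files).  One master seed feeds a
seed sequence forked per stage by fixed order, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlate, evolution, group_comparisons, io, nucleosome_map, phasing
from . import seqcomp, synthetic_data, tss_model
from .synthetic_data import TISSUES, SimConfig

STRAINS = ("focal", "sister")


@dataclass
class RealDataPaths:
    """File inputs for real-data mode (all 0-based half-open BED)."""

    focal_genome: str | None = None
    sister_genome: str | None = None
    outgroup_genome: str | None = None
    tag_beds: dict | None = None  # (strain, tissue) -> path
    read_beds: dict | None = None  # (strain, tissue) -> path

    def validate(self) -> None:
        for name in ("focal_genome", "sister_genome", "outgroup_genome"):
            if getattr(self, name) is None:
                raise ValueError(f"real-data mode requires the field {name!r}")
        for name in ("tag_beds", "read_beds"):
            mapping = getattr(self, name)
            if not mapping:
                raise ValueError(f"real-data mode requires the field {name!r}")
            for strain in STRAINS:
                for tissue in TISSUES:
                    if (strain, tissue) not in mapping:
                        raise ValueError(
                            f"{name} is missing an entry for {(strain, tissue)}"
                        )


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults."""

    sim: SimConfig | None = field(default_factory=SimConfig)
    real: RealDataPaths | None = None
    outdir: str | None = None
    seed: int = 0
    focal_tissue: str = "testes"
    target_total: float = tss_model.TARGET_TOTAL  # 300,000 tags = one cell
    min_expr: float = tss_model.MIN_EXPRESSION  # 0.1 = ~2 tags in 6M
    cluster_gap: int = tss_model.CLUSTER_GAP  # 20 bp
    rep_spacing: int = tss_model.REPRESENTATIVE_SPACING  # 500 bp
    smooth_window: int = nucleosome_map.SMOOTH_WINDOW  # 21 bp
    core_length: int = nucleosome_map.CORE_LENGTH  # 147 bp
    fragment_l_range: tuple = (137, 157)
    isolation: int = nucleosome_map.ISOLATION_BP  # 165 bp
    cross_tissue_bp: int = nucleosome_map.CROSS_TISSUE_BP  # 10 bp
    uniqueness_k: int = nucleosome_map.UNIQUENESS_K  # 25-mers
    first_dyad_window: tuple = nucleosome_map.FIRST_DYAD_WINDOW  # [+50, +150]
    lag_range: tuple = (phasing.LAG_MIN, phasing.LAG_MAX)  # 150..220
    flank: int = seqcomp.WINDOW  # 500 bp
    profile_smooth: int = seqcomp.PROFILE_SMOOTH  # 41 bp
    grouping: str = "tertile"

    def validated(self) -> "RunConfig":
        if self.sim is None:
            if self.real is None:
                raise ValueError("either a SimConfig or real-data paths are required")
            self.real.validate()
        return self


@dataclass
class World:
    """In-memory inputs the analysis consumes, however they were obtained."""

    genomes: dict  # "focal" | "sister" | "outgroup" -> sequence
    tag_libraries: dict  # (strain, tissue) -> DataFrame(pos, strand, count)
    nuc_reads: dict  # (strain, tissue) -> DataFrame(pos, strand)
    truth: synthetic_data.GroundTruth | None = None


def build_synthetic_world(config: RunConfig) -> World:
    sim = config.sim.with_seed(config.seed)
    ancestor, truth = synthetic_data.simulate_ancestor_genome(sim)
    strains, subs = synthetic_data.evolve_strains(ancestor, sim)
    truth.substitutions = subs
    seeds = np.random.SeedSequence(sim.seed).spawn(2 * len(STRAINS) * len(TISSUES))
    it = iter(seeds)
    tags = {}
    reads = {}
    for strain in STRAINS:
        lib = synthetic_data.simulate_tag_library(
            truth, sim, rng=np.random.default_rng(next(it))
        )
        for tissue in TISSUES:
            tags[(strain, tissue)] = lib[tissue]
    for strain in STRAINS:
        for tissue in TISSUES:
            reads[(strain, tissue)] = synthetic_data.simulate_nucleosome_reads(
                truth, sim, strains[strain], tissue, rng=np.random.default_rng(next(it))
            )
    return World(genomes=strains, tag_libraries=tags, nuc_reads=reads, truth=truth)


def load_real_world(paths: RealDataPaths) -> World:
    paths.validate()
    genomes = {
        "focal": next(iter(io.read_fasta(paths.focal_genome).values())),
        "sister": next(iter(io.read_fasta(paths.sister_genome).values())),
        "outgroup": next(iter(io.read_fasta(paths.outgroup_genome).values())),
    }
    tags = {key: io.read_bed_tags(p) for key, p in paths.tag_beds.items()}
    reads = {key: io.read_bed_reads(p) for key, p in paths.read_beds.items()}
    return World(genomes=genomes, tag_libraries=tags, nuc_reads=reads)


def _strain_tss(world: World, strain: str, config: RunConfig):
    """Normalize, merge, cluster and select representatives for one strain."""
    tracks = {
        t: tss_model.normalize_tags(world.tag_libraries[(strain, t)], config.target_total)
        for t in TISSUES
    }
    merged = tss_model.merge_tissue_expression(tracks)
    clusters = tss_model.call_tss_clusters(merged, config.min_expr, config.cluster_gap)
    reps = tss_model.select_representative_tss(clusters, config.rep_spacing)
    tss_model.attach_tissue_metrics(reps, tracks, config.min_expr)
    return reps, tracks


def _pair_representatives(reps_focal, reps_sister, max_dist: int):
    """Index of the nearest same-strand sister representative, else -1."""
    by_strand = {}
    for j, r in enumerate(reps_sister):
        by_strand.setdefault(r.strand, []).append((r.pos, j))
    for s in by_strand:
        by_strand[s].sort()
    pairing = []
    for r in reps_focal:
        best = (-1, None)
        arr = by_strand.get(r.strand, [])
        positions = [p for p, _ in arr]
        i = np.searchsorted(positions, r.pos)
        cand = [arr[j] for j in (i - 1, i) if 0 <= j < len(arr)]
        if cand:
            pos, j = min(cand, key=lambda t: abs(t[0] - r.pos))
            if abs(pos - r.pos) <= max_dist:
                best = (j, pos)
        pairing.append(best[0])
    return np.asarray(pairing)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    config = config.validated()
    report: dict = {"parameters": {"seed": config.seed, "focal_tissue": config.focal_tissue}}
    world = build_synthetic_world(config) if config.sim is not None else load_real_world(config.real)
    g_len = len(world.genomes["focal"])

    # --- TSS calling per strain ---------------------------------------
    reps = {}
    tracks = {}
    for strain in STRAINS:
        reps[strain], tracks[strain] = _strain_tss(world, strain, config)
    focal_reps = reps["focal"]
    report["tss"] = {s: len(reps[s]) for s in STRAINS}
    sets, venn = tss_model.active_tss_sets(focal_reps, TISSUES)
    report["tss"]["venn"] = venn

    # --- nucleosome tracks, fragment length, stable + first dyads -----
    dyad_tracks = {}
    for strain in STRAINS:
        for tissue in TISSUES:
            dyad_tracks[(strain, tissue)] = nucleosome_map.compute_dyad_scores(
                world.nuc_reads[(strain, tissue)],
                len(world.genomes[strain]),
                config.core_length,
                config.smooth_window,
            )
    frag = nucleosome_map.estimate_fragment_length(
        world.nuc_reads[("focal", config.focal_tissue)],
        world.genomes["focal"],
        *config.fragment_l_range,
    )
    report["fragment_length"] = {
        "optimal": frag.optimal_length,
        "n_skipped": frag.n_skipped,
    }
    stable = nucleosome_map.select_stable_dyads(
        {t: dyad_tracks[("focal", t)] for t in TISSUES},
        world.genomes["focal"],
        config.isolation,
        config.uniqueness_k,
        config.cross_tissue_bp,
    )
    report["stable_dyads"] = {t: int(len(stable[t].dyads)) for t in TISSUES}
    first_map, first_table = nucleosome_map.locate_first_dyads(
        focal_reps, dyad_tracks[("focal", config.focal_tissue)], config.first_dyad_window
    )

    # --- phasing and grouping ------------------------------------------
    metrics = {
        s: phasing.phasing_metrics(
            reps[s],
            {t: dyad_tracks[(s, t)] for t in TISSUES},
            config.flank,
            *config.lag_range,
        )
        for s in STRAINS
    }
    mfoc = metrics["focal"]
    focal_down = mfoc[
        (mfoc["tissue"] == config.focal_tissue) & (mfoc["side"] == "downstream")
    ].set_index("tss_id")["consistency"]
    consistency = focal_down.reindex(range(len(focal_reps))).to_numpy()
    groups = phasing.group_tss_by_consistency(consistency, method=config.grouping)
    for rep, grp in zip(focal_reps, groups):
        rep.group = int(grp) if grp > 0 else None
    report["groups"] = {int(k): int(v) for k, v in zip(*np.unique(groups, return_counts=True))}

    # --- sequence composition ------------------------------------------
    comp = [
        seqcomp.window_base_counts(world.genomes["focal"], r.pos, r.strand, config.flank)
        for r in focal_reps
    ]
    g1 = [c for c, grp in zip(comp, groups) if grp == 1 and c is not None]
    ztests = {}
    for base in "ACGT":
        n1 = sum(c.up[base] for c in g1)
        n2 = sum(c.down[base] for c in g1)
        m = config.flank * len(g1)
        for name, corrected in (("printed", False), ("corrected", True)):
            z, p = seqcomp.asymmetry_ztest(n1, m, n2, m, corrected=corrected)
            ztests[f"{base}_{name}"] = {"z": z, "p": p}
    report["asymmetry_ztests"] = ztests

    anchors_g1 = pd.DataFrame(
        [(r.pos, r.strand) for r, grp in zip(focal_reps, groups) if grp == 1],
        columns=["pos", "strand"],
    )
    tss_profile = seqcomp.incidence_profile(
        anchors_g1, world.genomes["focal"], config.flank, config.profile_smooth,
        mode="transcribed",
    )
    stable_anchors = pd.DataFrame(
        {"pos": stable[config.focal_tissue].dyads}
    )
    profiles = {"tss_group1": tss_profile}
    base_dyad_tests = {}
    if len(first_table) >= 3 and len(stable_anchors) >= 3:
        first_profile = seqcomp.incidence_profile(
            first_table, world.genomes["focal"], 200, config.profile_smooth,
            mode="transcribed", mnase_exclude=True,
        )
        genome_profile = seqcomp.incidence_profile(
            stable_anchors, world.genomes["focal"], 200, config.profile_smooth,
            mode="both", mnase_exclude=True,
        )
        profiles["first_dyads"] = first_profile
        profiles["genome_dyads"] = genome_profile
        for base in "ACGT":
            res = seqcomp.dyad_vs_linker_test(
                first_profile.raw[base], genome_profile.raw[base],
                first_profile.offsets, direction="greater",
            )
            base_dyad_tests[base] = {"p": res.p_value, "method": res.method}
    report["base_dyad_vs_linker"] = base_dyad_tests

    # --- evolution -------------------------------------------------------
    calls = evolution.infer_ancestral_calls(
        world.genomes["focal"], world.genomes["sister"], world.genomes["outgroup"]
    )
    tss_track = evolution.positional_mutation_rates(
        calls, anchors_g1, config.flank, mode="transcribed"
    )
    flux = evolution.mutational_flux_summary(tss_track)
    report["flux"] = {
        "net_change": flux.net_change.to_dict(),
        "conservation_residual": float(flux.net_change.sum().abs().max()),
    }
    tcr = evolution.ct_vs_ga_test(tss_track)
    report["ct_vs_ga"] = {"p": tcr.p_value, "method": tcr.method}
    mutation_tests = {}
    if len(first_table) >= 3 and len(stable_anchors) >= 3:
        first_mut = evolution.positional_mutation_rates(
            calls, first_table, 200, mode="transcribed"
        )
        genome_mut = evolution.positional_mutation_rates(
            calls, stable_anchors, 200, mode="both"
        )
        for cat in ("C->T", "T->C"):
            res = evolution.mutation_dyad_vs_linker_test(
                first_mut, genome_mut, cat, direction="greater"
            )
            mutation_tests[cat] = {"p": res.p_value, "method": res.method}
    report["mutation_dyad_vs_linker"] = mutation_tests

    # --- 48-parameter table and correlation -----------------------------
    pairing = _pair_representatives(focal_reps, reps["sister"], config.rep_spacing)
    table = _parameter_columns(reps, metrics, comp, pairing, config)
    try:
        complete, n_dropped = correlate.assemble_parameter_table(table)
        corr = correlate.spearman_matrix(complete)
        cell_a = f"focal_Na_{config.focal_tissue}_downstream"
        cell_b = f"focal_Exp_{config.focal_tissue}"
        report["correlation"] = {
            "n_tss": len(table),
            "n_complete": len(complete),
            "n_dropped": n_dropped,
            "bonferroni_threshold": corr.threshold,
            "n_significant_pairs": int(corr.significant.to_numpy().sum() // 2),
            "consistency_vs_expression": {
                "r": float(corr.r.loc[cell_a, cell_b]),
                "p": float(corr.p.loc[cell_a, cell_b]),
                "significant": bool(corr.significant.loc[cell_a, cell_b]),
            },
        }
    except ValueError as exc:
        complete, corr = None, None
        report["correlation"] = {"error": str(exc)}

    # --- group comparisons ----------------------------------------------
    expr = np.array([r.expression.get(config.focal_tissue, 0.0) for r in focal_reps])
    breadth = np.array([r.breadth.get(config.focal_tissue, 0) for r in focal_reps], float)
    comparisons = {}
    for name, vals, direction in (
        ("expression", correlate.log_expression(expr), "greater"),
        ("breadth", breadth, "greater"),
    ):
        res = group_comparisons.compare_groups(vals, groups, direction, parameter=name)
        comparisons[name] = {
            "p": res.p_value,
            "median_group1": res.median_group1,
            "median_rest": res.median_rest,
        }
    dists, fractions, n_excl = tss_model.compare_strain_tss_distance(
        focal_reps, reps["sister"], coordinate_map=None
    )
    report["strain_distance"] = {
        "fractions": {str(k): v for k, v in fractions.items()},
        "n_excluded": n_excl,
    }
    if len(dists) == len(focal_reps):
        res = group_comparisons.compare_groups(
            dists, groups, "less", parameter="strain_distance"
        )
        comparisons["strain_distance"] = {"p": res.p_value}
    report["group_comparisons"] = comparisons

    # --- outputs ---------------------------------------------------------
    if config.outdir is not None:
        _write_outputs(config, world, reps, metrics, stable, corr, complete, report)
    return report


def _parameter_columns(reps, metrics, comp, pairing, config) -> pd.DataFrame:
    """Assemble the 48 parameter columns for the focal-strain TSS list."""
    n = len(reps["focal"])
    cols: dict[str, np.ndarray] = {}

    def metric_lookup(strain):
        m = metrics[strain].set_index(["tss_id", "tissue", "side"])
        return m

    mf = metric_lookup("focal")
    ms = metric_lookup("sister")
    for t in TISSUES:
        focal_expr = np.array([r.expression.get(t, np.nan) for r in reps["focal"]])
        cols[f"focal_Exp_{t}"] = correlate.log_expression(focal_expr)
        cols[f"focal_Br_{t}"] = np.array(
            [float(r.breadth.get(t, np.nan)) for r in reps["focal"]]
        )
        sis_expr = np.full(n, np.nan)
        sis_br = np.full(n, np.nan)
        for i, j in enumerate(pairing):
            if j >= 0:
                sis_expr[i] = reps["sister"][j].expression.get(t, np.nan)
                sis_br[i] = float(reps["sister"][j].breadth.get(t, np.nan))
        cols[f"sister_Exp_{t}"] = correlate.log_expression(sis_expr)
        cols[f"sister_Br_{t}"] = sis_br
    for t in TISSUES:
        for side in ("upstream", "downstream"):
            for key, frame in (("focal", mf), ("sister", ms)):
                np_col = np.full(n, np.nan)
                na_col = np.full(n, np.nan)
                for i in range(n):
                    tid = i if key == "focal" else (pairing[i] if pairing[i] >= 0 else None)
                    if tid is None:
                        continue
                    try:
                        row = frame.loc[(tid, t, side)]
                    except KeyError:
                        continue
                    if not bool(row["missing"]):
                        np_col[i] = row["periodicity"]
                        na_col[i] = row["consistency"]
                cols[f"{key}_Np_{t}_{side}"] = np_col
                cols[f"{key}_Na_{t}_{side}"] = na_col
    for b in "ACGT":
        cols[f"focal_{b}_up"] = np.array(
            [c.up[b] if c else np.nan for c in comp], dtype=float
        )
        cols[f"focal_{b}_down"] = np.array(
            [c.down[b] if c else np.nan for c in comp], dtype=float
        )
        cols[f"focal_{b}_Sa"] = np.array(
            [c.asymmetry[b] if c else np.nan for c in comp], dtype=float
        )
    return pd.DataFrame(cols)


def _write_outputs(config, world, reps, metrics, stable, corr, complete, report):
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    if config.sim is not None:
        fa = out / "genomes.fa"
        io.write_fasta(fa, {k: v for k, v in world.genomes.items()})
        files.append(fa)
    for strain in STRAINS:
        path = out / f"representative_tss_{strain}.tsv"
        io.write_tsv(path, tss_model.rep_table(reps[strain], TISSUES))
        files.append(path)
        path = out / f"phasing_{strain}.tsv"
        io.write_tsv(path, metrics[strain])
        files.append(path)
    for tissue, result in stable.items():
        path = out / f"stable_dyads_{tissue}.bed"
        bed = pd.DataFrame(
            {
                "chrom": "chrSim",
                "start": result.dyads,
                "end": result.dyads + 1,
                "name": "stable_dyad",
                "score": 0,
                "strand": "+",
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)
        files.append(path)
    if corr is not None:
        path = out / "spearman_matrix.tsv"
        io.write_tsv(path, corr.r, index=True)
        files.append(path)
        path = out / "parameter_table.tsv"
        io.write_tsv(path, complete, index=True)
        files.append(path)
        correlate.save_heatmap(corr, out / "spearman_matrix.png")
        files.append(out / "spearman_matrix.png")
        with open(out / "significance_mask.json", "w") as fh:
            json.dump(
                {
                    "threshold": corr.threshold,
                    "significant_pairs": [
                        [a, b]
                        for i, a in enumerate(corr.significant.index)
                        for j, b in enumerate(corr.significant.columns)
                        if i < j and bool(corr.significant.iloc[i, j])
                    ],
                },
                fh,
                indent=2,
            )
        files.append(out / "significance_mask.json")
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    files.append(report_path)
    io.write_manifest(out / "manifest.json", report["parameters"], files)
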