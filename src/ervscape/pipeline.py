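"""End-to-end orchestration of the three analyses on one input bundle:
TE enrichment/association, differential expression/binding, and
nucleosome occupancy, plus the single-cell fraction statistics.

`run_all` consumes a `Simulation` (or the same inputs loaded from files)
and produces a report dictionary of the headline numbers together with a
manifest of every threshold used, so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import association, cell_stats, differential, nucleosome, signal_quant, te_annotation
from .synthetic_data import SimConfig, Simulation, simulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_all"]


@dataclass
class PipelineConfig:
    """Every analysis threshold, with the study's defaults."""

    seed: int = 0
    te_min_length: int = 300
    te_min_copies: int = 50
    stitch_family: str = "IAPEz-int"
    stitch_max_gap: int = 500
    full_length_family: str = "MERVL-int"
    full_length_min_bp: int = 4500
    peak_min_fe: float = 2.0
    pseudocount: float = 0.1
    gene_fc: float = 2.0
    te_fc: float = 1.5
    max_padj: float = 0.01
    diffpeak_p: float = 0.05
    diffpeak_fc: float = 1.5
    strong_2c_log2fc: float = 5.0
    span: int = 1000
    bin_size: int = 25
    central_bp: int = 200
    min_bound_copies: int = 10
    distance_threshold: int = 1000
    sim: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, inject defaults, reject unknown keys and
    non-positive thresholds.  Normalization is idempotent."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    for name in (
        "te_min_length", "te_min_copies", "stitch_max_gap", "full_length_min_bp",
        "peak_min_fe", "pseudocount", "gene_fc", "te_fc", "max_padj",
        "diffpeak_p", "diffpeak_fc", "span", "bin_size", "central_bp",
        "min_bound_copies", "distance_threshold",
    ):
        value = getattr(cfg, name)
        if value <= 0:
            raise ValueError(f"config threshold {name} must be positive, got {value}")
    return cfg


def run_all(
    config: PipelineConfig | None = None,
    sim: Simulation | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Execute simulate -> curate -> enrich -> de -> associate -> nucleosome
    -> cell_stats and return the report bundle.

    Stage failures surface as exceptions naming the stage.  With ``outdir``
    the report, manifest and main tables are written as JSON/TSV.
    """
    cfg = config or PipelineConfig()
    if sim is None:
        sim_cfg = SimConfig.from_dict({"seed": cfg.seed, **cfg.sim})
        sim = simulate(sim_cfg)
    report: dict = {}
    stage = "simulate"
    try:
        # ---- curate ------------------------------------------------------
        stage = "curate"
        curated = te_annotation.curate_te_instances(
            sim.tes, cfg.te_min_length, cfg.te_min_copies
        )
        stitched = te_annotation.stitch_fragments(
            curated, cfg.stitch_family, cfg.stitch_max_gap
        )
        curated_peaks = signal_quant.curate_peaks(sim.peaks, cfg.peak_min_fe)
        report["n_te_curated"] = len(curated)
        report["n_te_families_curated"] = len({t.family for t in curated})
        report["n_stitched_elements"] = len(stitched)
        report["n_peaks_curated"] = len(curated_peaks)

        # ---- enrich ------------------------------------------------------
        stage = "enrich"
        tracks1x = {
            name: signal_quant.normalize_1x(track) for name, track in sim.tracks.items()
        }
        full_length = te_annotation.select_full_length(
            curated, cfg.full_length_family, cfg.full_length_min_bp
        )
        fl_elements = [(t.instance_id, t.interval) for t in full_length]
        factor_fl = signal_quant.enrichment_table(
            tracks1x["factor_control"], tracks1x["input_control"], fl_elements,
            "factor", cfg.pseudocount,
        )
        me2_fl = signal_quant.enrichment_table(
            tracks1x["H3K9me2_control"], tracks1x["input_control"], fl_elements,
            "H3K9me2", cfg.pseudocount,
        )
        corr_ervl = signal_quant.per_element_correlation(factor_fl, me2_fl)
        st_elements = [(f"stitched{i}", e.interval) for i, e in enumerate(stitched)]
        factor_st = signal_quant.enrichment_table(
            tracks1x["factor_control"], tracks1x["input_control"], st_elements,
            "factor", cfg.pseudocount,
        )
        me3_st = signal_quant.enrichment_table(
            tracks1x["H3K9me3_control"], tracks1x["input_control"], st_elements,
            "H3K9me3", cfg.pseudocount,
        )
        corr_ervk = signal_quant.per_element_correlation(factor_st, me3_st)
        report["correlation_ervl_factor_me2"] = {
            "r": corr_ervl.r, "p": corr_ervl.p_two_sided, "n": corr_ervl.n,
        }
        report["correlation_stitched_factor_me3"] = {
            "r": corr_ervk.r, "p": corr_ervk.p_two_sided, "n": corr_ervk.n,
        }

        # depletion effect on marks at bound vs background elements
        bound_flags = association.bound_elements(curated_peaks, curated)
        deltas_bound, deltas_bg = [], []
        for t in curated:
            if t.te_class not in ("ERVL", "ERVK", "ERV1"):
                continue
            mark = "H3K9me2" if t.te_class == "ERVL" else "H3K9me3"
            el = [(t.instance_id, t.interval)]
            ctrl = signal_quant.enrichment_table(
                tracks1x[f"{mark}_control"], tracks1x["input_control"], el, mark,
                cfg.pseudocount,
            )["log2_fe"].iloc[0]
            dep = signal_quant.enrichment_table(
                tracks1x[f"{mark}_depleted"], tracks1x["input_depleted"], el, mark,
                cfg.pseudocount,
            )["log2_fe"].iloc[0]
            (deltas_bound if bound_flags[t.instance_id] else deltas_bg).append(dep - ctrl)
        report["mark_delta_bound_mean"] = float(np.mean(deltas_bound))
        report["mark_delta_background_mean"] = float(np.mean(deltas_bg))

        # ---- differential ------------------------------------------------
        stage = "differential"
        # genes and TE families are quantified and tested jointly, so size
        # factors and the FDR come from one run (TE-aware counting style)
        de_all = differential.joint_de_test(
            sim.counts_genes, sim.counts_te, sim.conditions, max_padj=cfg.max_padj
        )
        de_genes = de_all[de_all["feature_type"] == "gene"].reset_index(drop=True)
        de_te = de_all[de_all["feature_type"] == "te_family"].reset_index(drop=True)
        strong_2c = differential.select_strong_early2c(
            de_genes, cfg.strong_2c_log2fc, cfg.max_padj
        )
        up_genes = set(
            de_genes.loc[de_genes["significant"] & (de_genes["log2fc"] > 0), "feature_id"]
        )
        up_te = set(de_te.loc[de_te["significant"] & (de_te["log2fc"] > 0), "feature_id"])
        report["n_up_genes"] = len(up_genes)
        report["n_up_te_families"] = sorted(up_te)
        report["n_strong_early2c"] = len(strong_2c)

        # ---- associate ---------------------------------------------------
        stage = "associate"
        fam_bound = association.bound_families(
            bound_flags, curated, min_bound_copies=cfg.min_bound_copies
        )
        report["bound_families"] = sorted(fam_bound)
        if up_te:
            inter, n_de, pct = association.overlap_fraction(fam_bound, up_te)
            report["bound_de_te_overlap"] = {"n_bound_and_de": inter, "n_de": n_de, "pct": pct}
        bound_tes = [t for t in curated if bound_flags[t.instance_id]]
        other_tes = [t for t in curated if not bound_flags[t.instance_id]]
        up_gene_models = [g for g in sim.genes if g.gene_id in up_genes]
        if up_gene_models and bound_tes and other_tes:
            fg = association.nearest_element_distance(
                up_gene_models, bound_tes, (cfg.distance_threshold,)
            )
            bg = association.nearest_element_distance(
                up_gene_models, other_tes, (cfg.distance_threshold,)
            )
            p, med_fg, med_bg = association.compare_distance_distributions(
                fg.distances, bg.distances
            )
            report["tss_distance"] = {
                "p_fg_closer": p,
                "median_fg": med_fg,
                "median_bg": med_bg,
                "fraction_within_1kb_fg": fg.fraction_within[cfg.distance_threshold],
                "fraction_within_1kb_bg": bg.fraction_within[cfg.distance_threshold],
            }
        _, breakdown = association.annotate_peaks(curated_peaks, sim.genes, curated)
        report["peak_annotation_pct"] = dict(
            zip(breakdown["category"], breakdown["percentage"])
        )

        # ---- nucleosome --------------------------------------------------
        stage = "nucleosome"
        frag_ctrl = nucleosome.FragmentSet(sim.mnase["control"], "control")
        frag_dep = nucleosome.FragmentSet(sim.mnase["depleted"], "depleted")
        hist, mode = nucleosome.fragment_length_distribution(frag_ctrl)
        report["fragment_length_mode"] = mode
        prof_ctrl = nucleosome.occupancy_profiles(
            frag_ctrl, sim.anchors, sim.genome, cfg.span, cfg.bin_size
        )
        prof_dep = nucleosome.occupancy_profiles(
            frag_dep, sim.anchors, sim.genome, cfg.span, cfg.bin_size
        )
        nfr = nucleosome.classify_nfr(prof_ctrl, cfg.central_bp)
        report["n_nfr_depleted_sites"] = sum(c.depleted for c in nfr)
        classes = nucleosome.split_peak_classes(curated_peaks, k=3)
        comparison = nucleosome.compare_occupancy(prof_ctrl, prof_dep, central_bp=cfg.central_bp)
        reduced_tab = nucleosome.annotate_reduced_regions(
            comparison, sim.anchors, curated, classes
        )
        report["n_reduced_regions"] = int(comparison["reduced"].sum())
        report["reduced_in_te"] = {
            row["class"]: row["fraction_in_te"] for _, row in reduced_tab.iterrows()
        }

        # ---- cells -------------------------------------------------------
        stage = "cells"
        cells = sim.cells.copy()
        labels = cell_stats.marker_score_classify(
            sim.marker_expression,
            list(sim.config.markers_2c),
            list(sim.config.markers_pluri),
        )
        cells["cluster_label"] = labels.loc[cells["cell_id"]].to_numpy()
        f_dep = cell_stats.cluster_fraction(cells, "totipotent-like", "depleted")
        f_ctrl = cell_stats.cluster_fraction(cells, "totipotent-like", "control")
        fold, fold_round = cell_stats.fraction_fold_change(f_dep, f_ctrl)
        report["totipotent_fraction"] = {
            "depleted": {"n": f_dep.numerator, "of": f_dep.denominator,
                         "pct": f_dep.percentage_rounded},
            "control": {"n": f_ctrl.numerator, "of": f_ctrl.denominator,
                        "pct": f_ctrl.percentage_rounded},
            "fold_change": fold,
            "fold_change_rounded": fold_round,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {"seed": cfg.seed, "thresholds": cfg.as_dict()}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        de_genes.to_csv(outdir / "de_genes.tsv", sep="\t", index=False)
        de_te.to_csv(outdir / "de_te.tsv", sep="\t", index=False)
    report["manifest"] = manifest
    return report
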