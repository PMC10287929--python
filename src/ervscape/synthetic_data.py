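"""Seedable generator of a toy genome and every pipeline input.

The generator emulates the data structure of a degron-depletion chromatin
study in mouse embryonic stem cells at desk scale: a multi-chromosome toy
genome annotated with ERV1/ERVK/ERVL/LINE/SINE instances (including
fragmented copies of one ERVK family to exercise stitching), planted
factor binding with fold-enrichment-scored peaks, class-specific
heterochromatin marks (H3K9me2 co-planted on bound ERVL copies in
proportion to the factor signal, H3K9me3 on bound ERVK/ERV1 copies), a
depletion condition eroding marks and nucleosome occupancy at bound
elements, negative-binomial gene/TE-family counts with planted
up-regulation of 2C-like features, and per-cell QC tables with a planted
totipotent-like subpopulation.

Every stream of randomness derives from one seed fanned out to named
substreams, so the same seed reproduces every output byte-for-byte and
individual data types can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import GenomeSpec, Interval, SignalTrack, write_bed, write_bedgraph
from .signal_quant import Peak
from .te_annotation import TEInstance

__all__ = ["SimConfig", "GroundTruth", "Simulation", "simulate"]

_STREAMS = ("genome", "tes", "genes", "binding", "tracks", "mnase", "counts", "cells")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS.index(stream)])


@dataclass
class TEFamilyConfig:
    te_class: str
    copies: int
    mean_length: int
    sd_length: int
    min_length: int = 100
    fragmented_fraction: float = 0.0  # copies emitted as 2-3 adjacent fragments


@dataclass
class SimConfig:
    """All knobs of the simulation, with defaults defining the toy study."""

    seed: int = 0
    # genome
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    # TE families; classes span the analysis vocabulary, one family is
    # deliberately short (<300 bp) and one low-copy (<50) so curation bites
    te_families: dict[str, TEFamilyConfig] = field(
        default_factory=lambda: {
            "MERVL-int": TEFamilyConfig("ERVL", 100, 4800, 900, 400),
            "MT2_Mm": TEFamilyConfig("ERVL", 80, 480, 60, 320),
            "IAPEz-int": TEFamilyConfig("ERVK", 70, 4500, 400, 400, fragmented_fraction=0.4),
            "RLTR10-int": TEFamilyConfig("ERVK", 60, 3500, 300, 400),
            "RLTR6B_Mm": TEFamilyConfig("ERV1", 55, 600, 80, 320),
            "L1Md_T": TEFamilyConfig("LINE", 60, 3000, 700, 400),
            "B1_Mm": TEFamilyConfig("SINE", 60, 150, 20, 100),
            "MERVL_rare": TEFamilyConfig("ERVL", 20, 800, 100, 320),
        }
    )
    # binding: fraction of each family's copies carrying a factor peak
    bound_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "MERVL-int": 0.8,
            "MT2_Mm": 0.6,
            "IAPEz-int": 0.7,
            "RLTR10-int": 0.7,
            "RLTR6B_Mm": 0.6,
            "L1Md_T": 0.05,
        }
    )
    peak_width_mean: int = 400
    peak_width_sd: int = 50
    n_decoy_peaks: int = 30  # TE-free peaks, FE ~ U(0.5, 4): some fail FE>2 curation
    # tracks (per-25bp-bin Poisson rates)
    track_bin: int = 25
    background_rate: float = 20.0
    log2_amplitude_mean: float = 2.0  # planted factor enrichment, log2 over background
    log2_amplitude_sd: float = 0.8
    # log2 noise of the mark amplitude around the factor amplitude, sized so
    # the realized per-element factor-mark correlation is ~0.7 (the planted
    # target) after the log2-FE transform and the unbound background cluster
    mark_noise_sd: float = 1.5
    # depletion condition
    factor_erosion: float = 0.9
    mark_erosion: float = 0.5
    occupancy_erosion: float = 0.5
    # genes & counts
    n_genes: int = 300
    n_2c_genes: int = 40
    n_down_genes: int = 20
    proximity_fraction: float = 0.8  # 2C genes planted with TSS < 1 kb from a bound TE
    proximity_max_bp: int = 900
    gene_length_mean: int = 2000
    gene_length_sd: int = 400
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    up_te_families: tuple[str, ...] = ("MERVL-int", "MT2_Mm")
    te_family_log2fc: float = 2.0
    # MNase
    mnase_background_per_bp: float = 0.01
    mnase_anchor_depth: float = 60.0
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 10.0
    # cells
    n_cells_control: int = 9122
    n_cells_depleted: int = 8432
    frac_2c_control: float = 0.0106
    frac_2c_depleted: float = 0.0738
    qc_fail_fraction: float = 0.05
    markers_2c: tuple[str, ...] = ("Zscan4c", "Usp17la", "Gm13119", "Gm4027")
    markers_pluri: tuple[str, ...] = ("Pou5f1", "Nanog")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        cfg = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in known:
                raise ValueError(f"unknown simulation config key: {key!r}")
            if key == "te_families":
                value = {k: TEFamilyConfig(**v) for k, v in value.items()}
            setattr(cfg, key, value)
        return cfg


@dataclass
class GroundTruth:
    """Planted structure, for recovery tests."""

    bound_instance_ids: set[str]
    bound_families: set[str]
    marked_instance_ids: dict[str, set[str]]  # mark -> instance ids
    true_up_features: set[str]
    true_down_features: set[str]
    eroded_anchor_ids: set[str]
    true_cell_labels: dict[str, str]  # cell_id -> planted label

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bound_instance_ids": sorted(self.bound_instance_ids),
            "bound_families": sorted(self.bound_families),
            "marked_instance_ids": {m: sorted(v) for m, v in self.marked_instance_ids.items()},
            "true_up_features": sorted(self.true_up_features),
            "true_down_features": sorted(self.true_down_features),
            "eroded_anchor_ids": sorted(self.eroded_anchor_ids),
            "true_cell_labels": self.true_cell_labels,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class _TECopy:
    """A placed repeat copy; fragments > 1 means an interrupted element."""

    copy_id: str
    family: str
    te_class: str
    chrom: str
    strand: str
    fragments: list[tuple[int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return self.fragments[0][0], self.fragments[-1][1]

    @property
    def center(self) -> int:
        s, e = self.span
        return (s + e) // 2


@dataclass
class Simulation:
    """All generated inputs plus ground truth."""

    config: SimConfig
    genome: GenomeSpec
    tes: list[TEInstance]
    genes: list  # GeneModel
    peaks: list[Peak]
    tracks: dict[str, SignalTrack]  # "<mark>_<condition>"
    mnase: dict[str, list[Interval]]  # condition -> fragments
    anchors: list[tuple[str, str, int]]  # (anchor_id, chrom, center) = curated peak centers
    counts_genes: pd.DataFrame
    counts_te: pd.DataFrame
    conditions: dict[str, str]
    cells: pd.DataFrame
    marker_expression: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# placement helpers


def _place_nonoverlapping(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom_names: list[str],
    chrom_length: int,
    length: int,
    max_tries: int = 200,
) -> tuple[str, int] | None:
    for _ in range(max_tries):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        start = int(rng.integers(0, chrom_length - length))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied[chrom]):
            occupied[chrom].append((start, end))
            return chrom, start
    return None


# ---------------------------------------------------------------------------
# stages


def _generate_genome(cfg: SimConfig) -> GenomeSpec:
    names = tuple(f"chr{i + 1}" for i in range(cfg.n_chroms))
    return GenomeSpec(names, tuple([cfg.chrom_length] * cfg.n_chroms))


def _generate_tes(cfg: SimConfig, genome: GenomeSpec) -> list[_TECopy]:
    rng = _rng(cfg.seed, "tes")
    occupied = {c: [] for c in genome.chrom_names}
    copies: list[_TECopy] = []
    for family in sorted(cfg.te_families):
        fam = cfg.te_families[family]
        for i in range(fam.copies):
            length = max(
                fam.min_length, int(rng.normal(fam.mean_length, fam.sd_length))
            )
            fragmented = rng.random() < fam.fragmented_fraction and length >= 3 * fam.min_length
            strand = "+" if rng.random() < 0.5 else "-"
            if fragmented:
                n_frag = int(rng.integers(2, 4))
                gaps = rng.integers(50, 301, size=n_frag - 1)
                total = length + int(gaps.sum())
                placed = _place_nonoverlapping(
                    rng, occupied, list(genome.chrom_names), cfg.chrom_length, total
                )
                if placed is None:
                    continue
                chrom, start = placed
                cuts = np.sort(rng.choice(np.arange(1, length), n_frag - 1, replace=False))
                sizes = np.diff(np.concatenate(([0], cuts, [length])))
                frags = []
                pos = start
                for j, size in enumerate(sizes):
                    frags.append((pos, pos + int(size)))
                    if j < len(gaps):
                        pos += int(size) + int(gaps[j])
            else:
                placed = _place_nonoverlapping(
                    rng, occupied, list(genome.chrom_names), cfg.chrom_length, length
                )
                if placed is None:
                    continue
                chrom, start = placed
                frags = [(start, start + length)]
            copies.append(
                _TECopy(
                    copy_id=f"{family}.{i}",
                    family=family,
                    te_class=fam.te_class,
                    chrom=chrom,
                    strand=strand,
                    fragments=frags,
                )
            )
    return copies


def _copies_to_instances(copies: list[_TECopy]) -> list[TEInstance]:
    out = []
    for c in copies:
        for j, (s, e) in enumerate(c.fragments):
            suffix = f".f{j}" if len(c.fragments) > 1 else ""
            out.append(
                TEInstance(
                    interval=Interval(c.chrom, s, e, c.strand),
                    family=c.family,
                    te_class=c.te_class,
                    instance_id=f"{c.copy_id}{suffix}",
                )
            )
    out.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return out


def _generate_binding(
    cfg: SimConfig, genome: GenomeSpec, copies: list[_TECopy]
) -> tuple[list[Peak], dict[str, float], set[str]]:
    """Plant one factor peak on a fraction of each family's copies.

    Returns (all peaks incl. decoys, copy_id -> log2 amplitude, bound copy ids).
    Decoy peaks are placed in repeat-free positions so chance TE overlap
    cannot blur the planted bound set.
    """
    rng = _rng(cfg.seed, "binding")
    peaks: list[Peak] = []
    amplitudes: dict[str, float] = {}
    bound_copies: set[str] = set()
    k = 0
    for c in copies:
        frac = cfg.bound_fraction.get(c.family, 0.0)
        if rng.random() >= frac:
            continue
        bound_copies.add(c.copy_id)
        amp = float(rng.normal(cfg.log2_amplitude_mean, cfg.log2_amplitude_sd))
        amplitudes[c.copy_id] = amp
        width = max(100, int(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd)))
        # anchor on the longest fragment so the peak always overlaps the copy
        fs, fe = max(c.fragments, key=lambda f: f[1] - f[0])
        center = (fs + fe) // 2
        start = max(0, center - width // 2)
        end = min(genome.lengths[c.chrom], center + width // 2)
        # strong classes (ERVK/ERVL) get higher FE: these are the eroded,
        # TE-resident sites expected to dominate the top strength class
        fe_scale = 3.0 if c.te_class in ("ERVK", "ERVL") else 1.0
        fe_val = 2.0 + float(rng.exponential(fe_scale))
        peaks.append(Peak(Interval(c.chrom, start, end), fe_val, f"peak{k:04d}"))
        k += 1
    te_spans = {chrom: [] for chrom in genome.chrom_names}
    for c in copies:
        te_spans[c.chrom].append(c.span)
    for _ in range(cfg.n_decoy_peaks):
        width = max(100, int(rng.normal(cfg.peak_width_mean, cfg.peak_width_sd)))
        for _try in range(200):
            chrom = genome.chrom_names[rng.integers(len(genome.chrom_names))]
            start = int(rng.integers(0, cfg.chrom_length - width))
            end = start + width
            if all(end <= s or start >= e for s, e in te_spans[chrom]):
                peaks.append(
                    Peak(Interval(chrom, start, end), float(rng.uniform(0.5, 4.0)), f"peak{k:04d}")
                )
                k += 1
                break
    return peaks, amplitudes, bound_copies


def _generate_genes(cfg: SimConfig, genome: GenomeSpec, copies, bound_copies):
    from .association import GeneModel

    rng = _rng(cfg.seed, "genes")
    bound = [c for c in copies if c.copy_id in bound_copies]
    genes = []
    occupied = {c: [] for c in genome.chrom_names}
    is_2c = np.zeros(cfg.n_genes, dtype=bool)
    is_2c[: cfg.n_2c_genes] = True
    for i in range(cfg.n_genes):
        length = max(500, int(rng.normal(cfg.gene_length_mean, cfg.gene_length_sd)))
        if is_2c[i] and bound and rng.random() < cfg.proximity_fraction:
            anchor = bound[rng.integers(len(bound))]
            offset = int(rng.integers(50, cfg.proximity_max_bp))
            start = anchor.span[1] + offset
            chrom = anchor.chrom
            if start + length > genome.lengths[chrom]:
                start = max(0, anchor.span[0] - offset - length)
            genes.append(
                GeneModel(f"gene{i:04d}", Interval(chrom, start, start + length, "+"))
            )
            continue
        placed = _place_nonoverlapping(
            rng, occupied, list(genome.chrom_names), cfg.chrom_length, length
        )
        if placed is None:
            continue
        chrom, start = placed
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{i:04d}", Interval(chrom, start, start + length, strand)))
    flags = {g.gene_id: bool(is_2c[int(g.gene_id[4:])]) for g in genes}
    return genes, flags


def _bin_rates_to_track(
    genome: GenomeSpec, rng: np.random.Generator, rates: dict[str, np.ndarray], bin_size: int
) -> SignalTrack:
    runs = {}
    for chrom, lam in rates.items():
        counts = rng.poisson(lam).astype(np.float64)
        n = counts.size
        starts = np.arange(n, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, genome.lengths[chrom])
        runs[chrom] = (starts, ends, counts)
    return SignalTrack.from_runs(genome, runs)


def _generate_tracks(cfg: SimConfig, genome: GenomeSpec, copies, amplitudes):
    """Factor/input/H3K9me2/H3K9me3/remodeler tracks for both conditions.

    Marks ride on the factor amplitude: H3K9me2 on bound ERVL copies with
    log2 noise (driving a planted positive per-element correlation),
    H3K9me3 on bound ERVK/ERV1 copies.  The depletion condition multiplies
    the planted means at bound elements by (1 - erosion).
    """
    rng = _rng(cfg.seed, "tracks")
    bin_size = cfg.track_bin
    n_bins = {c: -(-genome.lengths[c] // bin_size) for c in genome.chrom_names}

    def flat():
        return {c: np.full(n_bins[c], cfg.background_rate) for c in genome.chrom_names}

    rates = {
        f"{mark}_{cond}": flat()
        for mark in ("factor", "input", "H3K9me2", "H3K9me3", "remodeler")
        for cond in ("control", "depleted")
    }
    marked: dict[str, set[str]] = {"H3K9me2": set(), "H3K9me3": set()}
    for c in copies:
        amp = amplitudes.get(c.copy_id)
        if amp is None:
            continue
        factor_lam = cfg.background_rate * (2.0**amp)
        me2_lam = me3_lam = 0.0
        if c.te_class == "ERVL":
            me2_lam = cfg.background_rate * 2.0 ** (amp + rng.normal(0, cfg.mark_noise_sd))
            marked["H3K9me2"].update(
                f"{c.copy_id}.f{j}" if len(c.fragments) > 1 else c.copy_id
                for j in range(len(c.fragments))
            )
        elif c.te_class in ("ERVK", "ERV1"):
            me3_lam = cfg.background_rate * 2.0 ** (amp + rng.normal(0, cfg.mark_noise_sd))
            marked["H3K9me3"].update(
                f"{c.copy_id}.f{j}" if len(c.fragments) > 1 else c.copy_id
                for j in range(len(c.fragments))
            )
        remod_lam = cfg.background_rate * 2.0 ** (amp * 0.8)
        s, e = c.span
        lo, hi = s // bin_size, -(-e // bin_size)
        sl = slice(lo, hi)
        adds = {
            "factor": factor_lam,
            "H3K9me2": me2_lam,
            "H3K9me3": me3_lam,
            "remodeler": remod_lam,
        }
        for mark, lam in adds.items():
            if lam <= 0:
                continue
            rates[f"{mark}_control"][c.chrom][sl] += lam
            erosion = cfg.factor_erosion if mark in ("factor", "remodeler") else cfg.mark_erosion
            rates[f"{mark}_depleted"][c.chrom][sl] += lam * (1.0 - erosion)
    tracks = {
        name: _bin_rates_to_track(genome, rng, r, bin_size) for name, r in rates.items()
    }
    return tracks, marked


def _truncnorm_lengths(rng, n, mean, sd, lo=100, hi=200):
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out.astype(np.int64)


def _generate_mnase(cfg: SimConfig, genome: GenomeSpec, anchors, eroded_ids):
    """Fragments per condition: uniform background plus anchor-centered
    occupancy, eroded at the flagged anchors in the depletion condition."""
    rng = _rng(cfg.seed, "mnase")
    out: dict[str, list[Interval]] = {}
    for cond in ("control", "depleted"):
        frags: list[Interval] = []
        for chrom in genome.chrom_names:
            n_bg = rng.poisson(genome.lengths[chrom] * cfg.mnase_background_per_bp)
            centers = rng.integers(0, genome.lengths[chrom], size=n_bg)
            lengths = _truncnorm_lengths(rng, n_bg, cfg.fragment_length_mean, cfg.fragment_length_sd)
            for ctr, ln in zip(centers, lengths):
                s = max(0, int(ctr) - int(ln) // 2)
                e = min(genome.lengths[chrom], s + int(ln))
                if e > s:
                    frags.append(Interval(chrom, s, e))
        for aid, chrom, center in anchors:
            depth = cfg.mnase_anchor_depth
            if cond == "depleted" and aid in eroded_ids:
                depth *= 1.0 - cfg.occupancy_erosion
            n = rng.poisson(depth)
            offs = rng.integers(-300, 301, size=n)
            lengths = _truncnorm_lengths(rng, n, cfg.fragment_length_mean, cfg.fragment_length_sd)
            for off, ln in zip(offs, lengths):
                s = max(0, center + int(off) - int(ln) // 2)
                e = min(genome.lengths[chrom], s + int(ln))
                if e > s:
                    frags.append(Interval(chrom, s, e))
        frags.sort(key=lambda f: (f.chrom, f.start, f.end))
        out[cond] = frags
    return out


def _nb_draw(rng, mean, dispersion, size):
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _generate_counts(cfg: SimConfig, gene_flags: dict[str, bool]):
    """Gene and TE-family count matrices, 2 conditions x n replicates.

    2C genes get planted up-regulation (log2FC uniform in [1.5, 7], so some
    clear the strong-early-2C bar of log2FC > 5); a batch of non-2C genes is
    planted down; the configured ERVL families are planted up 4-fold.
    """
    rng = _rng(cfg.seed, "counts")
    gene_ids = sorted(gene_flags)
    up = [g for g in gene_ids if gene_flags[g]]
    non2c = [g for g in gene_ids if not gene_flags[g]]
    down = list(rng.choice(non2c, size=min(cfg.n_down_genes, len(non2c)), replace=False))
    lfc = {g: 0.0 for g in gene_ids}
    for g in up:
        lfc[g] = float(rng.uniform(1.5, 7.0))
    for g in down:
        lfc[g] = -2.0
    base = rng.lognormal(np.log(100), 1.0, size=len(gene_ids))
    n_rep = cfg.n_replicates
    cols, conditions = [], {}
    for cond in ("control", "depleted"):
        for r in range(n_rep):
            s = f"{cond[:4]}{r + 1}"
            cols.append((s, cond))
            conditions[s] = cond
    data = {}
    for (s, cond) in cols:
        mult = np.array([2.0 ** lfc[g] if cond == "depleted" else 1.0 for g in gene_ids])
        data[s] = _nb_draw(rng, base * mult, cfg.nb_dispersion, len(gene_ids))
    counts_genes = pd.DataFrame(data, index=pd.Index(gene_ids, name="feature_id"))

    fams = sorted(cfg.te_families)
    fam_base = rng.lognormal(np.log(500), 0.7, size=len(fams))
    fam_lfc = {f: (cfg.te_family_log2fc if f in cfg.up_te_families else 0.0) for f in fams}
    data_te = {}
    for (s, cond) in cols:
        mult = np.array([2.0 ** fam_lfc[f] if cond == "depleted" else 1.0 for f in fams])
        data_te[s] = _nb_draw(rng, fam_base * mult, cfg.nb_dispersion, len(fams))
    counts_te = pd.DataFrame(data_te, index=pd.Index(fams, name="feature_id"))
    truth_up = set(up) | set(cfg.up_te_families)
    truth_down = set(down)
    return counts_genes, counts_te, conditions, truth_up, truth_down


def _generate_cells(cfg: SimConfig):
    """Cell QC table and marker expression with a planted 2C-like fraction.

    The planted count is the rounded fraction of each condition's cells;
    QC covariates are drawn so that roughly ``qc_fail_fraction`` of cells
    fail each filter, independently of the planted label.
    """
    rng = _rng(cfg.seed, "cells")
    rows = []
    expr_rows = []
    labels: dict[str, str] = {}
    genes = list(cfg.markers_2c) + list(cfg.markers_pluri)
    for cond, n, frac in (
        ("control", cfg.n_cells_control, cfg.frac_2c_control),
        ("depleted", cfg.n_cells_depleted, cfg.frac_2c_depleted),
    ):
        n_2c = round(frac * n)
        is_2c = np.zeros(n, dtype=bool)
        is_2c[rng.choice(n, size=n_2c, replace=False)] = True
        n_genes = rng.normal(3000, 600, size=n).astype(int)
        fail = rng.random(n) < cfg.qc_fail_fraction
        n_genes[fail] = rng.integers(50, 200, size=int(fail.sum()))
        pct_mito = rng.beta(2, 40, size=n)
        corr = rng.uniform(0.65, 0.95, size=n)
        for i in range(n):
            cid = f"{cond[:4]}_c{i:05d}"
            labels[cid] = "totipotent-like" if is_2c[i] else "pluripotent-like"
            rows.append(
                {
                    "cell_id": cid,
                    "n_genes_detected": int(n_genes[i]),
                    "pct_mito": float(pct_mito[i]),
                    "pairwise_corr": float(corr[i]),
                    "condition": cond,
                }
            )
        hi_2c = _nb_draw(rng, np.full((n, len(cfg.markers_2c)), 30.0), 0.3, (n, len(cfg.markers_2c)))
        lo_2c = _nb_draw(rng, np.full((n, len(cfg.markers_2c)), 0.2), 0.3, (n, len(cfg.markers_2c)))
        hi_pl = _nb_draw(rng, np.full((n, len(cfg.markers_pluri)), 20.0), 0.3, (n, len(cfg.markers_pluri)))
        lo_pl = _nb_draw(rng, np.full((n, len(cfg.markers_pluri)), 0.3), 0.3, (n, len(cfg.markers_pluri)))
        m2c = np.where(is_2c[:, None], hi_2c, lo_2c)
        mpl = np.where(is_2c[:, None], lo_pl, hi_pl)
        expr_rows.append(np.hstack([m2c, mpl]))
    cells = pd.DataFrame(rows)
    expr = pd.DataFrame(
        np.vstack(expr_rows), index=cells["cell_id"].to_numpy(), columns=genes
    )
    return cells, expr, labels


# ---------------------------------------------------------------------------
# driver


def simulate(config: SimConfig | None = None) -> Simulation:
    """Run every generator stage and assemble inputs plus ground truth."""
    cfg = config or SimConfig()
    genome = _generate_genome(cfg)
    copies = _generate_tes(cfg, genome)
    tes = _copies_to_instances(copies)
    peaks, amplitudes, bound_copies = _generate_binding(cfg, genome, copies)
    genes, gene_flags = _generate_genes(cfg, genome, copies, bound_copies)
    tracks, marked = _generate_tracks(cfg, genome, copies, amplitudes)

    bound_instance_ids = {
        t.instance_id
        for t in tes
        if any(t.interval.overlap_bp(p.interval) >= 1 for p in peaks if p.fold_enrichment > 2)
    }
    # family truth counted on curated-scale instances (>=300 bp)
    fam_bound: dict[str, int] = {}
    for t in tes:
        if t.instance_id in bound_instance_ids and t.length >= 300:
            fam_bound[t.family] = fam_bound.get(t.family, 0) + 1
    bound_families = {f for f, n in fam_bound.items() if n >= 10}

    # anchors: centers of curated (FE > 2) peaks; eroded = peaks on ERVK/ERVL copies
    anchors = []
    eroded: set[str] = set()
    curated = [p for p in peaks if p.fold_enrichment > 2]
    # planted peaks were emitted first, in copy order, before the decoys
    planted_class = {}
    k = 0
    for c in copies:
        if c.copy_id in amplitudes:
            planted_class[f"peak{k:04d}"] = c.te_class
            k += 1
    for p in curated:
        anchors.append((p.peak_id, p.interval.chrom, p.center))
        if planted_class.get(p.peak_id) in ("ERVK", "ERVL"):
            eroded.add(p.peak_id)
    mnase = _generate_mnase(cfg, genome, anchors, eroded)
    counts_genes, counts_te, conditions, true_up, true_down = _generate_counts(cfg, gene_flags)
    cells, expr, labels = _generate_cells(cfg)

    truth = GroundTruth(
        bound_instance_ids=bound_instance_ids,
        bound_families=bound_families,
        marked_instance_ids=marked,
        true_up_features=true_up,
        true_down_features=true_down,
        eroded_anchor_ids=eroded,
        true_cell_labels=labels,
    )
    return Simulation(
        config=cfg,
        genome=genome,
        tes=tes,
        genes=genes,
        peaks=peaks,
        tracks=tracks,
        mnase=mnase,
        anchors=anchors,
        counts_genes=counts_genes,
        counts_te=counts_te,
        conditions=conditions,
        cells=cells,
        marker_expression=expr,
        truth=truth,
    )


def write_outputs(sim: Simulation, outdir: str | Path) -> None:
    """Emit every input as files (genome TSV, BEDs, bedGraphs, TSVs, truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.genome.to_tsv(outdir / "genome.tsv")
    write_bed(
        [(t.interval, f"{t.instance_id};{t.family};{t.te_class}", None) for t in sim.tes],
        outdir / "tes.bed",
    )
    write_bed([(g.interval, g.gene_id, None) for g in sim.genes], outdir / "genes.bed")
    write_bed(
        [(p.interval, p.peak_id, p.fold_enrichment) for p in sim.peaks],
        outdir / "peaks.bed",
    )
    for name, track in sim.tracks.items():
        write_bedgraph(track, outdir / f"{name}.bedgraph")
    for cond, frags in sim.mnase.items():
        write_bed([(f, None, None) for f in frags], outdir / f"mnase_{cond}.bed")
    from .differential import CountMatrix

    CountMatrix(sim.counts_genes, sim.conditions).to_tsv(outdir / "counts_genes.tsv")
    CountMatrix(sim.counts_te, sim.conditions).to_tsv(outdir / "counts_te.tsv")
    sim.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    sim.marker_expression.rename_axis("cell_id").to_csv(outdir / "markers.tsv", sep="\t")
    sim.truth.to_json(outdir / "truth.json")
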