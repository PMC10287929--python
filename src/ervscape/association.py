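"""Relating factor binding to TEs and genes.

Interval Jaccard, bound-element/bound-family calls, overlap of bound and
differentially expressed feature sets, TSS-to-nearest-element distances
with a foreground/background rank test, and a priority-based peak
annotator standing in for Homer-style genomic annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Interval
from .te_annotation import TEInstance

__all__ = [
    "GeneModel",
    "DistanceSummary",
    "merge_intervals",
    "jaccard",
    "bound_elements",
    "bound_families",
    "overlap_fraction",
    "nearest_element_distance",
    "compare_distance_distributions",
    "annotate_peaks",
]

DEFAULT_PROMOTER_HALF_WIDTH = 2000
DEFAULT_PRIORITY = ("promoter", "te", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """Gene span with a strand-aware TSS (start if +, end-1 if -)."""

    gene_id: str
    interval: Interval

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand != "-" else self.interval.end - 1


@dataclass(frozen=True)
class DistanceSummary:
    """Per-gene distance to the nearest element plus threshold fractions."""

    gene_ids: tuple[str, ...]
    distances: tuple[int, ...]
    fraction_within: dict[int, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "distance": self.distances})


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Collapse overlapping/adjacent intervals within a set (strand ignored)."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return out


def _total_bp(intervals: list[Interval]) -> int:
    return sum(iv.length for iv in intervals)


def _intersect_bp(a: list[Interval], b: list[Interval]) -> int:
    by_chrom_b: dict[str, list[Interval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    total = 0
    for iv in a:
        for other in by_chrom_b.get(iv.chrom, ()):
            total += iv.overlap_bp(other)
    return total


def jaccard(set_a: list[Interval], set_b: list[Interval]) -> float:
    """Intersection-bp over union-bp of two interval sets (0 if both empty).

    Each set is merged internally first, so overlaps within a set never
    inflate the statistic.
    """
    a = merge_intervals(set_a) if set_a else []
    b = merge_intervals(set_b) if set_b else []
    inter = _intersect_bp(a, b)
    union = _total_bp(a) + _total_bp(b) - inter
    return inter / union if union > 0 else 0.0


def bound_elements(
    peaks: list,
    elements: list[TEInstance],
    min_overlap_bp: int = 1,
) -> dict[str, bool]:
    """Flag each element bound iff it overlaps any curated peak by at least
    ``min_overlap_bp`` base pairs (half-open: abutting intervals share 0 bp)."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    peak_ivs: dict[str, list[Interval]] = {}
    for p in peaks:
        iv = p.interval if hasattr(p, "interval") else p
        peak_ivs.setdefault(iv.chrom, []).append(iv)
    for ivs in peak_ivs.values():
        ivs.sort(key=lambda i: i.start)
    flags: dict[str, bool] = {}
    for el in elements:
        iv = el.interval
        bound = any(
            iv.overlap_bp(piv) >= min_overlap_bp for piv in peak_ivs.get(iv.chrom, ())
        )
        flags[el.instance_id] = bound
    return flags


def bound_families(
    flags: dict[str, bool],
    elements: list[TEInstance],
    min_bound_copies: int | None = 10,
    min_bound_fraction: float | None = None,
) -> set[str]:
    """Families with enough bound copies, by absolute count (default >= 10)
    or by fraction of the family's copies; configure exactly one rule."""
    if (min_bound_copies is None) == (min_bound_fraction is None):
        raise ValueError("configure exactly one of min_bound_copies / min_bound_fraction")
    n_bound: dict[str, int] = {}
    n_total: dict[str, int] = {}
    for el in elements:
        n_total[el.family] = n_total.get(el.family, 0) + 1
        if flags.get(el.instance_id, False):
            n_bound[el.family] = n_bound.get(el.family, 0) + 1
    if min_bound_copies is not None:
        return {f for f, n in n_bound.items() if n >= min_bound_copies}
    return {f for f, n in n_bound.items() if n / n_total[f] >= min_bound_fraction}


def overlap_fraction(bound_set: set[str], de_set: set[str]) -> tuple[int, int, float]:
    """(|bound ∩ de|, |de|, 100·|∩|/|de|): the percentage of the
    differential set that is bound."""
    if not de_set:
        raise ValueError("differential set is empty; fraction undefined")
    inter = len(bound_set & de_set)
    return inter, len(de_set), 100.0 * inter / len(de_set)


def _tss_to_element_distance(tss: int, iv: Interval) -> int:
    if iv.start <= tss < iv.end:
        return 0
    return min(abs(tss - iv.start), abs(tss - (iv.end - 1)))


def nearest_element_distance(
    genes: list[GeneModel],
    elements: list[TEInstance],
    thresholds: tuple[int, ...] = (1000,),
) -> DistanceSummary:
    """Distance from each gene's TSS to the nearest element.

    Distance is 0 when the TSS lies inside an element, otherwise the bp to
    the nearer element edge.  Ties go to the element with the smaller start
    coordinate (deterministic).  Elements on other chromosomes are ignored;
    a gene whose chromosome has no elements is skipped.
    """
    if not elements:
        raise ValueError("element set is empty")
    by_chrom: dict[str, list[Interval]] = {}
    for el in elements:
        by_chrom.setdefault(el.interval.chrom, []).append(el.interval)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda i: (i.start, i.end))
    gene_ids: list[str] = []
    dists: list[int] = []
    for g in genes:
        ivs = by_chrom.get(g.interval.chrom)
        if not ivs:
            continue
        best = min(_tss_to_element_distance(g.tss, iv) for iv in ivs)
        gene_ids.append(g.gene_id)
        dists.append(best)
    arr = np.asarray(dists)
    fracs = {
        t: float(np.mean(arr <= t)) if arr.size else float("nan") for t in thresholds
    }
    return DistanceSummary(tuple(gene_ids), tuple(dists), fracs)


def compare_distance_distributions(
    fg_distances, bg_distances
) -> tuple[float, float, float]:
    """One-sided Mann-Whitney test that foreground distances are
    stochastically smaller than background.

    Uses the exact null distribution when both groups have n <= 20 and no
    ties, the tie-corrected normal approximation otherwise.  Returns
    (p, median_fg, median_bg).
    """
    fg = np.asarray(fg_distances, dtype=float)
    bg = np.asarray(bg_distances, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both distance sets must be non-empty")
    method = "exact" if (fg.size <= 20 and bg.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(fg, bg, alternative="less", method=method)
    return float(res.pvalue), float(np.median(fg)), float(np.median(bg))


def annotate_peaks(
    peaks: list,
    genes: list[GeneModel],
    tes: list[TEInstance],
    exons: list[Interval] | None = None,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    promoter_half_width: int = DEFAULT_PROMOTER_HALF_WIDTH,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Assign each peak its first matching category in priority order.

    Categories: promoter (TSS +/- ``promoter_half_width``), te, exon
    (explicit exon intervals; defaults to gene bodies when not supplied),
    intron (remaining gene body), intergenic.  A category matches on >= 1 bp
    overlap with the peak interval.  Returns (peak_id -> category,
    percentage breakdown table).
    """
    promoter_ivs = [
        Interval(
            g.interval.chrom,
            max(0, g.tss - promoter_half_width),
            g.tss + promoter_half_width + 1,
        )
        for g in genes
    ]
    te_ivs = [t.interval for t in tes]
    gene_bodies = [g.interval for g in genes]
    exon_ivs = exons if exons is not None else gene_bodies
    category_ivs = {
        "promoter": promoter_ivs,
        "te": te_ivs,
        "exon": exon_ivs,
        "intron": gene_bodies,
    }

    def hits(iv: Interval, targets: list[Interval]) -> bool:
        return any(iv.overlap_bp(t) >= 1 for t in targets)

    assignment: dict[str, str] = {}
    for p in peaks:
        iv = p.interval
        cat = "intergenic"
        for c in priority:
            if c == "intergenic":
                break
            if hits(iv, category_ivs[c]):
                cat = c
                break
        assignment[p.peak_id] = cat
    n = len(assignment)
    counts = pd.Series(list(assignment.values())).value_counts()
    breakdown = pd.DataFrame(
        {
            "category": list(priority),
            "count": [int(counts.get(c, 0)) for c in priority],
        }
    )
    breakdown["percentage"] = 100.0 * breakdown["count"] / n if n else 0.0
    return assignment, breakdown
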