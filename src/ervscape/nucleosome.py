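"""MNase-seq nucleosome occupancy: fragment-length distributions,
anchor-centered binned profiles, median normalization, nucleosome-depletion
classification, peak-strength classes, and condition comparison.

Profiles span 1 kb either side of an anchor center in 25 bp bins by
default; a site is called nucleosome depleted when its central 200 bp tag
count falls strictly below the mean central 200 bp count over all sites.
"Tag count" here is fragment bp-coverage (DANPOS-style occupancy),
switchable to fragment-midpoint counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeSpec, Interval

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "ProfileSet",
    "NFRCall",
    "fragment_length_distribution",
    "occupancy_profiles",
    "median_normalize",
    "classify_nfr",
    "split_peak_classes",
    "compare_occupancy",
    "annotate_reduced_regions",
]

DEFAULT_SPAN = 1000
DEFAULT_BIN_SIZE = 25
CENTRAL_BP = 200


@dataclass
class FragmentSet:
    """Paired-end inferred fragment spans for one sample/condition."""

    fragments: list[Interval]
    label: str = ""

    def __post_init__(self) -> None:
        if any(f.length < 1 for f in self.fragments):
            raise ValueError("fragment length must be >= 1")


@dataclass
class ProfileSet:
    """Binned occupancy matrix (anchors x bins) around anchor centers."""

    anchor_ids: list[str]
    anchor_coords: list[tuple[str, int]]  # (chrom, center)
    matrix: np.ndarray
    bin_size: int
    span: int

    @property
    def n_bins(self) -> int:
        return 2 * self.span // self.bin_size

    def meta_profile(self) -> np.ndarray:
        """Mean profile across anchors."""
        return self.matrix.mean(axis=0)

    def central_counts(self, central_bp: int = CENTRAL_BP) -> np.ndarray:
        """Per-anchor tag count in the central ``central_bp`` window."""
        n_central = central_bp // self.bin_size
        mid = self.matrix.shape[1] // 2
        lo, hi = mid - n_central // 2, mid + n_central // 2
        return self.matrix[:, lo:hi].sum(axis=1)

    def scaled(self, factor: float) -> "ProfileSet":
        return ProfileSet(
            self.anchor_ids, self.anchor_coords, self.matrix * factor, self.bin_size, self.span
        )

    def to_frame(self) -> pd.DataFrame:
        offsets = np.arange(-self.span, self.span, self.bin_size)
        df = pd.DataFrame(self.matrix, columns=[str(o) for o in offsets])
        df.insert(0, "anchor_id", self.anchor_ids)
        return df


@dataclass(frozen=True)
class NFRCall:
    anchor_id: str
    central_count: float
    rank: int
    depleted: bool


def fragment_length_distribution(frags: FragmentSet) -> tuple[dict[int, int], int | None]:
    """Exact fragment-length histogram and its mode (None when empty).
    Ties on the mode go to the shorter length."""
    hist = Counter(f.length for f in frags.fragments)
    if not hist:
        return {}, None
    mode = min(hist, key=lambda l: (-hist[l], l))
    return dict(sorted(hist.items())), mode


def _fragment_coverage(
    frags: FragmentSet, genome: GenomeSpec
) -> dict[str, np.ndarray]:
    cov: dict[str, np.ndarray] = {}
    lengths = genome.lengths
    for chrom, clen in lengths.items():
        cov[chrom] = np.zeros(clen + 1, dtype=np.float64)
    for f in frags.fragments:
        cov[f.chrom][f.start] += 1
        cov[f.chrom][f.end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in cov.items()}


def occupancy_profiles(
    frags: FragmentSet,
    anchors: list[tuple[str, str, int]],
    genome: GenomeSpec,
    span: int = DEFAULT_SPAN,
    bin_size: int = DEFAULT_BIN_SIZE,
    midpoint_counts: bool = False,
) -> ProfileSet:
    """Occupancy matrix around anchors.

    ``anchors`` are ``(anchor_id, chrom, center)``; use the floor midpoint
    of a peak as its center.  Each bin holds the fragment bp-coverage
    (or, with ``midpoint_counts``, the number of fragment midpoints)
    within that 25 bp bin of [center - span, center + span).  Anchors whose
    window would extend past a chromosome edge are dropped with a warning.
    """
    if (2 * span) % bin_size != 0:
        raise ValueError("bin_size must divide the window 2*span")
    n_bins = 2 * span // bin_size
    lengths = genome.lengths

    kept: list[tuple[str, str, int]] = []
    for aid, chrom, center in anchors:
        if center - span < 0 or center + span > lengths[chrom]:
            logger.warning("anchor %s window clipped at chromosome edge; dropped", aid)
            continue
        kept.append((aid, chrom, center))

    matrix = np.zeros((len(kept), n_bins), dtype=np.float64)
    if midpoint_counts:
        mids: dict[str, np.ndarray] = {}
        for f in frags.fragments:
            mids.setdefault(f.chrom, [])
        for f in frags.fragments:
            mids[f.chrom].append((f.start + f.end) // 2)
        mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
        for i, (aid, chrom, center) in enumerate(kept):
            pos = mids.get(chrom, np.empty(0, dtype=np.int64))
            window = pos[(pos >= center - span) & (pos < center + span)]
            idx = (window - (center - span)) // bin_size
            np.add.at(matrix[i], idx, 1.0)
    else:
        cov = _fragment_coverage(frags, genome)
        for i, (aid, chrom, center) in enumerate(kept):
            window = cov[chrom][center - span : center + span]
            matrix[i] = window.reshape(n_bins, bin_size).sum(axis=1)
    return ProfileSet(
        anchor_ids=[a[0] for a in kept],
        anchor_coords=[(a[1], a[2]) for a in kept],
        matrix=matrix,
        bin_size=bin_size,
        span=span,
    )


def median_normalize(meta_profiles: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Normalize a set of meta-profiles shown together.

    Each profile is divided by its own median and multiplied by the median
    over all the profiles' medians, so library-size and digestion-depth
    differences cancel while the common scale is preserved.  The median of
    an even number of values is the mean of the two central values; after
    normalization every profile's median equals that median-of-medians
    exactly.  A profile with zero median cannot be normalized.
    """
    medians = {g: float(np.median(p)) for g, p in meta_profiles.items()}
    for g, m in medians.items():
        if m <= 0:
            raise ValueError(f"group {g!r} has non-positive profile median {m}")
    grand = float(np.median(list(medians.values())))
    return {g: np.asarray(p, dtype=float) * (grand / medians[g]) for g, p in meta_profiles.items()}


def classify_nfr(profiles: ProfileSet, central_bp: int = CENTRAL_BP) -> list[NFRCall]:
    """Nucleosome-depletion calls from central tag counts.

    A site is depleted iff its central tag count is strictly smaller than
    the mean central count over all sites.  Sites are ranked ascending by
    central count, ties broken by genomic coordinate.
    """
    if central_bp % profiles.bin_size != 0:
        raise ValueError("bin_size must divide the central window")
    central = profiles.central_counts(central_bp)
    if central.size == 0:
        return []
    mean = float(central.mean())
    # strictly-smaller with a relative guard so float accumulation on
    # identical profiles never produces spurious calls
    tol = 1e-9 * max(1.0, abs(mean))
    order = sorted(
        range(central.size), key=lambda i: (central[i], profiles.anchor_coords[i])
    )
    ranks = np.empty(central.size, dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return [
        NFRCall(
            anchor_id=profiles.anchor_ids[i],
            central_count=float(central[i]),
            rank=int(ranks[i]),
            depleted=bool(central[i] < mean - tol),
        )
        for i in range(central.size)
    ]


def split_peak_classes(peaks: list, k: int = 3) -> dict[str, str]:
    """Split peaks into k equal-size strength classes C1..Ck by fold
    enrichment, C1 strongest; remainder peaks go to the strongest classes.
    Ties are ordered deterministically by genomic coordinate."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(
        peaks,
        key=lambda p: (-p.fold_enrichment, p.interval.chrom, p.interval.start),
    )
    n = len(ordered)
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    out: dict[str, str] = {}
    i = 0
    for ci, size in enumerate(sizes, start=1):
        for p in ordered[i : i + size]:
            out[p.peak_id] = f"C{ci}"
        i += size
    return out


def compare_occupancy(
    profiles_control: ProfileSet,
    profiles_depleted: ProfileSet,
    threshold: float = 0.0,
    central_bp: int = CENTRAL_BP,
) -> pd.DataFrame:
    """Per-anchor occupancy change between conditions.

    Both conditions are first put on a common scale by median-normalizing
    their meta-profiles jointly; delta is then the depleted minus control
    mean signal in the central window.  An anchor is ``reduced`` iff
    delta < -threshold (strict).
    """
    if profiles_control.anchor_ids != profiles_depleted.anchor_ids:
        raise ValueError("conditions must share the same anchors")
    norm = median_normalize(
        {
            "control": profiles_control.meta_profile(),
            "depleted": profiles_depleted.meta_profile(),
        }
    )
    ctrl_med = float(np.median(profiles_control.meta_profile()))
    dep_med = float(np.median(profiles_depleted.meta_profile()))
    grand = float(np.median(norm["control"]))
    ctrl = profiles_control.scaled(grand / ctrl_med)
    dep = profiles_depleted.scaled(grand / dep_med)
    n_central = central_bp // profiles_control.bin_size
    delta = (dep.central_counts(central_bp) - ctrl.central_counts(central_bp)) / n_central
    return pd.DataFrame(
        {
            "anchor_id": profiles_control.anchor_ids,
            "delta": delta,
            "reduced": delta < -threshold,
        }
    )


def annotate_reduced_regions(
    comparison: pd.DataFrame,
    anchors: list[tuple[str, str, int]],
    tes: list,
    peak_classes: dict[str, str] | None = None,
    half_width: int = CENTRAL_BP // 2,
) -> pd.DataFrame:
    """Fraction of reduced anchors whose central window overlaps a curated
    TE, overall and per peak-strength class."""
    coords = {aid: (chrom, center) for aid, chrom, center in anchors}
    te_by_chrom: dict[str, list[Interval]] = {}
    for t in tes:
        iv = t.interval if hasattr(t, "interval") else t
        te_by_chrom.setdefault(iv.chrom, []).append(iv)

    def in_te(aid: str) -> bool:
        chrom, center = coords[aid]
        win = Interval(chrom, max(0, center - half_width), center + half_width)
        return any(win.overlap_bp(t) >= 1 for t in te_by_chrom.get(chrom, ()))

    reduced = comparison[comparison["reduced"]]
    rows = []
    groups: dict[str, list[str]] = {"all": list(reduced["anchor_id"])}
    if peak_classes is not None:
        for aid in reduced["anchor_id"]:
            groups.setdefault(peak_classes.get(aid, "unclassified"), []).append(aid)
    for label, aids in groups.items():
        n = len(aids)
        n_te = sum(in_te(a) for a in aids)
        rows.append(
            {
                "class": label,
                "n_reduced": n,
                "n_in_te": n_te,
                "fraction_in_te": n_te / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
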