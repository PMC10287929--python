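import itertools
import math

import numpy as np
import pytest

from ervscape.association import (
    GeneModel,
    annotate_peaks,
    bound_elements,
    bound_families,
    compare_distance_distributions,
    jaccard,
    merge_intervals,
    nearest_element_distance,
    overlap_fraction,
)
from ervscape.io_formats import GenomeSpec, Interval
from ervscape.signal_quant import Peak
from ervscape.te_annotation import TEInstance
from conftest import random_intervals


def make_te(chrom, start, end, family="F", uid=None, te_class="ERVL"):
    return TEInstance(Interval(chrom, start, end), family, te_class, uid or f"{family}:{start}")


def bitmap_jaccard(a, b, genome):
    """Per-bp bitmap oracle."""
    inter = union = 0
    for chrom in genome.chrom_names:
        n = genome.lengths[chrom]
        ba = np.zeros(n, dtype=bool)
        bb = np.zeros(n, dtype=bool)
        for iv in a:
            if iv.chrom == chrom:
                ba[iv.start : iv.end] = True
        for iv in b:
            if iv.chrom == chrom:
                bb[iv.start : iv.end] = True
        inter += int((ba & bb).sum())
        union += int((ba | bb).sum())
    return inter / union if union else 0.0


class TestJaccard:
    def test_identical_and_disjoint(self):
        a = [Interval("chr1", 0, 100), Interval("chr1", 200, 300)]
        assert jaccard(a, a) == 1.0
        assert jaccard(a, [Interval("chr1", 500, 600)]) == 0.0
        assert jaccard([], []) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bitmap_oracle(self, seed, toy_genome):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, toy_genome, 50)
        b = random_intervals(rng, toy_genome, 50)
        assert jaccard(a, b) == pytest.approx(bitmap_jaccard(a, b, toy_genome), rel=1e-12)
        assert jaccard(a, b) == pytest.approx(jaccard(b, a))

    def test_internal_merge_invariance(self, toy_genome):
        rng = np.random.default_rng(10)
        a = random_intervals(rng, toy_genome, 30)
        b = random_intervals(rng, toy_genome, 30)
        assert jaccard(merge_intervals(a), b) == pytest.approx(jaccard(a, b))


class TestBound:
    def test_abutting_not_bound(self):
        peaks = [Peak(Interval("chr1", 100, 200), 3.0, "p")]
        tes = [make_te("chr1", 200, 300, uid="abut"), make_te("chr1", 199, 300, uid="one_bp")]
        flags = bound_elements(peaks, tes)
        assert flags == {"abut": False, "one_bp": True}

    def test_family_rules(self):
        tes = [make_te("chr1", i * 1000, i * 1000 + 500, "A", uid=f"a{i}") for i in range(20)]
        flags = {t.instance_id: i < 12 for i, t in enumerate(tes)}
        assert bound_families(flags, tes, min_bound_copies=10) == {"A"}
        assert bound_families(flags, tes, min_bound_copies=13) == set()
        assert bound_families(flags, tes, min_bound_copies=None, min_bound_fraction=0.5) == {"A"}
        with pytest.raises(ValueError):
            bound_families(flags, tes, min_bound_copies=10, min_bound_fraction=0.5)

    def test_planted_binding_recovered(self, small_sim):
        from ervscape.signal_quant import curate_peaks
        from ervscape.te_annotation import curate_te_instances

        sim = small_sim
        curated = curate_te_instances(sim.tes, 300, 10)
        flags = bound_elements(curate_peaks(sim.peaks), curated)
        fams = bound_families(flags, curated, min_bound_copies=10)
        assert fams == sim.truth.bound_families


class TestOverlapFraction:
    def test_printed_worked_examples(self):
        bound = {f"te{i}" for i in range(40)} | {"x"}
        de = {f"te{i}" for i in range(69)}
        inter, n_de, pct = overlap_fraction(bound, de)
        assert (inter, n_de) == (40, 69)
        assert pct == pytest.approx(57.97, abs=0.01)

    def test_empty_de_undefined(self):
        with pytest.raises(ValueError):
            overlap_fraction({"a"}, set())

    def test_matches_set_oracle(self):
        rng = np.random.default_rng(3)
        universe = [f"e{i}" for i in range(200)]
        bound = set(rng.choice(universe, 80, replace=False))
        de = set(rng.choice(universe, 50, replace=False))
        inter, n_de, pct = overlap_fraction(bound, de)
        assert inter == len(bound & de)
        assert pct == pytest.approx(100 * len(bound & de) / len(de))


class TestNearestDistance:
    def test_tss_inside_element(self):
        genes = [GeneModel("g", Interval("chr1", 150, 1000, "+"))]
        tes = [make_te("chr1", 100, 200)]
        summary = nearest_element_distance(genes, tes)
        assert summary.distances == (0,)

    def test_edge_distance(self):
        genes = [GeneModel("g", Interval("chr1", 1000, 1500, "+"))]
        tes = [make_te("chr1", 2000, 3000)]
        assert nearest_element_distance(genes, tes).distances == (1000,)

    def test_minus_strand_tss(self):
        g = GeneModel("g", Interval("chr1", 1000, 1500, "-"))
        assert g.tss == 1499

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed, toy_genome):
        rng = np.random.default_rng(seed)
        genes = [
            GeneModel(f"g{i}", iv)
            for i, iv in enumerate(random_intervals(rng, toy_genome, 20))
        ]
        tes = [
            make_te(iv.chrom, iv.start, iv.end, uid=f"t{i}")
            for i, iv in enumerate(random_intervals(rng, toy_genome, 30))
        ]
        summary = nearest_element_distance(genes, tes)
        got = dict(zip(summary.gene_ids, summary.distances))
        for g in genes:
            cands = [t for t in tes if t.interval.chrom == g.interval.chrom]
            if not cands:
                assert g.gene_id not in got
                continue
            dists = []
            for t in cands:
                iv = t.interval
                if iv.start <= g.tss < iv.end:
                    dists.append(0)
                else:
                    dists.append(min(abs(g.tss - iv.start), abs(g.tss - (iv.end - 1))))
            assert got[g.gene_id] == min(dists)

    def test_adding_elements_weakly_decreases(self, toy_genome):
        rng = np.random.default_rng(8)
        genes = [GeneModel(f"g{i}", iv) for i, iv in enumerate(random_intervals(rng, toy_genome, 10))]
        tes = [make_te(iv.chrom, iv.start, iv.end, uid=f"t{i}")
               for i, iv in enumerate(random_intervals(rng, toy_genome, 10))]
        extra = tes + [make_te(iv.chrom, iv.start, iv.end, uid=f"x{i}")
                       for i, iv in enumerate(random_intervals(rng, toy_genome, 10))]
        s1 = nearest_element_distance(genes, tes)
        s2 = nearest_element_distance(genes, extra)
        m1 = dict(zip(s1.gene_ids, s1.distances))
        m2 = dict(zip(s2.gene_ids, s2.distances))
        for g in m1:
            assert m2[g] <= m1[g]


class TestCompareDistances:
    def test_identical_distributions(self):
        vals = [1, 2, 3, 4, 5]
        p, *_ = compare_distance_distributions(vals, vals)
        assert p >= 0.49

    def test_exact_enumeration_oracle(self):
        """fg all 0, bg all 10 (n=10 each): p from exhaustive rank enumeration."""
        fg, bg = [0] * 10, [10] * 10
        p, med_fg, med_bg = compare_distance_distributions(fg, bg)
        # enumerate all rank assignments; U_fg = 0 is observed
        n = 10
        total = math.comb(2 * n, n)
        count = 0
        for combo in itertools.combinations(range(2 * n), n):
            # U = #(fg rank < bg rank) pairs; for sorted combo, the number of
            # bg positions above position i is (2n-1-i) minus the fg ones
            u = sum((2 * n - 1 - i) - (n - 1 - idx) for idx, i in enumerate(combo))
            if u <= 0:
                count += 1
        assert p == pytest.approx(count / total, rel=1e-9)
        assert (med_fg, med_bg) == (0.0, 10.0)

    def test_planted_proximity_significant(self, small_sim):
        from ervscape.signal_quant import curate_peaks
        from ervscape.te_annotation import curate_te_instances

        sim = small_sim
        curated = curate_te_instances(sim.tes, 300, 10)
        flags = bound_elements(curate_peaks(sim.peaks), curated)
        bound = [t for t in curated if flags[t.instance_id]]
        other = [t for t in curated if not flags[t.instance_id]]
        up = [g for g in sim.genes
              if g.gene_id in sim.truth.true_up_features]
        fg = nearest_element_distance(up, bound, (1000,))
        bg = nearest_element_distance(up, other, (1000,))
        p, *_ = compare_distance_distributions(fg.distances, bg.distances)
        assert p < 0.01
        assert fg.fraction_within[1000] > bg.fraction_within[1000]


class TestAnnotatePeaks:
    def make_scene(self):
        genes = [GeneModel("g1", Interval("chr1", 5000, 8000, "+"))]
        tes = [make_te("chr1", 4500, 5200, uid="te1"), make_te("chr1", 20_000, 21_000, uid="te2")]
        return genes, tes

    def test_priority_promoter_over_te(self):
        genes, tes = self.make_scene()
        # overlaps both the promoter window (TSS 5000 +/- 2kb) and te1
        peaks = [Peak(Interval("chr1", 4800, 5100), 3.0, "p1")]
        assignment, _ = annotate_peaks(peaks, genes, tes)
        assert assignment["p1"] == "promoter"

    def test_intergenic_fallback(self):
        genes, tes = self.make_scene()
        peaks = [Peak(Interval("chr1", 50_000, 50_200), 3.0, "p1")]
        assignment, _ = annotate_peaks(peaks, genes, tes)
        assert assignment["p1"] == "intergenic"

    def test_fixture_matches_rule_by_rule_oracle(self):
        rng = np.random.default_rng(4)
        genes, tes = self.make_scene()
        peaks = [
            Peak(Interval("chr1", int(s), int(s) + 300), 3.0, f"p{i}")
            for i, s in enumerate(rng.integers(0, 60_000, 12))
        ]
        assignment, breakdown = annotate_peaks(peaks, genes, tes)
        prom = Interval("chr1", 3000, 7001)
        for p in peaks:
            iv = p.interval
            if iv.overlap_bp(prom) >= 1:
                expect = "promoter"
            elif any(iv.overlap_bp(t.interval) >= 1 for t in tes):
                expect = "te"
            elif iv.overlap_bp(genes[0].interval) >= 1:
                expect = "exon"
            else:
                expect = "intergenic"
            assert assignment[p.peak_id] == expect
        assert breakdown["percentage"].sum() == pytest.approx(100.0, abs=1e-9)
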