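import numpy as np
import pandas as pd
import pytest

from ervscape.io_formats import GenomeSpec, Interval
from ervscape.nucleosome import (
    FragmentSet,
    annotate_reduced_regions,
    classify_nfr,
    compare_occupancy,
    fragment_length_distribution,
    median_normalize,
    occupancy_profiles,
    split_peak_classes,
)
from ervscape.signal_quant import Peak

GENOME = GenomeSpec(("chr1",), (100_000,))


def frags_of(spans):
    return FragmentSet([Interval("chr1", s, e) for s, e in spans])


class TestFragmentLengths:
    def test_single_length(self):
        hist, mode = fragment_length_distribution(frags_of([(0, 147), (500, 647)]))
        assert hist == {147: 2} and mode == 147

    def test_empty(self):
        hist, mode = fragment_length_distribution(FragmentSet([]))
        assert hist == {} and mode is None

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        spans = [(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 90_000, 200), rng.integers(100, 200, 200))]
        hist, _ = fragment_length_distribution(frags_of(spans))
        lengths = [e - s for s, e in spans]
        assert hist == {l: lengths.count(l) for l in set(lengths)}

    def test_simulated_mode_near_147(self, small_sim):
        hist, mode = fragment_length_distribution(
            FragmentSet(small_sim.mnase["control"])
        )
        assert abs(mode - 147) <= 3


class TestOccupancyProfiles:
    def test_one_fragment_fills_one_bin(self):
        # anchor center 1000, span 1000 -> window [0, 2000); bin 40 covers [1000, 1025)
        frags = frags_of([(1000, 1025)])
        prof = occupancy_profiles(frags, [("a", "chr1", 1000)], GENOME)
        assert prof.matrix[0, 40] == 25
        assert prof.matrix.sum() == 25

    def test_no_fragments_zero_matrix(self):
        prof = occupancy_profiles(FragmentSet([]), [("a", "chr1", 5000)], GENOME)
        assert not prof.matrix.any()

    def test_edge_window_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            prof = occupancy_profiles(
                FragmentSet([]), [("edge", "chr1", 500), ("ok", "chr1", 5000)], GENOME
            )
        assert prof.anchor_ids == ["ok"] and "edge" in caplog.text

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_bp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spans = [(int(s), int(s) + int(l)) for s, l in
                 zip(rng.integers(0, 20_000, 50), rng.integers(100, 200, 50))]
        anchors = [(f"a{i}", "chr1", int(c)) for i, c in
                   enumerate(rng.integers(1500, 18_000, 10))]
        prof = occupancy_profiles(frags_of(spans), anchors, GENOME)
        # per-bp oracle
        cov = np.zeros(100_000)
        for s, e in spans:
            cov[s:e] += 1
        for i, (_, _, c) in enumerate(anchors):
            window = cov[c - 1000 : c + 1000]
            np.testing.assert_allclose(prof.matrix[i], window.reshape(80, 25).sum(axis=1))

    def test_mass_conservation(self):
        rng = np.random.default_rng(5)
        spans = [(int(s), int(s) + 150) for s in rng.integers(0, 90_000, 100)]
        anchors = [(f"a{i}", "chr1", int(c)) for i, c in enumerate(rng.integers(2000, 88_000, 5))]
        prof = occupancy_profiles(frags_of(spans), anchors, GENOME)
        assert prof.matrix.sum() <= len(anchors) * sum(e - s for s, e in spans)

    def test_midpoint_mode_counts_fragments(self):
        frags = frags_of([(990, 1140)])  # midpoint 1065 -> bin (1065-0)//25 = 42
        prof = occupancy_profiles(frags, [("a", "chr1", 1000)], GENOME, midpoint_counts=True)
        assert prof.matrix[0, 42] == 1 and prof.matrix.sum() == 1


class TestMedianNormalize:
    def test_single_group_identity(self):
        p = np.arange(1.0, 9.0)
        out = median_normalize({"g": p})
        np.testing.assert_allclose(out["g"], p)

    def test_two_groups_hand_value(self):
        # medians 2 and 8; median of {2, 8} (even n -> mean of central pair) = 5
        a = np.full(5, 2.0)
        b = np.full(5, 8.0)
        out = median_normalize({"a": a, "b": b})
        np.testing.assert_allclose(out["a"], 5.0)
        np.testing.assert_allclose(out["b"], 5.0)

    def test_postcondition_median_equals_grand_median(self):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.random(81) * (i + 1) + 0.1 for i in range(5)}
        out = median_normalize(groups)
        grand = float(np.median([np.median(p) for p in groups.values()]))
        for p in out.values():
            assert float(np.median(p)) == pytest.approx(grand, rel=1e-12)

    def test_zero_median_names_group(self):
        with pytest.raises(ValueError, match="flat"):
            median_normalize({"ok": np.ones(5), "flat": np.zeros(5)})


def profile_set(matrix, coords=None):
    from ervscape.nucleosome import ProfileSet

    n = matrix.shape[0]
    return ProfileSet(
        anchor_ids=[f"a{i}" for i in range(n)],
        anchor_coords=coords or [("chr1", 2000 + 100 * i) for i in range(n)],
        matrix=np.asarray(matrix, dtype=float),
        bin_size=25,
        span=1000,
    )


class TestClassifyNfr:
    def test_identical_sites_none_depleted(self):
        prof = profile_set(np.ones((4, 80)))
        calls = classify_nfr(prof)
        assert not any(c.depleted for c in calls)
        assert sorted(c.rank for c in calls) == [1, 2, 3, 4]

    def test_direct_arithmetic_example(self):
        m = np.zeros((3, 80))
        m[1, 36:44] = 10 / 8  # central 8 bins sum to 10
        m[2, 36:44] = 20 / 8
        calls = classify_nfr(profile_set(m))
        depleted = [c.anchor_id for c in calls if c.depleted]
        assert depleted == ["a0"]  # 0 < mean(10) only for the first site
        assert [c.rank for c in calls] == [1, 2, 3]

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.random((10, 80))
        base = [(c.anchor_id, c.depleted, c.rank) for c in classify_nfr(profile_set(m))]
        scaled = [(c.anchor_id, c.depleted, c.rank) for c in classify_nfr(profile_set(m * 7.3))]
        assert base == scaled

    def test_depletion_enriched_at_eroded_sites(self, small_sim):
        """Depleted-condition NFR calls concentrate at the eroded anchors."""
        from ervscape.nucleosome import FragmentSet, occupancy_profiles

        sim = small_sim
        prof = occupancy_profiles(
            FragmentSet(sim.mnase["depleted"]), sim.anchors, sim.genome
        )
        calls = {c.anchor_id: c.depleted for c in classify_nfr(prof)}
        eroded = [calls[a] for a in calls if a in sim.truth.eroded_anchor_ids]
        other = [calls[a] for a in calls if a not in sim.truth.eroded_anchor_ids]
        assert np.mean(eroded) > np.mean(other)


class TestPeakClasses:
    def make_peaks(self, fes):
        return [
            Peak(Interval("chr1", 1000 * i, 1000 * i + 200), fe, f"p{i}")
            for i, fe in enumerate(fes)
        ]

    def test_nine_peaks_even_split(self):
        peaks = self.make_peaks([9, 8, 7, 6, 5, 4, 3, 2.5, 2.1])
        classes = split_peak_classes(peaks)
        assert [classes[f"p{i}"] for i in range(9)] == ["C1"] * 3 + ["C2"] * 3 + ["C3"] * 3

    def test_ten_peaks_remainder_to_strongest(self):
        peaks = self.make_peaks(np.linspace(12, 3, 10))
        classes = split_peak_classes(peaks)
        sizes = pd.Series(list(classes.values())).value_counts()
        assert (sizes["C1"], sizes["C2"], sizes["C3"]) == (4, 3, 3)

    def test_ties_broken_by_coordinate(self):
        peaks = self.make_peaks([5, 5, 5, 5, 5, 5])
        classes = split_peak_classes(peaks)
        # stable coordinate order: first two -> C1, etc.
        assert [classes[f"p{i}"] for i in range(6)] == ["C1", "C1", "C2", "C2", "C3", "C3"]
        assert set(classes) == {f"p{i}" for i in range(6)}


class TestCompareOccupancy:
    def test_identical_conditions_nothing_reduced(self):
        rng = np.random.default_rng(3)
        m = rng.random((6, 80)) + 0.5
        out = compare_occupancy(profile_set(m), profile_set(m.copy()))
        assert not out["reduced"].any()

    def test_uniform_depletion_all_reduced_when_library_matched(self):
        """50% loss at anchor centers with flanks intact: every anchor reduced."""
        rng = np.random.default_rng(4)
        base = rng.random((8, 80)) + 1.0
        dep = base.copy()
        dep[:, 36:44] *= 0.5  # central erosion only; medians (flanks) match
        out = compare_occupancy(profile_set(base), profile_set(dep))
        assert out["reduced"].all()
        assert (out["delta"] < 0).all()

    def test_reduced_regions_in_te_by_class(self, small_sim):
        from ervscape.nucleosome import FragmentSet, occupancy_profiles
        from ervscape.signal_quant import curate_peaks
        from ervscape.te_annotation import curate_te_instances

        sim = small_sim
        ctrl = occupancy_profiles(FragmentSet(sim.mnase["control"]), sim.anchors, sim.genome)
        dep = occupancy_profiles(FragmentSet(sim.mnase["depleted"]), sim.anchors, sim.genome)
        comparison = compare_occupancy(ctrl, dep)
        # erosion was planted only at the flagged anchors
        flagged = comparison["anchor_id"].isin(sim.truth.eroded_anchor_ids)
        assert comparison.loc[flagged, "reduced"].mean() > comparison.loc[~flagged, "reduced"].mean()
        classes = split_peak_classes(curate_peaks(sim.peaks))
        tab = annotate_reduced_regions(
            comparison, sim.anchors, curate_te_instances(sim.tes, 300, 10), classes
        )
        assert set(tab["class"]) >= {"all"}
        assert ((tab["fraction_in_te"] >= 0) & (tab["fraction_in_te"] <= 1)).all()
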