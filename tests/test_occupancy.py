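"""Centromere-window statistics: brute-force interval oracles, density
invariants, size filtering, species comparison, and architecture calls."""

import numpy as np
import pandas as pd
import pytest

import cenfiber as cf
from cenfiber.errors import ConsistencyError, ValidationError
from cenfiber.footprints import Footprint, footprint_frame
from conftest import make_fiber


def plain_fiber(fiber_id, start, end, chrom="chr1"):
    return cf.Fiber(fiber_id=fiber_id, chrom=chrom, start=start, end=end)


def fp(fiber_id, start, end, chrom="chr1", size_class="nucleosomal", censored=False):
    return Footprint(
        fiber_id=fiber_id,
        chrom=chrom,
        start=start,
        end=end,
        n_unmethylated_sites=10,
        size_class=size_class,
        boundary_censored=censored,
    )


WINDOW = cf.CentromereWindow(chrom="chr1", center=5_000, flank=1_000)


class TestExtraction:
    def test_fiber_ending_at_window_start_excluded(self):
        fiber = plain_fiber("f", 3_000, WINDOW.start)
        assert cf.extract_centromeric_fibers([fiber], WINDOW) == []

    def test_fiber_containing_window_included(self):
        fiber = plain_fiber("f", 1_000, 9_000)
        assert cf.extract_centromeric_fibers([fiber], WINDOW) == [fiber]

    def test_wrong_chromosome_excluded(self):
        fiber = plain_fiber("f", 4_000, 6_000, chrom="chr2")
        assert cf.extract_centromeric_fibers([fiber], WINDOW) == []

    def test_matches_bruteforce_overlap(self):
        rng = np.random.default_rng(17)
        fibers = [
            plain_fiber(f"f{i}", s, s + w, chrom=rng.choice(["chr1", "chr2"]))
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 10_000, 200), rng.integers(1, 4_000, 200))
            )
        ]
        got = cf.extract_centromeric_fibers(fibers, WINDOW)
        expected = [
            f
            for f in fibers
            if f.chrom == WINDOW.chrom
            and max(f.start, WINDOW.start) < min(f.end, WINDOW.end)
        ]
        assert got == expected


class TestDensityProfile:
    def test_single_fiber_single_footprint(self):
        fiber = plain_fiber("f", 3_000, 7_000)
        table = footprint_frame([fp("f", 4_900, 5_100)])
        profile = cf.nucleosome_density_profile(table, [fiber], WINDOW)
        d = profile.density
        assert np.all(d[900:1100] == 1.0)
        assert np.all(d[:900] == 0.0) and np.all(d[1100:] == 0.0)

    def test_half_coverage_ratio(self):
        fibers = [plain_fiber("a", 3_000, 7_000), plain_fiber("b", 3_000, 7_000)]
        table = footprint_frame([fp("a", 4_900, 5_100)])
        profile = cf.nucleosome_density_profile(table, fibers, WINDOW)
        assert np.all(profile.density[900:1100] == 0.5)

    def test_uncovered_bases_are_nan_not_zero(self):
        fiber = plain_fiber("f", 4_500, 5_500)
        profile = cf.nucleosome_density_profile(footprint_frame([]), [fiber], WINDOW)
        assert np.isnan(profile.density[0])
        assert profile.density[600] == 0.0

    def test_subnucleosomal_footprints_excluded_from_numerator(self):
        fiber = plain_fiber("f", 3_000, 7_000)
        table = footprint_frame([fp("f", 4_950, 5_010, size_class="subnucleosomal")])
        profile = cf.nucleosome_density_profile(table, [fiber], WINDOW)
        assert np.nanmax(profile.density) == 0.0

    def test_matches_per_base_bruteforce(self):
        rng = np.random.default_rng(23)
        fibers, fps = [], []
        for i in range(40):
            s = int(rng.integers(2_000, 7_500))
            e = s + int(rng.integers(500, 3_000))
            fibers.append(plain_fiber(f"f{i}", s, e))
            pos = s
            while pos + 147 < e:
                fps.append(fp(f"f{i}", pos, pos + 147))
                pos += 147 + int(rng.integers(5, 60))
        profile = cf.nucleosome_density_profile(footprint_frame(fps), fibers, WINDOW)
        for bp in rng.integers(WINDOW.start, WINDOW.end, size=60):
            cover = sum(1 for f in fibers if f.start <= bp < f.end)
            nuc = sum(1 for x in fps if x.start <= bp < x.end)
            expected = nuc / cover if cover else np.nan
            got = profile.density[bp - WINDOW.start]
            if cover:
                assert got == pytest.approx(expected)
            else:
                assert np.isnan(got)

    def test_density_bounded_and_duplication_invariant(self, small_fibers):
        fibers, cen = small_fibers
        table = cf.call_footprints_all(fibers)
        window = cf.CentromereWindow.from_centromere(cen, 1_000)
        sub = cf.extract_centromeric_fibers(fibers, window)
        ids = {f.fiber_id for f in sub}
        sub_table = table[table["fiber_id"].isin(ids)]
        profile = cf.nucleosome_density_profile(sub_table, sub, window)
        defined = ~np.isnan(profile.density)
        assert np.all(profile.density[defined] >= 0)
        assert np.all(profile.density[defined] <= 1)
        # duplicating every fiber (with its footprints) changes nothing
        clones = [
            cf.Fiber(f.fiber_id + "_dup", f.chrom, f.start, f.end,
                     f.methylated_sites, f.methylatable_sites)
            for f in sub
        ]
        dup_table = sub_table.copy()
        dup_table["fiber_id"] = dup_table["fiber_id"] + "_dup"
        both = pd.concat([sub_table, dup_table], ignore_index=True)
        profile2 = cf.nucleosome_density_profile(both, sub + clones, window)
        np.testing.assert_allclose(profile2.density, profile.density)

    def test_footprint_without_fiber_is_consistency_error(self):
        table = footprint_frame([fp("ghost", 4_900, 5_100)])
        with pytest.raises(ConsistencyError):
            cf.nucleosome_density_profile(table, [plain_fiber("f", 3_000, 7_000)], WINDOW)


class TestAverageProfiles:
    def _profile(self, density):
        return cf.OccupancyProfile(
            window=WINDOW,
            density=np.asarray(density, dtype=float),
            n_fibers=np.ones(WINDOW.width, dtype=np.int64),
        )

    def test_average_of_identical_profiles(self):
        rng = np.random.default_rng(2)
        d = rng.random(WINDOW.width)
        avg = cf.average_profiles([self._profile(d)] * 5)
        np.testing.assert_allclose(avg.density, d)

    def test_average_of_zero_and_one(self):
        avg = cf.average_profiles(
            [self._profile(np.ones(WINDOW.width)), self._profile(np.zeros(WINDOW.width))]
        )
        np.testing.assert_allclose(avg.density, 0.5)
        np.testing.assert_array_equal(avg.n_contributing, 2)

    def test_nan_excluded_from_denominator(self):
        a = np.ones(WINDOW.width)
        b = np.zeros(WINDOW.width)
        b[:10] = np.nan
        avg = cf.average_profiles([self._profile(a), self._profile(b)])
        np.testing.assert_allclose(avg.density[:10], 1.0)
        np.testing.assert_allclose(avg.density[10:], 0.5)

    def test_mixed_flanks_rejected(self):
        other = cf.OccupancyProfile(
            window=cf.CentromereWindow("chr1", 5_000, 500),
            density=np.zeros(1_000),
            n_fibers=np.ones(1_000, dtype=np.int64),
        )
        with pytest.raises(ValidationError):
            cf.average_profiles([self._profile(np.ones(WINDOW.width)), other])

    def test_averaged_density_peaks_at_centromere_center(self):
        """Eight synthetic single-nucleosome centromeres: the cross-centromere
        average attains its maximum inside the central protected region."""
        cde = (8, 165, 25)
        total = sum(cde)
        cens = [
            cf.CentromereModel(f"chr{i+1}", 10_000 - total // 2, 10_000 - total // 2 + total,
                               "single", 227, cde)
            for i in range(8)
        ]
        genome = cf.build_genome(8, 20_000, 0.6, cens, seed=51)
        layout = cf.layout_chromatin(genome, seed=52)
        # per-fiber bulk phasing: each molecule is a different cell, so only
        # the positioned centromeric nucleosome lines up across fibers
        fibers = cf.simulate_fibers(genome, layout, 400, (15_000, 3_000),
                                    cf.MethylationParams(), seed=53,
                                    bulk_phasing="fiber")
        table = cf.call_footprints_all(fibers)
        profiles = []
        for cen in cens:
            window = cf.CentromereWindow.from_centromere(cen, 1_000)
            sub = cf.extract_centromeric_fibers(fibers, window)
            ids = {f.fiber_id for f in sub}
            profiles.append(
                cf.nucleosome_density_profile(table[table["fiber_id"].isin(ids)], sub, window)
            )
        avg = cf.average_profiles(profiles)
        peak_offset = avg.offsets()[np.nanargmax(avg.density)]
        assert abs(peak_offset) <= 227 // 2
        # and the protected center is denser than the flanks
        center_band = (avg.offsets() > -50) & (avg.offsets() < 50)
        flank_band = np.abs(avg.offsets()) > 600
        assert np.nanmean(avg.density[center_band]) > np.nanmean(avg.density[flank_band])


class TestFootprintSizes:
    def test_oversize_filtered(self):
        table = footprint_frame(
            [fp("a", 4_950, 5_100), fp("b", 4_900, 5_127), fp("c", 4_800, 5_250, size_class="oversize")]
        )
        sample = cf.centromeric_footprint_sizes(table, ("chr1", 4_950, 5_050), max_size=400)
        assert sorted(sample.sizes) == [150, 227]
        assert (sample.n_raw, sample.n_filtered) == (3, 2)

    def test_disjoint_footprint_excluded(self):
        table = footprint_frame([fp("a", 6_000, 6_150)])
        sample = cf.centromeric_footprint_sizes(table, ("chr1", 4_950, 5_050))
        assert sample.sizes.size == 0

    def test_matches_bruteforce_overlap_and_size(self):
        rng = np.random.default_rng(29)
        fps = [
            fp(f"f{i}", int(s), int(s + w))
            for i, (s, w) in enumerate(
                zip(rng.integers(4_000, 6_000, 150), rng.integers(50, 500, 150))
            )
        ]
        cen = ("chr1", 4_950, 5_050)
        sample = cf.centromeric_footprint_sizes(footprint_frame(fps), cen, max_size=400)
        expected = sorted(
            x.end - x.start
            for x in fps
            if x.start < cen[2] and x.end > cen[1] and (x.end - x.start) <= 400
        )
        assert sorted(sample.sizes) == expected


class TestCompareSizes:
    def _sample(self, values, species="x"):
        values = np.asarray(values, dtype=float)
        return cf.FootprintSizeSample(species, values, values.size, values.size)

    def test_identical_samples_null(self):
        a = self._sample([100, 100, 100])
        res = cf.compare_footprint_sizes(a, a)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_textbook_pooled_t(self):
        res = cf.compare_footprint_sizes(self._sample([1, 2, 3]), self._sample([4, 5, 6]))
        assert abs(res.t_statistic) == pytest.approx(3 * np.sqrt(3 / 2), rel=1e-12)
        from scipy import stats

        assert res.p_value == pytest.approx(
            2 * stats.t.sf(3 * np.sqrt(3 / 2), df=4), rel=1e-12
        )

    def test_species_scale_separation_significant(self):
        rng = np.random.default_rng(37)
        a = self._sample(rng.normal(227, 8, 1_000), "kmx")
        b = self._sample(rng.normal(165, 8, 1_000), "scer")
        res = cf.compare_footprint_sizes(a, b)
        assert res.p_value < 1e-4
        assert res.median_a > res.median_b


class TestClassifyFiber:
    CEN = ("chr1", 4_900, 5_100)

    def _spanning_fiber(self, methylated, fiber_id="f"):
        sites = np.arange(4_000, 6_000, 10)
        return make_fiber(sites, methylated, fiber_id=fiber_id, start=4_000, end=6_000)

    def test_clean_single(self):
        fiber = self._spanning_fiber([])
        fps = [fp("f", 4_890, 5_110, size_class="oversize")]
        call = cf.classify_fiber_model(fiber, fps, self.CEN)
        assert call.call == "single"
        assert call.internal_methylations == 0

    def test_double_with_methylated_linker(self):
        fiber = self._spanning_fiber([4_990, 5_000, 5_010])
        fps = [fp("f", 4_850, 4_980), fp("f", 5_020, 5_160)]
        call = cf.classify_fiber_model(fiber, fps, self.CEN)
        assert call.call == "double"
        assert call.internal_methylations == 3

    def test_uninformative_iff_not_spanning(self):
        sites = np.arange(4_950, 6_000, 10)
        fiber = make_fiber(sites, [], start=4_950, end=6_000)
        call = cf.classify_fiber_model(fiber, [], self.CEN)
        assert call.call == "uninformative"

    def test_no_footprints_ambiguous(self):
        call = cf.classify_fiber_model(self._spanning_fiber([]), [], self.CEN)
        assert call.call == "ambiguous"

    @pytest.mark.parametrize("model,expect,threshold", [("single", "single", 0.9), ("double", "double", 0.8)])
    def test_architecture_recovered_from_generator_truth(self, model, expect, threshold,
                                                         single_cen_genome, double_cen_genome):
        genome, layout, cen = single_cen_genome if model == "single" else double_cen_genome
        fibers = cf.simulate_fibers(genome, layout, 300, (15_000, 3_000),
                                    cf.MethylationParams(), seed=61)
        table = cf.call_footprints_all(fibers)
        from cenfiber.io import footprints_from_frame

        calls = cf.classify_fibers(fibers, footprints_from_frame(table),
                                   (cen.chrom, cen.start, cen.end))
        informative = calls[calls["call"] != "uninformative"]
        assert len(informative) >= 100
        frac = (informative["call"] == expect).mean()
        assert frac > threshold


class TestMedianRecovery:
    @pytest.mark.parametrize("width,cde2", [(227, 165), (165, 84)])
    def test_protected_width_recovered_as_sample_median(self, width, cde2):
        cde = (8, cde2, 25)
        total = sum(cde)
        start = 15_000 - total // 2
        cen = cf.CentromereModel("chr1", start, start + total, "single", width, cde)
        genome = cf.build_genome(1, 30_000, 0.6, [cen], seed=71)
        layout = cf.layout_chromatin(genome, seed=72)
        fibers = cf.simulate_fibers(genome, layout, 150, (15_000, 3_000),
                                    cf.MethylationParams(), seed=73)
        table = cf.call_footprints_all(fibers)
        sample = cf.centromeric_footprint_sizes(table, (cen.chrom, cen.start, cen.end))
        max_gap = int(np.diff(genome.site_positions["chr1"]).max())
        assert sample.n_filtered > 50
        assert abs(float(np.median(sample.sizes)) - width) <= max_gap
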