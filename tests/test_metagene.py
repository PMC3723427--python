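import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import constant_track, make_track, ramp_track
from stresschip.annotations import FlankRegions, GeneAnnotation
from stresschip.metagene import (
    average_profiles,
    bin_segment,
    central_orf_summary,
    profile_gene,
)


def brute_force_bins(positions, values, start, end, n_bins):
    """Independent per-bin mean: probe p is in bin k iff
    start + k*L/n <= p < start + (k+1)*L/n."""
    length = end - start
    out = np.full(n_bins, np.nan)
    for k in range(n_bins):
        lo = start + k * length / n_bins
        hi = start + (k + 1) * length / n_bins
        sel = [v for p, v in zip(positions, values) if lo <= p < hi]
        if sel:
            out[k] = np.mean(sel)
    return out


class TestBinSegment:
    def test_constant_signal_gives_constant_bins(self):
        t = constant_track(1.0, start=0, end=100, spacing=5)
        np.testing.assert_allclose(bin_segment(t, "chr1", (0, 100), 20), 1.0)

    def test_ramp_bin_means(self):
        t = ramp_track(start=0, end=100)
        expected = np.arange(2.0, 100.0, 5.0)  # mean of 0-4, 5-9, ...
        np.testing.assert_allclose(bin_segment(t, "chr1", (0, 100), 20), expected)

    def test_fractional_edges_seven_over_three(self):
        t = ramp_track(start=0, end=7)
        np.testing.assert_allclose(
            bin_segment(t, "chr1", (0, 7), 3), [1.0, 3.5, 5.5]
        )

    def test_empty_interval_all_missing(self):
        t = ramp_track()
        assert np.isnan(bin_segment(t, "chr1", None, 5)).all()
        assert np.isnan(bin_segment(t, "chr1", (50, 50), 5)).all()

    def test_probe_free_bins_missing(self):
        t = make_track("chr1", [2], [7.0])
        out = bin_segment(t, "chr1", (0, 30), 3)
        assert out[0] == 7.0 and np.isnan(out[1:]).all()

    @given(
        st.integers(1, 12),
        st.integers(2, 120),
        st.lists(st.integers(0, 119), min_size=0, max_size=40, unique=True),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=200)
    def test_matches_brute_force_oracle(self, n_bins, length, probes, vseed):
        rng = np.random.default_rng(vseed)
        positions = sorted(p for p in probes if p < length)
        values = rng.normal(size=len(positions))
        t = make_track("chr1", positions, values)
        got = bin_segment(t, "chr1", (0, length), n_bins)
        want = brute_force_bins(positions, values, 0, length, n_bins)
        np.testing.assert_allclose(got, want, equal_nan=True)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        pos = np.arange(0, 90, 7)
        vals = rng.normal(size=pos.size)
        base = bin_segment(make_track("c", pos, vals), "c", (0, 90), 9)
        shifted = bin_segment(make_track("c", pos, vals + 2.5), "c", (0, 90), 9)
        np.testing.assert_allclose(shifted, base + 2.5, equal_nan=True)


def _gene_with_flanks(strand="+"):
    gene = GeneAnnotation("g", "chr1", 100, 300, strand)
    flanks = FlankRegions("g", (40, 100), (300, 360))
    if strand == "-":
        flanks = FlankRegions("g", (300, 360), (40, 100))
    return gene, flanks


class TestProfileGene:
    def test_bin_count_and_labels(self):
        gene, flanks = _gene_with_flanks()
        prof = profile_gene(ramp_track(end=400), gene, flanks)
        assert prof.n_bins == 38
        assert prof.region_labels.count("ORF") == 20
        assert prof.region_labels.count("IGR5") == 9

    def test_ramp_gives_increasing_orf_bins(self):
        gene, flanks = _gene_with_flanks()
        prof = profile_gene(ramp_track(end=400), gene, flanks)
        orf = prof.bins[9:29]
        assert np.all(np.diff(orf) > 0)

    def test_minus_strand_is_exact_reverse(self):
        t = ramp_track(end=400)
        gp, fp = _gene_with_flanks("+")
        gm, fm = _gene_with_flanks("-")
        plus = profile_gene(t, gp, fp)
        minus = profile_gene(t, gm, fm)
        np.testing.assert_allclose(minus.bins, plus.bins[::-1], equal_nan=True)

    def test_empty_igr3_gives_trailing_missing(self):
        gene = GeneAnnotation("g", "chr1", 100, 300, "+")
        flanks = FlankRegions("g", (40, 100), None)
        prof = profile_gene(ramp_track(end=400), gene, flanks)
        assert np.isnan(prof.bins[-9:]).all()
        assert not np.isnan(prof.bins[:29]).any()

    def test_strand_reflected_track_symmetry(self):
        """Profiling a reflected genome with the strand flipped reproduces
        the original profile.  Segment widths divisible by their bin counts
        keep the fractional bin edges on integer coordinates, where the
        symmetry is exact (probes sitting on fractional edges would flip
        sides under reflection otherwise)."""
        rng = np.random.default_rng(5)
        size = 400
        pos = np.arange(0, size, 3)
        vals = rng.normal(size=pos.size)
        t = make_track("c", pos, vals)
        gene = GeneAnnotation("g", "c", 100, 300, "+")
        flanks = FlankRegions("g", (37, 100), (300, 363))  # 63 = 9 bins x 7 bp
        fwd = profile_gene(t, gene, flanks)
        rpos = np.sort(size - 1 - pos)
        rvals = vals[np.argsort(size - 1 - pos)]
        rt = make_track("c", rpos, rvals)
        rgene = GeneAnnotation("g", "c", size - 300, size - 100, "-")
        rflanks = FlankRegions("g", (size - 100, size - 37), (size - 363, size - 300))
        rev = profile_gene(rt, rgene, rflanks)
        np.testing.assert_allclose(rev.bins, fwd.bins, equal_nan=True)


class TestAverageProfiles:
    def _profiles(self, rows):
        from stresschip.metagene import GeneProfile

        return {
            f"g{i}": GeneProfile(f"g{i}", np.asarray(r, float), ["ORF"] * len(r))
            for i, r in enumerate(rows)
        }

    def test_single_gene_identity(self):
        profs = self._profiles([[1.0, 2.0]])
        gp = average_profiles(profs, ["g0"])
        np.testing.assert_allclose(gp.bins, [1.0, 2.0])

    def test_mean_of_two(self):
        profs = self._profiles([[1.0, 0.0], [3.0, 0.0]])
        gp = average_profiles(profs, ["g0", "g1"])
        assert gp.bins[0] == 2.0

    def test_missing_bins_skipped_not_zero_filled(self):
        profs = self._profiles([[np.nan, 5.0], [4.0, 1.0]])
        gp = average_profiles(profs, ["g0", "g1"])
        assert gp.bins[0] == 4.0 and gp.n[0] == 1
        assert gp.bins[1] == 3.0 and gp.n[1] == 2

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            average_profiles({}, [])


class TestCentralOrfSummary:
    def test_central_40_percent_window(self):
        gene = GeneAnnotation("g", "chr1", 0, 1000, "+")
        t = ramp_track(end=1000)
        s = central_orf_summary(t, gene, fraction=0.4)
        # probes 300..699 -> mean 499.5
        assert s.value == pytest.approx(499.5)
        assert s.probe_values.size == 400

    def test_fraction_one_covers_whole_orf(self):
        gene = GeneAnnotation("g", "chr1", 0, 100, "+")
        s = central_orf_summary(ramp_track(end=100), gene, fraction=1.0)
        assert s.probe_values.size == 100

    def test_constant_signal_any_fraction(self):
        gene = GeneAnnotation("g", "chr1", 0, 100, "+")
        s = central_orf_summary(constant_track(2.5, end=100), gene, fraction=0.3)
        assert s.value == pytest.approx(2.5)

    def test_no_probes_gives_missing(self):
        gene = GeneAnnotation("g", "chr1", 0, 100, "+")
        t = make_track("chr1", [5], [1.0])
        s = central_orf_summary(t, gene, fraction=0.1)
        assert np.isnan(s.value) and s.probe_values.size == 0

    def test_invalid_fraction_rejected(self):
        gene = GeneAnnotation("g", "chr1", 0, 100, "+")
        with pytest.raises(ValueError):
            central_orf_summary(ramp_track(), gene, fraction=0.0)
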