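import numpy as np
import pytest

from conftest import make_track
from stresschip.annotations import GeneAnnotation
from stresschip.chromatin_norm import NormalizationPolicy
from stresschip.promoter_profiles import (
    bin_promoter,
    cluster_promoter_averages,
    profile_promoter,
    promoter_peak,
    promoter_window_bins,
    upstream_mean,
)


def flat(level, size=3000, spacing=5):
    pos = np.arange(0, size, spacing)
    return make_track("c", pos, np.full(pos.size, float(level)))


def gaussian_dip(center_offset, gene, depth=0.8, sigma=30, size=3000, spacing=5,
                 level=1.0):
    pos = np.arange(0, size, spacing)
    if gene.strand == "+":
        t = pos - gene.start
    else:
        t = (gene.end - 1) - pos
    vals = level - depth * np.exp(-((t - center_offset) ** 2) / (2 * sigma**2))
    return make_track("c", pos, vals)


GENE = GeneAnnotation("g", "c", 1000, 2000, "+")


def test_window_bins_default_shape():
    offs = promoter_window_bins()
    assert offs[0] == -500 and offs[-1] == 75 and offs.size == 24


def test_window_must_span_atg_and_divide():
    with pytest.raises(ValueError):
        promoter_window_bins((-500, -100))
    with pytest.raises(ValueError):
        promoter_window_bins((-500, 100), bin_width=33)


class TestProfilePromoter:
    def test_constant_tracks_flat_raw_and_zero_normalized(self):
        tracks = {"Gcn5": {"A": flat(2.0)}, "H3": {"A": flat(1.5)}}
        prof = profile_promoter(tracks, GENE)
        np.testing.assert_allclose(prof.raw[("Gcn5", "A")], 2.0)
        np.testing.assert_allclose(prof.normalized[("Gcn5", "A")], 0.5)

    def test_ratio_mode_constant_gives_ratio(self):
        tracks = {"Gcn5": {"A": flat(3.0)}, "H3": {"A": flat(1.5)}}
        prof = profile_promoter(
            tracks, GENE, policy=NormalizationPolicy(mode="ratio", floor=1e-9)
        )
        np.testing.assert_allclose(prof.normalized[("Gcn5", "A")], 2.0)

    def test_h3_dip_with_flat_target_peaks_at_dip_position(self):
        tracks = {
            "H3K18ac": {"A": flat(1.0)},
            "H3": {"A": gaussian_dip(-100, GENE)},
        }
        prof = profile_promoter(tracks, GENE)
        pk = promoter_peak(prof, "H3K18ac", "A")
        assert pk.peak_offset == -100  # bin [-100, -75) contains the dip centre

    def test_minus_strand_matches_reflected_plus_twin(self):
        rng = np.random.default_rng(0)
        size = 3000
        pos = np.arange(0, size, 5)
        vals = rng.normal(1.0, 0.2, pos.size)
        plus_tracks = {
            "Gcn5": {"A": make_track("c", pos, vals)},
            "H3": {"A": flat(1.0)},
        }
        plus = profile_promoter(plus_tracks, GENE)
        rpos = np.sort(size - 1 - pos)
        rvals = vals[np.argsort(size - 1 - pos)]
        minus_tracks = {
            "Gcn5": {"A": make_track("c", rpos, rvals)},
            "H3": {"A": flat(1.0)},
        }
        mgene = GeneAnnotation("g", "c", size - GENE.end, size - GENE.start, "-")
        minus = profile_promoter(minus_tracks, mgene)
        np.testing.assert_allclose(
            minus.raw[("Gcn5", "A")], plus.raw[("Gcn5", "A")], equal_nan=True
        )

    def test_chromosome_edge_truncates_to_missing_bins(self):
        near_edge = GeneAnnotation("g", "c", 200, 900, "+")
        tracks = {"Gcn5": {"A": flat(1.0, size=1000)}, "H3": {"A": flat(1.0, size=1000)}}
        prof = profile_promoter(tracks, near_edge, chrom_sizes={"c": 1000})
        vals = prof.raw[("Gcn5", "A")]
        assert np.isnan(vals[prof.offsets < -200]).all()
        assert not np.isnan(vals[prof.offsets >= -200]).any()

    def test_h3_normalized_against_itself_is_identity_value(self):
        tracks = {"H3": {"A": gaussian_dip(-100, GENE)}}
        prof = profile_promoter(tracks, GENE)
        bins = bin_promoter(tracks["H3"]["A"], GENE)
        from stresschip.chromatin_norm import normalize_bins

        np.testing.assert_allclose(
            normalize_bins(bins, bins, NormalizationPolicy()), 0.0
        )
        np.testing.assert_allclose(
            normalize_bins(bins, bins, NormalizationPolicy(mode="ratio", floor=1e-9)),
            1.0,
        )


class TestPromoterPeak:
    def _prof_with(self, values):
        tracks = {"X": {"A": flat(0.0)}, "H3": {"A": flat(0.0)}}
        prof = profile_promoter(tracks, GENE)
        arr = np.zeros(prof.offsets.size)
        for off, v in values.items():
            arr[list(prof.offsets).index(off)] = v
        prof.normalized[("X", "A")] = arr
        return prof

    def test_single_peak_found(self):
        pk = promoter_peak(self._prof_with({-75: 2.0}), "X", "A")
        assert pk.peak_offset == -75 and pk.peak_value == 2.0

    def test_tie_broken_toward_start_codon(self):
        pk = promoter_peak(self._prof_with({-200: 2.0, -50: 2.0}), "X", "A")
        assert pk.peak_offset == -50

    def test_monotone_increasing_peaks_nearest_atg(self):
        prof = self._prof_with({})
        prof.normalized[("X", "A")] = prof.offsets.astype(float)
        pk = promoter_peak(prof, "X", "A")
        assert pk.peak_offset == -25

    def test_downstream_bins_do_not_compete(self):
        pk = promoter_peak(self._prof_with({0: 99.0, -125: 1.0}), "X", "A")
        assert pk.peak_offset == -125

    def test_all_upstream_missing_gives_none(self):
        prof = self._prof_with({})
        vals = np.full(prof.offsets.size, np.nan)
        vals[prof.offsets >= 0] = 1.0
        prof.normalized[("X", "A")] = vals
        assert promoter_peak(prof, "X", "A") is None

    def test_shift_equivariance_in_log_mode(self):
        prof = self._prof_with({-75: 2.0, -300: 1.0})
        pk = promoter_peak(prof, "X", "A")
        prof.normalized[("X", "A")] = prof.normalized[("X", "A")] + 3.0
        pk2 = promoter_peak(prof, "X", "A")
        assert pk2.peak_offset == pk.peak_offset
        assert pk2.peak_value == pytest.approx(pk.peak_value + 3.0)

    def test_upstream_mean_ignores_downstream(self):
        prof = self._prof_with({-25: 4.0})
        prof.normalized[("X", "A")][prof.offsets >= 0] = 100.0
        n_up = int((prof.offsets + 25 <= 0).sum())
        assert upstream_mean(prof, "X", "A") == pytest.approx(4.0 / n_up)


class TestClusterAverages:
    def _two_gene_profiles(self, deltas):
        """Two one-gene clusters; cluster ci gets Gcn5 delta and an opposite
        H3 move in condition B."""
        genes = {
            "up": GeneAnnotation("up", "c", 1000, 2000, "+"),
            "down": GeneAnnotation("down", "c", 1000, 2000, "+"),
        }
        profs = {}
        for gid, d in zip(genes, deltas):
            tracks = {
                "Gcn5": {
                    "A": flat(1.0),
                    "B": flat(1.0 + max(d, 0.0)),
                },
                "H3": {"A": flat(1.0), "B": flat(1.0 - 0.5 * d)},
            }
            profs[gid] = profile_promoter(tracks, genes[gid])
        return profs

    def test_one_gene_cluster_is_that_gene(self):
        profs = self._two_gene_profiles([0.6, -0.6])
        out = cluster_promoter_averages(profs, {"up": 1, "down": 2}, "Gcn5", "B")
        raw_up, norm_up = out[1]
        np.testing.assert_allclose(raw_up.bins, profs["up"].raw[("Gcn5", "B")])

    def test_normalized_change_signs_follow_planted_regulation(self):
        """Activated genes gain H3-relative Gcn5 in B, repressed genes lose
        it even with flat raw Gcn5 (the histone-density reinterpretation)."""
        profs = self._two_gene_profiles([0.6, -0.6])
        clusters = {"up": 1, "down": 2}
        b = cluster_promoter_averages(profs, clusters, "Gcn5", "B")
        a = cluster_promoter_averages(profs, clusters, "Gcn5", "A")
        delta_up = np.nanmean(b[1][1].bins) - np.nanmean(a[1][1].bins)
        delta_down = np.nanmean(b[2][1].bins) - np.nanmean(a[2][1].bins)
        assert delta_up > 0.2
        assert delta_down < -0.2

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError):
            cluster_promoter_averages({}, {}, "Gcn5", "B")
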