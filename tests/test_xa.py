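import numpy as np
import pandas as pd
import pytest

from frapkit.xa import (
    BinnedTrack,
    ContactMatrix,
    DecayCurve,
    contact_decay,
    equalize_total,
    read_bedgraph,
    read_contact_matrix,
    read_dense_matrix,
    simulate_contact_matrix,
    sliding_mean,
    unity_normalize_decay,
    write_bedgraph,
    write_contact_matrix,
    xa_ratio,
    zscore_standardize,
)


def make_track(chrom_values: dict, bin_size=1000) -> BinnedTrack:
    rows = []
    for chrom, values in chrom_values.items():
        for i, v in enumerate(values):
            rows.append({"chrom": chrom, "start": i * bin_size, "value": float(v)})
    return BinnedTrack(pd.DataFrame(rows), bin_size=bin_size)


class TestZscoreStandardize:
    def test_background_becomes_standard_normal(self):
        rng = np.random.default_rng(0)
        track = make_track({"I": rng.normal(3, 1, 500), "X": rng.normal(5, 1, 200)})
        z = zscore_standardize(track, {"I"})
        bg = z.chrom_values("I")
        assert bg.mean() == pytest.approx(0.0, abs=1e-12)
        assert bg.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_constant_background_rejected(self):
        track = make_track({"I": np.full(100, 3.0), "X": [1, 2, 3]})
        with pytest.raises(ValueError, match="sigma"):
            zscore_standardize(track, {"I"})

    def test_two_sigma_bin_maps_to_z_of_two(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(3, 1, 1000)
        mu, sigma = bg.mean(), bg.std(ddof=0)
        track = make_track({"I": bg, "X": [mu + 2 * sigma]})
        z = zscore_standardize(track, {"I"})
        assert z.chrom_values("X")[0] == pytest.approx(2.0, abs=1e-12)

    def test_missing_background_rejected(self):
        track = make_track({"I": [1, 2, 3]})
        with pytest.raises(ValueError, match="absent"):
            zscore_standardize(track, {"I", "II"})

    def test_idempotent_on_background(self):
        rng = np.random.default_rng(2)
        track = make_track({"I": rng.normal(3, 2, 300), "X": rng.normal(4, 2, 100)})
        once = zscore_standardize(track, {"I"})
        twice = zscore_standardize(once, {"I"})
        np.testing.assert_allclose(
            twice.data["value"], once.data["value"], atol=1e-12
        )


class TestEqualizeTotal:
    def test_divides_by_target_total(self):
        track = make_track({"I": [1.0, 1.0], "X": [2.0, 3.0]})
        eq = equalize_total(track, {"X"})
        assert eq.data.loc[eq.data["chrom"] == "X", "value"].sum() == pytest.approx(1.0)
        np.testing.assert_allclose(eq.chrom_values("I"), [0.2, 0.2])

    def test_idempotent_at_unit_total(self):
        track = make_track({"X": [0.25, 0.75]})
        eq = equalize_total(track, {"X"})
        np.testing.assert_allclose(eq.chrom_values("X"), [0.25, 0.75])

    def test_replicates_share_target_total(self):
        rng = np.random.default_rng(3)
        a = make_track({"I": rng.random(50), "X": rng.random(80)})
        b = make_track({"I": rng.random(50), "X": rng.random(80) * 7})
        ta = equalize_total(a, {"X"}).data
        tb = equalize_total(b, {"X"}).data
        sa = ta.loc[ta["chrom"] == "X", "value"].sum()
        sb = tb.loc[tb["chrom"] == "X", "value"].sum()
        assert sa == pytest.approx(sb, abs=1e-12)

    def test_zero_total_rejected(self):
        track = make_track({"X": [0.0, 0.0]})
        with pytest.raises(ValueError, match="zero total"):
            equalize_total(track, {"X"})


def sliding_mean_brute_force(values, wb, sb):
    return [
        np.mean(values[i : i + wb]) for i in range(0, len(values) - wb + 1, sb)
    ]


class TestSlidingMean:
    def test_constant_track(self):
        track = make_track({"I": np.full(100, 3.5)}, bin_size=10_000)
        out = sliding_mean(track, window=100_000, step=20_000)
        np.testing.assert_allclose(out["value"], 3.5)

    def test_matches_brute_force_on_toy_chromosome(self):
        rng = np.random.default_rng(4)
        values = rng.random(100)  # 1 Mb at 10 kb bins
        track = make_track({"I": values}, bin_size=10_000)
        out = sliding_mean(track, window=100_000, step=30_000)
        expected = sliding_mean_brute_force(values, 10, 3)
        np.testing.assert_allclose(out["value"], expected, atol=1e-12)

    def test_step_equals_window_gives_block_means(self):
        values = np.arange(12, dtype=float)
        track = make_track({"I": values}, bin_size=1000)
        out = sliding_mean(track, window=4000, step=4000)
        np.testing.assert_allclose(out["value"], [1.5, 5.5, 9.5])

    def test_window_longer_than_chromosome_is_empty(self):
        track = make_track({"I": np.ones(5), "II": np.ones(50)}, bin_size=1000)
        out = sliding_mean(track, window=10_000, step=1000)
        assert set(out["chrom"]) == {"II"}

    def test_windows_never_span_chromosomes(self):
        track = make_track({"I": np.zeros(20), "II": np.full(20, 1.0)}, bin_size=1000)
        out = sliding_mean(track, window=5000, step=5000)
        assert set(out.loc[out["chrom"] == "I", "value"]) == {0.0}
        assert set(out.loc[out["chrom"] == "II", "value"]) == {1.0}

    def test_invalid_window_step_rejected(self):
        track = make_track({"I": np.ones(10)}, bin_size=1000)
        with pytest.raises(ValueError):
            sliding_mean(track, window=500, step=500)
        with pytest.raises(ValueError):
            sliding_mean(track, window=2500, step=1000)


class TestContactDecay:
    def test_diagonal_only_matrix(self):
        m = np.diag(np.full(6, 4.0))
        curves = contact_decay(ContactMatrix({"I": m}, bin_size=5000))
        assert (curves["I"].p[1:] == 0).all()
        assert curves["I"].p[0] == 4.0

    def test_first_off_diagonal_mean(self):
        m = np.zeros((5, 5))
        for i in range(4):
            m[i, i + 1] = m[i + 1, i] = 2.0
        curves = contact_decay(ContactMatrix({"I": m}, bin_size=5000))
        assert curves["I"].p[1] == 2.0
        assert curves["I"].s[1] == 5000

    def test_power_law_round_trip_slope(self):
        cm, _ = simulate_contact_matrix(300, exponent=1.5, x_factor=1.0, seed=0)
        curve = contact_decay(cm)["I"]
        sel = curve.s > 0
        slope = np.polyfit(np.log(curve.s[sel]), np.log(curve.p[sel]), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.05)

    def test_max_depth_truncation(self):
        cm, _ = simulate_contact_matrix(300, bin_size=5000, seed=0)
        curve = contact_decay(cm, max_depth=50_000)["I"]
        assert curve.s[-1] == 50_000

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((4, 4))
        m[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            ContactMatrix({"I": m})


class TestUnityNormalize:
    def test_sum_in_range_is_one(self):
        cm, _ = simulate_contact_matrix(400, noise=True, seed=1)
        for chrom, curve in contact_decay(cm).items():
            norm = unity_normalize_decay(curve)
            sel = (norm.s >= 5000) & (norm.s <= 4_000_000)
            assert norm.p[sel].sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self):
        curve = DecayCurve(np.arange(10) * 5000.0, 1.0 / (np.arange(10) + 1))
        a = unity_normalize_decay(curve)
        b = unity_normalize_decay(DecayCurve(curve.s, curve.p * 10))
        np.testing.assert_allclose(a.p, b.p, atol=1e-15)

    def test_no_support_rejected(self):
        curve = DecayCurve(np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="support"):
            unity_normalize_decay(curve)


class TestXaRatio:
    @staticmethod
    def _unity_decays(cm):
        return {c: unity_normalize_decay(v) for c, v in contact_decay(cm).items()}

    def test_identical_x_gives_unit_ratio(self):
        cm, truth = simulate_contact_matrix(200, x_factor=1.0, seed=2)
        ratio = xa_ratio(self._unity_decays(cm), "X", truth["autosomes"])
        sel = ratio.s > 0
        np.testing.assert_allclose(ratio.p[sel], 1.0, atol=1e-12)

    def test_enrichment_band_detected(self):
        cm, truth = simulate_contact_matrix(400, x_factor=1.5, seed=3)
        ratio = xa_ratio(self._unity_decays(cm), "X", truth["autosomes"])
        s1, s2 = truth["x_band"]
        inside = (ratio.s >= s1) & (ratio.s <= s2)
        outside = ~inside & (ratio.s > 0)
        assert np.nanmean(ratio.p[inside]) > 1.2
        assert np.nanmean(ratio.p[outside]) < 1.1

    def test_prenormalization_rescale_invariance(self):
        cm, truth = simulate_contact_matrix(200, seed=4)
        decays = contact_decay(cm)
        doubled = {
            c: DecayCurve(v.s, v.p * (2.0 if c != "X" else 1.0), chrom=c)
            for c, v in decays.items()
        }
        r1 = xa_ratio({c: unity_normalize_decay(v) for c, v in decays.items()},
                      "X", truth["autosomes"])
        r2 = xa_ratio({c: unity_normalize_decay(v) for c, v in doubled.items()},
                      "X", truth["autosomes"])
        np.testing.assert_allclose(r1.p, r2.p, atol=1e-12)

    def test_missing_chromosomes_rejected(self):
        cm, _ = simulate_contact_matrix(50, seed=5)
        decays = self._unity_decays(cm)
        with pytest.raises(ValueError, match="missing"):
            xa_ratio(decays, "chrX", ["I"])
        with pytest.raises(ValueError, match="missing autosome"):
            xa_ratio(decays, "X", ["VII"])


class TestSimulateContactMatrix:
    def test_determinism(self):
        a, _ = simulate_contact_matrix(100, noise=True, seed=6)
        b, _ = simulate_contact_matrix(100, noise=True, seed=6)
        for chrom in a.matrices:
            np.testing.assert_array_equal(a.matrices[chrom], b.matrices[chrom])

    def test_noiseless_round_trip_exact(self):
        cm, truth = simulate_contact_matrix(150, exponent=1.2, x_factor=1.0, seed=7)
        curve = contact_decay(cm)["II"]
        d = np.arange(1, len(curve.s))
        expected = truth["intensity"] * d ** -1.2
        np.testing.assert_allclose(curve.p[1:], expected, rtol=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_contact_matrix(50, exponent=0.0)
        with pytest.raises(ValueError):
            simulate_contact_matrix(50, x_band=(100, 100))


class TestTextIO:
    def test_bedgraph_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        track = make_track({"I": rng.random(20), "X": rng.random(10)}, bin_size=500)
        write_bedgraph(track, tmp_path / "t.bedgraph")
        back = read_bedgraph(tmp_path / "t.bedgraph")
        assert back.bin_size == 500
        pd.testing.assert_frame_equal(
            back.data.reset_index(drop=True), track.data.reset_index(drop=True)
        )

    def test_variable_bins_rejected(self, tmp_path):
        (tmp_path / "bad.bedgraph").write_text("I\t0\t100\t1.0\nI\t100\t300\t2.0\n")
        with pytest.raises(ValueError, match="constant"):
            read_bedgraph(tmp_path / "bad.bedgraph")

    def test_contact_matrix_round_trip(self, tmp_path):
        cm, _ = simulate_contact_matrix(30, noise=True, seed=9, n_autosomes=2)
        write_contact_matrix(cm, tmp_path / "bins.tsv", tmp_path / "trip.tsv")
        back = read_contact_matrix(tmp_path / "bins.tsv", tmp_path / "trip.tsv")
        assert back.bin_size == cm.bin_size
        for chrom in cm.matrices:
            np.testing.assert_allclose(back.matrices[chrom], cm.matrices[chrom])

    def test_dense_matrix_reader(self, tmp_path):
        m = np.array([[1.0, 2.0], [2.0, 3.0]])
        np.savetxt(tmp_path / "d.tsv", m, delimiter="\t")
        cm = read_dense_matrix(tmp_path / "d.tsv", "X", 5000)
        np.testing.assert_allclose(cm.matrices["X"], m)
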