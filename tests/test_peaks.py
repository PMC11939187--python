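import numpy as np
import pytest

from serumml.peaks import (FeatureMatrix, Peak, PeakList, collapse_replicates,
                           detect_peaks, flag_matrix_region, greedy_align,
                           impute_missing)
from serumml.preprocess import Spectrum
from oracles import exhaustive_align


def spec(y, mz=None):
    y = np.asarray(y, float)
    mz = np.arange(len(y), dtype=float) + 1000.0 if mz is None else mz
    return Spectrum("s", 0, "unknown", mz, y)


def gauss(x, c, h, sigma=2.5):
    return h * np.exp(-0.5 * ((x - c) / sigma) ** 2)


def peaklist(sample_id, mz_h_pairs, replicate=0, group="unknown"):
    peaks = tuple(Peak(mz=m, height=h, area=h, width=6.0)
                  for m, h in sorted(mz_h_pairs))
    return PeakList(sample_id, replicate, group, peaks)


class TestDetectPeaks:
    def test_subthreshold_bump_rejected(self):
        x = np.arange(300, dtype=float) + 1000
        y = gauss(x, 1100, 100) + gauss(x, 1200, 2)  # 2% of max < 3% gate
        pl = detect_peaks(spec(y, x))
        assert len(pl.peaks) == 1
        assert abs(pl.peaks[0].mz - 1100) < 1.0

    def test_flat_spectrum_yields_no_peaks(self):
        assert detect_peaks(spec(np.zeros(100))).peaks == ()

    def test_two_peaks_centroids_within_grid_step(self):
        x = np.arange(400, dtype=float) + 1000
        y = gauss(x, 1080, 50) + gauss(x, 1300, 80)
        pl = detect_peaks(spec(y, x))
        assert len(pl.peaks) == 2
        got = [p.mz for p in pl.peaks]
        assert abs(got[0] - 1080) <= 1.0 and abs(got[1] - 1300) <= 1.0

    def test_narrow_spike_fails_width_gate(self):
        y = np.zeros(100)
        y[50] = 100.0  # 1-point spike, width < 5
        assert detect_peaks(spec(y)).peaks == ()

    def test_area_matches_analytic_gaussian_integral(self):
        x = np.arange(600, dtype=float) + 1000
        sigma, h = 2.5, 60.0
        pl = detect_peaks(spec(gauss(x, 1300, h, sigma), x))
        analytic = h * sigma * np.sqrt(2 * np.pi)
        assert len(pl.peaks) == 1
        assert abs(pl.peaks[0].area - analytic) / analytic < 0.05


class TestFlagMatrixRegion:
    def test_exclusion_drops_in_region_peak(self):
        pl = peaklist("a", [(1600.0, 10), (2500.0, 10)])
        out = flag_matrix_region(pl, exclude=True)
        assert [p.mz for p in out.peaks] == [2500.0]

    def test_default_flags_without_removal(self):
        pl = peaklist("a", [(1600.0, 10), (2500.0, 10)])
        out = flag_matrix_region(pl)
        assert [p.mz for p in out.peaks] == [1600.0, 2500.0]
        assert out.peaks[0].flagged and not out.peaks[1].flagged

    def test_empty_list_passthrough(self):
        pl = peaklist("a", [])
        assert flag_matrix_region(pl).peaks == ()

    def test_invalid_interval(self):
        with pytest.raises(ValueError, match="lo"):
            flag_matrix_region(peaklist("a", []), lo=2000, hi=1500)


class TestGreedyAlign:
    def test_single_sample_features_are_its_peaks(self):
        pl = peaklist("a", [(1000.0, 5), (2000.0, 7), (3000.0, 2)])
        fm = greedy_align([pl])
        assert fm.n_features == 3
        assert np.allclose(fm.feature_mzs, [1000, 2000, 3000])
        assert not fm.missing.any()

    def test_peaks_within_tolerance_merge(self):
        # 1000 ppm apart < 2500 ppm: one consensus feature with 2 members
        fm = greedy_align([peaklist("a", [(1000.0, 5)]),
                           peaklist("b", [(1001.0, 5)])])
        assert fm.n_features == 1
        assert not fm.missing.any()

    def test_peaks_beyond_tolerance_stay_separate(self):
        # 10,000 ppm apart: two features, each missing in one sample
        fm = greedy_align([peaklist("a", [(1000.0, 5)]),
                           peaklist("b", [(1010.0, 5)])])
        assert fm.n_features == 2
        assert fm.missing.sum() == 2

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            greedy_align([])
        with pytest.raises(ValueError, match="tol_ppm"):
            greedy_align([peaklist("a", [(1000.0, 5)])], tol_ppm=-1)

    def test_partition_property(self):
        # every peak lands in exactly one feature; one peak per sample/feature
        rng = np.random.default_rng(0)
        pls = []
        for sid in "abcd":
            mzs = np.sort(rng.uniform(1000, 5000, 6))
            pls.append(peaklist(sid, [(m, rng.uniform(1, 10)) for m in mzs]))
        fm = greedy_align(pls)
        n_peaks = sum(len(p.peaks) for p in pls)
        assert (~fm.missing).sum() == n_peaks

    def test_row_relative_areas_sum_to_one(self):
        rng = np.random.default_rng(1)
        pls = [peaklist(sid, [(m, rng.uniform(1, 10))
                              for m in np.sort(rng.uniform(1000, 9000, 5))])
               for sid in "abc"]
        fm = greedy_align(pls)
        detected = np.where(fm.missing, 0.0, fm.values)
        assert np.allclose(detected.sum(axis=1), 1.0)

    @pytest.mark.parametrize("case", range(6))
    def test_matches_exhaustive_partition_oracle(self, case):
        """Greedy partition equals the min-total-deviation exhaustive optimum
        on small instances whenever that optimum is unique and feasible."""
        rng = np.random.default_rng(case)
        n_samples = rng.integers(2, 5)
        centers = np.sort(rng.uniform(1000, 8000, rng.integers(2, 4)))
        pls, flat = [], []
        for si in range(n_samples):
            pairs = []
            for c in centers:
                if rng.random() < 0.8:
                    m = c * (1 + rng.normal(0, 300e-6))
                    h = rng.uniform(1, 10)
                    pairs.append((m, h))
                    flat.append((si, m, h))
            if pairs:
                pls.append(peaklist(f"s{si}", pairs))
        if not pls:
            pytest.skip("degenerate draw")
        oracle = exhaustive_align(flat, tol_ppm=2500.0)
        if oracle is None or not oracle[2]:
            pytest.skip("no unique feasible optimum")
        fm = greedy_align(pls, tol_ppm=2500.0)
        # reconstruct the greedy partition: each peak belongs to the nearest
        # consensus centroid among the features detected in its row
        recon: dict[int, set] = {j: set() for j in range(fm.n_features)}
        for pid, (si, m, h) in enumerate(flat):
            row = fm.sample_ids.index(f"s{si}")
            cand = [j for j in range(fm.n_features) if not fm.missing[row, j]]
            j_best = min(cand, key=lambda j: abs(fm.feature_mzs[j] - m))
            recon[j_best].add(pid)
        greedy_partition = {frozenset(b) for b in recon.values() if b}
        assert greedy_partition == oracle[0]


class TestImputeCollapse:
    def test_zero_mode_fills_zero(self):
        fm = greedy_align([peaklist("a", [(1000.0, 5)]),
                           peaklist("b", [(1010.0, 5)])])
        out = impute_missing(fm, "zero")
        assert out.values[out.missing].sum() == 0.0
        assert out.imputed

    def test_no_missing_is_identity(self):
        fm = greedy_align([peaklist("a", [(1000.0, 5), (2000.0, 5)])])
        out = impute_missing(fm, "interpolate")
        assert np.allclose(out.values, fm.values)

    def test_interpolation_midpoint(self):
        # missing cell flanked by 2 and 4 at equidistant feature m/z -> 3
        fm = FeatureMatrix(
            feature_mzs=np.array([1000.0, 1100.0, 1200.0]),
            values=np.array([[2.0, 0.0, 4.0]]),
            sample_ids=["a"], labels=np.array(["x"]),
            missing=np.array([[False, True, False]]))
        out = impute_missing(fm, "interpolate")
        assert out.values[0, 1] == pytest.approx(3.0)

    def test_unknown_mode_rejected(self):
        fm = greedy_align([peaklist("a", [(1000.0, 5)])])
        with pytest.raises(ValueError, match="mode"):
            impute_missing(fm, "knn")

    def test_collapse_replicates_means(self):
        pls = [peaklist("a", [(1000.0, 1)], replicate=r) for r in range(3)]
        fm = greedy_align(pls)
        fm.values[:, 0] = [1.0, 2.0, 3.0]
        out = collapse_replicates(fm)
        assert out.n_samples == 1
        assert out.values[0, 0] == pytest.approx(2.0)

    def test_collapse_single_replicate_identity(self):
        fm = greedy_align([peaklist("a", [(1000.0, 5)], replicate=0)])
        out = collapse_replicates(fm)
        assert np.allclose(out.values, fm.values)


def test_end_to_end_feature_count_zero_noise():
    from serumml import synth
    from serumml.pipeline import build_feature_matrix
    cfg = synth.SynthConfig(n_cancer=3, n_healthy=3, replicates_per_sample=2,
                            n_peaks=15, noise_sd=0.0, baseline_amplitude=0.0,
                            matrix_artifact_rate=0.0, intensity_cv=0.0,
                            seed=13)
    spectra, _, truth = synth.generate_cohort(cfg)
    fm = build_feature_matrix(spectra)
    assert fm.n_features == 15


def test_matrix_csv_round_trip(tmp_path, small_cohort):
    fm = small_cohort["fm"]
    path = tmp_path / "fm.csv"
    fm.write_csv(path)
    back = FeatureMatrix.read_csv(path)
    assert back.n_features == fm.n_features
    assert np.allclose(back.values, fm.values, atol=1e-9)
    assert list(back.labels) == list(fm.labels)
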