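import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from csretina import roi_pipeline, synthetic_data
from csretina.roi_pipeline import ConditionSegment, ImagingMovie, ROI


def _movie_with_segments(data, frame_hz=50.0, baseline=(0, 25)):
    n_t = data.shape[-1]
    seg = [ConditionSegment("flash_full", baseline[1], n_t, baseline[1] + 25)]
    return ImagingMovie(
        data, frame_hz=frame_hz, segments=seg, baseline=baseline, is_dff=True
    )


class TestPreprocess:
    def test_constant_movie_gives_zero_dff(self):
        raw = ImagingMovie(
            np.full((8, 8, 100), 5.0),
            segments=[ConditionSegment("flash_full", 25, 100, 50)],
            baseline=(0, 25),
        )
        out = roi_pipeline.preprocess(raw)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)
        assert out.is_dff

    def test_binning_halves_spatial_dimensions(self):
        raw = ImagingMovie(np.ones((16, 12, 40)), baseline=(0, 10))
        out = roi_pipeline.preprocess(raw)
        assert out.data.shape[:2] == (8, 6)
        assert out.um_per_px == pytest.approx(2 * raw.um_per_px)

    def test_repeats_are_averaged(self, rng):
        base = rng.uniform(1, 2, size=(4, 4, 30))
        reps = np.stack([base, base + 0.5])
        out = roi_pipeline.preprocess(
            ImagingMovie(reps, baseline=(0, 10)), bin_factor=1, lowpass_hz=100.0
        )
        manual = roi_pipeline.preprocess(
            ImagingMovie(reps.mean(axis=0), baseline=(0, 10)),
            bin_factor=1,
            lowpass_hz=100.0,
        )
        np.testing.assert_allclose(out.data, manual.data)

    def test_lowpass_attenuates_stopband_passes_passband(self):
        """20-Hz Butterworth: 5-Hz sine passes, 24-Hz sine is attenuated by
        the filter's own designed magnitude response."""
        from scipy.signal import butter, sosfreqz

        fs = 100.0
        t = np.arange(1000) / fs
        for freq in (5.0, 24.0):
            sine = np.sin(2 * np.pi * freq * t)
            raw = ImagingMovie(
                1.0 + 0.1 * sine[None, None, :] * np.ones((2, 2, 1)),
                frame_hz=fs,
                baseline=(0, 1000),
            )
            out = roi_pipeline.preprocess(raw, bin_factor=1)
            gain = out.data[0, 0, 200:800].std() / (0.1 * sine[200:800].std())
            sos = butter(4, 20.0 / (fs / 2), output="sos")
            w, h = sosfreqz(sos, worN=[2 * np.pi * freq / fs])
            designed = np.abs(h[0]) ** 2  # filtfilt applies the filter twice
            assert gain == pytest.approx(designed, rel=0.05)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            roi_pipeline.preprocess(ImagingMovie(np.ones((4, 4, 10))))


class TestSelectPixels:
    def test_all_zero_movie_selects_nothing(self):
        movie = _movie_with_segments(np.zeros((6, 6, 100)))
        with pytest.warns(UserWarning):
            sel = roi_pipeline.select_pixels(movie)
        assert not sel.any()

    def test_constructed_responsive_pixels_exactly_selected(self, rng):
        data = rng.normal(0, 0.05, size=(10, 10, 100))
        hot = [(2, 3), (7, 7), (5, 1)]
        for y, x in hot:
            data[y, x, 40:60] += 0.5
        movie = _movie_with_segments(data)
        sel = roi_pipeline.select_pixels(movie, threshold=0.20)
        got = set(zip(*np.nonzero(sel)))
        assert got == set(hot)

    def test_zero_threshold_selects_everything_positive(self, rng):
        data = np.abs(rng.normal(0.3, 0.1, size=(5, 5, 60))) + 0.01
        movie = _movie_with_segments(data)
        sel = roi_pipeline.select_pixels(movie, threshold=0.0)
        assert sel.all()


class TestFarthestPoint:
    def test_two_well_separated_groups(self):
        pts = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        dist = np.abs(pts - pts.T)
        labels = roi_pipeline.farthest_point_cluster(dist, threshold=1.0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_threshold_above_diameter_gives_single_cluster(self):
        pts = np.random.default_rng(0).uniform(0, 1, (20, 1))
        dist = np.abs(pts - pts.T)
        labels = roi_pipeline.farthest_point_cluster(dist, threshold=10.0)
        assert len(set(labels)) == 1

    def test_deterministic(self, rng):
        x = rng.uniform(0, 1, (30, 3))
        dist = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        a = roi_pipeline.farthest_point_cluster(dist, 0.4)
        b = roi_pipeline.farthest_point_cluster(dist, 0.4)
        np.testing.assert_array_equal(a, b)


class TestPrimaryCluster:
    def _two_population_movie(self, rng, noise=0.02):
        n_t = 150
        t = np.arange(n_t)
        w1 = np.exp(-0.5 * ((t - 60) / 5.0) ** 2)  # fast transient
        w2 = np.clip((t - 60) / 40.0, 0, 1) * (t < 120)  # slow ramp
        data = rng.normal(0, noise, size=(12, 12, n_t))
        data[2:5, 2:5] += w1
        data[8:11, 8:11] += w2
        return _movie_with_segments(data, baseline=(0, 25))

    def test_two_orthogonal_waveforms_two_rois(self, rng):
        movie = self._two_population_movie(rng)
        sel = roi_pipeline.select_pixels(movie)
        rois = roi_pipeline.primary_cluster(movie, sel, threshold=0.6)
        assert len(rois) == 2
        memberships = {tuple(sorted(map(tuple, r.pixels))) for r in rois}
        expected = {
            tuple((y, x) for y in range(2, 5) for x in range(2, 5)),
            tuple((y, x) for y in range(8, 11) for x in range(8, 11)),
        }
        assert memberships == expected

    def test_spatially_split_same_waveform_gives_two_rois_same_cluster(self, rng):
        n_t = 120
        t = np.arange(n_t)
        w = np.exp(-0.5 * ((t - 50) / 6.0) ** 2)
        data = rng.normal(0, 0.02, size=(12, 12, n_t))
        data[1:3, 1:3] += w
        data[9:11, 9:11] += w
        movie = _movie_with_segments(data, baseline=(0, 25))
        rois = roi_pipeline.primary_cluster(movie, threshold=0.6)
        assert len(rois) == 2
        assert rois[0].cluster == rois[1].cluster

    def test_too_few_pixels_rejected(self, rng):
        movie = self._two_population_movie(rng)
        sel = np.zeros((12, 12), dtype=bool)
        sel[0, 0] = True
        with pytest.raises(ValueError):
            roi_pipeline.primary_cluster(movie, sel)


class TestCuration:
    def _roi_with_cov(self, cov_target):
        base = np.sin(np.linspace(0, np.pi, 80)) + 1.1
        traces = np.stack([base * (1 + s) for s in (-cov_target, cov_target)])
        return ROI(
            pixels=np.array([[0, 0], [0, 1]]),
            member_traces=traces,
            cluster=0,
        )

    def test_identical_members_kept(self):
        roi = ROI(
            pixels=np.array([[0, 0], [0, 1]]),
            member_traces=np.ones((2, 50)),
            cluster=0,
        )
        assert roi.cov() == pytest.approx(0.0)
        assert roi_pipeline.curate_rois([roi]) == [roi]

    def test_high_variability_roi_dropped(self):
        roi = self._roi_with_cov(1.5)
        assert roi.cov() > 1.0
        assert roi_pipeline.curate_rois([roi]) == []

    def test_boundary_cov_exactly_one_kept(self):
        roi = self._roi_with_cov(1.0)
        assert roi.cov() == pytest.approx(1.0)
        assert roi_pipeline.curate_rois([roi]) == [roi]

    def test_raising_noise_only_removes_rois(self, rng):
        base = np.sin(np.linspace(0, np.pi, 80)) + 1.1
        kept = []
        for noise in (0.1, 0.5, 1.0, 2.0):
            rois = []
            for i in range(10):
                jit = rng.normal(0, noise, size=(4, 80))
                rois.append(
                    ROI(
                        pixels=np.array([[0, j] for j in range(4)]),
                        member_traces=base + jit,
                        cluster=0,
                    )
                )
            kept.append(len(roi_pipeline.curate_rois(rois)))
        assert all(a >= b for a, b in zip(kept, kept[1:]))


class TestCIndex:
    def test_perfect_split_is_zero(self):
        pts = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])[:, None]
        dist = np.abs(pts - pts.T)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert roi_pipeline.c_index(dist, labels) == pytest.approx(0.0)

    def test_label_permutation_invariance(self, rng):
        x = rng.uniform(0, 1, (20, 2))
        dist = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        labels = rng.integers(0, 3, 20)
        c1 = roi_pipeline.c_index(dist, labels)
        mapping = {0: 7, 1: 3, 2: 9}
        c2 = roi_pipeline.c_index(dist, np.array([mapping[v] for v in labels]))
        assert c1 == pytest.approx(c2)


class TestSecondaryCluster:
    @staticmethod
    def _waveform_bank(k, n_per, rng, noise=0.05):
        templates = synthetic_data.make_cluster_templates(k, seed=k)
        t = np.arange(0, 1000.0, 20.0)
        wfs, labels = [], []
        for i, tpl in enumerate(templates):
            base = synthetic_data.template_waveform(tpl, t, onset_ms=100.0)
            for _ in range(n_per):
                wfs.append(base + rng.normal(0, noise * base.max(), t.size))
                labels.append(i)
        return np.array(wfs), np.array(labels)

    def test_recovers_three_separated_templates(self, rng):
        wfs, truth = self._waveform_bank(3, 15, rng)
        model = roi_pipeline.secondary_cluster(wfs, k_range=range(2, 10))
        assert model.k == 3
        assert adjusted_rand_score(truth, model.assignments) >= 0.9

    def test_cindex_curve_covers_requested_range(self, rng):
        wfs, _ = self._waveform_bank(3, 8, rng)
        model = roi_pipeline.secondary_cluster(wfs, k_range=range(2, 8))
        assert set(model.cindex_curve) == set(range(2, 8))

    def test_empty_k_range_rejected(self, rng):
        wfs, _ = self._waveform_bank(3, 5, rng)
        with pytest.raises(ValueError):
            roi_pipeline.secondary_cluster(wfs, k_range=[])


class TestClusterSummary:
    def test_single_roi_cluster_matches_roi_metrics(self):
        from csretina import metrics

        tpl = synthetic_data.ClusterTemplate(rise_t50=80.0, decay_tau=300.0)
        t = np.arange(0, 1500.0, 20.0)
        wf = synthetic_data.template_waveform(tpl, t, onset_ms=100.0)
        model = roi_pipeline.ClusterModel(
            assignments=np.array([0]),
            k=1,
            cluster_means=wf[None, :],
            cindex_curve={},
        )
        table = roi_pipeline.cluster_summary(model, wf[None, :])
        assert len(table) == 1
        assert table.loc[0, "transiency_index"] == pytest.approx(
            metrics.transiency_index(wf)
        )
        assert table.loc[0, "n_rois"] == 1
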