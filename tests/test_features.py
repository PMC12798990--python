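"""Mass-trace building, peak detection and integration."""

import numpy as np
import pytest

import ligandfish as lf
from ligandfish.chem import MassTolerance, monoisotopic_mass, mz_from_neutral
from ligandfish.features import (
    CentroidSpectrum,
    MassTrace,
    build_mass_traces,
    detect_peaks,
    integrate_area,
)


def make_run(peaks, rts, noise_sd=0.0, seed=0):
    """Synthesize scans from (mz, amplitude, apex_rt, sigma) tuples."""
    rng = np.random.default_rng(seed)
    run = []
    for rt in rts:
        acc: dict[float, float] = {}
        for mz, amp, apex, sigma in peaks:
            y = amp * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)
            if noise_sd:
                # persistent detector baseline: centroid present every scan
                y = max(y + rng.normal(0, noise_sd), 1.0)
            if y >= 1.0:
                acc[mz] = acc.get(mz, 0.0) + y
        mzs = np.array(sorted(acc))
        run.append(CentroidSpectrum(rt, mzs, np.array([acc[m] for m in mzs])))
    return run


RTS = np.arange(0, 2.0, 1 / 120)  # 0.5-s scans over 2 min


class TestTraceBuilding:
    def test_single_ion_single_trace(self):
        run = make_run([(300.0, 1e6, 1.0, 0.05)], RTS)
        traces = build_mass_traces(run)
        assert len(traces) == 1
        assert traces[0].mz_center == pytest.approx(300.0)

    def test_ions_ten_ppm_apart_stay_separate(self):
        mz1 = 300.0
        mz2 = 300.0 * (1 + 10e-6)
        run = make_run([(mz1, 1e6, 1.0, 0.05), (mz2, 8e5, 1.0, 0.05)], RTS)
        traces = build_mass_traces(run, tol=MassTolerance(5.0))
        assert len(traces) == 2

    def test_empty_run_gives_no_traces(self):
        assert build_mass_traces([]) == []

    def test_unordered_spectra_rejected(self):
        run = make_run([(300.0, 1e6, 1.0, 0.05)], [1.0, 0.5])
        with pytest.raises(ValueError, match="order"):
            build_mass_traces(run)

    def test_centroids_partition_into_traces(self):
        run = make_run(
            [(300.0, 1e6, 0.7, 0.05), (500.0, 5e5, 1.3, 0.05)], RTS
        )
        traces = build_mass_traces(run)
        traced = sum(float(t.intensity.sum()) for t in traces)
        total = sum(float(s.intensity.sum()) for s in run)
        assert traced <= total + 1e-6


class TestPeakDetection:
    def test_clean_gaussian_detected_with_high_snr(self):
        run = make_run([(300.0, 1e6, 1.0, 0.05)], RTS, noise_sd=1e3, seed=1)
        (trace,) = build_mass_traces(run)
        feats = detect_peaks(trace)
        assert len(feats) == 1
        assert feats[0].snr > 3
        assert feats[0].height == pytest.approx(1e6, rel=0.05)
        assert feats[0].rt_apex == pytest.approx(1.0, abs=1 / 120)

    def test_peak_below_minimum_intensity_suppressed(self):
        run = make_run([(300.0, 5e4, 1.0, 0.05)], RTS)
        (trace,) = build_mass_traces(run)
        assert detect_peaks(trace) == []

    def test_flat_trace_has_no_peaks(self):
        trace = MassTrace(300.0, np.linspace(0, 1, 50), np.zeros(50))
        assert detect_peaks(trace) == []

    def test_two_resolved_peaks_on_one_trace(self):
        run = make_run(
            [(300.0, 1e6, 0.7, 0.04), (300.0, 8e5, 1.3, 0.04)],
            RTS,
            noise_sd=100.0,  # baseline keeps the trace continuous
            seed=4,
        )
        (trace,) = build_mass_traces(run)
        feats = detect_peaks(trace)
        assert len(feats) == 2
        assert feats[0].rt_apex == pytest.approx(0.7, abs=0.02)
        assert feats[1].rt_apex == pytest.approx(1.3, abs=0.02)

    def test_loosening_thresholds_never_removes_features(self):
        run = make_run(
            [(300.0, 2e5, 0.7, 0.05), (300.0, 9e5, 1.3, 0.05)],
            RTS,
            noise_sd=5e3,
            seed=2,
        )
        (trace,) = build_mass_traces(run)
        strict = detect_peaks(trace, snr_min=10, min_height=5e5)
        loose = detect_peaks(trace, snr_min=3, min_height=1e5)
        strict_keys = {(f.rt_apex, f.height) for f in strict}
        loose_keys = {(f.rt_apex, f.height) for f in loose}
        assert strict_keys <= loose_keys


class TestIntegration:
    def test_rectangle_area(self):
        n = 600
        trace = MassTrace(300.0, np.linspace(0, 1, n), np.full(n, 1e5))
        # height 1e5 over 60 s
        assert integrate_area(trace, 0.0, 1.0) == pytest.approx(6e6, rel=0.01)

    def test_gaussian_closed_form(self):
        rt = np.arange(0, 2.0, 1 / 240)
        amp, sigma = 1e6, 0.05
        y = amp * np.exp(-0.5 * ((rt - 1.0) / sigma) ** 2)
        trace = MassTrace(300.0, rt, y)
        expected = amp * sigma * 60 * np.sqrt(2 * np.pi)
        assert integrate_area(trace, 0.0, 2.0) == pytest.approx(expected, rel=0.02)

    def test_single_point_window_rejected(self):
        trace = MassTrace(300.0, np.linspace(0, 1, 100), np.ones(100))
        with pytest.raises(ValueError):
            integrate_area(trace, 0.5, 0.504)

    def test_inverted_window_rejected(self):
        trace = MassTrace(300.0, np.linspace(0, 1, 100), np.ones(100))
        with pytest.raises(ValueError):
            integrate_area(trace, 0.8, 0.2)


class TestSimulatorClosure:
    def test_noise_free_run_recovers_planted_compounds(self, tiny_run):
        """Each planted compound above threshold yields a feature at its
        [M+H]+ m/z (<= 5 ppm) and true RT (<= one scan interval)."""
        compounds, config, runs, _ = tiny_run
        feats = lf.extract_features(runs["sample_1"], run_id="sample_1")
        for c in compounds:
            mz0 = mz_from_neutral(monoisotopic_mass(c.formula))
            hits = [
                f
                for f in feats
                if abs(f.mz - mz0) / mz0 * 1e6 <= 5.0
                and abs(f.rt_apex - c.retention_time) <= config.scan_interval / 60
            ]
            assert len(hits) == 1, c.name
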