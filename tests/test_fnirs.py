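"""fNIRS signal chain: OD, MBLL, QC, filtering, PCA, ROI averaging."""

import numpy as np
import pytest

from exercog.fnirs import (
    MbllParams,
    bandpass,
    channel_quality_check,
    default_montage,
    hemoglobin_to_od,
    intensity_to_od,
    od_to_hemoglobin,
    pca_denoise,
    roi_average,
)
from exercog.fnirs.io import read_intensity_csv, write_intensity_csv

FS = 10.2


class TestOpticalDensity:
    def test_constant_intensity_zero_od(self):
        inten = np.full((2, 2, 500), 3.7)
        assert np.allclose(intensity_to_od(inten), 0.0)

    def test_log10_identity(self):
        inten = np.ones(1000)
        # one sample at mean/10 (approximately; mean barely moves)
        inten[500] = np.mean(inten) / 10
        od = intensity_to_od(inten)
        assert od[500] == pytest.approx(1.0, abs=0.05)

    def test_nonpositive_rejected_with_location(self):
        inten = np.ones((1, 2, 10))
        inten[0, 1, 3] = 0.0
        with pytest.raises(ValueError, match=r"\(0, 1, 3\)"):
            intensity_to_od(inten)


class TestMbll:
    def test_zero_od_zero_concentration(self):
        hbo, hbr = od_to_hemoglobin(np.zeros((3, 2, 100)))
        assert np.allclose(hbo, 0) and np.allclose(hbr, 0)

    def test_forward_inverse_roundtrip(self, rng):
        hbo = rng.standard_normal(200) * 0.5
        hbr = rng.standard_normal(200) * 0.2
        od = hemoglobin_to_od(hbo, hbr)
        hbo2, hbr2 = od_to_hemoglobin(od)
        np.testing.assert_allclose(hbo2, hbo, atol=1e-12)
        np.testing.assert_allclose(hbr2, hbr, atol=1e-12)

    def test_linearity(self, rng):
        od = rng.standard_normal((1, 2, 50)) * 0.01
        h1 = od_to_hemoglobin(od)[0]
        h2 = od_to_hemoglobin(2 * od)[0]
        np.testing.assert_allclose(h2, 2 * h1, rtol=1e-12)

    def test_singular_extinction_rejected(self):
        bad = {760: {"hbo": 1.0, "hbr": 2.0}, 850: {"hbo": 1.0, "hbr": 2.0}}
        with pytest.raises(ValueError, match="ill-conditioned"):
            MbllParams(extinction=bad)


class TestQualityCheck:
    def _intensity(self, cvs, n=300):
        t = np.arange(n)
        out = np.empty((len(cvs), 2, n))
        for i, cv in enumerate(cvs):
            base = 1.0 + cv * np.sqrt(2) * np.sin(2 * np.pi * t / 25)
            out[i, 0] = base
            out[i, 1] = 1.0
        return out

    def test_constant_channel_retained(self):
        rep = channel_quality_check(self._intensity([0.0]), ["C1"], FS)
        assert rep.retained == ["C1"]

    def test_high_cv_excluded(self):
        rep = channel_quality_check(self._intensity([0.0, 0.20]), ["C1", "C2"], FS)
        assert rep.excluded == ["C2"]

    def test_boundary_cv_excluded(self):
        # threshold wording is inclusive: exactly 15% is excluded
        inten = np.full((1, 2, 200), 100.0)
        inten[0, 0, :100] = 115.0
        inten[0, 0, 100:] = 85.0  # sd/mean = 15/100 = 0.15 exactly
        rep = channel_quality_check(inten, ["C1"], FS)
        assert rep.excluded == ["C1"]

    def test_requires_ten_seconds(self):
        with pytest.raises(ValueError, match="10 s"):
            channel_quality_check(np.ones((1, 2, 50)), ["C1"], FS)


class TestBandpass:
    def _sine(self, freq, n=6000):
        t = np.arange(n) / FS
        return np.sin(2 * np.pi * freq * t)

    def test_passband_amplitude_preserved(self):
        out = bandpass(self._sine(0.04), FS)
        mid = out[2000:4000]
        amp = (mid.max() - mid.min()) / 2
        assert 0.95 <= amp <= 1.05

    def test_cardiac_band_attenuated(self):
        out = bandpass(self._sine(1.0), FS)
        assert np.abs(out[2000:4000]).max() < 0.1

    def test_dc_removed(self):
        out = bandpass(np.full(6000, 5.0), FS)
        assert np.abs(out).max() < 1e-6

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass(np.ones(30), FS)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="sampling rate"):
            bandpass(np.ones(1000), fs=0.1)


class TestPcaDenoise:
    def test_common_mode_removed(self, rng):
        t = np.arange(3000) / FS
        common = np.sin(2 * np.pi * 0.05 * t) * 5
        x = rng.standard_normal((8, 3000)) * 0.1 + common
        cleaned = pca_denoise(x, 1)
        resid_power = np.mean(cleaned.mean(axis=0) ** 2)
        injected_power = np.mean(common**2)
        assert resid_power < 0.01 * injected_power

    def test_zero_components_identity(self, rng):
        x = rng.standard_normal((4, 100))
        np.testing.assert_array_equal(pca_denoise(x, 0), x)

    def test_orthogonality_to_removed_components(self, rng):
        x = rng.standard_normal((6, 500))
        xc = x - x.mean(axis=1, keepdims=True)
        u, _, _ = np.linalg.svd(xc, full_matrices=False)
        cleaned = pca_denoise(x, 2)
        cc = cleaned - cleaned.mean(axis=1, keepdims=True)
        inner = u[:, :2].T @ cc
        assert np.abs(inner).max() < 1e-8 * np.linalg.norm(cc)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_denoise(rng.standard_normal((3, 50)), 3)


class TestRoiAverage:
    def test_montage_roi_sizes(self):
        m = default_montage()
        sizes = {roi: len(chs) for roi, chs in m.roi_channels.items()}
        assert sizes["medial_frontal"] == 3
        assert sizes["left_superior_frontal"] == 8
        assert sizes["right_parietal"] == 7
        assert len(m.rois) == 9
        assert len(m.channels) == 49

    def test_identical_channels_equal_member(self, rng):
        m = default_montage()
        series = rng.standard_normal(100)
        data = {ch: series for ch in m.roi_channels["medial_frontal"]}
        roi = roi_average(data, m)
        np.testing.assert_allclose(roi.data["medial_frontal"], series)

    def test_two_channel_mean(self, rng):
        m = default_montage()
        a, b = rng.standard_normal((2, 50))
        data = {"C10": a, "C12": b}
        roi = roi_average(data, m)
        np.testing.assert_allclose(roi.data["medial_frontal"], (a + b) / 2)
        assert roi.retained_channels["medial_frontal"] == 2

    def test_dropped_roi_flagged(self, rng):
        m = default_montage()
        data = {ch: rng.standard_normal(20) for ch in m.channels}
        retained = [ch for ch in m.channels if ch not in m.roi_channels["left_precentral"]]
        roi = roi_average(data, m, retained=retained)
        assert roi.dropped_rois == ["left_precentral"]
        assert "left_precentral" not in roi.data.columns


def test_intensity_csv_roundtrip(tmp_path, rng):
    inten = rng.uniform(0.5, 2.0, size=(3, 2, 40))
    path = tmp_path / "rec.csv"
    write_intensity_csv(inten, ["C1", "C2", "C3"], (760, 850), FS, path)
    back, channels, wavelengths, fs = read_intensity_csv(path)
    assert channels == ["C1", "C2", "C3"]
    assert wavelengths == (760, 850)
    assert fs == pytest.approx(FS, rel=1e-3)
    np.testing.assert_allclose(back, inten, rtol=1e-6)


def test_pipeline_linearity_in_concentration(rng):
    """Doubling concentration fluctuations doubles the filtered output."""
    hbo = rng.standard_normal(4000) * 0.1
    hbr = -0.3 * hbo
    out1 = bandpass(od_to_hemoglobin(hemoglobin_to_od(hbo, hbr))[0], FS)
    out2 = bandpass(od_to_hemoglobin(hemoglobin_to_od(2 * hbo, 2 * hbr))[0], FS)
    np.testing.assert_allclose(out2, 2 * out1, rtol=1e-9, atol=1e-12)
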