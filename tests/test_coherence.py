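import numpy as np
import pytest

from dyadsync import constants
from dyadsync.coherence import (
    BandSpec,
    CoherenceMap,
    WaveletParams,
    band_segment_mean,
    compute_ibs,
    cwt_morlet,
    fisher_z,
    ibs_per_dyad,
    wavelet_coherence,
)
from dyadsync.errors import StageError, ValidationError
from conftest import make_hb_noise_recording
from _reference import reference_wtc

FS = 10.0
FAST = WaveletParams(period_min=2.0, period_max=17.0)


class TestCwt:
    def test_sinusoid_localization(self):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * t / 6.4)
        res = cwt_morlet(x, FS, WaveletParams())
        power = np.abs(res.coefficients) ** 2
        # restrict to the COI-safe center to avoid edge bias
        center = power[:, 300:700].mean(axis=1)
        best = res.periods[np.argmax(center)]
        assert abs(np.log2(best / 6.4)) < 1.0 / 12  # within one voice

    def test_zero_input(self):
        res = cwt_morlet(np.zeros(256), FS, FAST)
        assert np.allclose(res.coefficients, 0.0)

    def test_parseval_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4096)
        params = WaveletParams(period_min=0.2, period_max=120.0, voices_per_octave=16)
        res = cwt_morlet(x, FS, params)
        dj = 1.0 / params.voices_per_octave
        dt = 1.0 / FS
        c_delta = 0.776  # Morlet omega0=6 reconstruction constant
        est = (
            dj * dt / (c_delta * x.size)
            * (np.abs(res.coefficients) ** 2 / res.scales[:, None]).sum()
        )
        assert abs(est - x.var()) / x.var() < 0.10

    def test_short_series_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            res = cwt_morlet(np.random.default_rng(1).standard_normal(300), FS, WaveletParams())
        assert res.periods.max() <= 15.1

    def test_nonfinite_errors(self):
        x = np.zeros(256)
        x[3] = np.nan
        with pytest.raises(ValidationError):
            cwt_morlet(x, FS, FAST)


class TestWaveletCoherence:
    def test_self_coherence(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1024)
        cmap = wavelet_coherence(x, x, FS, FAST)
        band = (cmap.periods >= 3.2) & (cmap.periods <= 12.8)
        inside = cmap.coi[:, None] >= cmap.periods[None, band]
        assert cmap.values[:, band][inside].mean() > 0.99

    def test_amplitude_offset_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(512)
        base = wavelet_coherence(x, x, FS, FAST)
        scaled = wavelet_coherence(x, 3.5 * x + 2.0, FS, FAST)
        assert np.abs(base.values - scaled.values).max() < 1e-6

    def test_bounds(self):
        rng = np.random.default_rng(4)
        cmap = wavelet_coherence(
            rng.standard_normal(512), rng.standard_normal(512), FS, FAST
        )
        assert cmap.values.min() >= 0.0
        assert cmap.values.max() <= 1.0
        assert np.all(np.diff(cmap.periods) > 0)

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(20):
            x = rng.standard_normal(1024)
            y = rng.standard_normal(1024)
            cmap = wavelet_coherence(x, y, FS, FAST)
            band = (cmap.periods >= 3.2) & (cmap.periods <= 12.8)
            inside = cmap.coi[:, None] >= cmap.periods[None, band]
            vals.append(cmap.values[:, band][inside].mean())
        # null band coherence sits well below self-coherence
        assert np.mean(vals) < 0.5

    def test_length_mismatch_errors(self):
        with pytest.raises(ValidationError):
            wavelet_coherence(np.zeros(128), np.zeros(129), FS, FAST)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(512)
        y = 0.4 * x + rng.standard_normal(512)
        r2_ref, periods_ref, coi_ref = reference_wtc(x, y, FS)
        cmap = wavelet_coherence(x, y, FS, WaveletParams(period_min=2.0, period_max=16.0))
        assert np.allclose(cmap.periods, periods_ref)
        assert np.allclose(cmap.coi, coi_ref)
        assert np.abs(cmap.values.T - r2_ref).max() < 1e-6


def _const_map(value, n_t=3900):
    periods = np.array([3.5, 5.0, 7.0, 10.0, 12.0])
    times = np.arange(n_t) / FS
    coi = np.full(n_t, np.inf)
    return CoherenceMap(
        values=np.full((n_t, periods.size), value),
        periods=periods,
        times=times,
        coi=coi,
        coi_policy="exclude",
    )


class TestBandSegmentMean:
    def test_constant_map(self, default_timeline):
        cmap = _const_map(0.42)
        for segs in ({"task1"}, {"rest2"}, {"task1", "task2"}):
            assert band_segment_mean(cmap, BandSpec(), segs, default_timeline) == pytest.approx(0.42)

    def test_duration_weighted_linearity(self, default_timeline):
        cmap = _const_map(0.3)
        # make task2 values different
        times = cmap.times
        m2 = (times >= 210) & (times < 360)
        cmap.values[m2] = 0.6
        v1 = band_segment_mean(cmap, BandSpec(), {"task1"}, default_timeline)
        v2 = band_segment_mean(cmap, BandSpec(), {"task2"}, default_timeline)
        both = band_segment_mean(cmap, BandSpec(), {"task1", "task2"}, default_timeline)
        assert both == pytest.approx((150 * v1 + 150 * v2) / 300, abs=1e-9)

    def test_coi_excludes_edges(self, default_timeline):
        cmap = _const_map(0.5)
        cmap.coi = constants.BAND_PERIOD_LO_S / 2 * np.ones(cmap.times.size)
        # nothing inside COI at band periods -> NaN with warning
        with pytest.warns(UserWarning):
            out = band_segment_mean(cmap, BandSpec(), {"rest2"}, default_timeline)
        assert np.isnan(out)

    def test_unknown_segment_errors(self, default_timeline):
        with pytest.raises(ValidationError):
            band_segment_mean(_const_map(0.1), BandSpec(), {"task9"}, default_timeline)


class TestComputeIbs:
    def test_constant_map_zero(self, default_timeline):
        _, _, ibs, ibs_z = compute_ibs(_const_map(0.37), default_timeline)
        assert ibs == pytest.approx(0.0, abs=1e-12)
        assert ibs_z == pytest.approx(0.0, abs=1e-12)

    def test_task_rest_difference(self, default_timeline):
        cmap = _const_map(0.4)
        times = cmap.times
        task = ((times >= 30) & (times < 180)) | ((times >= 210) & (times < 360))
        cmap.values[task] = 0.6
        coh_task, coh_rest, ibs, _ = compute_ibs(cmap, default_timeline)
        assert coh_task == pytest.approx(0.6)
        assert coh_rest == pytest.approx(0.4)
        assert ibs == pytest.approx(0.2)

    def test_null_cohort_mean_near_zero(self):
        vals = []
        for seed in range(30):
            rec = make_hb_noise_recording(seed, n_channels=1, strength=0.0)
            res = ibs_per_dyad(rec, params=FAST, single_precision=True)
            vals.append(res[0].ibs)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 2 * se + 0.01


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_monotone(self):
        r = np.linspace(0, 0.999, 50)
        z = fisher_z(r)
        assert np.all(np.diff(z) > 0)

    def test_clips_at_one(self):
        assert np.isfinite(fisher_z(1.0))

    def test_negative_errors(self):
        with pytest.raises(ValidationError):
            fisher_z(-0.1)


class TestIbsPerDyad:
    def test_coupled_channel_is_max(self):
        rec = make_hb_noise_recording(7, strength=4.0, coupled_channel=19)
        res = ibs_per_dyad(rec, params=FAST, single_precision=True)
        by_ch = {r.channel: r.ibs for r in res if r.valid}
        assert max(by_ch, key=by_ch.get) == 19
        assert by_ch[19] > 0.1

    def test_rejected_channel_invalid(self):
        rec = make_hb_noise_recording(8, n_channels=4)
        rec.bad_channels[0, 2] = True
        res = ibs_per_dyad(rec, params=FAST, single_precision=True)
        assert not res[2].valid
        assert np.isnan(res[2].ibs)
        assert sum(r.valid for r in res) == 3

    def test_identical_recordings_high_task_coherence(self):
        rec = make_hb_noise_recording(9, n_channels=2)
        rec.data[1] = rec.data[0]
        res = ibs_per_dyad(rec, params=FAST)
        for r in res:
            assert r.coh_task > 0.99

    def test_wrong_stage_errors(self, intensity_recording):
        with pytest.raises(StageError):
            ibs_per_dyad(intensity_recording)

    def test_single_precision_agrees(self):
        rec = make_hb_noise_recording(10, n_channels=2, strength=2.0, coupled_channel=1)
        a = ibs_per_dyad(rec, params=FAST)
        b = ibs_per_dyad(rec, params=FAST, single_precision=True)
        for ra, rb in zip(a, b):
            assert ra.ibs == pytest.approx(rb.ibs, abs=1e-4)


class TestCouplingMonotonicity:
    def test_band_coherence_nondecreasing_in_strength(self):
        strengths = [0.0, 0.5, 1.0, 2.0]
        means = []
        for s in strengths:
            vals = []
            for seed in range(6):
                rec = make_hb_noise_recording(
                    1000 + seed, n_channels=1, strength=s, coupled_channel=1
                )
                res = ibs_per_dyad(rec, params=FAST, single_precision=True)
                vals.append(res[0].coh_task)
            means.append(np.mean(vals))
        assert all(a < b + 1e-6 for a, b in zip(means, means[1:]))


class TestContrastSpecificity:
    def test_task_only_coupling_positive_ibs(self):
        vals = [
            ibs_per_dyad(
                make_hb_noise_recording(2000 + s, n_channels=1, strength=3.0, coupled_channel=1),
                params=FAST,
                single_precision=True,
            )[0].ibs
            for s in range(6)
        ]
        assert np.mean(vals) > 0.1

    def test_always_on_coupling_cancels(self):
        all_segments = constants.SEGMENT_LABELS
        vals = [
            ibs_per_dyad(
                make_hb_noise_recording(
                    3000 + s,
                    n_channels=1,
                    strength=3.0,
                    coupled_channel=1,
                    active_segments=all_segments,
                ),
                params=FAST,
                single_precision=True,
            )[0].ibs
            for s in range(8)
        ]
        assert abs(np.mean(vals)) < 0.05
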