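"""Synthetic-data generator: waveform structure, recoverability, splits."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from rppglite.evaluation import estimate_hr, preprocess_signal
from rppglite.signal import Signal1D
from rppglite.synthetic import (
    ClipDataset,
    PpgParams,
    SceneParams,
    gen_ppg,
    green_trace,
    load_dataset,
    make_dataset,
    render_clip,
    save_dataset,
    skin_mask,
)
from rppglite.video import VideoClip

FS = 25.0
DUR = 128 / FS


def small_scene(**kw):
    return SceneParams(height=16, width=16, **kw)


class TestGenPpg:
    def test_pure_tone_peak_at_hr(self):
        p = PpgParams(hr_bpm=75.0, harmonic_ratio=0.0, baseline_amp=0.0,
                      noise_sd=0.0, duration_s=20.0, fs=30.0)
        s = gen_ppg(p, seed=0)
        spec = np.abs(np.fft.rfft(s.values))
        freqs = np.fft.rfftfreq(len(s), 1 / s.fs)
        assert 60 * freqs[np.argmax(spec)] == pytest.approx(75.0, abs=0.2)

    def test_harmonic_amplitude_ratio(self):
        p = PpgParams(hr_bpm=72.0, harmonic_ratio=0.3, baseline_amp=0.0,
                      noise_sd=0.0, duration_s=25.0, fs=30.0)
        s = gen_ppg(p, seed=1)
        spec = np.abs(np.fft.rfft(s.values))
        freqs = np.fft.rfftfreq(len(s), 1 / s.fs)
        fund = spec[np.argmin(np.abs(freqs - 1.2))]
        harm = spec[np.argmin(np.abs(freqs - 2.4))]
        assert harm / fund == pytest.approx(0.3, abs=0.03)

    def test_seed_determinism(self):
        p = PpgParams(duration_s=DUR, fs=FS)
        assert np.array_equal(gen_ppg(p, seed=9).values, gen_ppg(p, seed=9).values)

    def test_standardized_output(self):
        s = gen_ppg(PpgParams(duration_s=DUR, fs=FS), seed=2)
        assert abs(s.values.mean()) < 1e-12
        assert s.values.std() == pytest.approx(1.0, abs=1e-12)

    def test_drift_leaving_band_rejected(self):
        p = PpgParams(hr_bpm=170.0, hr_drift_bpm_per_s=2.0, duration_s=10.0, fs=30.0)
        with pytest.raises(ValueError, match="leaves"):
            gen_ppg(p, seed=0)

    def test_out_of_range_hr_rejected(self):
        with pytest.raises(ValueError, match="hr_bpm"):
            PpgParams(hr_bpm=190.0)


class TestRenderClip:
    def _ppg(self, hr=72.0, seed=0):
        return gen_ppg(replace(PpgParams(), hr_bpm=hr, duration_s=DUR, fs=FS), seed)

    def _inband_peak_and_floor(self, trace: Signal1D):
        v = trace.values - trace.values.mean()
        spec = np.abs(np.fft.rfft(v, 2048))  # pad: grid finer than 1 bpm
        freqs = np.fft.rfftfreq(2048, 1 / trace.fs)
        in_band = (freqs >= 40 / 60) & (freqs <= 3.0)
        return spec[in_band], freqs[in_band]

    def test_zero_modulation_has_no_peak(self):
        sc = small_scene(modulation_rgb=(0.0, 0.0, 0.0))
        clip = render_clip(self._ppg(), sc, seed=3)
        mags, _ = self._inband_peak_and_floor(green_trace(clip, sc))
        assert mags.max() < 6 * np.median(mags)

    def test_default_modulation_peak_at_hr(self):
        sc = small_scene()
        hr = 84.0
        clip = render_clip(self._ppg(hr=hr), sc, seed=3)
        mags, freqs = self._inband_peak_and_floor(green_trace(clip, sc))
        assert 60 * freqs[np.argmax(mags)] == pytest.approx(hr, abs=1.5)

    def test_motion_reduces_in_band_snr(self):
        def snr(motion):
            ratios = []
            for seed in range(3):
                sc = small_scene(motion_amplitude_px=motion)
                clip = render_clip(self._ppg(seed=seed), sc, seed=10 + seed)
                mags, freqs = self._inband_peak_and_floor(green_trace(clip, sc))
                ratios.append(mags.max() / np.median(mags))
            return np.median(ratios)

        assert snr(0.0) > snr(3.0)

    def test_8bit_quantization_and_range_check(self):
        sc = small_scene(pixel_depth="8bit")
        clip = render_clip(self._ppg(), sc, seed=5)
        assert np.allclose(clip.frames, np.round(clip.frames * 255) / 255, atol=1e-7)
        loud = small_scene(pixel_depth="8bit", modulation_rgb=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError, match="reduce modulation"):
            render_clip(self._ppg(), loud, seed=5)

    def test_label_paired_with_frames(self):
        ppg = self._ppg()
        clip = render_clip(ppg, small_scene(), seed=1)
        assert clip.label is ppg
        assert clip.n_frames == len(ppg)


class TestMakeDataset:
    def _make(self, n=10, seed=0, **kw):
        ppg = replace(PpgParams(), duration_s=DUR, fs=FS)
        return make_dataset(n, ppg=ppg, scene=small_scene(), seed=seed, **kw)

    def test_split_sizes_and_subject_exclusivity(self):
        ds = self._make(10)
        assert (ds.split == "train").sum() == 6
        assert (ds.split == "val").sum() == 2
        assert (ds.split == "test").sum() == 2
        for a in ("train", "val", "test"):
            for b in ("train", "val", "test"):
                if a != b:
                    assert not (set(ds.subject[ds.split == a])
                                & set(ds.subject[ds.split == b]))

    def test_same_seed_identical_manifest(self):
        import json

        a = json.dumps(self._make(6, seed=3).manifest, sort_keys=True)
        b = json.dumps(self._make(6, seed=3).manifest, sort_keys=True)
        assert a == b

    def test_hr_distribution_uniform(self):
        """HRs over many clips are uniform over the stated range (chi-square)."""
        rng = np.random.default_rng(0)
        # sampling path identical to make_dataset but without rendering cost
        hrs = self._make(60, seed=1).hr_bpm
        counts, _ = np.histogram(hrs, bins=6, range=(50.0, 150.0))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01
        assert rng is not None

    def test_roundtrip_through_files(self, tmp_path):
        ds = self._make(4, seed=5)
        save_dataset(ds, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert np.allclose(back.clips, ds.clips)
        assert np.allclose(back.labels, ds.labels)
        assert list(back.split) == list(ds.split)


class TestOracleRecoverability:
    def _oracle_rmse(self, ds: ClipDataset, scene: SceneParams) -> float:
        errs = []
        for i in range(len(ds)):
            clip = VideoClip(ds.clips[i], ds.fs)
            pred = estimate_hr(preprocess_signal(green_trace(clip, scene)))
            ref = estimate_hr(preprocess_signal(Signal1D(ds.labels[i], ds.fs)))
            errs.append(pred.hr - ref.hr)
        return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))

    def test_dataset_solvable_by_handcrafted_oracle(self):
        """Mean skin green trace + bandpass + STFT recovers HR to < 2 bpm at
        default noise: the dataset is solvable before any learning."""
        scene = small_scene()
        ppg = replace(PpgParams(), duration_s=DUR, fs=FS)
        ds = make_dataset(8, ppg=ppg, scene=scene, seed=21)
        assert self._oracle_rmse(ds, scene) < 2.0

    def test_difficulty_monotone_in_noise(self):
        ppg_quiet = replace(PpgParams(), duration_s=DUR, fs=FS, noise_sd=0.0)
        rmses = []
        for sensor_scale in (1.0, 30.0):
            scene = small_scene(
                modulation_rgb=tuple(m / sensor_scale for m in (0.010, 0.020, 0.008))
            )
            per_seed = [
                self._oracle_rmse(
                    make_dataset(4, ppg=ppg_quiet, scene=scene, seed=40 + s), scene
                )
                for s in range(3)
            ]
            rmses.append(np.median(per_seed))
        assert rmses[1] >= rmses[0]


def test_skin_mask_inside_frame():
    sc = small_scene()
    mask = skin_mask(sc)
    assert mask.any()
    assert not mask[0].any() and not mask[-1].any()
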