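"""Synthetic pulse-video generator: paired (clip, PPG) data with rPPG structure.

Real rPPG benchmarks pair face video with a contact PPG waveform; what the
method actually exploits is a skin region whose color is weakly modulated,
green-dominantly, at the heart-rate frequency, buried in sensor noise,
illumination flicker and motion. The generator reproduces exactly that
structure: an elliptical "skin" patch in a textured frame, its color driven
by a PPG-shaped waveform (fundamental + second harmonic + slow baseline
wander), corrupted by per-pixel sensor noise, shared per-frame illumination
fluctuation, and a smooth bounded random walk of the patch position. The
driving waveform is the ground-truth label.

It deliberately does not model face geometry, expressions, or specular
lighting — a trained model here demonstrates the learning machinery, not
performance on real faces.

Default geometry is desk-scale (32x32 pixels, 128 frames at 30 fps) so CPU
training is feasible; the full benchmark-scale geometry (128x128, 256
frames) is a parameter change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .signal import Signal1D
from .video import VideoClip

__all__ = [
    "PpgParams",
    "SceneParams",
    "gen_ppg",
    "render_clip",
    "make_clip",
    "ClipDataset",
    "make_dataset",
    "save_dataset",
    "load_dataset",
    "skin_mask",
    "green_trace",
]


@dataclass(frozen=True)
class PpgParams:
    """Waveform parameters of one synthetic PPG."""

    hr_bpm: float = 72.0
    hr_drift_bpm_per_s: float = 0.0
    harmonic_ratio: float = 0.3     # 2nd-harmonic amplitude relative to fundamental
    baseline_freq_hz: float = 0.1   # slow wander (respiratory-scale)
    baseline_amp: float = 0.1
    noise_sd: float = 0.05
    duration_s: float = 128 / 30
    fs: float = 30.0

    def __post_init__(self) -> None:
        if not (45.0 <= self.hr_bpm <= 170.0):
            raise ValueError("hr_bpm must lie in [45, 170] (inside the band with margin)")
        if self.fs < 4 * self.hr_bpm / 60.0:
            raise ValueError("fs too low for the 2nd harmonic (need fs >= 4*hr_hz)")
        if self.duration_s * self.fs < 2:
            raise ValueError("duration too short")


@dataclass(frozen=True)
class SceneParams:
    """Geometry and noise parameters of the rendered scene."""

    height: int = 32
    width: int = 32
    ellipse_center: tuple[float, float] | None = None  # defaults to frame center
    ellipse_axes: tuple[float, float] | None = None    # defaults to 0.35*(H, W)
    base_rgb: tuple[float, float, float] = (0.55, 0.45, 0.40)
    # hemoglobin-like ordering R:G:B ~ 0.5 : 1 : 0.4
    modulation_rgb: tuple[float, float, float] = (0.010, 0.020, 0.008)
    texture_sd: float = 0.02
    illumination_sd: float = 0.005
    motion_amplitude_px: float = 1.0
    pixel_depth: str = "continuous"   # or "8bit"

    def __post_init__(self) -> None:
        if self.pixel_depth not in ("continuous", "8bit"):
            raise ValueError("pixel_depth must be 'continuous' or '8bit'")
        center = self.ellipse_center or (self.height / 2.0, self.width / 2.0)
        axes = self.ellipse_axes or (0.35 * self.height, 0.35 * self.width)
        if not (0 < center[0] - axes[0] and center[0] + axes[0] < self.height
                and 0 < center[1] - axes[1] and center[1] + axes[1] < self.width):
            raise ValueError("skin ellipse must lie inside the frame")
        object.__setattr__(self, "ellipse_center", tuple(center))
        object.__setattr__(self, "ellipse_axes", tuple(axes))


def gen_ppg(p: PpgParams, seed: int = 0) -> Signal1D:
    """Generate one standardized PPG-shaped waveform.

    ppg(t) = sin(phi(t)) + harmonic_ratio*sin(2*phi(t) + phase) + baseline
             + Gaussian noise,   phi(t) = 2*pi * integral of f(t),
    with instantaneous frequency f(t) = hr/60 + drift*t/60. The result is
    standardized to zero mean, unit variance.
    """
    rng = np.random.default_rng(seed)
    n = int(round(p.duration_s * p.fs))
    t = np.arange(n) / p.fs
    f_inst = p.hr_bpm / 60.0 + p.hr_drift_bpm_per_s * t / 60.0
    hr_inst = 60.0 * f_inst
    if hr_inst.min() < 40.0 or hr_inst.max() > 180.0:
        raise ValueError(
            f"instantaneous HR leaves [40, 180] bpm during the clip "
            f"(range [{hr_inst.min():.1f}, {hr_inst.max():.1f}])"
        )
    phase = 2 * np.pi * np.cumsum(f_inst) / p.fs
    phi_h = rng.uniform(0, 2 * np.pi)
    phi_b = rng.uniform(0, 2 * np.pi)
    values = np.sin(phase)
    if p.harmonic_ratio:
        values = values + p.harmonic_ratio * np.sin(2 * phase + phi_h)
    if p.baseline_amp:
        values = values + p.baseline_amp * np.sin(2 * np.pi * p.baseline_freq_hz * t + phi_b)
    if p.noise_sd:
        values = values + rng.normal(0, p.noise_sd, n)
    values = values - values.mean()
    return Signal1D(values / values.std(), p.fs)


def skin_mask(sc: SceneParams, dy: int = 0, dx: int = 0) -> np.ndarray:
    """Boolean skin ellipse, optionally translated by integer pixels."""
    cy, cx = sc.ellipse_center
    ay, ax = sc.ellipse_axes
    yy, xx = np.mgrid[0:sc.height, 0:sc.width]
    return ((yy - cy - dy) / ay) ** 2 + ((xx - cx - dx) / ax) ** 2 <= 1.0


def _motion_walk(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Smooth bounded 2-D random walk, amplitude in pixels; shape (n, 2)."""
    if amplitude <= 0:
        return np.zeros((n, 2))
    steps = rng.normal(size=(n, 2))
    walk = np.cumsum(steps, axis=0)
    # moving-average smoothing then rescale to the requested amplitude
    k = max(3, n // 16)
    kernel = np.ones(k) / k
    for axis in range(2):
        walk[:, axis] = np.convolve(walk[:, axis], kernel, mode="same")
    walk -= walk.mean(axis=0)
    peak = np.abs(walk).max()
    if peak > 0:
        walk *= amplitude / peak
    return walk


def render_clip(ppg: Signal1D, sc: SceneParams, seed: int = 0,
                texture: np.ndarray | None = None,
                base_rgb: tuple[float, float, float] | None = None) -> VideoClip:
    """Render a clip whose skin-region color is modulated by the waveform.

    ``texture`` and ``base_rgb`` can be supplied to reuse one "subject"
    identity across clips; by default they are drawn from the seed.
    """
    rng = np.random.default_rng(seed)
    n = len(ppg)
    h, w = sc.height, sc.width
    base = np.asarray(base_rgb if base_rgb is not None else sc.base_rgb, dtype=float)
    if texture is None:
        texture = rng.normal(0, sc.texture_sd, (h, w))
    walk = np.round(_motion_walk(rng, n, sc.motion_amplitude_px)).astype(int)
    illum = rng.normal(0, sc.illumination_sd, n)
    mod = np.asarray(sc.modulation_rgb, dtype=float)

    frames = np.empty((3, n, h, w), dtype=np.float32)
    static = base[:, None, None] + texture[None]
    for t in range(n):
        mask = skin_mask(sc, dy=walk[t, 0], dx=walk[t, 1])
        frame = static + illum[t]
        frame = frame + mod[:, None, None] * ppg.values[t] * mask[None]
        frames[:, t] = frame
    frames += rng.normal(0, 0.01, frames.shape).astype(np.float32)  # sensor noise

    if sc.pixel_depth == "8bit":
        if frames.min() < 0 or frames.max() > 1:
            raise ValueError(
                "pixel values leave [0, 1] at 8-bit depth; reduce modulation or "
                "noise amplitudes"
            )
        frames = np.round(frames * 255) / np.float32(255.0)
    return VideoClip(frames=frames, fs=ppg.fs, label=ppg)


def make_clip(p: PpgParams, sc: SceneParams, seed: int = 0) -> VideoClip:
    """Convenience: one waveform + one rendering from a single seed."""
    ppg = gen_ppg(p, seed=seed)
    return render_clip(ppg, sc, seed=seed + 1)


def green_trace(clip: VideoClip, sc: SceneParams) -> Signal1D:
    """Handcrafted oracle feature: mean green intensity over the skin ellipse."""
    mask = skin_mask(sc)
    return Signal1D(clip.frames[1][:, mask].mean(axis=1).astype(float), clip.fs)


# --------------------------------------------------------------------------- #


@dataclass
class ClipDataset:
    """In-memory dataset: stacked clips, labels, and per-clip metadata."""

    clips: np.ndarray      # (n, 3, T, H, W) float32
    labels: np.ndarray     # (n, T) float64
    fs: float
    hr_bpm: np.ndarray     # (n,)
    subject: np.ndarray    # (n,) int
    split: np.ndarray      # (n,) str: train/val/test
    manifest: dict

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.split == split
        return self.clips[idx], self.labels[idx]

    def __len__(self) -> int:
        return len(self.clips)


def make_dataset(
    n_clips: int,
    hr_range_bpm: tuple[float, float] = (50.0, 150.0),
    ppg: PpgParams = PpgParams(),
    scene: SceneParams = SceneParams(),
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    clips_per_subject: int = 1,
    seed: int = 0,
) -> ClipDataset:
    """Generate a subject-exclusive train/val/test dataset.

    A "subject" is one base color + texture identity reused across its
    clips; subjects are disjoint across splits, mirroring the
    subject-exclusive protocol of real rPPG benchmarks. Heart rates are
    sampled uniformly over ``hr_range_bpm``.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_subjects = -(-n_clips // clips_per_subject)

    # subject identities
    subjects = []
    for s in range(n_subjects):
        jitter = rng.normal(0, 0.03, 3)
        base = tuple(np.clip(np.asarray(scene.base_rgb) + jitter, 0.1, 0.9))
        texture = rng.normal(0, scene.texture_sd, (scene.height, scene.width))
        subjects.append((base, texture))

    # subject-exclusive split allocation
    order = rng.permutation(n_subjects)
    n_train = int(round(split_fractions[0] * n_subjects))
    n_val = int(round(split_fractions[1] * n_subjects))
    split_of_subject = {}
    for rank, s in enumerate(order):
        split_of_subject[s] = ("train" if rank < n_train
                               else "val" if rank < n_train + n_val else "test")

    clips, labels, hrs, subj_ids, splits, records = [], [], [], [], [], []
    for i in range(n_clips):
        s = i % n_subjects
        hr = float(rng.uniform(*hr_range_bpm))
        clip_seed = int(rng.integers(0, 2**31 - 1))
        p = replace(ppg, hr_bpm=hr)
        wave = gen_ppg(p, seed=clip_seed)
        base, texture = subjects[s]
        clip = render_clip(wave, scene, seed=clip_seed + 1,
                           texture=texture, base_rgb=base)
        clips.append(clip.frames)
        labels.append(wave.values)
        hrs.append(hr)
        subj_ids.append(s)
        splits.append(split_of_subject[s])
        records.append({"index": i, "subject": s, "hr_bpm": hr,
                        "seed": clip_seed, "split": split_of_subject[s]})

    manifest = {
        "n_clips": n_clips,
        "hr_range_bpm": list(hr_range_bpm),
        "ppg_params": asdict(ppg),
        "scene_params": asdict(scene),
        "split_fractions": list(split_fractions),
        "clips_per_subject": clips_per_subject,
        "seed": seed,
        "clips": records,
    }
    return ClipDataset(
        clips=np.stack(clips),
        labels=np.stack(labels),
        fs=ppg.fs,
        hr_bpm=np.array(hrs),
        subject=np.array(subj_ids),
        split=np.array(splits),
        manifest=manifest,
    )


def save_dataset(ds: ClipDataset, outdir) -> Path:
    """Persist clips as compressed tensors, labels as CSV, manifest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(outdir / "clips.npz", clips=ds.clips)
    import pandas as pd

    t = np.arange(ds.labels.shape[1]) / ds.fs
    frames = []
    for i in range(len(ds)):
        frames.append(pd.DataFrame({"clip": i, "time_s": t, "ppg": ds.labels[i]}))
    pd.concat(frames).to_csv(outdir / "labels.csv", index=False)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(ds.manifest, indent=2, sort_keys=True))
    return manifest_path


def load_dataset(outdir) -> ClipDataset:
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    clips = np.load(outdir / "clips.npz")["clips"]
    import pandas as pd

    lab = pd.read_csv(outdir / "labels.csv")
    n = manifest["n_clips"]
    labels = np.stack([lab[lab["clip"] == i]["ppg"].to_numpy() for i in range(n)])
    records = manifest["clips"]
    return ClipDataset(
        clips=clips,
        labels=labels,
        fs=manifest["ppg_params"]["fs"],
        hr_bpm=np.array([r["hr_bpm"] for r in records]),
        subject=np.array([r["subject"] for r in records]),
        split=np.array([r["split"] for r in records]),
        manifest=manifest,
    )
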