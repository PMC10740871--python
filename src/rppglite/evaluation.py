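"""STFT heart-rate estimation and the RMSE / MAE / PCC evaluation protocol.

Predicted and reference waveforms undergo the same pipeline: frequency-bin
bandpass to 40–180 bpm, standardization, then a sliding-window short-time
Fourier transform (5 s window, 0.1 s step by default). Each window's heart
rate is 60x the frequency of the in-band magnitude peak; windows are
zero-padded to at least 2048 samples so the frequency grid is finer than
1 bpm at typical frame rates. Repeated-run statistics use Welch's two-sided
t-test, reflecting that run-to-run variability of retrained networks is too
large to compare single runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .signal import BandpassSpec, HR_BAND, Signal1D

__all__ = [
    "HRSeries",
    "MetricReport",
    "RunStatistics",
    "preprocess_signal",
    "estimate_hr",
    "compute_metrics",
    "run_statistics",
    "n_windows",
]


@dataclass(frozen=True)
class HRSeries:
    """Per-window heart-rate estimates on a sliding-window grid."""

    times: np.ndarray  # window-center seconds
    hr: np.ndarray     # bpm

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        hr = np.asarray(self.hr, dtype=float)
        if times.shape != hr.shape:
            raise ValueError("times and hr must have equal shapes")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "hr", hr)

    def __len__(self) -> int:
        return int(self.hr.size)


@dataclass(frozen=True)
class MetricReport:
    rmse: float
    mae: float
    pcc: float
    pcc_defined: bool = True

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "pcc": self.pcc,
                "pcc_defined": self.pcc_defined}


@dataclass(frozen=True)
class RunStatistics:
    mean: dict
    std: dict
    p_value: dict


def preprocess_signal(s: Signal1D, band: BandpassSpec = HR_BAND) -> Signal1D:
    """Bandpass to the heart-rate band and standardize to zero mean, unit var.

    The filter zeroes FFT bins outside the band (the same frequency-bin
    masking the loss uses), which also removes DC.
    """
    band.validate_for(s.fs)
    n = len(s)
    spec = np.fft.rfft(s.values)
    freqs = np.fft.rfftfreq(n, d=1.0 / s.fs)
    spec[(freqs < band.f_lo) | (freqs > band.f_hi)] = 0.0
    filtered = np.fft.irfft(spec, n)
    sigma = filtered.std()
    if sigma == 0:
        raise ValueError("signal has no energy inside the heart-rate band")
    return Signal1D((filtered - filtered.mean()) / sigma, s.fs)


def n_windows(n_samples: int, fs: float, window_s: float, step_s: float) -> int:
    """Number of sliding windows: floor((duration - window)/step) + 1."""
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    return (n_samples - win) // step + 1


def estimate_hr(
    s: Signal1D,
    window_s: float = 5.0,
    step_s: float = 0.1,
    band: BandpassSpec = HR_BAND,
    n_fft_min: int = 2048,
) -> HRSeries:
    """Sliding-window spectral heart-rate estimate in bpm.

    Each window's magnitude spectrum (Hann-tapered, zero-padded to at least
    ``n_fft_min``) is restricted to the band and its peak frequency taken as
    the heart rate.
    """
    win = int(round(window_s * s.fs))
    step = int(round(step_s * s.fs))
    if step < 1:
        raise ValueError(
            f"step {step_s} s is below one sample at fs={s.fs} Hz"
        )
    if len(s) < win:
        raise ValueError(
            f"signal too short: {len(s)} samples < one {window_s} s window "
            f"({win} samples at fs={s.fs} Hz)"
        )
    n_fft = n_fft_min
    while n_fft < win:
        n_fft *= 2
    freqs, times, zxx = sps.stft(
        s.values,
        fs=s.fs,
        window="hann",
        nperseg=win,
        noverlap=win - step,
        nfft=n_fft,
        boundary=None,
        padded=False,
    )
    in_band = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    mag = np.abs(zxx[in_band])
    hr = 60.0 * freqs[in_band][np.argmax(mag, axis=0)]
    return HRSeries(times=times, hr=hr)


def compute_metrics(pred: HRSeries, ref: HRSeries) -> MetricReport:
    """RMSE, MAE and Pearson correlation over aligned window grids.

    Two identical series score PCC 1 by convention; identical *constant*
    series are additionally flagged (``pcc_defined=False``) because the
    correlation is then formally undefined.
    """
    if len(pred) != len(ref):
        raise ValueError(f"window-grid mismatch: {len(pred)} vs {len(ref)} windows")
    if not np.allclose(pred.times, ref.times):
        raise ValueError("window-center times are not aligned")
    diff = pred.hr - ref.hr
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    const_pred = np.ptp(pred.hr) == 0
    const_ref = np.ptp(ref.hr) == 0
    if const_pred or const_ref:
        if np.array_equal(pred.hr, ref.hr):
            return MetricReport(rmse, mae, 1.0, pcc_defined=False)
        return MetricReport(rmse, mae, float("nan"), pcc_defined=False)
    pcc = float(stats.pearsonr(pred.hr, ref.hr).statistic)
    return MetricReport(rmse, mae, pcc)


def _metric_arrays(reports: list[MetricReport]) -> dict[str, np.ndarray]:
    return {
        "rmse": np.array([r.rmse for r in reports]),
        "mae": np.array([r.mae for r in reports]),
        "pcc": np.array([r.pcc for r in reports]),
    }


def run_statistics(
    reports: list[MetricReport],
    comparator: list[MetricReport] | None = None,
) -> RunStatistics:
    """Mean/std over repeated runs, and Welch t-test p-values vs a comparator.

    The repeated-run protocol (10 independent trainings by default) exists
    because single-run metric differences between architectures are smaller
    than run-to-run noise.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 runs for a standard deviation")
    own = _metric_arrays(reports)
    mean = {k: float(v.mean()) for k, v in own.items()}
    std = {k: float(v.std(ddof=1)) for k, v in own.items()}
    p_value: dict[str, float] = {}
    if comparator is not None:
        if len(comparator) < 2:
            raise ValueError("comparator arm needs at least 2 runs")
        other = _metric_arrays(comparator)
        for k in own:
            if np.ptp(own[k]) == 0 and np.ptp(other[k]) == 0 and np.all(
                own[k][0] == other[k]
            ):
                p_value[k] = 1.0
                continue
            p_value[k] = float(
                stats.ttest_ind(own[k], other[k], equal_var=False).pvalue
            )
    return RunStatistics(mean=mean, std=std, p_value=p_value)
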