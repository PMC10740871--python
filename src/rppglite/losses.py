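"""Spectral maximum cross-correlation (MCC) loss and comparison losses.

The MCC statistic scores how well a predicted waveform tracks a reference
waveform inside the heart-rate band, irrespective of a constant time lag:

    MCC = c_pr * max_k  IFFT{ BPass( FFT(y) * conj(FFT(yhat)) ) }[k]
          -----------------------------------------------------------
                              N * sigma_y * sigma_yhat

Both signals are mean-centered and band-limited by exact frequency-bin
masking on their native N-point grid (so an in-band tone is untouched), then
zero-padded to at least twice their length before the correlation transforms
so the lag scan is linear, not circular; the maximum over lags absorbs phase
misalignment between prediction and ground truth. ``c_pr`` is the fraction
of the reference signal's (non-DC) power that lies inside the band — a
constant with respect to the prediction — so a perfect in-band match scores
MCC = c_pr = 1 exactly. Dividing by N makes the score length-independent.

A k-sample delay necessarily costs the non-overlapping k/N fraction of
correlation mass under linear correlation; the lag max removes the *phase*
penalty (a half-period delay would otherwise score -1), which is the
misalignment the loss is designed to forgive.

Each loss here also returns its analytic gradient with respect to the
prediction, which is what the training loop backpropagates: the network is
numpy-based, so losses supply their own derivatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal import BandpassSpec, Signal1D

__all__ = [
    "MccComponents",
    "bandpass_mask",
    "mcc",
    "mcc_with_grad",
    "neg_pcc",
    "neg_pcc_with_grad",
    "mse_with_grad",
    "loss_value",
    "loss_value_with_grad",
    "LOSS_KINDS",
]

LOSS_KINDS = ("mse", "negpcc", "mcc", "negmcc")


@dataclass(frozen=True)
class MccComponents:
    """Full decomposition of one MCC evaluation."""

    cross_corr: np.ndarray  # linear cross-correlation over lags (padded length)
    c_max: float            # maximum of the band-limited cross-correlation
    lag_max: int            # lag index attaining the maximum (FFT convention)
    sigma_y: float
    sigma_yhat: float
    cpr: float              # in-band power fraction of the reference, in [0, 1]
    mcc: float


def _next_pow2(n: int) -> int:
    m = 1
    while m < n:
        m *= 2
    return m


def bandpass_mask(n_fft: int, fs: float, band: BandpassSpec) -> np.ndarray:
    """Binary mask over the ``n_fft`` FFT bins selecting |f| in [f_lo, f_hi].

    Both positive- and negative-frequency bins are kept so that masking a
    Hermitian spectrum preserves Hermitian symmetry and the inverse transform
    stays real. DC (and Nyquist, when outside the band) are zero.
    """
    if n_fft < 2:
        raise ValueError("n_fft must be >= 2")
    band.validate_for(fs)
    freqs = np.fft.fftfreq(n_fft, d=1.0 / fs)
    return ((np.abs(freqs) >= band.f_lo) & (np.abs(freqs) <= band.f_hi)).astype(float)


def _check_pair(y: Signal1D, yhat: Signal1D) -> None:
    if len(y) != len(yhat):
        raise ValueError(f"length mismatch: {len(y)} vs {len(yhat)}")
    if y.fs != yhat.fs:
        raise ValueError(f"sampling-rate mismatch: {y.fs} vs {yhat.fs}")


def _centered_std(v: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    c = v - v.mean()
    sigma = float(np.sqrt(np.mean(c * c)))
    if sigma == 0.0:
        raise ValueError(f"degenerate (constant) {what} signal: zero variance")
    return c, sigma


def mcc(y: Signal1D, yhat: Signal1D, band: BandpassSpec = None) -> MccComponents:
    """Band-limited, lag-maximized, variance-normalized cross-correlation.

    Parameters
    ----------
    y : Signal1D
        Reference (ground-truth) signal; also defines ``cpr``.
    yhat : Signal1D
        Predicted signal. Same length and sampling rate as ``y``.
    band : BandpassSpec
        Passband; defaults to the 40–180 bpm heart-rate band.
    """
    from .signal import HR_BAND

    if band is None:
        band = HR_BAND
    _check_pair(y, yhat)
    band.validate_for(y.fs)

    n = len(y)
    yc, sigma_y = _centered_std(y.values, "reference")
    hc, sigma_h = _centered_std(yhat.values, "predicted")

    mask = bandpass_mask(n, y.fs, band)
    spec_y = np.fft.fft(yc)
    yb = np.fft.ifft(mask * spec_y).real
    hb = np.fft.ifft(mask * np.fft.fft(hc)).real

    m = _next_pow2(2 * n)
    cross = np.fft.ifft(np.fft.fft(yb, m) * np.conj(np.fft.fft(hb, m)))
    assert np.max(np.abs(cross.imag)) <= 1e-9 * max(np.max(np.abs(cross.real)), 1e-30)
    cross = cross.real
    k_max = int(np.argmax(cross))
    c_max = float(cross[k_max])

    power = np.abs(spec_y) ** 2
    total = float(power.sum() - power[0])
    cpr = float((mask * power).sum() / total) if total > 0 else 0.0

    value = cpr * c_max / (n * sigma_y * sigma_h)
    return MccComponents(
        cross_corr=cross,
        c_max=c_max,
        lag_max=k_max,
        sigma_y=sigma_y,
        sigma_yhat=sigma_h,
        cpr=cpr,
        mcc=value,
    )


def mcc_with_grad(
    y: Signal1D, yhat: Signal1D, band: BandpassSpec = None
) -> tuple[MccComponents, np.ndarray]:
    """MCC plus its analytic gradient with respect to ``yhat.values``.

    The lag attaining the maximum is treated as locally constant (the usual
    subgradient of a max), ``cpr`` and ``sigma_y`` depend on the reference
    only, and the chain rule runs through the mean-centering and the
    1/sigma_yhat normalization.
    """
    from .signal import HR_BAND

    if band is None:
        band = HR_BAND
    comp = mcc(y, yhat, band)
    n = len(y)
    yc = y.values - y.values.mean()
    hc = yhat.values - yhat.values.mean()
    mask = bandpass_mask(n, y.fs, band)
    yb = np.fft.ifft(mask * np.fft.fft(yc)).real
    m = _next_pow2(2 * n)

    # c_max is linear in the band-limited prediction hb: its coefficient at
    # sample j is the padded reference rolled by the winning lag. Chain back
    # through the (self-adjoint) native-grid bandpass filter.
    ybp = np.concatenate([yb, np.zeros(m - n)])
    coeff = np.roll(ybp, -comp.lag_max)[:n]
    g = np.fft.ifft(mask * np.fft.fft(coeff)).real

    scale = comp.cpr / (n * comp.sigma_y)
    grad_c = scale * (
        g / comp.sigma_yhat
        - comp.c_max * hc / (n * comp.sigma_yhat**3)
    )
    grad = grad_c - grad_c.mean()
    return comp, grad


def neg_pcc(y: Signal1D, yhat: Signal1D) -> float:
    """Negative Pearson correlation of the two signals."""
    value, _ = neg_pcc_with_grad(y, yhat)
    return value


def neg_pcc_with_grad(y: Signal1D, yhat: Signal1D) -> tuple[float, np.ndarray]:
    _check_pair(y, yhat)
    n = len(y)
    yc, sigma_y = _centered_std(y.values, "reference")
    hc, sigma_h = _centered_std(yhat.values, "predicted")
    cov = float(np.mean(yc * hc))
    rho = cov / (sigma_y * sigma_h)
    # d(-rho)/d hc, then re-center for the mean-subtraction chain rule.
    grad_c = -(yc / (n * sigma_y * sigma_h) - rho * hc / (n * sigma_h**2))
    grad = grad_c - grad_c.mean()
    return -rho, grad


def mse_with_grad(y: Signal1D, yhat: Signal1D) -> tuple[float, np.ndarray]:
    _check_pair(y, yhat)
    diff = yhat.values - y.values
    return float(np.mean(diff * diff)), 2.0 * diff / len(y)


def loss_value(kind: str, y: Signal1D, yhat: Signal1D, band: BandpassSpec = None) -> float:
    """Scalar training loss of the requested kind (to be minimized).

    ``"mse"``: mean squared difference. ``"negpcc"``: negative Pearson
    correlation. ``"negmcc"``: −MCC (minimizing it maximizes the band-limited
    correlation). ``"mcc"``: +MCC, exposed so the sign ablation of the loss
    study can be reproduced.
    """
    value, _ = loss_value_with_grad(kind, y, yhat, band)
    return value


def loss_value_with_grad(
    kind: str, y: Signal1D, yhat: Signal1D, band: BandpassSpec = None
) -> tuple[float, np.ndarray]:
    kind = kind.lower()
    if kind == "mse":
        return mse_with_grad(y, yhat)
    if kind == "negpcc":
        return neg_pcc_with_grad(y, yhat)
    if kind == "mcc":
        comp, grad = mcc_with_grad(y, yhat, band)
        return comp.mcc, grad
    if kind == "negmcc":
        comp, grad = mcc_with_grad(y, yhat, band)
        return -comp.mcc, -grad
    raise ValueError(f"unknown loss kind {kind!r}; expected one of {LOSS_KINDS}")
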