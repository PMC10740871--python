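"""Cost-function selection of channel widths from sweep results.

The sweep trains the network at channel widths alpha in {1, 2, 4, ..., 64}
and records the mean heart-rate RMSE eps(alpha) and the exact parameter
count P(alpha). The selected width minimizes

    cost(alpha) = eps(alpha) + lambda * P(alpha),   lambda = sigma_eps / sigma_P,

where the sigmas are standard deviations across the sweep — the lambda that
gives both addends equal spread, so neither scale dominates. The protocol is
sequential: the encoder axis is swept with the decoder at its baseline
width, then the decoder axis with the encoder fixed at its selected width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import ChannelConfig, PRESETS
from .network import count_parameters

__all__ = ["SweepPoint", "CostResult", "compute_cost", "sweep_channels",
           "sequential_sweep"]


@dataclass(frozen=True)
class SweepPoint:
    alpha: int
    error: float       # mean HR RMSE (bpm) over repeats
    error_std: float   # bpm
    params: int

    def __post_init__(self) -> None:
        if self.params <= 0:
            raise ValueError("params must be > 0")
        if self.error < 0:
            raise ValueError("error must be >= 0")


@dataclass(frozen=True)
class CostResult:
    lam: float
    costs: dict[int, float]
    alpha_star: int

    def to_dataframe(self, sweep: Sequence[SweepPoint] | None = None) -> pd.DataFrame:
        rows = []
        by_alpha = {p.alpha: p for p in (sweep or [])}
        for alpha, cost in sorted(self.costs.items()):
            row = {"alpha": alpha, "cost": cost, "selected": alpha == self.alpha_star}
            if alpha in by_alpha:
                p = by_alpha[alpha]
                row.update(error=p.error, error_std=p.error_std, params=p.params)
            rows.append(row)
        return pd.DataFrame(rows)


def compute_cost(sweep: Sequence[SweepPoint]) -> CostResult:
    """Evaluate the cost function over a sweep and pick the best width.

    Cost ties (within 1e-9 relative) break toward the smaller parameter
    count — a free efficiency win when the error is indistinguishable.
    """
    if len(sweep) < 2:
        raise ValueError("need at least 2 sweep points")
    errors = np.array([p.error for p in sweep], dtype=float)
    params = np.array([p.params for p in sweep], dtype=float)
    sigma_p = params.std()
    if sigma_p == 0:
        raise ValueError("all sweep points have identical parameter counts; "
                         "lambda is undefined")
    lam = float(errors.std() / sigma_p)
    costs = errors + lam * params
    c_min = costs.min()
    tol = 1e-9 * max(1.0, abs(c_min))
    tied = [p for p, c in zip(sweep, costs) if c <= c_min + tol]
    alpha_star = min(tied, key=lambda p: p.params).alpha
    return CostResult(
        lam=lam,
        costs={p.alpha: float(c) for p, c in zip(sweep, costs)},
        alpha_star=alpha_star,
    )


def sweep_channels(
    axis: str,
    widths: Sequence[int],
    trainer: Callable[[ChannelConfig, int], float],
    repeats: int = 10,
    base_config: ChannelConfig | None = None,
    seed: int = 0,
) -> list[SweepPoint]:
    """Sweep one width axis, training ``repeats`` times per width.

    Parameters
    ----------
    axis : "encoder" or "decoder"
        Encoder sweeps set the stem and all encoder blocks to alpha;
        decoder sweeps set both decoder layers to alpha.
    trainer : callable (ChannelConfig, seed) -> float
        Trains one network and returns its test heart-rate RMSE in bpm.
        A failed training is recorded as a NaN-error point, not fatal.
    """
    if axis not in ("encoder", "decoder"):
        raise ValueError("axis must be 'encoder' or 'decoder'")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    base = base_config or PRESETS["baseline"]
    points = []
    for alpha in widths:
        config = (base.with_encoder_width(alpha) if axis == "encoder"
                  else base.with_decoder_width(alpha))
        errors = []
        for r in range(repeats):
            try:
                errors.append(float(trainer(config, seed + 1000 * r)))
            except Exception:  # noqa: BLE001 - sweep continues past failures
                continue
        if errors:
            mean = float(np.mean(errors))
            std = float(np.std(errors, ddof=1)) if len(errors) > 1 else 0.0
        else:
            mean, std = float("nan"), float("nan")
        points.append(SweepPoint(alpha=int(alpha), error=mean, error_std=std,
                                 params=count_parameters(config)))
    return points


def sequential_sweep(
    encoder_widths: Sequence[int],
    decoder_widths: Sequence[int],
    trainer: Callable[[ChannelConfig, int], float],
    repeats: int = 10,
    seed: int = 0,
) -> tuple[list[SweepPoint], CostResult, list[SweepPoint], CostResult, ChannelConfig]:
    """Encoder sweep at baseline decoder, then decoder sweep at the winner."""
    enc_points = sweep_channels("encoder", encoder_widths, trainer, repeats,
                                seed=seed)
    enc_result = compute_cost([p for p in enc_points if np.isfinite(p.error)])
    mid = PRESETS["baseline"].with_encoder_width(enc_result.alpha_star)
    dec_points = sweep_channels("decoder", decoder_widths, trainer, repeats,
                                base_config=mid, seed=seed + 1)
    dec_result = compute_cost([p for p in dec_points if np.isfinite(p.error)])
    final = mid.with_decoder_width(dec_result.alpha_star)
    return enc_points, enc_result, dec_points, dec_result, final


def sweep_to_csv(points: Sequence[SweepPoint], result: CostResult, path) -> None:
    result.to_dataframe(points).to_csv(path, index=False)
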