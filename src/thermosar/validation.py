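"""Model-vs-measurement agreement metrics.

Simulated surface-temperature curves are resampled at the measurement
times (10-minute grid) and compared with the measured trial means using
RMSE, MAE, maximum absolute error and the Pearson correlation
coefficient, reported in the published-table layout together with the
peak temperature rise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationMetrics",
    "rmse",
    "mae",
    "maxae",
    "pearson_r",
    "validate_model",
]


def _paired(measured, predicted, min_len: int = 1):
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < min_len:
        raise ValueError(f"need at least {min_len} points")
    return y, yhat


def rmse(measured, predicted) -> float:
    """Root mean square error between paired series."""
    y, yhat = _paired(measured, predicted)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(measured, predicted) -> float:
    """Mean absolute error between paired series."""
    y, yhat = _paired(measured, predicted)
    return float(np.mean(np.abs(y - yhat)))


def maxae(measured, predicted) -> float:
    """Maximum absolute error between paired series."""
    y, yhat = _paired(measured, predicted)
    return float(np.max(np.abs(y - yhat)))


def pearson_r(measured, predicted) -> float:
    """Product-moment correlation; errors out on constant input rather
    than silently returning 0."""
    y, yhat = _paired(measured, predicted, min_len=2)
    if np.std(y) == 0 or np.std(yhat) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(y, yhat)[0, 1])


@dataclass(frozen=True)
class ValidationMetrics:
    """Agreement metrics between simulated and measured rise curves."""

    rmse: float
    mae: float
    maxae: float
    pearson_r: float
    n_points: int
    peak_delta_t: float           # max measured mean rise, K
    peak_delta_t_sd: float | None = None

    def __post_init__(self) -> None:
        assert self.rmse >= self.mae >= 0.0 or np.isclose(self.rmse, self.mae)
        assert self.maxae >= self.rmse or np.isclose(self.maxae, self.rmse)

    def to_frame(self) -> pd.DataFrame:
        """Two-decimal display table in the published layout."""
        rows = [("RMSE (K)", round(self.rmse, 2)),
                ("MAE (K)", round(self.mae, 2)),
                ("MaxAE (K)", round(self.maxae, 2)),
                ("r", round(self.pearson_r, 2)),
                ("Peak dT (K)", round(self.peak_delta_t, 2))]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def to_json(self) -> str:
        return json.dumps({
            "rmse_K": self.rmse, "mae_K": self.mae, "maxae_K": self.maxae,
            "pearson_r": self.pearson_r, "n_points": self.n_points,
            "peak_delta_t_K": self.peak_delta_t,
            "peak_delta_t_sd_K": self.peak_delta_t_sd,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ValidationMetrics":
        d = json.loads(text)
        return cls(rmse=d["rmse_K"], mae=d["mae_K"], maxae=d["maxae_K"],
                   pearson_r=d["pearson_r"], n_points=d["n_points"],
                   peak_delta_t=d["peak_delta_t_K"],
                   peak_delta_t_sd=d.get("peak_delta_t_sd_K"))


def validate_model(sim_times, sim_values, meas_times, meas_values,
                   meas_sd=None, include_baseline: bool = True) -> ValidationMetrics:
    """Resample a simulated curve at the measurement times and score it.

    Parameters
    ----------
    sim_times, sim_values : array_like
        Simulated rise curve; must cover the measured time span.
    meas_times, meas_values : array_like
        Measured (aggregated) rise means.
    meas_sd : array_like, optional
        Per-time SDs, used only to report the SD at the peak.
    include_baseline : bool
        Whether the t = 0 point (exactly zero by construction on both
        sides) enters the metrics.  Included by default.

    Raises
    ------
    ValueError
        If the simulated curve does not cover the measured span.
    """
    st = np.asarray(sim_times, dtype=float)
    sv = np.asarray(sim_values, dtype=float)
    mt = np.asarray(meas_times, dtype=float)
    mv = np.asarray(meas_values, dtype=float)
    if mt.min() < st.min() - 1e-9 or mt.max() > st.max() + 1e-9:
        raise ValueError("simulated curve does not cover the measured time span")
    resampled = np.interp(mt, st, sv)
    if not include_baseline:
        keep = mt > mt.min()
        mt_k, mv_k, rs_k = mt[keep], mv[keep], resampled[keep]
    else:
        mt_k, mv_k, rs_k = mt, mv, resampled
    i_peak = int(np.argmax(mv))
    sd_peak = None if meas_sd is None else float(np.asarray(meas_sd)[i_peak])
    return ValidationMetrics(
        rmse=rmse(mv_k, rs_k), mae=mae(mv_k, rs_k), maxae=maxae(mv_k, rs_k),
        pearson_r=pearson_r(mv_k, rs_k), n_points=len(mt_k),
        peak_delta_t=float(mv[i_peak]), peak_delta_t_sd=sd_peak)
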