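"""Published measurement summaries of the implanted-tibia heating study.

These are the study's printed repeated-trial summaries (mean +/- SD over
n = 10 trials, 10-minute sampling at 10 kHz excitation) and its reported
validation metrics.  They serve as *inputs* for worked examples and
stabilization/peak analyses; they are not used as fit targets anywhere in
the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "measured_series",
    "REPORTED_VALIDATION",
]

_TIME_MIN = np.arange(0, 61, 10)

# 0.75 A RMS drive: implant vs non-implant surface temperature rise (K)
_SERIES_075 = {
    "implant_mean": [0.00, 0.37, 0.45, 0.45, 0.40, 0.37, 0.37],
    "implant_sd": [0.00, 0.05, 0.08, 0.08, 0.12, 0.13, 0.05],
    "nonimplant_mean": [0.00, -0.15, -0.10, 0.00, -0.10, -0.10, 0.08],
    "nonimplant_sd": [0.00, 0.02, 0.03, 0.02, 0.03, 0.03, 0.02],
}

# 0.1 A RMS drive
_SERIES_01 = {
    "implant_mean": [0.00, 0.05, 0.07, 0.02, 0.00, 0.05, 0.03],
    "implant_sd": [0.00, 0.08, 0.10, 0.12, 0.11, 0.10, 0.08],
    "nonimplant_mean": [0.00, 0.00, 0.02, 0.02, 0.00, 0.00, -0.03],
    "nonimplant_sd": [0.00, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02],
}


def measured_series(current: str = "0.75A") -> pd.DataFrame:
    """Published mean +/- SD temperature-rise series for one drive level.

    Parameters
    ----------
    current : {"0.75A", "0.1A"}

    Returns
    -------
    pandas.DataFrame
        Columns: time_min, time_s, implant_mean, implant_sd,
        nonimplant_mean, nonimplant_sd (temperatures in K).
    """
    try:
        data = {"0.75A": _SERIES_075, "0.1A": _SERIES_01}[current]
    except KeyError:
        raise KeyError(f"unknown drive level {current!r}; "
                       "options: '0.75A', '0.1A'") from None
    return pd.DataFrame({"time_min": _TIME_MIN,
                         "time_s": _TIME_MIN * 60.0, **data})


#: Validation metrics as reported by the study (display precision).  Not
#: reproducible from public data (the underlying simulated series was not
#: published); kept for context only.
REPORTED_VALIDATION = {
    "implant": {"rmse_K": 0.11, "mae_K": 0.08, "maxae_K": 0.18, "r": 0.98,
                "peak_dt_K": (0.45, 0.08)},
    "nonimplant": {"rmse_K": 0.09, "mae_K": 0.07, "maxae_K": 0.15, "r": 0.93,
                   "peak_dt_K": (0.05, 0.02)},
}
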