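"""Synthetic repeated-trial infrared-thermography datasets.

Emulates the measurement structure of the phantom heating experiments:
surface temperature read at 10-minute intervals over 60 minutes, n = 10
repeated trials, an IR camera with ~0.05 K thermal noise and a 0.1 K
display resolution, a slowly varying ambient drift shared by all samples
in the scene, and a co-located non-exposed reference sample whose series
is subtracted to correct for that drift.  Every trial is reported as a
temperature *change*: the (noisy, quantized) baseline reading at t = 0 is
subtracted, so each trial starts at exactly zero.

The underlying true response is the first-order lumped curve

    dT(t) = (P / hA) (1 - exp(-hA t / (m c))),

degenerating to the linear law ``P t / (m c)`` when the loss term hA is
zero.  The generator stores the noiseless truth and the drift realization
alongside the measured channels so downstream estimators can be scored
against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .bioheat import solve_lumped

__all__ = [
    "CameraModel",
    "TrialSet",
    "true_response",
    "simulate_trials",
    "environmental_correction",
    "aggregate_trials",
    "generate_preset",
    "PRESETS",
    "quantize",
]

#: Default measurement grid: readings at the end of each 10-minute
#: interval over a 60-minute exposure.
DEFAULT_TIMES_S = np.arange(0.0, 3601.0, 600.0)


@dataclass(frozen=True)
class CameraModel:
    """IR camera as seen by the analysis: noise, readout quantization.

    ``noise_sd`` models the stated thermal sensitivity (Gaussian, K);
    ``display_resolution`` the readout step (K).  They are distinct
    effects: sub-resolution noise dithers the quantizer.
    """

    noise_sd: float = 0.05
    display_resolution: float = 0.1
    sampling_interval: float = 600.0
    emissivity_bias: float = 0.0
    noise_kind: str = "gaussian"     # or "student_t" (df=3, heavy-tailed)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.display_resolution <= 0:
            raise ValueError("display_resolution must be positive")
        if self.noise_kind not in ("gaussian", "student_t"):
            raise ValueError("noise_kind must be 'gaussian' or 'student_t'")

    def draw_noise(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.noise_sd == 0:
            return np.zeros(shape)
        if self.noise_kind == "gaussian":
            return rng.normal(0.0, self.noise_sd, shape)
        # Student-t with df=3 scaled to the requested SD
        df = 3.0
        return rng.standard_t(df, shape) * self.noise_sd / np.sqrt(df / (df - 2))


def quantize(x, resolution: float) -> np.ndarray:
    """Round to the display resolution, half away from zero.

    A tiny relative nudge keeps decimal half-steps (0.15 at a 0.1 step)
    rounding up despite binary float representation.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) / resolution + 0.5 + 1e-9) * resolution


def true_response(p_abs: float, mass: float, heat_capacity: float,
                  loss_coefficient: float, times) -> np.ndarray:
    """Noiseless lumped temperature-rise curve at the given times."""
    return solve_lumped(mass, heat_capacity, p_abs, loss_coefficient,
                        times=np.asarray(times, dtype=float)).delta_t


@dataclass
class TrialSet:
    """Repeated-trial measurement set with its generating ground truth."""

    sample_id: str
    times: np.ndarray                 # (nt,), s
    exposed: np.ndarray               # (n_trials, nt) quantized dT, K
    reference: np.ndarray             # (n_trials, nt) quantized dT, K
    exposed_raw: np.ndarray           # pre-quantization dT
    reference_raw: np.ndarray
    truth: np.ndarray                 # (nt,) noiseless exposed dT
    drift_truth: np.ndarray           # (n_trials, nt) drift realizations
    seed: int
    camera: CameraModel
    truth_params: dict = dc_field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.exposed.shape[0]

    def corrected(self) -> np.ndarray:
        """Exposed-channel trials after environmental correction."""
        return environmental_correction(self.exposed, self.reference,
                                        self.times, self.times)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sample_id, trial, time_s, channel, delta_t_K."""
        rows = []
        for channel, data in (("exposed", self.exposed),
                              ("reference", self.reference)):
            for trial in range(self.n_trials):
                for t, v in zip(self.times, data[trial]):
                    rows.append((self.sample_id, trial, float(t), channel,
                                 float(v)))
        return pd.DataFrame(rows, columns=["sample_id", "trial", "time_s",
                                           "channel", "delta_t_K"])

    def sidecar(self) -> str:
        """JSON metadata with the generating truth, for test oracles."""
        return json.dumps({
            "sample_id": self.sample_id, "seed": self.seed,
            "truth_params": self.truth_params,
            "camera": {"noise_sd": self.camera.noise_sd,
                       "display_resolution": self.camera.display_resolution,
                       "sampling_interval": self.camera.sampling_interval},
            "times_s": self.times.tolist(),
            "truth_delta_t_K": self.truth.tolist(),
        }, indent=2)


def _drift(rng: np.random.Generator, n_trials: int, nt: int,
           step_sd: float, linear_per_step: float) -> np.ndarray:
    """Shared ambient drift per trial: Gaussian random walk + linear term."""
    steps = rng.normal(0.0, step_sd, (n_trials, nt)) if step_sd > 0 \
        else np.zeros((n_trials, nt))
    steps[:, 0] = 0.0
    walk = np.cumsum(steps, axis=1)
    return walk + linear_per_step * np.arange(nt)


def simulate_trials(truth, times, camera: CameraModel = CameraModel(),
                    drift_step_sd: float = 0.02,
                    drift_linear_per_step: float = 0.0,
                    n_trials: int = 10, seed: int = 0,
                    sample_id: str = "sample",
                    truth_params: dict | None = None) -> TrialSet:
    """Measure a truth curve through the camera model, repeatedly.

    Per trial, the exposed reading is
    ``quantize(truth + drift + noise) - quantize(truth(0) + drift(0) + noise(0))``
    so the reported change is exactly zero at t = 0; the reference channel
    sees the *same* drift realization but no heating (drift + noise only),
    which is what environmental correction exploits.  Identical seeds give
    bit-identical output.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    times = np.asarray(times, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if truth.shape != times.shape:
        raise ValueError("truth and times must have matching shapes")
    rng = np.random.default_rng(seed)
    nt = len(times)
    drift = _drift(rng, n_trials, nt, drift_step_sd, drift_linear_per_step)
    eps_exp = camera.draw_noise(rng, (n_trials, nt))
    eps_ref = camera.draw_noise(rng, (n_trials, nt))

    raw_exp = truth[None, :] + drift + eps_exp + camera.emissivity_bias
    raw_ref = drift + eps_ref + camera.emissivity_bias
    q = camera.display_resolution
    exp_reading = quantize(raw_exp, q)
    ref_reading = quantize(raw_ref, q)
    exposed = exp_reading - exp_reading[:, :1]
    reference = ref_reading - ref_reading[:, :1]
    exposed_raw = raw_exp - raw_exp[:, :1]
    reference_raw = raw_ref - raw_ref[:, :1]

    return TrialSet(sample_id=sample_id, times=times, exposed=exposed,
                    reference=reference, exposed_raw=exposed_raw,
                    reference_raw=reference_raw, truth=truth,
                    drift_truth=drift, seed=seed, camera=camera,
                    truth_params=dict(truth_params or {}))


def environmental_correction(exposed, reference,
                             exposed_times=None, reference_times=None):
    """Subtract the non-exposed reference channel, pointwise.

    Removes ambient drift shared between the exposed sample and the
    co-located reference.  Time axes, when given, must match exactly.
    """
    exposed = np.asarray(exposed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if exposed_times is not None and reference_times is not None:
        if not np.array_equal(np.asarray(exposed_times),
                              np.asarray(reference_times)):
            raise ValueError("exposed and reference time axes differ")
    if exposed.shape != reference.shape:
        raise ValueError("exposed and reference shapes differ")
    return exposed - reference


def aggregate_trials(trials: TrialSet, corrected: bool = True) -> pd.DataFrame:
    """Per-time mean and unbiased sample SD across trials.

    Returns the published-table layout: time_min, mean_K, sd_K.

    Raises
    ------
    ValueError
        If the set holds a single trial (sample SD undefined).
    """
    if trials.n_trials < 2:
        raise ValueError("sample SD requires at least 2 trials")
    data = trials.corrected() if corrected else trials.exposed
    return pd.DataFrame({
        "time_min": trials.times / 60.0,
        "mean_K": data.mean(axis=0),
        "sd_K": data.std(axis=0, ddof=1),
    })


# ---------------------------------------------------------------------------
# Presets reproducing the study conditions (0.75 A / 0.1 A drives, control)
# ---------------------------------------------------------------------------

def _implant_params(scale: float = 1.0) -> dict:
    """Lumped parameters for the steel implant under the 0.75 A drive.

    Calibrated to the published implant behavior: initial rise rate
    4.44e-3 K/s and plateau 0.45 K.  Mass 0.05 kg is a representative
    intramedullary-rod figure (only P/(m c) and P/hA are observable).
    Scaling the drive current by r scales the absorbed power by r^2.
    """
    mass, c = 0.05, 500.0
    p = mass * c * 4.44e-3 * scale          # W
    h_a = p / (0.45 * scale) if scale > 0 else 0.0
    return {"p_abs": p, "mass": mass, "heat_capacity": c,
            "loss_coefficient": h_a}


def _resin_params() -> dict:
    """Resin phantom: rise 5.55e-4 K/s (0.05 K over 90 s), plateau 0.05 K."""
    mass, c = 0.10, 1300.0
    p = mass * c * 5.55e-4
    return {"p_abs": p, "mass": mass, "heat_capacity": c,
            "loss_coefficient": p / 0.05}


PRESETS: dict[str, dict] = {
    # steel implant, 0.75 A RMS drive at 10 kHz
    "implant-0.75A": _implant_params(1.0),
    # resin phantom (no implant), 0.75 A
    "nonimplant-0.75A": _resin_params(),
    # steel implant at the reduced 0.1 A drive: power scales with I^2
    "implant-0.1A": _implant_params((0.1 / 0.75) ** 2),
    # no excitation: fluctuation-only control
    "control": {"p_abs": 0.0, "mass": 0.05, "heat_capacity": 500.0,
                "loss_coefficient": 0.0},
}


def generate_preset(name: str, seed: int = 0, n_trials: int = 10,
                    times=None, camera: CameraModel | None = None,
                    drift_step_sd: float = 0.02) -> TrialSet:
    """Generate a trial set for one of the study configurations."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    params = PRESETS[name]
    times = DEFAULT_TIMES_S if times is None else np.asarray(times, dtype=float)
    camera = camera or CameraModel()
    truth = true_response(params["p_abs"], params["mass"],
                          params["heat_capacity"],
                          params["loss_coefficient"], times)
    return simulate_trials(truth, times, camera=camera,
                           drift_step_sd=drift_step_sd, n_trials=n_trials,
                           seed=seed, sample_id=name, truth_params=params)
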