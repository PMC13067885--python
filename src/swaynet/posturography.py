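"""Center-of-pressure (COP) balance indices from force-platform trajectories.

A standing trial is a two-axis COP trajectory: medio-lateral (ML, x) and
anterior-posterior (AP, y) displacement in mm, sampled at the platform rate
(1 kHz typically, 30 s per trial). Trajectories are low-pass filtered and
seven indices are computed per trial:

* ``ML_RMS``, ``AP_RMS``, ``RMS`` — root-mean-square displacement about the
  trial mean, per axis and resultant (``RMS^2 = ML_RMS^2 + AP_RMS^2``).
* ``ML_V``, ``AP_V``, ``V`` — mean sway velocity: total path length per axis
  (or of the planar path) divided by trial duration.
* ``AREA`` — 95 % confidence-ellipse sway area of the (ML, AP) point cloud.

Per-condition values are the arithmetic mean over the (three) trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, fields

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CopTrial",
    "CopMetrics",
    "CHI2_Q95_2DF",
    "filter_cop",
    "cop_rms",
    "cop_velocity",
    "cop_sway_area",
    "cop_metrics",
    "aggregate_trials",
    "read_cop_csv",
    "write_cop_csv",
    "metrics_to_frame",
]

#: 0.95 quantile of the chi-square distribution with 2 degrees of freedom;
#: scales the sample covariance ellipse to a 95 % confidence ellipse.
CHI2_Q95_2DF = 5.991465


@dataclass(frozen=True)
class CopTrial:
    """One standing trial: ML (x) and AP (y) COP displacement in mm."""

    sampling_rate: float
    ml: np.ndarray
    ap: np.ndarray
    condition: str = "open"
    trial_index: int = 0
    participant_id: str = ""

    def __post_init__(self):
        ml = np.asarray(self.ml, dtype=float)
        ap = np.asarray(self.ap, dtype=float)
        object.__setattr__(self, "ml", ml)
        object.__setattr__(self, "ap", ap)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if ml.ndim != 1 or ap.ndim != 1 or ml.shape != ap.shape:
            raise ValueError("ml and ap must be 1-D series of equal length")
        if ml.size < 2:
            raise ValueError("a COP trial needs at least 2 samples")
        if not (np.isfinite(ml).all() and np.isfinite(ap).all()):
            raise ValueError("COP series must be finite")

    @property
    def n_samples(self) -> int:
        return self.ml.size


@dataclass(frozen=True)
class CopMetrics:
    """The seven balance indices of one trial (or a trial average)."""

    AREA: float  # mm^2
    V: float  # mm/s
    ML_V: float
    AP_V: float
    RMS: float  # mm
    ML_RMS: float
    AP_RMS: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def filter_cop(trial: CopTrial, cutoff_hz: float = 10.0, order: int = 4) -> CopTrial:
    """Zero-phase Butterworth low-pass smoothing of both axes.

    Applied forward-backward (``sosfiltfilt``), so there is no phase lag and
    the effective magnitude response is the squared filter response.
    """
    nyq = trial.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trial.sampling_rate, output="sos")
    ml = signal.sosfiltfilt(sos, trial.ml)
    ap = signal.sosfiltfilt(sos, trial.ap)
    return replace(trial, ml=ml, ap=ap)


def cop_rms(trial: CopTrial) -> tuple[float, float, float]:
    """(RMS, ML_RMS, AP_RMS) about the trial mean, in mm."""
    ml = trial.ml - trial.ml.mean()
    ap = trial.ap - trial.ap.mean()
    ml_rms = float(np.sqrt(np.mean(ml**2)))
    ap_rms = float(np.sqrt(np.mean(ap**2)))
    return float(np.hypot(ml_rms, ap_rms)), ml_rms, ap_rms


def cop_velocity(trial: CopTrial) -> tuple[float, float, float]:
    """(V, ML_V, AP_V) mean sway velocities in mm/s.

    Path lengths are divided by T = (n-1)/fs so a constant-speed trajectory
    yields its exact speed.
    """
    dml = np.diff(trial.ml)
    dap = np.diff(trial.ap)
    t_total = (trial.n_samples - 1) / trial.sampling_rate
    v = float(np.sum(np.hypot(dml, dap)) / t_total)
    ml_v = float(np.sum(np.abs(dml)) / t_total)
    ap_v = float(np.sum(np.abs(dap)) / t_total)
    return v, ml_v, ap_v


def cop_sway_area(trial: CopTrial) -> float:
    """95 % confidence-ellipse sway area in mm^2.

    ``AREA = pi * q * sqrt(det(S))`` with S the 2x2 sample covariance of the
    (ML, AP) cloud and q the 0.95 chi-square quantile at 2 df. Degenerate
    (rank-deficient) clouds return 0 with a warning.
    """
    pts = np.column_stack([trial.ml, trial.ap])
    if pts.shape[0] < 3:
        warnings.warn("fewer than 3 samples: sway area undefined, returning 0")
        return 0.0
    cov = np.cov(pts, rowvar=False, ddof=1)
    det = float(np.linalg.det(cov))
    if det <= 0 or not np.isfinite(det):
        if det < -1e-9:
            warnings.warn("numerically negative covariance determinant; returning 0")
        elif det <= 0:
            warnings.warn("degenerate (collinear/constant) COP cloud; sway area 0")
        return 0.0
    return float(np.pi * CHI2_Q95_2DF * np.sqrt(det))


def cop_metrics(trial: CopTrial, *, prefilter: bool = True,
                cutoff_hz: float = 10.0, order: int = 4) -> CopMetrics:
    """All seven indices of one trial; smoothing applied first by default."""
    if prefilter:
        trial = filter_cop(trial, cutoff_hz=cutoff_hz, order=order)
    rms, ml_rms, ap_rms = cop_rms(trial)
    v, ml_v, ap_v = cop_velocity(trial)
    return CopMetrics(AREA=cop_sway_area(trial), V=v, ML_V=ml_v, AP_V=ap_v,
                      RMS=rms, ML_RMS=ml_rms, AP_RMS=ap_rms)


def aggregate_trials(metrics: list[CopMetrics]) -> CopMetrics:
    """Field-wise arithmetic mean over a participant-condition's trials.

    Note the per-trial identity RMS^2 = ML_RMS^2 + AP_RMS^2 need not survive
    averaging.
    """
    if not metrics:
        raise ValueError("aggregate_trials requires a non-empty list")
    return CopMetrics(**{
        f.name: float(np.mean([getattr(m, f.name) for m in metrics]))
        for f in fields(CopMetrics)
    })


# ---------------------------------------------------------------------------
# I/O


def read_cop_csv(path, **trial_kwargs) -> CopTrial:
    """Read a trial CSV with columns time_s, ml_mm, ap_mm."""
    df = pd.read_csv(path)
    for col in ("time_s", "ml_mm", "ap_mm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    fs = float(1.0 / np.median(np.diff(t)))
    return CopTrial(sampling_rate=fs, ml=df["ml_mm"].to_numpy(float),
                    ap=df["ap_mm"].to_numpy(float), **trial_kwargs)


def write_cop_csv(trial: CopTrial, path) -> None:
    t = np.arange(trial.n_samples) / trial.sampling_rate
    pd.DataFrame({"time_s": t, "ml_mm": trial.ml, "ap_mm": trial.ap}).to_csv(
        path, index=False)


def metrics_to_frame(rows: dict[tuple, CopMetrics]) -> pd.DataFrame:
    """Tidy table from {(participant, group, condition): CopMetrics}."""
    recs = []
    for (pid, group, cond), m in rows.items():
        recs.append({"participant": pid, "group": group, "condition": cond,
                     **m.as_dict()})
    return pd.DataFrame(recs)
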