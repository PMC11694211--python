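"""Signal conditioning: filtering, differentiation, normalisation.

Turns a :class:`~snatchlab.io.RawTrial` into a :class:`TrialSignals` holding
the filtered barbell centre trajectory (AP, V), its derivatives, the summed
body-weight-normalised vertical ground reaction force, and the derived RFD
and power series on the force timebase.

Filtering is zero-phase (forward-backward Butterworth) so event timing is
not lagged; note the effective order of an order-``k`` design is ``2k``.
Derivatives use central differences (one-sided at the ends).  Acceleration
is the derivative of the derived velocity, which amplifies high-frequency
error — hence the low 4 Hz kinematic cutoff upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .io import PipelineConfig, RawTrial, StaticRecord, SubjectInfo

__all__ = [
    "G",
    "TrialSignals",
    "butter_lowpass",
    "barbell_center",
    "differentiate",
    "body_weight_from_static",
    "total_grf",
    "time_normalize",
    "normalize_trial",
]

#: Standard gravity used to convert weight to mass, m/s^2.
G = 9.81


def butter_lowpass(series: np.ndarray, fs: float, cutoff: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (applied forward and backward).

    Works column-wise on 2-D input.  DC gain is exactly 1; a sine at the
    cutoff frequency comes out with amplitude ~0.5 (-3 dB twice).
    """
    series = np.asarray(series, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"sampling rate {fs} Hz must exceed twice the cutoff {cutoff} Hz")
    minlen = 3 * (order + 1)
    if len(series) < minlen:
        raise ValueError(
            f"series of length {len(series)} is too short to filter; "
            f"need at least {minlen} samples"
        )
    sos = _signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, series, axis=0)


def barbell_center(marker_left: np.ndarray, marker_right: np.ndarray) -> np.ndarray:
    """Per-sample midpoint of the two bar-end markers, keeping (AP, V) only.

    Averaging the bar ends cancels artefacts of asymmetric bar motion.
    """
    if marker_left.shape != marker_right.shape:
        raise ValueError("marker series must have identical shapes")
    center = 0.5 * (np.asarray(marker_left, float) + np.asarray(marker_right, float))
    return center[:, [0, 2]]  # (AP, V) of the canonical (AP, ML, V) frame


def differentiate(series: np.ndarray, fs: float) -> np.ndarray:
    """Numerical time derivative: central differences, one-sided at the ends."""
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(series, 1.0 / fs, axis=0)


def body_weight_from_static(static: StaticRecord) -> tuple[float, float]:
    """Weight (N) and mass (kg) from a quiet-standing record.

    The mean of the summed vertical plate forces over the whole record; the
    plate split is irrelevant.
    """
    total_v = static.plate1[:, 2] + static.plate2[:, 2]
    weight = float(np.mean(total_v))
    if weight <= 0:
        raise ValueError(
            "static record has non-positive mean vertical force; "
            "check the axis map / sign convention"
        )
    return weight, weight / G


def total_grf(plate1: np.ndarray, plate2: np.ndarray) -> np.ndarray:
    """Per-sample vector sum of the two plates; returns the (n, 3) total."""
    if plate1.shape != plate2.shape:
        raise ValueError("plate series must have identical shapes")
    return np.asarray(plate1, float) + np.asarray(plate2, float)


def time_normalize(series: np.ndarray, start_idx: int, catch_idx: int,
                   n_points: int = 101) -> np.ndarray:
    """Linearly resample ``series[start:catch]`` onto ``n_points`` fractions.

    The first and last output samples equal the input at ``start_idx`` and
    ``catch_idx`` exactly.
    """
    if start_idx >= catch_idx:
        raise ValueError("start index must precede catch index")
    series = np.asarray(series, dtype=float)
    src = np.arange(start_idx, catch_idx + 1, dtype=float)
    tgt = np.linspace(start_idx, catch_idx, n_points)
    if series.ndim == 1:
        return np.interp(tgt, src, series[start_idx:catch_idx + 1])
    return np.column_stack(
        [np.interp(tgt, src, series[start_idx:catch_idx + 1, j])
         for j in range(series.shape[1])]
    )


@dataclass
class TrialSignals:
    """Conditioned signals for one trial.

    Kinematic arrays live on the camera timebase ``f_kin``; force-derived
    arrays on the plate timebase ``f_force``.  Positions are baseline
    subtracted (first sample = 0).  ``vgrf_bw`` is the summed vertical GRF
    in body-weight multiples; ``rfd`` its sample-to-sample slope in BW/s;
    ``power`` the product of total vertical force and (interpolated)
    vertical bar velocity, in kW.  ``norm_curves`` holds the 101-point
    height-/weight-normalised start-to-catch curves once events are known.
    """

    subject_id: str
    condition: str
    trial_index: int
    barbell_pos: np.ndarray     # (n, 2): AP, V in m, baseline subtracted
    barbell_vel: np.ndarray     # (n, 2) m/s
    barbell_acc: np.ndarray     # (n, 2) m/s^2
    f_kin: float
    vgrf_total: np.ndarray      # (m,) N, filtered vertical total
    vgrf_bw: np.ndarray         # (m,) body-weight multiples
    rfd: np.ndarray             # (m-1,) BW/s
    vvel_force: np.ndarray      # (m,) vertical bar velocity on force timebase
    power: np.ndarray           # (m,) kW, total force x bar velocity
    f_force: float
    body_weight: float          # N
    body_height: float          # m
    norm_curves: dict[str, np.ndarray] = field(default_factory=dict)

    def kin_to_force_idx(self, idx: int) -> int:
        j = int(round(idx * self.f_force / self.f_kin))
        return min(j, len(self.vgrf_bw) - 1)


def normalize_trial(
    raw: RawTrial,
    subject: SubjectInfo,
    body_weight: float | None = None,
    cfg: PipelineConfig | None = None,
) -> TrialSignals:
    """Run the full conditioning chain on one raw trial.

    Filter (4 Hz markers / 15 Hz forces, zero phase) -> bar centre ->
    baseline-subtract -> differentiate twice -> sum plates -> express vGRF
    in body-weight multiples -> RFD and power series.  ``body_weight`` in
    newtons overrides ``subject.body_mass * g`` (use the static record via
    :func:`body_weight_from_static` when available).

    The 101-point normalised curves need the phase events and are attached
    by :func:`snatchlab.features.extract_features`.
    """
    cfg = cfg or PipelineConfig()
    weight = body_weight if body_weight is not None else subject.body_mass * G

    left = butter_lowpass(raw.marker_left, raw.f_kin, cfg.cutoff_kin, cfg.filter_order)
    right = butter_lowpass(raw.marker_right, raw.f_kin, cfg.cutoff_kin, cfg.filter_order)
    pos = barbell_center(left, right)
    pos = pos - pos[0]  # baseline: all trajectories start at zero
    vel = differentiate(pos, raw.f_kin)
    acc = differentiate(vel, raw.f_kin)

    total = total_grf(raw.plate1, raw.plate2)[:, 2]
    total = butter_lowpass(total, raw.f_force, cfg.cutoff_force, cfg.filter_order)
    vgrf_bw = total / weight
    rfd = np.diff(vgrf_bw) / cfg.rfd_interval

    # vertical bar velocity resampled onto the force grid for the power series
    t_kin = np.arange(len(pos)) / raw.f_kin
    t_force = np.arange(len(total)) / raw.f_force
    vvel_force = np.interp(t_force, t_kin, vel[:, 1])
    power = total * vvel_force / 1000.0  # F * v in kW

    return TrialSignals(
        subject_id=raw.subject_id,
        condition=raw.condition,
        trial_index=raw.trial_index,
        barbell_pos=pos,
        barbell_vel=vel,
        barbell_acc=acc,
        f_kin=raw.f_kin,
        vgrf_total=total,
        vgrf_bw=vgrf_bw,
        rfd=rfd,
        vvel_force=vvel_force,
        power=power,
        f_force=raw.f_force,
        body_weight=weight,
        body_height=subject.body_height,
    )


def attach_norm_curves(signals: TrialSignals, start_idx: int, catch_idx: int,
                       cfg: PipelineConfig | None = None) -> None:
    """Compute the 101-point start-to-catch curves and store them in-place.

    Positions and velocities are height-normalised (divided by body height);
    vGRF is already in body-weight multiples.
    """
    cfg = cfg or PipelineConfig()
    n = cfg.n_time_points
    h = signals.body_height
    start_f = signals.kin_to_force_idx(start_idx)
    catch_f = signals.kin_to_force_idx(catch_idx)
    # trimmed trajectories are re-zeroed at the movement start
    pos = signals.barbell_pos - signals.barbell_pos[start_idx]
    signals.norm_curves = {
        "position": time_normalize(pos, start_idx, catch_idx, n) / h,
        "velocity": time_normalize(signals.barbell_vel, start_idx, catch_idx, n) / h,
        "vgrf": time_normalize(signals.vgrf_bw, start_f, catch_f, n),
    }
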