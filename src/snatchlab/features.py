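"""Phase segmentation and the 23 discrete snatch parameters.

Events
------
* ``start``     — first sample where vertical bar velocity reaches 0.01 m/s
  and stays there for a sustain window (rejects single-sample noise spikes).
* ``ymax``      — peak vertical bar position after the start.
* ``catch``     — first sample at which vertical velocity returns to >= 0
  after the negative-velocity phase that follows the peak height (the lifter
  has dropped under the bar and stabilised it).
* ``rearmost`` / ``foremost`` — anteroposterior extremes defining the pull
  (toward the lifter) and turnover (away) excursions.
* ``takeoff``   — optional flight onset: vGRF below 5% body weight sustained
  20 ms ("until the jump" windows end here).

Parameters
----------
Displacements are reported in centimetres, forces in body-weight multiples
(BW), RFD in BW/s and power in W/kg.  The identities
``VTR = Y_max - Y_catch``, ``DxV = X1 - X2``, ``DxL = X3 - X2`` and
``DxT = X3`` hold exactly by construction.  Power is the product of total
vertical force and bar velocity, reported in kW.

The sign convention makes the classic optimal bar path literal: AP is
positive toward the lifter, so a technically sound snatch shows the
positive-negative-positive (toward-away-toward) pattern in (X1, X2, X3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import PipelineConfig
from .preprocess import G, TrialSignals, attach_norm_curves

__all__ = [
    "PhaseEvents",
    "SnatchFeatures",
    "PathClassification",
    "detect_start",
    "detect_catch",
    "detect_takeoff",
    "horizontal_extremes",
    "kinematic_features",
    "kinetic_features",
    "classify_path",
    "subject_adherence",
    "extract_features",
]


class EventDetectionError(RuntimeError):
    """A required movement event could not be located in the signals."""


@dataclass
class PhaseEvents:
    """Sample indices of the movement events.

    All indices are on the kinematic timebase except ``takeoff_idx`` (force
    timebase), which is ``None`` when no flight phase is detected.
    """

    start_idx: int
    rearmost_idx: int
    ymax_idx: int
    foremost_idx: int
    catch_idx: int
    takeoff_idx: int | None = None

    def __post_init__(self) -> None:
        if not self.start_idx < self.ymax_idx < self.catch_idx:
            raise ValueError("event order must be start < ymax < catch")
        if not self.start_idx <= self.rearmost_idx <= self.ymax_idx:
            raise ValueError("rearmost point must lie in [start, ymax]")
        if not self.rearmost_idx <= self.foremost_idx <= self.catch_idx:
            raise ValueError("foremost point must lie in [rearmost, catch]")


def detect_start(vvel: np.ndarray, fs: float,
                 threshold: float = 0.01, sustain: float = 0.04) -> int:
    """First index where vertical velocity >= ``threshold`` and stays there.

    The sustain window (default 40 ms) rejects single-sample noise spikes.
    """
    vvel = np.asarray(vvel, float)
    w = max(1, int(round(sustain * fs)))
    above = vvel >= threshold
    for i in np.flatnonzero(above):
        if above[i:i + w].all() and i + w <= len(vvel):
            return int(i)
    raise EventDetectionError(
        f"no movement detected: vertical velocity never sustains >= {threshold} m/s"
    )


def detect_catch(vpos: np.ndarray, vvel: np.ndarray, start_idx: int,
                 descent_threshold: float = 0.05) -> tuple[int, int]:
    """Peak-height index and catch index.

    The catch is the first instant of non-negative vertical velocity after
    the negative-velocity (drop-under) phase that follows peak bar height.
    The drop-under phase is recognised when the bar genuinely descends
    (velocity below ``-descent_threshold`` m/s), so sub-ripple sign flips
    right at the peak are not mistaken for a catch.
    """
    vpos = np.asarray(vpos, float)
    vvel = np.asarray(vvel, float)
    ymax_idx = start_idx + int(np.argmax(vpos[start_idx:]))
    after = vvel[ymax_idx:]
    neg = np.flatnonzero(after < -abs(descent_threshold))
    if len(neg) == 0:
        raise EventDetectionError("no catch detected: no descent after peak height")
    first_neg = neg[0]
    nonneg = np.flatnonzero(after[first_neg:] >= 0)
    if len(nonneg) == 0:
        raise EventDetectionError("no catch detected: velocity never returns to zero")
    catch_idx = ymax_idx + first_neg + int(nonneg[0])
    return int(ymax_idx), int(catch_idx)


def detect_takeoff(vgrf_bw: np.ndarray, fs: float, start_idx: int = 0,
                   threshold: float = 0.05, sustain: float = 0.02) -> int | None:
    """Flight onset: first force sample below ``threshold`` BW sustained.

    Returns ``None`` when no flight phase exists (a valid outcome: the
    until-jump features then fall back to the whole movement).
    """
    vgrf_bw = np.asarray(vgrf_bw, float)
    w = max(1, int(round(sustain * fs)))
    below = vgrf_bw < threshold
    below[:start_idx] = False
    for i in np.flatnonzero(below):
        if i + w <= len(vgrf_bw) and below[i:i + w].all():
            return int(i)
    return None


#: Minimum prominence (m) for an AP stationary point to count as a bar-path
#: landmark; filters sub-millimetre ripple left after filtering.
_AP_PROMINENCE = 0.001


def _local_extrema(x: np.ndarray, lo: int, hi: int,
                   prominence: float = _AP_PROMINENCE) -> np.ndarray:
    """Interior local extrema of ``x`` on the open index range (lo, hi)."""
    from scipy.signal import find_peaks

    seg = x[lo:hi + 1]
    if len(seg) < 3:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(seg, prominence=prominence)
    troughs, _ = find_peaks(-seg, prominence=prominence)
    idx = np.sort(np.concatenate([peaks, troughs])) + lo
    return idx[(idx > lo) & (idx < hi)]


def horizontal_extremes(
    appos: np.ndarray, start_idx: int, ymax_idx: int, catch_idx: int
) -> tuple[int, int, float, float, float]:
    """AP landmark indices and the signed displacements X1, X2, X3 in cm.

    The rule is odd-symmetric (negating the AP axis negates all three
    displacements):

    * ``rearmost`` — the last stationary point of the AP path during the
      pull, on ``(start, ymax]``.  In a sound snatch this is the
      toward-lifter excursion (X1 > 0); a bar that only drifts away still
      has its recovery point here and yields a negative X1, as commonly
      seen in beginners.  If the pull path is monotone there is no
      stationary point and X1 degenerates to the first post-start sample
      (near zero by baseline subtraction).
    * ``foremost`` — the largest-magnitude stationary point between the
      rearmost point and the catch (the away excursion of the turnover,
      X2 < 0 in practice); falls back to the most-away sample when the
      turnover has no stationary point.
    * ``X3`` — AP position at the catch.
    """
    appos = np.asarray(appos, float)
    if ymax_idx <= start_idx or catch_idx <= ymax_idx:
        raise ValueError("need start < ymax < catch to search AP extremes")
    pull_ext = _local_extrema(appos, start_idx, ymax_idx + 1)
    pull_ext = pull_ext[pull_ext <= ymax_idx]
    rearmost_idx = int(pull_ext[-1]) if len(pull_ext) else start_idx + 1
    turn_ext = _local_extrema(appos, rearmost_idx, catch_idx)
    if len(turn_ext):
        foremost_idx = int(turn_ext[np.argmax(np.abs(appos[turn_ext]))])
    else:
        turn = appos[rearmost_idx:catch_idx + 1]
        foremost_idx = rearmost_idx + int(np.argmin(turn))
    x1 = 100.0 * appos[rearmost_idx]
    x2 = 100.0 * appos[foremost_idx]
    x3 = 100.0 * appos[catch_idx]
    return rearmost_idx, foremost_idx, x1, x2, x3


@dataclass
class SnatchFeatures:
    """The 12 kinematic + 11 kinetic discrete parameters for one trial."""

    subject_id: str
    condition: str
    trial_index: int
    # kinematics
    mvt_duration: float   # s, start -> catch
    v_avg: float          # m/s
    v_max: float          # m/s
    acc_max: float        # m/s^2
    y_max: float          # cm
    y_catch: float        # cm
    vtr: float            # cm, = y_max - y_catch
    x1: float             # cm, pull extreme toward the lifter
    x2: float             # cm, turnover extreme away from the lifter
    x3_dxt: float         # cm, net displacement at the catch
    dxl: float            # cm, loop: = x3 - x2
    dxv: float            # cm, = x1 - x2
    # kinetics
    vgrf_max: float       # BW
    vgrf_mean_all: float  # BW
    vgrf_mean_jump: float  # BW
    rfd_max_all: float    # BW/s
    rfd_max_jump: float   # BW/s
    rfd_mean_all: float   # BW/s
    rfd_mean_jump: float  # BW/s
    power_max_all: float  # kW
    power_max_jump: float  # kW
    power_mean_all: float  # kW
    power_mean_jump: float  # kW
    #: True when no flight was detected and the "until the jump" windows
    #: fell back to the whole movement.
    jump_window_is_whole_movement: bool = False

    _NAMES = {
        "V-avg": "v_avg", "V-max": "v_max", "Acc-max": "acc_max",
        "Y-max": "y_max", "Y-catch": "y_catch", "VTR": "vtr",
        "X1": "x1", "X2": "x2", "X3_DxT": "x3_dxt", "DxL": "dxl", "DxV": "dxv",
        "MvT_duration": "mvt_duration",
        "vGRF_max": "vgrf_max", "vGRF_mean_all": "vgrf_mean_all",
        "vGRF_mean_jump": "vgrf_mean_jump",
        "RFD_max_all": "rfd_max_all", "RFD_max_jump": "rfd_max_jump",
        "RFD_mean_all": "rfd_mean_all", "RFD_mean_jump": "rfd_mean_jump",
        "Power_max_all": "power_max_all", "Power_max_jump": "power_max_jump",
        "Power_mean_all": "power_mean_all", "Power_mean_jump": "power_mean_jump",
    }

    def to_row(self) -> dict[str, object]:
        """One feature-table row using the published column names."""
        row: dict[str, object] = {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "trial": self.trial_index,
        }
        row.update({name: getattr(self, attr) for name, attr in self._NAMES.items()})
        return row


def kinematic_features(
    signals: TrialSignals, events: PhaseEvents
) -> dict[str, float]:
    """Kinematic half of the parameter set (displacements in cm)."""
    s, c, ym = events.start_idx, events.catch_idx, events.ymax_idx
    # displacements are measured from the start *event* (the trimmed
    # trajectory is re-zeroed at its first sample)
    vpos = signals.barbell_pos[:, 1] - signals.barbell_pos[s, 1]
    appos = signals.barbell_pos[:, 0] - signals.barbell_pos[s, 0]
    vvel = signals.barbell_vel[:, 1]
    vacc = signals.barbell_acc[:, 1]
    _, _, x1, x2, x3 = horizontal_extremes(appos, s, ym, c)
    y_max = 100.0 * vpos[ym]
    y_catch = 100.0 * vpos[c]
    return {
        "mvt_duration": (c - s) / signals.f_kin,
        "v_avg": float(np.mean(vvel[s:c + 1])),
        "v_max": float(np.max(vvel[s:c + 1])),
        "acc_max": float(np.max(vacc[s:c + 1])),
        "y_max": y_max,
        "y_catch": y_catch,
        "vtr": y_max - y_catch,
        "x1": x1,
        "x2": x2,
        "x3_dxt": x3,
        "dxl": x3 - x2,
        "dxv": x1 - x2,
    }


def kinetic_features(
    signals: TrialSignals, events: PhaseEvents
) -> dict[str, float]:
    """Kinetic half: vGRF (BW), RFD (BW/s) and power (kW) summaries.

    "All" windows span start to catch; "jump" windows span start to takeoff
    and fall back to the whole movement (flagged) when no flight exists.
    """
    start_f = signals.kin_to_force_idx(events.start_idx)
    catch_f = signals.kin_to_force_idx(events.catch_idx)
    takeoff = events.takeoff_idx
    no_flight = takeoff is None or takeoff <= start_f
    end_jump = catch_f if no_flight else int(takeoff)

    vgrf = signals.vgrf_bw
    rfd = signals.rfd
    power = signals.power

    def window(x: np.ndarray, a: int, b: int) -> np.ndarray:
        return x[a:max(b, a + 1) + 1]

    return {
        "vgrf_max": float(np.max(window(vgrf, start_f, catch_f))),
        "vgrf_mean_all": float(np.mean(window(vgrf, start_f, catch_f))),
        "vgrf_mean_jump": float(np.mean(window(vgrf, start_f, end_jump))),
        "rfd_max_all": float(np.max(window(rfd, start_f, catch_f - 1))),
        "rfd_max_jump": float(np.max(window(rfd, start_f, end_jump - 1))),
        "rfd_mean_all": float(np.mean(window(rfd, start_f, catch_f - 1))),
        "rfd_mean_jump": float(np.mean(window(rfd, start_f, end_jump - 1))),
        "power_max_all": float(np.max(window(power, start_f, catch_f))),
        "power_max_jump": float(np.max(window(power, start_f, end_jump))),
        "power_mean_all": float(np.mean(window(power, start_f, catch_f))),
        "power_mean_jump": float(np.mean(window(power, start_f, end_jump))),
        "jump_window_is_whole_movement": no_flight,
    }


@dataclass(frozen=True)
class PathClassification:
    """Sign pattern of (X1, X2, X3) and whether it matches the optimal path."""

    sign_pattern: tuple[int, int, int]
    is_optimal: bool


def classify_path(x1: float, x2: float, x3: float) -> PathClassification:
    """Classify a bar path against the optimal toward-away-toward pattern.

    Optimal iff X1 > 0, X2 < 0 and X3 > 0 (strict: an exactly zero
    displacement does not count as toward or away).
    """
    pattern = (int(np.sign(x1)), int(np.sign(x2)), int(np.sign(x3)))
    return PathClassification(
        sign_pattern=pattern,
        is_optimal=(x1 > 0) and (x2 < 0) and (x3 > 0),
    )


def subject_adherence(classifications: Sequence[PathClassification]) -> bool:
    """True iff every one of the subject's repetitions followed the optimal path."""
    if len(classifications) == 0:
        raise ValueError("need at least one classified trial")
    return all(c.is_optimal for c in classifications)


def extract_features(
    signals: TrialSignals, cfg: PipelineConfig | None = None
) -> tuple[PhaseEvents, SnatchFeatures]:
    """Segment one conditioned trial and compute all 23 parameters.

    Also attaches the 101-point normalised start-to-catch curves to
    ``signals.norm_curves``.
    """
    cfg = cfg or PipelineConfig()
    vpos = signals.barbell_pos[:, 1]
    vvel = signals.barbell_vel[:, 1]
    start = detect_start(vvel, signals.f_kin,
                         cfg.start_velocity_threshold, cfg.start_sustain)
    ymax, catch = detect_catch(vpos, vvel, start)
    rearmost, foremost, _, _, _ = horizontal_extremes(
        signals.barbell_pos[:, 0], start, ymax, catch)
    takeoff = detect_takeoff(signals.vgrf_bw, signals.f_force,
                             signals.kin_to_force_idx(start),
                             cfg.takeoff_force_threshold, cfg.takeoff_sustain)
    events = PhaseEvents(
        start_idx=start, rearmost_idx=rearmost, ymax_idx=ymax,
        foremost_idx=foremost, catch_idx=catch, takeoff_idx=takeoff,
    )
    kin = kinematic_features(signals, events)
    kinx = kinetic_features(signals, events)
    attach_norm_curves(signals, start, catch, cfg)
    feats = SnatchFeatures(
        subject_id=signals.subject_id,
        condition=signals.condition,
        trial_index=signals.trial_index,
        **kin, **kinx,
    )
    return events, feats
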