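"""Synthetic snatch trials with known ground truth.

The generator emulates the measurement setup the pipeline expects — two
bar-end markers at 250 Hz and two force plates at 1000 Hz — from a small
set of programmable trial parameters, so every pipeline stage can be tested
against exact ground truth without any recorded data.

Vertical bar path: a quintic smoothstep rise of amplitude ``y_max`` whose
peak slope is exactly the programmed ``v_max``, then a single smoothstep
descent to ``y_catch`` ending in a small dip-and-rebound whose minimum
marks the catch (a transversal velocity zero crossing, as in real lifts).
AP bar path: piecewise quintic smoothsteps between labelled landmarks, so
the programmed X1/X2/X3 are true stationary points of the path; trials
with a non-positive X1 get an early away-drift dip followed by a recovery
to X1, the pattern seen in beginners.  Both paths are emitted 4 Hz
band-limited (the generator's smoothness model of human bar motion), with
the landmark amplitudes re-anchored by a short fixed-point correction so
the programmed values are exact features of the emitted signal.  Ground
reaction force: a two-mass surrogate — (body+bar) weight plus a pull peak
reaching the programmed ``vgrf_max_bw``, an unweighting dip, an optional
zero-force flight window with ramps and a landing bump — split smoothly
between the two plates.  Gaussian sensor noise is added per channel;
everything is deterministic per seed.

The cohort generator layers a hierarchical model on top: per-subject random
effects with a configurable intraclass correlation across the four learning
conditions (default 0.5), per-condition mean shifts (default all zero — the
global null), and trial-to-trial noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .io import (
    CONDITIONS,
    RawTrial,
    StaticRecord,
    SubjectInfo,
    write_force_file,
    write_marker_file,
)
from .preprocess import G

__all__ = [
    "TrialParams",
    "TrialTruth",
    "CohortParams",
    "generate_trial",
    "generate_static",
    "generate_cohort",
    "draw_cohort_truth",
    "simulate_variable_tables",
    "write_trial",
]

_MIN_DESCENT = 0.28  # s, minimum drop-under (peak height -> catch) time


@dataclass
class TrialParams:
    """Ground truth for one synthetic trial.

    Displacements in cm (matching the reported parameter scale), velocity
    in m/s, masses in kg, heights in m, times in s, noise in mm / N.
    Defaults sit at realistic beginner magnitudes for a 20 kg power snatch.
    """

    y_max: float = 161.44       # cm, peak bar height above the start
    y_catch: float = 140.75     # cm, bar height at the catch
    x1: float = 0.31            # cm, pull landmark toward the lifter
    x2: float = -16.93          # cm, turnover landmark away from the lifter
    x3: float = 9.19            # cm, AP position at the catch
    v_max: float = 3.15         # m/s, peak vertical bar velocity
    duration: float = 1.32      # s, movement start -> catch
    body_mass: float = 75.0     # kg
    body_height: float = 1.78   # m
    barbell_mass: float = 20.0  # kg
    vgrf_max_bw: float = 2.55   # peak total vGRF in body-weight multiples
    flight: bool = True
    flight_onset: float | None = None    # s from movement onset; default 0.95*rise
    flight_duration: float = 0.12        # s
    lead_in: float = 0.8        # s of quiet stance before the movement
    tail: float = 0.6           # s after the catch
    noise_sd_pos: float = 1.0   # mm, per marker axis
    noise_sd_force: float = 5.0  # N, per plate channel
    f_kin: float = 250.0
    f_force: float = 1000.0
    bar_half_width: float = 0.6  # m, marker distance from bar centre
    marker_asym: float = 0.003   # m, antisymmetric marker offset (cancels in the mean)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0.5:
            raise ValueError("movement duration must exceed 0.5 s")
        if self.noise_sd_pos < 0 or self.noise_sd_force < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.v_max <= 0 or self.y_max <= 0:
            raise ValueError("v_max and y_max must be positive")

    @property
    def rise_time(self) -> float:
        """Duration of the ascent; fixed by y_max and v_max (peak slope 1.875/T)."""
        return 1.875 * (self.y_max / 100.0) / self.v_max

    @property
    def descent_time(self) -> float:
        """Drop-under time: whatever of the movement the rise leaves over."""
        return self.duration - self.rise_time


@dataclass
class TrialTruth:
    """Analytic ground truth of the generated trial, on the reported scales."""

    start_time: float           # s, first analytic vvel >= 0.01 m/s
    catch_time: float           # s
    takeoff_time: float | None  # s, flight onset
    duration: float             # s, start -> catch
    v_max: float                # m/s
    y_max: float                # cm
    y_catch: float              # cm
    vtr: float                  # cm
    x1: float                   # cm
    x2: float                   # cm
    x3: float                   # cm
    vgrf_max_bw: float          # BW


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u ** 2)


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """cos^2 bump of unit height, support [center - width/2, center + width/2]."""
    u = (t - center) / width
    out = np.where(np.abs(u) <= 0.5, np.cos(np.pi * u) ** 2, 0.0)
    return out


_CATCH_BOUNCE = 0.015   # m the bar dips below the settle height at the catch
_BOUNCE_WIDTH = 0.24    # s


def _band_limit(x: np.ndarray, fs: float, cutoff: float = 4.0) -> np.ndarray:
    """The generator's smoothness model: bar paths are ~4 Hz band-limited."""
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def _vertical_path(p: TrialParams, t: np.ndarray, t0: float,
                   amp_ymax: float, amp_ycatch: float) -> np.ndarray:
    """Rise to amp_ymax, then a single smooth descent settling just above
    amp_ycatch, with a small dip-and-rebound whose minimum is the catch.

    The descent spans the whole post-peak movement so its interior velocity
    is strictly negative (no flat pockets that sensor noise could flip)."""
    rise = p.rise_time
    t_catch = t0 + p.duration
    settle = amp_ycatch + _CATCH_BOUNCE
    y = amp_ymax * _smoothstep((t - t0) / rise)
    y -= (amp_ymax - settle) * _smoothstep(
        (t - t0 - rise) / max(p.descent_time, 1e-6))
    y -= _CATCH_BOUNCE * _bump(t, t_catch, _BOUNCE_WIDTH)
    return y


def _ap_path(p: TrialParams, t: np.ndarray, t0: float,
             a1: float, a2: float, a3: float) -> np.ndarray:
    """Piecewise quintic-smoothstep AP path through the landmark amplitudes."""
    rise = p.rise_time
    t_catch = t0 + p.duration
    tx1 = t0 + 0.50 * rise
    tx2 = t0 + rise + 0.15 * p.descent_time
    segs: list[tuple[float, float, float, float]] = []  # (ta, tb, a, b)
    if p.x1 <= 0:
        tdip = t0 + 0.22 * rise
        dip = a1 - 0.03
        segs += [(t0, tdip, 0.0, dip), (tdip, tx1, dip, a1)]
    else:
        segs += [(t0, tx1, 0.0, a1)]
    segs += [(tx1, tx2, a1, a2), (tx2, t_catch, a2, a3)]
    x = np.zeros_like(t)
    for ta, tb, a, b in segs:
        x = np.where(t < ta, x, a + (b - a) * _smoothstep((t - ta) / (tb - ta)))
    x = np.where(t >= t_catch, a3, x)
    return x


def _ap_landmark_windows(p: TrialParams, t0: float) -> dict[str, tuple[float, float]]:
    rise = p.rise_time
    t_catch = t0 + p.duration
    tx1 = t0 + 0.50 * rise
    tx2 = t0 + rise + 0.15 * p.descent_time
    return {
        "x1": (tx1 - 0.12, tx1 + 0.12),
        "x2": (tx2 - 0.10, min(tx2 + 0.15, t_catch - 0.02)),
        "x3": (t_catch - 0.01, t_catch + 0.05),
    }


def _anchored_paths(
    p: TrialParams, t: np.ndarray, t0: float, fs: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Band-limited vertical and AP paths whose landmarks hit the programmed
    values, via a short fixed-point correction of the knot amplitudes.

    Returns (vertical, ap, catch_time): the catch time is the bounce minimum
    of the emitted vertical path.
    """
    t_catch = t0 + p.duration
    ymax_target = p.y_max / 100.0
    ycatch_target = p.y_catch / 100.0
    x_target = np.array([p.x1, p.x2, p.x3]) / 100.0
    win = _ap_landmark_windows(p, t0)
    degenerate = ymax_target <= ycatch_target

    amp_y, amp_c = ymax_target, ycatch_target
    a = x_target.copy()
    vert = ap = None
    catch_t = t_catch
    for _ in range(3):
        vert = _band_limit(_vertical_path(p, t, t0, amp_y, amp_c), fs)
        ap = _band_limit(_ap_path(p, t, t0, *a), fs)
        if degenerate:
            break
        # measure landmarks as the analysis chain sees them: the pipeline
        # low-passes the emitted signal once more, so anchor to that view
        vert_m = _band_limit(vert, fs)
        ap_m = _band_limit(ap, fs)
        y_meas = float(np.max(vert_m))
        cwin = (t >= t_catch - 0.5 * _BOUNCE_WIDTH) & (t <= t_catch + 0.5 * _BOUNCE_WIDTH)
        i_catch = np.flatnonzero(cwin)[np.argmin(vert_m[cwin])]
        catch_t = float(t[i_catch])
        c_meas = float(vert_m[i_catch])
        meas = []
        for key, sign in (("x1", 1.0), ("x2", -1.0), ("x3", 0.0)):
            lo, hi = win[key]
            m = (t >= lo) & (t <= hi)
            if key == "x3":
                meas.append(float(ap_m[i_catch]))
            else:
                meas.append(float(sign * np.max(sign * ap_m[m])))
        amp_y += ymax_target - y_meas
        amp_c += ycatch_target - c_meas
        a += x_target - np.asarray(meas)
    return vert, ap, catch_t


def _force_profile(p: TrialParams, t: np.ndarray, t0: float,
                   t_catch: float) -> tuple[np.ndarray, float | None]:
    rise = p.rise_time
    w_tot = (p.body_mass + p.barbell_mass) * G
    bw = p.body_mass * G
    f_max = p.vgrf_max_bw * bw
    if f_max <= 1.1 * w_tot:
        raise ValueError(
            "vgrf_max_bw too small: programmed peak force must exceed the "
            "(body + bar) weight"
        )
    f = np.full_like(t, w_tot)
    f += (f_max - w_tot) * _bump(t, t0 + 0.40 * rise, 0.50 * rise)
    f -= 0.45 * w_tot * _bump(t, t0 + 0.78 * rise, 0.20 * rise)

    takeoff: float | None = None
    if p.flight:
        onset = p.flight_onset if p.flight_onset is not None else 0.95 * rise
        t_on = t0 + onset
        t_off = t_on + p.flight_duration
        if not (t0 < t_on < t_off <= t_catch):
            raise ValueError(
                f"inconsistent flight window [{t_on:.3f}, {t_off:.3f}] for a "
                f"movement on [{t0:.3f}, {t_catch:.3f}]"
            )
        mask = np.ones_like(t)
        # ramp lengths chosen so the 15 Hz-filtered force crosses the 5% BW
        # takeoff threshold at the programmed onset
        ramp_dn, ramp_up = 0.045, 0.015
        dn = (t > t_on - ramp_dn) & (t < t_on)
        mask[dn] = np.cos(0.5 * np.pi * (t[dn] - (t_on - ramp_dn)) / ramp_dn) ** 2
        mask[(t >= t_on) & (t < t_off)] = 0.0
        up = (t >= t_off) & (t < t_off + ramp_up)
        mask[up] = np.sin(0.5 * np.pi * (t[up] - t_off) / ramp_up) ** 2
        f = f * mask
        land_amp = min(0.55 * w_tot, 0.8 * (f_max - w_tot))
        f += land_amp * _bump(t, t_off + 0.045, 0.07)
        takeoff = t_on
    return f, takeoff


def generate_trial(
    p: TrialParams,
    subject_id: str = "S01",
    condition: str = "DL",
    trial_index: int = 1,
) -> tuple[RawTrial, TrialTruth]:
    """Synthesise one raw trial and its analytic ground truth."""
    if p.descent_time < _MIN_DESCENT:
        raise ValueError(
            f"duration {p.duration} s is too short: the rise to y_max at v_max "
            f"alone takes {p.rise_time:.3f} s and the drop-under needs "
            f"{_MIN_DESCENT:.2f} s more"
        )
    rng = np.random.default_rng(p.seed)
    t0 = p.lead_in
    t_catch_nominal = t0 + p.duration
    total_t = t_catch_nominal + p.tail

    t_kin = np.arange(0.0, total_t, 1.0 / p.f_kin)
    t_force = np.arange(0.0, total_t, 1.0 / p.f_force)

    # --- kinematics -------------------------------------------------------
    vert_rel, ap, catch_time = _anchored_paths(p, t_kin, t0, p.f_kin)
    vert = vert_rel + 0.45  # bar starts 0.45 m above ground
    center = np.column_stack([ap, np.zeros_like(ap), vert])
    asym = p.marker_asym * np.sin(2 * np.pi * 1.2 * t_kin)
    left = center + np.column_stack(
        [np.zeros_like(ap), -p.bar_half_width * np.ones_like(ap), asym])
    right = center + np.column_stack(
        [np.zeros_like(ap), p.bar_half_width * np.ones_like(ap), -asym])
    if p.noise_sd_pos > 0:
        sd = p.noise_sd_pos / 1000.0
        left = left + rng.normal(0.0, sd, left.shape)
        right = right + rng.normal(0.0, sd, right.shape)

    # --- kinetics ---------------------------------------------------------
    total_f, takeoff_t = _force_profile(p, t_force, t0, t_catch_nominal)
    split = 0.5 + 0.06 * np.sin(2 * np.pi * 0.7 * t_force)
    move_env = _bump(t_force, 0.5 * (t0 + t_catch_nominal), (t_catch_nominal - t0))
    shear_ap = 0.02 * (p.body_mass * G) * np.sin(2 * np.pi * 1.1 * t_force) * move_env
    shear_ml = 0.01 * (p.body_mass * G) * np.sin(2 * np.pi * 0.9 * t_force) * move_env
    plate1 = np.column_stack([shear_ap * split, shear_ml * split, total_f * split])
    plate2 = np.column_stack([shear_ap * (1 - split), shear_ml * (1 - split),
                              total_f * (1 - split)])
    if p.noise_sd_force > 0:
        plate1 = plate1 + rng.normal(0.0, p.noise_sd_force, plate1.shape)
        plate2 = plate2 + rng.normal(0.0, p.noise_sd_force, plate2.shape)

    raw = RawTrial(
        subject_id=subject_id, condition=condition, trial_index=trial_index,
        marker_left=left, marker_right=right, f_kin=p.f_kin,
        plate1=plate1, plate2=plate2, f_force=p.f_force,
    )

    # --- analytic truth (from the emitted noiseless path) -----------------
    v_clean = np.gradient(vert_rel, 1.0 / p.f_kin)
    above = np.flatnonzero(v_clean >= 0.01)
    start_time = float(t_kin[above[0]]) if len(above) else float("nan")
    truth = TrialTruth(
        start_time=start_time,
        catch_time=float(catch_time),
        takeoff_time=takeoff_t,
        duration=float(catch_time - start_time),
        v_max=p.v_max,
        y_max=p.y_max,
        y_catch=p.y_catch,
        vtr=p.y_max - p.y_catch,
        x1=p.x1,
        x2=p.x2,
        x3=p.x3,
        vgrf_max_bw=p.vgrf_max_bw,
    )
    return raw, truth


def generate_static(subject_id: str, body_mass: float, duration: float = 2.0,
                    f_force: float = 1000.0, split: float = 0.55,
                    noise_sd: float = 2.0, seed: int = 0) -> StaticRecord:
    """Quiet-standing record: constant body weight split between the plates."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * f_force))
    w = body_mass * G
    p1 = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, split * w)])
    p2 = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, (1 - split) * w)])
    if noise_sd > 0:
        p1 = p1 + rng.normal(0.0, noise_sd, p1.shape)
        p2 = p2 + rng.normal(0.0, noise_sd, p2.shape)
    return StaticRecord(subject_id=subject_id, plate1=p1, plate2=p2, f_force=f_force)


def write_trial(raw: RawTrial, outdir: str | Path) -> tuple[Path, Path]:
    """Write one trial in the reference TSV dialects; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{raw.subject_id}_{raw.condition}_{raw.trial_index}"
    mpath = outdir / f"{stem}_markers.tsv"
    fpath = outdir / f"{stem}_forces.tsv"
    write_marker_file(mpath, raw.marker_left, raw.marker_right, raw.f_kin)
    write_force_file(fpath, raw.plate1, raw.plate2, raw.f_force)
    return mpath, fpath


# ---------------------------------------------------------------------------
# cohort model
# ---------------------------------------------------------------------------

#: Population mean and between-subject SD of each varied trial parameter,
#: centred on the magnitudes typical of novice power-snatch cohorts.
_POPULATION: dict[str, tuple[float, float]] = {
    "y_max": (160.5, 17.0),       # cm
    "vtr": (18.4, 12.0),          # cm (y_catch = y_max - vtr)
    "x1": (-0.3, 7.0),            # cm
    "x2": (-16.5, 7.0),           # cm
    "x3": (9.0, 9.5),             # cm
    "v_max": (3.16, 0.44),        # m/s
    "duration": (1.30, 0.24),     # s
    "vgrf_max_bw": (2.60, 1.00),  # BW
}


@dataclass
class CohortParams:
    """Hierarchical model of a subjects x conditions x trials cohort.

    For each varied parameter with population SD sigma, a subject effect
    with SD ``sqrt(icc) * sigma`` is shared across the four conditions, a
    condition-cell effect with SD ``sqrt(1 - icc) * sigma`` is drawn per
    condition, and trial-to-trial noise with SD ``trial_sd_frac * sigma``
    is added per repetition.  ``condition_shifts`` plants fixed mean
    offsets, e.g. ``{"x1": {"DL": 2.0}}``; the default (no shifts) is the
    global null.
    """

    n_subjects: int = 16
    n_trials: int = 3
    icc: float = 0.5
    condition_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    trial_sd_frac: float = 0.35
    sd_scale: float = 1.0       # global multiplier on all population SDs
    noise_sd_pos: float = 1.0    # mm, passed to each trial
    noise_sd_force: float = 5.0  # N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("need at least one subject and one trial")
        if not 0 <= self.icc < 1:
            raise ValueError("icc must be in [0, 1)")
        if self.trial_sd_frac < 0:
            raise ValueError("trial_sd_frac must be >= 0")
        if self.sd_scale < 0:
            raise ValueError("sd_scale must be >= 0")
        for var in self.condition_shifts:
            if var not in _POPULATION:
                raise ValueError(f"unknown shifted variable {var!r}; "
                                 f"known: {sorted(_POPULATION)}")


def _clip_params(row: dict[str, float]) -> dict[str, float]:
    """Keep drawn parameters physically and numerically realisable."""
    row["y_max"] = float(np.clip(row["y_max"], 100.0, 220.0))
    row["vtr"] = float(np.clip(row["vtr"], 8.0, 60.0))
    row["v_max"] = float(np.clip(row["v_max"], 1.8, 5.0))
    row["x2"] = float(min(row["x2"], -4.0))
    row["x1"] = float(np.clip(row["x1"], row["x2"] + 2.0, 25.0))
    row["x3"] = float(np.clip(row["x3"], row["x2"] + 2.0, 40.0))
    row["vgrf_max_bw"] = float(np.clip(row["vgrf_max_bw"], 1.7, 6.0))
    rise = 1.875 * (row["y_max"] / 100.0) / row["v_max"]
    row["duration"] = float(np.clip(row["duration"], rise + 0.30, 2.5))
    return row


def draw_cohort_truth(c: CohortParams,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-trial ground-truth parameter table of one cohort.

    Returns one row per subject x condition x trial with the varied
    parameters plus subject anthropometry.  This is the feature-level part
    of the generator: :func:`generate_cohort` turns each row into signals.
    """
    rng = rng or np.random.default_rng(c.seed)
    rows = []
    for s in range(c.n_subjects):
        sid = f"S{s + 1:02d}"
        mass = float(np.clip(rng.normal(75.0, 8.0), 55.0, 110.0))
        height = float(np.clip(rng.normal(1.78, 0.06), 1.60, 2.00))
        subj_eff = {v: rng.normal(0.0, np.sqrt(c.icc) * sd * c.sd_scale)
                    for v, (_, sd) in _POPULATION.items()}
        for cond in CONDITIONS:
            cell = {}
            for v, (mu, sd) in _POPULATION.items():
                shift = c.condition_shifts.get(v, {}).get(cond, 0.0)
                cell[v] = (mu + shift + subj_eff[v]
                           + rng.normal(0.0, np.sqrt(1.0 - c.icc) * sd * c.sd_scale))
            for k in range(1, c.n_trials + 1):
                row = {v: cell[v] + rng.normal(0.0, c.trial_sd_frac * sd * c.sd_scale)
                       for v, (_, sd) in _POPULATION.items()}
                row = _clip_params(row)
                row.update(subject_id=sid, condition=cond, trial=k,
                           body_mass=mass, body_height=height)
                rows.append(row)
    return pd.DataFrame(rows)


def _trial_params_from_row(row: pd.Series, c: CohortParams, seed: int) -> TrialParams:
    return TrialParams(
        y_max=row["y_max"], y_catch=row["y_max"] - row["vtr"],
        x1=row["x1"], x2=row["x2"], x3=row["x3"],
        v_max=row["v_max"], duration=row["duration"],
        body_mass=row["body_mass"], body_height=row["body_height"],
        vgrf_max_bw=row["vgrf_max_bw"],
        noise_sd_pos=c.noise_sd_pos, noise_sd_force=c.noise_sd_force,
        seed=seed,
    )


def iter_cohort_trials(
    c: CohortParams, truth: pd.DataFrame | None = None
) -> Iterator[tuple[RawTrial, SubjectInfo, TrialTruth]]:
    """Yield every cohort trial as in-memory signals with its ground truth."""
    truth = truth if truth is not None else draw_cohort_truth(c)
    seeds = np.random.SeedSequence(c.seed).generate_state(len(truth) + 1)[1:]
    for i, (_, row) in enumerate(truth.iterrows()):
        p = _trial_params_from_row(row, c, int(seeds[i] % (2 ** 31)))
        raw, tr = generate_trial(p, subject_id=row["subject_id"],
                                 condition=row["condition"],
                                 trial_index=int(row["trial"]))
        info = SubjectInfo(subject_id=row["subject_id"],
                           body_height=row["body_height"],
                           body_mass=row["body_mass"])
        yield raw, info, tr


def generate_cohort(c: CohortParams, outdir: str | Path) -> tuple[Path, pd.DataFrame]:
    """Write a full cohort to disk: trial TSVs, statics, manifest, truth table.

    Returns the manifest path and the ground-truth DataFrame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = draw_cohort_truth(c)
    subjects: dict[str, dict] = {}
    for raw, info, _ in iter_cohort_trials(c, truth):
        mpath, fpath = write_trial(raw, outdir)
        sub = subjects.setdefault(info.subject_id, {
            "id": info.subject_id,
            "body_height": round(info.body_height, 3),
            "body_mass": round(info.body_mass, 2),
            "trials": [],
        })
        sub["trials"].append({
            "condition": raw.condition, "trial": raw.trial_index,
            "markers": mpath.name, "forces": fpath.name,
        })
    statics_seed = np.random.SeedSequence([c.seed, 9_999]).generate_state(
        len(subjects)) % (2 ** 31)
    for i, (sid, sub) in enumerate(subjects.items()):
        static = generate_static(sid, sub["body_mass"], seed=int(statics_seed[i]))
        spath = outdir / f"{sid}_static.tsv"
        write_force_file(spath, static.plate1, static.plate2, static.f_force)
        sub["static"] = spath.name
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"subjects": list(subjects.values())}, fh, sort_keys=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    return manifest_path, truth


def simulate_variable_tables(
    c: CohortParams, variable: str, n_tables: int, seed: int | None = None
) -> Iterator[pd.DataFrame]:
    """Yield subject x condition tables of subject-mean ground-truth values.

    The fast, feature-level route for statistical calibration studies: each
    table is one independent cohort draw collapsed to the unit of analysis
    used by the study battery.
    """
    if variable not in _POPULATION:
        raise ValueError(f"unknown variable {variable!r}")
    root = np.random.SeedSequence(c.seed if seed is None else seed)
    for child in root.spawn(n_tables):
        rng = np.random.default_rng(child)
        truth = draw_cohort_truth(replace(c), rng=rng)
        yield (truth.groupby(["subject_id", "condition"])[variable].mean()
                    .unstack("condition").reindex(columns=list(CONDITIONS)))
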