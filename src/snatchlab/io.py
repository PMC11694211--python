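"""Data model, file formats and cohort manifest handling.

The package works in a canonical right-handed frame:

* ``AP`` — anteroposterior, **positive toward the lifter** (so the classic
  "toward–away–toward" bar path reads positive–negative–positive),
* ``ML`` — mediolateral,
* ``V``  — vertical, positive up.

On disk, marker files store positions in **millimetres** (motion-capture
export convention) and force files store **newtons**; in memory everything
is metres and newtons.  The reference marker/force format is a plain
tab-separated table with a ``time`` column:

``time  left_X  left_Y  left_Z  right_X  right_Y  right_Z``   (markers, mm)
``time  p1_Fx  p1_Fy  p1_Fz  p2_Fx  p2_Fy  p2_Fz``            (forces, N)

An :class:`AxisMap` says which file axis letter feeds each canonical axis
and with which sign, so exports with a different lab frame can be ingested
without editing files.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CONDITIONS",
    "FEATURE_COLUMNS",
    "AxisMap",
    "RawTrial",
    "StaticRecord",
    "SubjectInfo",
    "PipelineConfig",
    "CohortIndex",
    "TrialEntry",
    "FormatError",
    "read_marker_file",
    "read_force_file",
    "write_marker_file",
    "write_force_file",
    "write_features",
    "read_features",
    "load_manifest",
]

#: The four learning conditions compared by the study design.
CONDITIONS = ("RL", "bCI", "sCI", "DL")

#: Column contract of the discrete-parameter table (one row per trial).
FEATURE_COLUMNS = [
    "V-avg", "V-max", "Acc-max", "Y-max", "Y-catch", "VTR",
    "X1", "X2", "X3_DxT", "DxL", "DxV", "MvT_duration",
    "vGRF_max", "vGRF_mean_all", "vGRF_mean_jump",
    "RFD_max_all", "RFD_max_jump", "RFD_mean_all", "RFD_mean_jump",
    "Power_max_all", "Power_max_jump", "Power_mean_all", "Power_mean_jump",
]


class FormatError(ValueError):
    """A file does not follow the documented column grammar."""


@dataclass(frozen=True)
class AxisMap:
    """Mapping of file axis letters onto the canonical (AP, ML, V) frame.

    ``ap``, ``ml``, ``v`` each name a file axis with an optional sign,
    e.g. ``AxisMap(ap="-Y", ml="+X", v="+Z")``.
    """

    ap: str = "+X"
    ml: str = "+Y"
    v: str = "+Z"

    def __post_init__(self) -> None:
        letters = [self._parse(a)[0] for a in (self.ap, self.ml, self.v)]
        if sorted(letters) != ["X", "Y", "Z"]:
            raise ValueError(
                f"axis map must use each of X, Y, Z exactly once, got {letters}"
            )

    @staticmethod
    def _parse(spec: str) -> tuple[str, float]:
        s = spec.strip()
        sign = 1.0
        if s[0] in "+-":
            sign = -1.0 if s[0] == "-" else 1.0
            s = s[1:]
        if s.upper() not in ("X", "Y", "Z"):
            raise ValueError(f"bad axis spec {spec!r}")
        return s.upper(), sign

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        """Reorder/sign-flip an (n, 3) file-order [X, Y, Z] array into (AP, ML, V)."""
        cols = {"X": 0, "Y": 1, "Z": 2}
        out = np.empty_like(xyz, dtype=float)
        for i, spec in enumerate((self.ap, self.ml, self.v)):
            letter, sign = self._parse(spec)
            out[:, i] = sign * xyz[:, cols[letter]]
        return out


@dataclass
class RawTrial:
    """Unprocessed marker and force time series for one snatch attempt.

    Marker arrays are (n, 3) positions in metres, force arrays (m, 3) in
    newtons, both already in the canonical (AP, ML, V) frame.
    """

    subject_id: str
    condition: str
    trial_index: int
    marker_left: np.ndarray
    marker_right: np.ndarray
    f_kin: float
    plate1: np.ndarray
    plate2: np.ndarray
    f_force: float
    axis_map: AxisMap = field(default_factory=AxisMap)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not 1 <= int(self.trial_index) <= 3:
            raise ValueError("trial_index must be 1..3")
        if self.marker_left.shape != self.marker_right.shape:
            raise ValueError("marker series must have identical shapes")
        if self.plate1.shape != self.plate2.shape:
            raise ValueError("plate series must have identical shapes")
        if self.f_kin <= 0 or self.f_force <= 0:
            raise ValueError("sampling rates must be positive")


@dataclass
class StaticRecord:
    """Quiet-standing force record (no barbell) used to weigh the subject."""

    subject_id: str
    plate1: np.ndarray
    plate2: np.ndarray
    f_force: float = 1000.0

    @property
    def duration(self) -> float:
        return len(self.plate1) / self.f_force

    def __post_init__(self) -> None:
        if self.plate1.shape != self.plate2.shape:
            raise ValueError("plate series must have identical shapes")
        if self.duration < 1.0:
            raise ValueError("static record must cover at least 1 s")


@dataclass
class SubjectInfo:
    subject_id: str
    body_height: float  # m
    body_mass: float    # kg

    def __post_init__(self) -> None:
        if not 1.0 < self.body_height < 2.5:
            raise ValueError(f"implausible body height {self.body_height} m")
        if not 30.0 < self.body_mass < 200.0:
            raise ValueError(f"implausible body mass {self.body_mass} kg")


@dataclass
class PipelineConfig:
    """Tunables of the signal pipeline and statistical battery.

    Defaults follow standard practice for barbell kinematics: 4 Hz / 15 Hz
    fourth-order zero-phase Butterworth cutoffs, a 0.01 m/s vertical-velocity
    movement-start threshold, and 101-point time normalisation of the
    start-to-catch phase.
    """

    cutoff_kin: float = 4.0          # Hz, marker low-pass
    cutoff_force: float = 15.0       # Hz, force low-pass
    filter_order: int = 4
    start_velocity_threshold: float = 0.01   # m/s
    start_sustain: float = 0.04              # s the threshold must hold
    takeoff_force_threshold: float = 0.05    # fraction of body weight
    takeoff_sustain: float = 0.02            # s below threshold
    rfd_interval: float = 0.001              # s between force samples
    n_time_points: int = 101
    stats_unit: str = "subject_mean"         # or "trial"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("cutoff_kin", "cutoff_force", "start_velocity_threshold",
                     "takeoff_force_threshold", "rfd_interval", "start_sustain",
                     "takeoff_sustain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_time_points < 2:
            raise ValueError("n_time_points must be >= 2")
        if self.stats_unit not in ("subject_mean", "trial"):
            raise ValueError("stats_unit must be 'subject_mean' or 'trial'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# marker / force TSV readers and writers
# ---------------------------------------------------------------------------

_MARKER_COLS = ["left_X", "left_Y", "left_Z", "right_X", "right_Y", "right_Z"]
_FORCE_COLS = ["p1_Fx", "p1_Fy", "p1_Fz", "p2_Fx", "p2_Fy", "p2_Fz"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".c3d":
        raise FormatError(
            "C3D input is not supported by this build; export the trial to the "
            "documented TSV dialect instead"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ["time", *required] if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    t = df["time"].to_numpy(float)
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise FormatError(f"{path.name}: time column must be strictly increasing")
    return df


def _rate_from_time(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


def read_marker_file(
    path: str | Path, axis_map: AxisMap | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a two-marker barbell TSV (mm) into canonical-frame metres.

    Returns ``(marker_left, marker_right, f_kin)`` with (n, 3) arrays.
    """
    axis_map = axis_map or AxisMap()
    df = _read_tsv(path, _MARKER_COLS)
    left = df[["left_X", "left_Y", "left_Z"]].to_numpy(float) / 1000.0
    right = df[["right_X", "right_Y", "right_Z"]].to_numpy(float) / 1000.0
    return (
        axis_map.apply(left),
        axis_map.apply(right),
        _rate_from_time(df["time"].to_numpy(float)),
    )


def read_force_file(
    path: str | Path, axis_map: AxisMap | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a two-plate force TSV (N); returns ``(plate1, plate2, f_force)``."""
    axis_map = axis_map or AxisMap()
    df = _read_tsv(path, _FORCE_COLS)
    p1 = df[["p1_Fx", "p1_Fy", "p1_Fz"]].to_numpy(float)
    p2 = df[["p2_Fx", "p2_Fy", "p2_Fz"]].to_numpy(float)
    return axis_map.apply(p1), axis_map.apply(p2), _rate_from_time(df["time"].to_numpy(float))


def _write_tsv(path: str | Path, time: np.ndarray, cols: Mapping[str, np.ndarray]) -> None:
    df = pd.DataFrame({"time": time, **cols})
    df.to_csv(path, sep="\t", index=False)  # full float repr: round-trippable


def write_marker_file(
    path: str | Path, left: np.ndarray, right: np.ndarray, f_kin: float
) -> None:
    """Write canonical-frame metre marker arrays as the mm TSV dialect."""
    n = len(left)
    time = np.arange(n) / f_kin
    lf, rf = left * 1000.0, right * 1000.0
    _write_tsv(path, time, dict(zip(_MARKER_COLS, [*lf.T, *rf.T])))


def write_force_file(
    path: str | Path, plate1: np.ndarray, plate2: np.ndarray, f_force: float
) -> None:
    n = len(plate1)
    time = np.arange(n) / f_force
    _write_tsv(path, time, dict(zip(_FORCE_COLS, [*plate1.T, *plate2.T])))


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def write_features(features: Iterable[Mapping[str, object]] | pd.DataFrame,
                   path: str | Path) -> pd.DataFrame:
    """Write the discrete-parameter table, one row per trial.

    ``features`` is an iterable of per-trial dicts (as produced by
    :meth:`snatchlab.features.SnatchFeatures.to_row`) or an equivalent
    DataFrame.  Columns are ``subject_id, condition, trial`` followed by the
    23 parameters of :data:`FEATURE_COLUMNS`.
    """
    if isinstance(features, pd.DataFrame):
        df = features.copy()
    else:
        rows = list(features)
        if not rows:
            raise ValueError("cannot write an empty feature table")
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("cannot write an empty feature table")
    lead = [c for c in ("subject_id", "condition", "trial") if c in df.columns]
    cols = lead + [c for c in FEATURE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df = df[cols + extra]
    df.to_csv(path, index=False)
    return df


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialEntry:
    subject_id: str
    condition: str
    trial_index: int
    marker_file: str
    force_file: str
    force_offset: int = 0  # force samples by which the plates lead the cameras


@dataclass
class CohortIndex:
    """Index of a subjects x conditions x trials cohort on disk."""

    subjects: dict[str, SubjectInfo]
    static_files: dict[str, str]
    trials: list[TrialEntry]
    root: Path

    @property
    def missing_cells(self) -> list[tuple[str, str, int]]:
        have = {(t.subject_id, t.condition, t.trial_index) for t in self.trials}
        return [
            (s, c, k)
            for s in self.subjects
            for c in CONDITIONS
            for k in (1, 2, 3)
            if (s, c, k) not in have
        ]

    def is_complete(self) -> bool:
        return not self.missing_cells


def load_manifest(path: str | Path) -> CohortIndex:
    """Load a YAML cohort manifest mapping subjects x conditions x trials to files.

    Expected structure::

        subjects:
          - id: S01
            body_height: 1.78
            body_mass: 75.0        # optional if a static record is given
            static: S01_static.tsv
            trials:
              - {condition: DL, trial: 1, markers: S01_DL_1_markers.tsv,
                 forces: S01_DL_1_forces.tsv, force_offset: 0}

    Duplicate (subject, condition, trial) cells raise; incomplete cells are
    reported with a warning and listed in :attr:`CohortIndex.missing_cells`.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "subjects" not in doc:
        raise FormatError(f"{path.name}: manifest must have a 'subjects' list")
    subjects: dict[str, SubjectInfo] = {}
    statics: dict[str, str] = {}
    trials: list[TrialEntry] = []
    seen: set[tuple[str, str, int]] = set()
    for sub in doc["subjects"]:
        sid = str(sub["id"])
        if sid in subjects:
            raise FormatError(f"duplicate subject id {sid!r}")
        subjects[sid] = SubjectInfo(
            subject_id=sid,
            body_height=float(sub["body_height"]),
            body_mass=float(sub.get("body_mass", 75.0)),
        )
        if "static" in sub:
            statics[sid] = str(sub["static"])
        for tr in sub.get("trials", []):
            cond = str(tr["condition"])
            if cond not in CONDITIONS:
                raise FormatError(f"unknown condition {cond!r} for subject {sid}")
            idx = int(tr["trial"])
            key = (sid, cond, idx)
            if key in seen:
                raise FormatError(f"duplicate trial cell {key}")
            seen.add(key)
            trials.append(
                TrialEntry(
                    subject_id=sid,
                    condition=cond,
                    trial_index=idx,
                    marker_file=str(tr["markers"]),
                    force_file=str(tr["forces"]),
                    force_offset=int(tr.get("force_offset", 0)),
                )
            )
    index = CohortIndex(subjects=subjects, static_files=statics, trials=trials,
                        root=path.parent)
    if index.missing_cells:
        warnings.warn(
            f"manifest {path.name} is incomplete: "
            f"{len(index.missing_cells)} missing cell(s), e.g. {index.missing_cells[:3]}",
            stacklevel=2,
        )
    return index


def load_trial(entry: TrialEntry, index: CohortIndex,
               axis_map: AxisMap | None = None) -> RawTrial:
    """Materialise one manifest entry as a :class:`RawTrial`."""
    left, right, f_kin = read_marker_file(index.root / entry.marker_file, axis_map)
    p1, p2, f_force = read_force_file(index.root / entry.force_file, axis_map)
    if entry.force_offset:
        off = entry.force_offset
        p1 = p1[off:] if off > 0 else np.pad(p1, ((-off, 0), (0, 0)), mode="edge")
        p2 = p2[off:] if off > 0 else np.pad(p2, ((-off, 0), (0, 0)), mode="edge")
    return RawTrial(
        subject_id=entry.subject_id,
        condition=entry.condition,
        trial_index=entry.trial_index,
        marker_left=left,
        marker_right=right,
        f_kin=f_kin,
        plate1=p1,
        plate2=p2,
        f_force=f_force,
        axis_map=axis_map or AxisMap(),
    )
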