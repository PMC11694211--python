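"""Quick-look figures: bar path and force trace with detected events."""

from __future__ import annotations

import numpy as np

from .features import PhaseEvents
from .preprocess import TrialSignals

__all__ = ["plot_bar_path", "plot_force_trace"]


def plot_bar_path(signals: TrialSignals, events: PhaseEvents | None = None, ax=None):
    """Sagittal-plane bar trajectory (AP vs vertical, cm) with landmarks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    ap = 100.0 * signals.barbell_pos[:, 0]
    v = 100.0 * signals.barbell_pos[:, 1]
    ax.plot(ap, v, lw=1.2, color="C0")
    if events is not None:
        marks = {
            "start": events.start_idx, "X1": events.rearmost_idx,
            "Y-max": events.ymax_idx, "X2": events.foremost_idx,
            "catch": events.catch_idx,
        }
        for label, idx in marks.items():
            ax.plot(ap[idx], v[idx], "o", ms=5)
            ax.annotate(label, (ap[idx], v[idx]), textcoords="offset points",
                        xytext=(6, 0), fontsize=8)
    ax.axvline(0.0, color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("AP displacement toward lifter (cm)")
    ax.set_ylabel("vertical displacement (cm)")
    ax.set_title(f"{signals.subject_id} {signals.condition} "
                 f"trial {signals.trial_index}")
    return ax


def plot_force_trace(signals: TrialSignals, events: PhaseEvents | None = None, ax=None):
    """Body-weight-normalised vGRF over time with start/takeoff/catch marks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    t = np.arange(len(signals.vgrf_bw)) / signals.f_force
    ax.plot(t, signals.vgrf_bw, lw=1.0, color="C1")
    ax.axhline(1.0, color="0.8", lw=0.8, zorder=0)
    if events is not None:
        for label, idx_f in (
            ("start", signals.kin_to_force_idx(events.start_idx)),
            ("takeoff", events.takeoff_idx),
            ("catch", signals.kin_to_force_idx(events.catch_idx)),
        ):
            if idx_f is None:
                continue
            ax.axvline(idx_f / signals.f_force, color="0.5", lw=0.8, ls="--")
            ax.annotate(label, (idx_f / signals.f_force, ax.get_ylim()[1]),
                        fontsize=8, rotation=90, va="top")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("vGRF (BW)")
    return ax
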