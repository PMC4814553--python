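"""Event streams, GLM design matrices, and DCM stimulus functions.

The session timeline is three concatenated blocks with no run breaks:
Block 1 — six 60-s ambiguous (Rubin face-vase) trials each followed by 6 s
fixation; Block 2 — sixteen 16-s non-ambiguous "biasing" trials each
followed by 4 s fixation; Block 3 — identical to Block 1.  Total 1112 s,
556 BOLD samples at TR = 2 s.

The task model has nine regressors (ambiguous-block boxcars, the
non-ambiguous block, button presses per block, and the 2-s "pre-switch"
windows immediately preceding each press), convolved with a canonical
double-gamma HRF on a 16-bins-per-TR microtime grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

TR = 2.0
MICROTIME_BINS_PER_TR = 16
MICROTIME_DT = TR / MICROTIME_BINS_PER_TR

# Block structure: (n_trials, trial_s, fixation_s)
BLOCK_STRUCTURE = {1: (6, 60.0, 6.0), 2: (16, 16.0, 4.0), 3: (6, 60.0, 6.0)}
PRESWITCH_WINDOW = 2.0  # s immediately before each button press
PRESS_DURATION = MICROTIME_DT  # presses modeled as one-microtime-bin events

# Task regressors in their conventional listing order.
TASK_CONDITIONS = (
    "amb_block1", "amb_block3", "nonamb_block2",
    "press_block1", "preswitch_block1",
    "press_block3", "preswitch_block3",
    "press_block2", "preswitch_block2",
)
ALL_CONDITIONS = TASK_CONDITIONS + ("fixation",)
PRESS_CONDITIONS = ("press_block1", "press_block2", "press_block3")

EVENT_COLUMNS = ("onset", "duration", "trial_type", "percept", "trial_index")


def block_offsets() -> dict[int, float]:
    """Session-clock onset (s) of each block."""
    offs, t = {}, 0.0
    for b in (1, 2, 3):
        offs[b] = t
        n, trial, fix = BLOCK_STRUCTURE[b]
        t += n * (trial + fix)
    return offs


def session_duration() -> float:
    n1, t1, f1 = BLOCK_STRUCTURE[1]
    n2, t2, f2 = BLOCK_STRUCTURE[2]
    n3, t3, f3 = BLOCK_STRUCTURE[3]
    return n1 * (t1 + f1) + n2 * (t2 + f2) + n3 * (t3 + f3)


def trial_windows(block: int) -> list[tuple[float, float]]:
    """(start, end) of each stimulus interval of a block, session clock."""
    n, trial, fix = BLOCK_STRUCTURE[block]
    start = block_offsets()[block]
    return [(start + k * (trial + fix), start + k * (trial + fix) + trial)
            for k in range(n)]


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "onset": pd.Series(dtype=float),
        "duration": pd.Series(dtype=float),
        "trial_type": pd.Series(dtype=object),
        "percept": pd.Series(dtype=object),
        "trial_index": pd.Series(dtype="Int64"),
    })


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table contract; returns the (possibly coerced) table."""
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if len(events) == 0:
        return events
    if (events["onset"] < 0).any():
        raise ValueError("event onsets must be nonnegative")
    if (events["duration"] <= 0).any():
        raise ValueError("event durations must be positive")
    bad = set(events["trial_type"]) - set(ALL_CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    for cond, grp in events.groupby("trial_type"):
        if not grp["onset"].is_monotonic_increasing:
            # order within condition is what matters; rows may be shuffled
            if not grp["onset"].sort_values().is_monotonic_increasing:
                raise ValueError(f"onsets not orderable within {cond}")
    is_press = events["trial_type"].isin(PRESS_CONDITIONS)
    has_percept = events["percept"].notna()
    if (is_press & ~has_percept & events["trial_type"].isin(
            ("press_block1", "press_block3"))).any():
        raise ValueError("ambiguous-block press events need a percept label")
    if (~is_press & has_percept).any():
        raise ValueError("percept labels only allowed on press events")
    return events


def derive_preswitch_events(presses: pd.DataFrame,
                            windows: list[tuple[float, float]],
                            condition: str = "preswitch_block1") -> pd.DataFrame:
    """2-s windows ending at each button press, truncated at trial onset.

    Each press must fall inside one of the given (start, end) trial windows;
    a press earlier than 2 s into its trial yields a shortened event starting
    at the trial onset.
    """
    rows = []
    for _, press in presses.iterrows():
        t = float(press["onset"])
        window = next(((a, b) for a, b in windows if a <= t <= b), None)
        if window is None:
            raise ValueError(f"press at {t:.3f}s lies outside every trial window")
        onset = max(window[0], t - PRESWITCH_WINDOW)
        dur = t - onset
        if dur <= 0:
            continue  # press exactly at trial onset: no pre-switch interval
        rows.append({"onset": onset, "duration": dur, "trial_type": condition,
                     "percept": None, "trial_index": press.get("trial_index")})
    if not rows:
        return empty_events()
    return pd.DataFrame(rows)[list(EVENT_COLUMNS)]


def canonical_hrf(tr: float = TR, microtime_step: float = MICROTIME_DT) -> np.ndarray:
    """Canonical double-gamma HRF sampled on the microtime grid, unit sum.

    Response gamma with shape 6, undershoot with shape 16, peak:undershoot
    amplitude ratio 6:1, 32-s support.
    """
    if tr <= 0 or microtime_step <= 0:
        raise ValueError("TR and microtime step must be positive")
    t = np.arange(0.0, 32.0, microtime_step)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    return h / h.sum()


@dataclass
class DesignMatrix:
    """Convolved task regressors plus nuisance columns and a constant."""

    X: np.ndarray
    labels: tuple[str, ...]
    tr: float

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")
        if self.labels.count("constant") != 1:
            raise ValueError("exactly one constant column required")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def columns(self, labels) -> np.ndarray:
        idx = [self.labels.index(l) for l in labels]
        return self.X[:, idx]


def _microtime_boxcar(events: pd.DataFrame, n_bins: int,
                      dt: float = MICROTIME_DT, warn_overlap: bool = True) -> np.ndarray:
    """Binary step function on the microtime grid; overlaps merge to 1."""
    box = np.zeros(n_bins)
    overlap = False
    for _, ev in events.iterrows():
        a = int(round(ev["onset"] / dt))
        b = max(a + 1, int(round((ev["onset"] + ev["duration"]) / dt)))
        b = min(b, n_bins)
        if a >= n_bins:
            continue
        if box[a:b].any():
            overlap = True
        box[a:b] = 1.0
    if overlap and warn_overlap:
        warnings.warn("overlapping events within one condition were merged",
                      stacklevel=3)
    return box


def build_design_matrix(events: pd.DataFrame, motion: np.ndarray | None,
                        n_samples: int, tr: float = TR,
                        bins_per_tr: int = MICROTIME_BINS_PER_TR) -> DesignMatrix:
    """HRF-convolved task regressors, motion nuisance columns, constant.

    Boxcars are built per condition on the microtime grid, convolved with the
    canonical HRF, and sampled at the end of each TR (matching the forward
    model's BOLD sampling convention).  Conditions with no events contribute
    a zero column so the column layout is stable.
    """
    validate_events(events)
    dt = tr / bins_per_tr
    S = n_samples * bins_per_tr
    hrf = canonical_hrf(tr, dt)
    sample_idx = np.arange(1, n_samples + 1) * bins_per_tr - 1
    cols, labels = [], []
    for cond in TASK_CONDITIONS:
        sub = events[events["trial_type"] == cond]
        if len(sub) == 0:
            warnings.warn(f"no events for condition {cond}; zero column kept",
                          stacklevel=2)
            cols.append(np.zeros(n_samples))
        else:
            box = _microtime_boxcar(sub, S, dt, warn_overlap=False)
            conv = np.convolve(box, hrf)[:S]
            cols.append(conv[sample_idx])
        labels.append(cond)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_samples:
            raise ValueError("motion table row count must equal n_samples")
        for k in range(motion.shape[1]):
            cols.append(motion[:, k])
            labels.append(f"motion{k + 1}")
    cols.append(np.ones(n_samples))
    labels.append("constant")
    return DesignMatrix(X=np.column_stack(cols), labels=tuple(labels), tr=tr)


def build_stimulus_functions(events: pd.DataFrame,
                             microtime_step: float = MICROTIME_DT,
                             duration: float | None = None,
                             include_block2_input: bool = False):
    """Unconvolved DCM inputs: driving boxcars plus pre-switch modulators.

    Driving inputs are the two ambiguous-block boxcars (optionally also the
    non-ambiguous training block); modulators are the 2-s pre-switch windows
    of blocks 1 and 3.
    """
    from .dcm import DRIVING_INPUTS, MODULATORY_INPUTS, StimulusFunctions

    validate_events(events)
    if duration is None:
        duration = session_duration()
    n_bins = int(round(duration / microtime_step))
    driving = DRIVING_INPUTS + (("nonamb_block2",) if include_block2_input
                                else ())
    names = (*driving, *MODULATORY_INPUTS)
    U = np.zeros((n_bins, len(names)))
    for k, name in enumerate(names):
        sub = events[events["trial_type"] == name]
        if len(sub):
            U[:, k] = _microtime_boxcar(sub, n_bins, microtime_step)
    return StimulusFunctions(dt=microtime_step, names=names, U=U)
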