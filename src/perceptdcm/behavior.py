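"""Percept-duration statistics from button-press streams.

Subjects report their current percept (faces or vase) with a button press at
each perceptual switch during 60-s ambiguous trials.  A percept holds from
its report until the next press, or until the trial end for the final
percept; the interval before the first press is unassigned.  The biasing
effect of the non-ambiguous training block is quantified by the bias ratio:
post-training / pre-training mean duration of the trained ("faces") percept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

TRIAL_LENGTH = 60.0
PERCEPTS = ("face", "vase")
MIN_SWITCHES = 3  # inclusion: at least 3 switches (presses after the first)


@dataclass
class PerceptRecord:
    """Press streams of one subject in one block.

    ``trials`` is a list of trials, each a list of (press time s from trial
    onset, percept) tuples in strictly increasing time order; the first
    press defines the initial percept.
    """

    trials: list
    trial_length: float = TRIAL_LENGTH

    def __post_init__(self) -> None:
        for trial in self.trials:
            times = [t for t, _ in trial]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("press times must be strictly increasing")
            if any(t > self.trial_length for t in times):
                raise ValueError("press after trial end")
            if any(p not in PERCEPTS for _, p in trial):
                raise ValueError("percept must be 'face' or 'vase'")

    def switch_counts(self) -> list[int]:
        return [max(len(trial) - 1, 0) for trial in self.trials]


@dataclass
class BehaviorSummary:
    """Per-block duration summaries (ms) for one subject."""

    mean_face_ms: dict[int, float]
    mean_vase_ms: dict[int, float]
    total_face_ms: dict[int, float]
    total_vase_ms: dict[int, float]
    switch_counts: dict[int, list] = field(default_factory=dict)

    @property
    def bias_ratio(self) -> float:
        return bias_ratio_from_means(self.mean_face_ms[1], self.mean_face_ms[3])


def percept_durations(record: PerceptRecord) -> list[dict[str, list]]:
    """Per-trial percept durations (s): each percept holds until the next
    press or the trial end; the pre-first-press interval is unassigned."""
    out = []
    for trial in record.trials:
        if not trial:
            raise ValueError("each trial needs at least one press")
        durs = {p: [] for p in PERCEPTS}
        for k, (t, percept) in enumerate(trial):
            end = trial[k + 1][0] if k + 1 < len(trial) else record.trial_length
            durs[percept].append(end - t)
        out.append(durs)
    return out


def summarize(records_by_block: dict[int, PerceptRecord]) -> BehaviorSummary:
    """Pool all percepts across the trials of each block (ms)."""
    mean_f, mean_v, tot_f, tot_v, switches = {}, {}, {}, {}, {}
    for block, record in records_by_block.items():
        faces, vases = [], []
        for durs in percept_durations(record):
            faces.extend(durs["face"])
            vases.extend(durs["vase"])
        mean_f[block] = 1000.0 * float(np.mean(faces)) if faces else 0.0
        mean_v[block] = 1000.0 * float(np.mean(vases)) if vases else 0.0
        tot_f[block] = 1000.0 * float(np.sum(faces))
        tot_v[block] = 1000.0 * float(np.sum(vases))
        switches[block] = record.switch_counts()
    return BehaviorSummary(mean_face_ms=mean_f, mean_vase_ms=mean_v,
                           total_face_ms=tot_f, total_vase_ms=tot_v,
                           switch_counts=switches)


def bias_ratio_from_means(block1_face_ms: float, block3_face_ms: float) -> float:
    if block1_face_ms <= 0:
        raise ZeroDivisionError("pre-training mean face duration must be positive")
    return block3_face_ms / block1_face_ms


def bias_ratio(summary: BehaviorSummary) -> float:
    """Post-training / pre-training mean duration of the trained percept."""
    return summary.bias_ratio


def filter_subjects(records: dict[str, dict[int, PerceptRecord]],
                    require_all_trials: bool = True) -> set[str]:
    """Subjects whose ambiguous trials all contain >= 3 switches.

    With ``require_all_trials=False`` a subject is kept if ANY trial reaches
    the threshold (the laxer reading of the inclusion rule).
    """
    included = set()
    for subject, blocks in records.items():
        counts = []
        for record in blocks.values():
            counts.extend(record.switch_counts())
        if not counts:
            continue
        ok = (min(counts) if require_all_trials else max(counts)) >= MIN_SWITCHES
        if ok:
            included.add(subject)
    return included


def cohort_compare(values: np.ndarray, cohorts: np.ndarray) -> dict:
    """Welch two-sample t-test plus Cohen's d with pooled standard deviation."""
    values = np.asarray(values, dtype=float)
    cohorts = np.asarray(cohorts)
    levels = sorted(set(cohorts.tolist()))
    if len(levels) != 2:
        raise ValueError("exactly two cohorts required")
    x = values[cohorts == levels[0]]
    y = values[cohorts == levels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each cohort needs at least two subjects")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    pooled = np.sqrt(((len(x) - 1) * sx ** 2 + (len(y) - 1) * sy ** 2)
                     / (len(x) + len(y) - 2))
    degenerate = pooled == 0
    if degenerate:
        t, p, d = 0.0, 1.0, 0.0
    else:
        t, p = stats.ttest_ind(x, y, equal_var=False)
        d = (x.mean() - y.mean()) / pooled
    return {"t": float(t), "p": float(p), "cohens_d": float(d),
            "mean_by_cohort": {levels[0]: float(x.mean()), levels[1]: float(y.mean())},
            "degenerate": bool(degenerate)}


def initial_percepts(records_by_block: dict[int, PerceptRecord]) -> dict[int, list]:
    """First-press percept of every trial, per block."""
    return {block: [trial[0][1] for trial in rec.trials]
            for block, rec in records_by_block.items()}


def chi_square_2x2(table: np.ndarray) -> dict:
    """Pearson chi-square (no continuity correction) with exact-test fallback
    when an expected cell drops below 1."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected < 1).any():
        _, p = stats.fisher_exact(table)
        return {"statistic": float("nan"), "p": float(p), "exact": True}
    with np.errstate(invalid="ignore"):
        chi2 = np.nansum((table - expected) ** 2 / expected)
    pval = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return {"statistic": float(chi2), "p": pval, "exact": False}


def initial_percept_test(records: dict[str, dict[int, PerceptRecord]],
                         cohort_of: dict[str, str]) -> dict:
    """Association of the initial percept with cohort and with block.

    Two separate 2x2 chi-square tests on trial counts of first-press
    percepts: (percept x cohort) and (percept x block).
    """
    by_cohort = np.zeros((2, 2))
    by_block = np.zeros((2, 2))
    cohort_levels = sorted(set(cohort_of.values()))
    for subject, blocks in records.items():
        ci = cohort_levels.index(cohort_of[subject])
        for block, firsts in initial_percepts(blocks).items():
            bi = 0 if block == 1 else 1
            for percept in firsts:
                pi = PERCEPTS.index(percept)
                by_cohort[pi, ci] += 1
                by_block[pi, bi] += 1
    return {"by_cohort": chi_square_2x2(by_cohort),
            "by_block": chi_square_2x2(by_block),
            "tables": {"by_cohort": by_cohort, "by_block": by_block}}
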