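"""Synthetic cohorts: press streams with age-dependent bias and region BOLD
series from a known ground-truth DCM.

The generator emulates the study conditions: a young cohort (n = 14) that is
susceptible to the face-bias training (bias ratio > 1) and an older cohort
(n = 16) that resists it (bias ratio < 1); ground-truth connectivity follows
the model-1 structure, with the older cohort carrying a positive top-down
MTG->LIN modulation of the post-training pre-switch input and the young
cohort carrying none, plus cohort- and block-specific negative driving
inputs to posterior sources.  Holding times of the bistable percepts are
lognormal (heavy-tailed, as typical of bistable perception).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import design
from .behavior import MIN_SWITCHES, PerceptRecord
from .dcm import (BOTTOM_UP_EDGES, DCMParams, REGIONS, RegionTimeSeries,
                  TOP_DOWN_EDGES, build_model_space, simulate_bold)
from .glm import VoxelBlock

COHORTS = ("young", "older")


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Percept-duration medians/sigmas are on the lognormal scale (ms); the
    bias-ratio targets scale the block-3 face-percept median.  Ground-truth
    connectivity magnitudes are in Hz.  All per-subject randomness derives
    deterministically from ``master_seed``.
    """

    n_young: int = 14
    n_older: int = 16
    # percept stream parameters
    face_median_ms: float = 6000.0
    vase_median_ms: float = 6000.0
    duration_sigma: float = 0.6          # lognormal sigma of holding times
    first_press_median_ms: float = 1500.0
    first_press_sigma: float = 0.5
    bias_target: dict = field(default_factory=lambda: {"young": 1.5, "older": 0.85})
    subject_bias_sigma: float = 0.15     # between-subject spread of log bias
    # ground-truth connectivity (model-1 structure)
    a_self: float = -0.5
    a_forward: float = 0.15              # LIN/PRE -> MTG/IOF
    a_backward: float = 0.05             # MTG/IOF -> LIN/PRE and PRE -> LIN
    a_lin_pre: float = 0.1               # LIN -> PRE
    b_bottom_up: float = 0.3             # pre-switch block-1 gating
    b_top_down_young: float = 0.3        # block-3 gating, MTG->LIN excluded
    b_top_down_older: float = 0.2        # block-3 gating on minor edges
    b_mtg_lin_older: float = 0.4         # the age-specific MTG->LIN effect
    # driving-input magnitudes are capped so that sustained 60-s deactivation
    # keeps venous inflow positive (balloon-model domain)
    c_positive: float = 0.2
    c_negative: float = -0.06
    max_deactivation: float = 0.22       # plausibility bound on |steady z| (Hz)
    # between-subject truth variability
    connection_jitter_sd: float = 0.05   # on nonzero A/B/C entries
    self_jitter_sd: float = 0.1          # on log self-connection scaling
    hemo_jitter_sd: float = 0.1          # on log kappa and log tau
    # noise levels
    innovation_sd: float = 0.015          # Hz^0.5 neuronal innovations
    obs_noise_sd: float = 0.0015         # BOLD units observation noise
    master_seed: int = 2026

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_older < 2:
            raise ValueError("cohort sizes must be at least 2")
        if self.face_median_ms <= 0 or self.vase_median_ms <= 0:
            raise ValueError("percept-duration medians must be positive")


@dataclass
class SyntheticSubject:
    subject_id: str
    cohort: str
    events: pd.DataFrame
    records: dict[int, PerceptRecord]
    bold: RegionTimeSeries | None
    truth: DCMParams | None


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    return int(np.random.SeedSequence(
        entropy=master_seed, spawn_key=(index,)).generate_state(1)[0] % (2 ** 31))


def generate_session_events(config: CohortConfig | None = None) -> pd.DataFrame:
    """Session skeleton: stimulus and fixation events of the three blocks."""
    rows = []
    for block in (1, 2, 3):
        n, trial_s, fix_s = design.BLOCK_STRUCTURE[block]
        cond = {1: "amb_block1", 2: "nonamb_block2", 3: "amb_block3"}[block]
        for k, (start, end) in enumerate(design.trial_windows(block)):
            rows.append({"onset": start, "duration": trial_s, "trial_type": cond,
                         "percept": None, "trial_index": k})
            rows.append({"onset": end, "duration": fix_s, "trial_type": "fixation",
                         "percept": None, "trial_index": k})
    return pd.DataFrame(rows)[list(design.EVENT_COLUMNS)]


def _other(percept: str) -> str:
    return "vase" if percept == "face" else "face"


def _sample_trial(rng, face_median_s: float, vase_median_s: float,
                  sigma: float, first_median_s: float, first_sigma: float,
                  trial_length: float) -> list:
    first = min(first_median_s * np.exp(first_sigma * rng.standard_normal()),
                trial_length / 4.0)
    percept = "face" if rng.random() < 0.5 else "vase"
    presses = [(float(first), percept)]
    t = first
    while True:
        median = face_median_s if percept == "face" else vase_median_s
        hold = median * np.exp(sigma * rng.standard_normal())
        t = t + hold
        if t >= trial_length:
            break
        percept = _other(percept)
        presses.append((float(t), percept))
    return presses


def generate_press_streams(config: CohortConfig, cohort: str, seed,
                           max_retries: int = 1000):
    """Press streams for blocks 1 and 3 of one subject.

    Holding times are lognormal, truncated by the trial end; the block-3
    face-percept median is scaled by the cohort's bias-ratio target times a
    subject-level lognormal factor.  Trials are regenerated until the
    >= 3-switches inclusion filter passes.
    """
    if config.face_median_ms / 1000.0 * (MIN_SWITCHES + 1) > 10 * design.BLOCK_STRUCTURE[1][1]:
        raise ValueError("percept-duration median too long for 3 switches in a trial")
    rng = np.random.default_rng(seed)
    subject_factor = float(np.exp(config.subject_bias_sigma * rng.standard_normal()))
    records = {}
    for block in (1, 3):
        ratio = config.bias_target[cohort] * subject_factor if block == 3 else 1.0
        face_med = config.face_median_ms / 1000.0 * ratio
        vase_med = config.vase_median_ms / 1000.0
        n_trials, trial_s, _ = design.BLOCK_STRUCTURE[block]
        trials = []
        for _k in range(n_trials):
            for _retry in range(max_retries):
                presses = _sample_trial(
                    rng, face_med, vase_med, config.duration_sigma,
                    config.first_press_median_ms / 1000.0,
                    config.first_press_sigma, trial_s)
                if len(presses) - 1 >= MIN_SWITCHES:
                    break
            else:
                raise ValueError("could not satisfy the switch-count filter; "
                                 "percept medians are too long for 60-s trials")
            trials.append(presses)
        records[block] = PerceptRecord(trials=trials, trial_length=trial_s)
    return records


def press_events_from_records(records: dict[int, PerceptRecord],
                              rng=None) -> pd.DataFrame:
    """Full-session event table: skeleton + presses + derived pre-switch
    windows (and block-2 fixation-cross presses if an rng is given)."""
    frames = [generate_session_events()]
    for block, record in records.items():
        windows = design.trial_windows(block)
        rows = []
        for k, trial in enumerate(record.trials):
            start = windows[k][0]
            for t, percept in trial:
                rows.append({"onset": start + t, "duration": design.PRESS_DURATION,
                             "trial_type": f"press_block{block}",
                             "percept": percept, "trial_index": k})
        presses = pd.DataFrame(rows)
        frames.append(presses)
        frames.append(design.derive_preswitch_events(
            presses, windows, condition=f"preswitch_block{block}"))
    if rng is not None:  # block-2 responses to the lateralized fixation cross
        rows = []
        windows2 = design.trial_windows(2)
        for k, (start, end) in enumerate(windows2):
            t = start + rng.uniform(1.0, 15.0)
            rows.append({"onset": t, "duration": design.PRESS_DURATION,
                         "trial_type": "press_block2", "percept": None,
                         "trial_index": k})
        presses2 = pd.DataFrame(rows)
        frames.append(presses2)
        frames.append(design.derive_preswitch_events(
            presses2, windows2, condition="preswitch_block2"))
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(["onset", "trial_type"], kind="mergesort",
                                ignore_index=True)
    return design.validate_events(events)


def make_truth_params(config: CohortConfig, cohort: str, rng,
                      max_draws: int = 200) -> DCMParams:
    """Ground-truth model-1 parameters for one subject of a cohort.

    Jittered draws are rejected until the steady-state neuronal deactivation
    under either driving input stays above ``-max_deactivation`` Hz, which
    keeps venous inflow well inside the balloon model's domain even with
    endogenous fluctuations on top.
    """
    for _ in range(max_draws):
        params = _draw_truth_params(config, cohort, rng)
        zmin = 0.0
        # steady states under each driving input, with and without the
        # pre-switch gating engaged (windows can cover much of a trial)
        matrices = (params.A, params.A + params.B[0], params.A + params.B[1])
        for d in range(params.C.shape[1]):
            u = np.zeros(params.C.shape[1])
            u[d] = 1.0
            for M in matrices:
                zmin = min(zmin, float((-np.linalg.solve(M, params.C @ u)).min()))
        if zmin > -config.max_deactivation:
            return params
    raise ValueError("could not draw physiologically plausible ground truth; "
                     "reduce jitter or driving-input magnitudes")


def _draw_truth_params(config: CohortConfig, cohort: str, rng) -> DCMParams:
    n = len(REGIONS)
    A = np.zeros((n, n))
    lin, pre, mtg, iof = range(4)
    for i, j in BOTTOM_UP_EDGES:
        A[i, j] = config.a_forward
    for i, j in TOP_DOWN_EDGES:
        A[i, j] = config.a_backward
    A[pre, lin] = config.a_lin_pre
    A[lin, pre] = config.a_backward
    B = np.zeros((2, n, n))
    for i, j in BOTTOM_UP_EDGES:
        B[0, i, j] = config.b_bottom_up
    # Post-training top-down gating: PRE receives modulation in both cohorts;
    # LIN receives it from MTG only, and only in the older cohort (IOF->LIN
    # stays zero everywhere so the LIN effect is attributable to MTG).
    B[1, pre, mtg] = B[1, pre, iof] = (config.b_top_down_older
                                       if cohort == "older"
                                       else config.b_top_down_young)
    if cohort == "older":
        B[1, lin, mtg] = config.b_mtg_lin_older
    C = np.full((n, 2), config.c_positive)
    if cohort == "young":
        C[lin, 0] = C[pre, 0] = config.c_negative  # pre-training
        C[lin, 1] = config.c_negative              # post-training: LIN only
    else:
        C[lin, 1] = C[iof, 1] = config.c_negative  # post-training LIN + IOF
    # between-subject variability on nonzero entries only (structural zeros,
    # notably the young MTG->LIN modulation, stay exactly zero)
    jit = config.connection_jitter_sd
    A = np.where(A != 0, A + jit * rng.standard_normal(A.shape), 0.0)
    B = np.where(B != 0, B + jit * rng.standard_normal(B.shape), 0.0)
    C = C + jit * rng.standard_normal(C.shape)
    np.fill_diagonal(A, config.a_self
                     * np.exp(config.self_jitter_sd * rng.standard_normal(n)))
    kappa = 0.64 * np.exp(config.hemo_jitter_sd * rng.standard_normal(n))
    tau = 2.0 * np.exp(config.hemo_jitter_sd * rng.standard_normal(n))
    return DCMParams(A=A, B=B, C=C, kappa=kappa, tau=tau,
                     innovation_sd=config.innovation_sd,
                     obs_noise_sd=config.obs_noise_sd)


def generate_subject_bold(events: pd.DataFrame, truth: DCMParams,
                          config: CohortConfig, seed) -> RegionTimeSeries:
    """Simulate the subject's 4-region BOLD under model-1 ground truth."""
    spec = build_model_space()[0]
    truth.conform(spec)
    inputs = design.build_stimulus_functions(events)
    return simulate_bold(spec, truth, inputs,
                         duration=design.session_duration(), tr=design.TR,
                         seed=seed)


def generate_subject(config: CohortConfig, index: int, cohort: str,
                     with_bold: bool = True) -> SyntheticSubject:
    seed = subject_seed(config.master_seed, index)
    rng = np.random.default_rng(seed)
    records = generate_press_streams(config, cohort, rng)
    events = press_events_from_records(records, rng=rng)
    truth = make_truth_params(config, cohort, rng)
    bold = None
    if with_bold:
        bold = generate_subject_bold(events, truth, config,
                                     seed=subject_seed(config.master_seed,
                                                       10_000 + index))
    return SyntheticSubject(subject_id=f"sub-{index + 1:02d}", cohort=cohort,
                            events=events, records=records, bold=bold,
                            truth=truth)


def generate_cohort(config: CohortConfig,
                    with_bold: bool = True) -> list[SyntheticSubject]:
    """The full two-cohort sample: young subjects first, then older."""
    subjects = []
    idx = 0
    for cohort, n in (("young", config.n_young), ("older", config.n_older)):
        for _ in range(n):
            subjects.append(generate_subject(config, idx, cohort, with_bold))
            idx += 1
    return subjects


def generate_roi_voxels(series: np.ndarray, n_voxels: int = 20,
                        loading_spread: float = 0.5, noise_sd: float = 0.0,
                        seed=None, radius_mm: float = 8.0,
                        artifact: np.ndarray | None = None) -> VoxelBlock:
    """Rank-1 voxel block around one region series inside an 8-mm sphere.

    voxel_v = loading_v * series + artifact + noise, with positive loadings.
    ``artifact`` (e.g. a motion regressor) is added to every voxel.
    """
    if n_voxels < 1:
        raise ValueError("need at least one voxel")
    rng = np.random.default_rng(seed)
    loadings = 1.0 + loading_spread * rng.uniform(-1.0, 1.0, size=n_voxels)
    Y = np.outer(series, loadings)
    if artifact is not None:
        Y = Y + np.asarray(artifact, dtype=float)[:, None]
    if noise_sd > 0:
        Y = Y + noise_sd * rng.standard_normal(Y.shape)
    # uniform offsets inside the sphere
    pts = rng.standard_normal((n_voxels, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    offsets = pts * radius_mm * rng.uniform(0, 1, size=(n_voxels, 1)) ** (1 / 3)
    return VoxelBlock(Y=Y, offsets_mm=offsets, radius_mm=radius_mm)


def generate_motion(n_samples: int, seed=None, scale: float = 0.05,
                    n_params: int = 6) -> np.ndarray:
    """Slow random-walk motion parameters (T, 6) for nuisance modeling."""
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_samples, n_params)) * scale
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(8) / 8.0
    smooth = np.column_stack([np.convolve(walk[:, k], kernel, mode="same")
                              for k in range(n_params)])
    return smooth - smooth.mean(axis=0)
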