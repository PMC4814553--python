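"""Desk-scale simulation studies: model/parameter recovery and behavior.

These are the package's headline analyses.  The cohort data of the original
experiment are not deposited, so every quantitative claim the pipeline can
make is property-based: a synthetic cohort is generated under known
model-1 ground truth, pushed through inversion and random-effects BMS, and
the recovered structure is compared with the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior, bms, design, synthetic
from .dcm import build_model_space
from .inversion import InversionOptions, ParamPacker, variational_laplace

MTG_LIN = "B[preswitch_block3][MTG->LIN]"


@dataclass
class RecoveryResult:
    """Raw outputs of the recovery study (one row per subject x model)."""

    evidence: pd.DataFrame
    posteriors: dict                     # (subject, model) -> Posterior
    subjects: list                       # SyntheticSubject, without BOLD kept
    config: synthetic.CohortConfig
    models: tuple[str, ...] = ("model1", "model2", "model3", "model4")
    bms_result: object = None


def run_recovery_study(n_young: int = 6, n_older: int = 6,
                       master_seed: int = 2026,
                       models=("model1", "model2", "model3", "model4"),
                       options: InversionOptions | None = None,
                       bms_seed: int | None = None,
                       progress=None) -> RecoveryResult:
    """Generate a cohort under model-1 truth, invert all candidate models,
    and run random-effects BMS over the evidence."""
    cfg = synthetic.CohortConfig(n_young=n_young, n_older=n_older,
                                 master_seed=master_seed)
    options = options or InversionOptions()
    space = {s.name: s for s in build_model_space()}
    subjects = synthetic.generate_cohort(cfg, with_bold=True)
    rows, posteriors = [], {}
    for sub in subjects:
        inputs = design.build_stimulus_functions(sub.events)
        for name in models:
            post = variational_laplace(space[name], sub.bold, inputs, options)
            post.subject = sub.subject_id
            post.cohort = sub.cohort
            posteriors[(sub.subject_id, name)] = post
            rows.append({"subject": sub.subject_id, "cohort": sub.cohort,
                         "model": name, "free_energy": post.free_energy})
            if progress:
                progress(sub.subject_id, name, post.free_energy)
    evidence = pd.DataFrame(rows)
    result = RecoveryResult(evidence=evidence, posteriors=posteriors,
                            subjects=subjects, config=cfg,
                            models=tuple(models))
    if len(models) >= 2:
        result.bms_result = bms.rfx_bms(
            evidence, seed=master_seed if bms_seed is None else bms_seed)
    return result


def summarize_recovery(result: RecoveryResult) -> dict:
    """Recovery metrics: model selection, parameter correlation, group tests.

    - exceedance probability and per-subject winner counts of the
      generating model (model 1);
    - pooled Pearson correlation between true and posterior-mean A entries;
    - sign-recovery rate of the older cohort's MTG->LIN block-3 modulation;
    - one-sample group tests of that modulation per cohort;
    - mean per-region R^2 of the model-1 fits.
    """
    spec = build_model_space()[0]
    packer = ParamPacker(spec)
    mask = spec.A_mask
    truth_by_id = {s.subject_id: s for s in result.subjects}
    a_true, a_est = [], []
    sign_hits, n_older = 0, 0
    mtg_lin_by_cohort = {"young": [], "older": []}
    r2 = []
    model1_posts = []
    for (sid, model), post in result.posteriors.items():
        if model != "model1":
            continue
        model1_posts.append(post)
        sub = truth_by_id[sid]
        A_hat = packer.to_params(post.means[:packer.n_free]).A
        a_true.extend(sub.truth.A[mask].tolist())
        a_est.extend(A_hat[mask].tolist())
        est = post[MTG_LIN]
        mtg_lin_by_cohort[sub.cohort].append(est)
        if sub.cohort == "older":
            n_older += 1
            if np.sign(est) == np.sign(sub.truth.B[1, 0, 2]):
                sign_hits += 1
        r2.append(post.r2)
    a_corr = float(np.corrcoef(a_true, a_est)[0, 1])
    group = {c: bms.group_parameter_test(model1_posts, MTG_LIN, cohort=c)
             for c in ("young", "older")}
    summary = {
        "a_recovery_pearson_r": a_corr,
        "mtg_lin_sign_recovery_rate": sign_hits / max(n_older, 1),
        "group_mtg_lin": group,
        "mean_r2_per_region": dict(zip(spec.region_names,
                                       np.mean(r2, axis=0).round(4).tolist())),
        "n_subjects": len(result.subjects),
    }
    if result.bms_result is not None:
        res = result.bms_result
        counts = bms.subject_winning_counts(res)
        m1 = res.models.index("model1")
        summary["bms"] = {
            "exceedance": dict(zip(res.models, map(float, res.exceedance))),
            "exceedance_model1": float(res.exceedance[m1]),
            "winning_counts": counts,
            "n_model1_winners": counts["model1"],
        }
    return summary


def run_bias_study(n_young: int = 14, n_older: int = 16,
                   master_seed: int = 2026) -> dict:
    """Behavioral arm at the full cohort sizes (press streams only)."""
    cfg = synthetic.CohortConfig(n_young=n_young, n_older=n_older,
                                 master_seed=master_seed)
    subjects = synthetic.generate_cohort(cfg, with_bold=False)
    rows, records = [], {}
    for sub in subjects:
        summ = behavior.summarize(sub.records)
        records[sub.subject_id] = sub.records
        rows.append({"subject": sub.subject_id, "cohort": sub.cohort,
                     "bias_ratio": summ.bias_ratio,
                     "mean_face_block1_ms": summ.mean_face_ms[1],
                     "mean_face_block3_ms": summ.mean_face_ms[3]})
    table = pd.DataFrame(rows)
    compare = behavior.cohort_compare(table["bias_ratio"].to_numpy(),
                                      table["cohort"].to_numpy())
    included = behavior.filter_subjects(records)
    return {
        "table": table,
        "bias_ratio_mean": {
            c: float(table.loc[table.cohort == c, "bias_ratio"].mean())
            for c in ("young", "older")},
        "mean_face_block3_ms": {
            c: float(table.loc[table.cohort == c, "mean_face_block3_ms"].mean())
            for c in ("young", "older")},
        "cohort_compare": compare,
        "n_included": len(included),
    }
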