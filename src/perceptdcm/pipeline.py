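"""End-to-end pipeline stages over the synthetic cohort.

Each stage is idempotent given identical inputs and seeds and writes
plain-text artifacts (TSV/JSON) into the configured directories.  The CLI
subcommands and the numbered analysis scripts are thin wrappers over these
functions.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, bms, design, glm, io, synthetic
from .config import PipelineConfig
from .dcm import REGIONS, RegionTimeSeries, build_model_space
from .inversion import InversionOptions, variational_laplace

log = logging.getLogger("perceptdcm")

KEEP_EFFECTS = ("amb_block1", "amb_block3",
                "preswitch_block1", "preswitch_block3")


def _subject_dirs(data_dir: Path) -> list[Path]:
    return sorted(p for p in Path(data_dir).glob("sub-*") if p.is_dir())


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{producer}' stage first")
    return path


def stage_simulate(cfg: PipelineConfig, cohort_config=None) -> pd.DataFrame:
    """Generate the synthetic cohort and write per-subject artifacts."""
    cohort_config = cohort_config or synthetic.CohortConfig(
        n_young=cfg.cohort.n_young, n_older=cfg.cohort.n_older,
        master_seed=cfg.cohort.master_seed)
    data_dir = Path(cfg.data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    subjects = synthetic.generate_cohort(cohort_config, with_bold=True)
    manifest = []
    for sub in subjects:
        d = data_dir / sub.subject_id
        d.mkdir(exist_ok=True)
        io.write_events(sub.events, d / "events.tsv")
        io.write_timeseries(sub.bold, d / "bold_regions.tsv")
        io.write_params(sub.truth, d / "truth.json")
        manifest.append({"subject": sub.subject_id, "cohort": sub.cohort})
    mf = pd.DataFrame(manifest)
    mf.to_csv(data_dir / "manifest.tsv", sep="\t", index=False)
    log.info("simulated %d subjects into %s", len(subjects), data_dir)
    return mf


def load_manifest(cfg: PipelineConfig) -> pd.DataFrame:
    path = _require(Path(cfg.data_dir) / "manifest.tsv", "simulate")
    return pd.read_csv(path, sep="\t")


def _records_from_events(events: pd.DataFrame) -> dict[int, behavior.PerceptRecord]:
    records = {}
    for block in (1, 3):
        windows = design.trial_windows(block)
        presses = events[events["trial_type"] == f"press_block{block}"]
        trials = []
        for k, (start, _end) in enumerate(windows):
            sub = presses[presses["trial_index"] == k].sort_values("onset")
            trials.append([(float(r["onset"] - start), r["percept"])
                           for _, r in sub.iterrows()])
        records[block] = behavior.PerceptRecord(
            trials=trials, trial_length=design.BLOCK_STRUCTURE[block][1])
    return records


def stage_behavior(cfg: PipelineConfig) -> dict:
    """Percept-duration summaries, bias ratios, and cohort statistics."""
    manifest = load_manifest(cfg)
    results_dir = Path(cfg.results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    all_records, rows = {}, []
    cohort_of = dict(zip(manifest["subject"], manifest["cohort"]))
    for _, entry in manifest.iterrows():
        events = io.read_events(
            _require(Path(cfg.data_dir) / entry["subject"] / "events.tsv",
                     "simulate"))
        records = _records_from_events(events)
        all_records[entry["subject"]] = records
        summ = behavior.summarize(records)
        rows.append({
            "subject": entry["subject"], "cohort": entry["cohort"],
            "mean_face_block1_ms": summ.mean_face_ms[1],
            "mean_face_block3_ms": summ.mean_face_ms[3],
            "mean_vase_block1_ms": summ.mean_vase_ms[1],
            "mean_vase_block3_ms": summ.mean_vase_ms[3],
            "bias_ratio": summ.bias_ratio,
            "min_switches": min(min(r.switch_counts())
                                for r in records.values()),
        })
    table = pd.DataFrame(rows)
    table.to_csv(results_dir / "behavior_summary.tsv", sep="\t", index=False,
                 float_format="%.12g")
    included = behavior.filter_subjects(all_records)
    compare = behavior.cohort_compare(table["bias_ratio"].to_numpy(),
                                      table["cohort"].to_numpy())
    initial = behavior.initial_percept_test(all_records, cohort_of)
    stats = {
        "n_included": len(included), "n_total": len(table),
        "bias_ratio_mean": {
            c: float(table.loc[table.cohort == c, "bias_ratio"].mean())
            for c in ("young", "older")},
        "mean_face_block3_ms": {
            c: float(table.loc[table.cohort == c, "mean_face_block3_ms"].mean())
            for c in ("young", "older")},
        "cohort_compare": compare,
        "initial_percept": {k: initial[k] for k in ("by_cohort", "by_block")},
    }
    io.write_json(stats, results_dir / "behavior_stats.json")
    return stats


def stage_design(cfg: PipelineConfig) -> None:
    """Write each subject's convolved design matrix (design.tsv)."""
    manifest = load_manifest(cfg)
    T = int(design.session_duration() / cfg.tr)
    for si, entry in manifest.iterrows():
        d = Path(cfg.data_dir) / entry["subject"]
        events = io.read_events(_require(d / "events.tsv", "simulate"))
        seed = synthetic.subject_seed(cfg.cohort.master_seed, 20_000 + si)
        motion = synthetic.generate_motion(T, seed=seed)
        X = design.build_design_matrix(events, motion, T, tr=cfg.tr,
                                       bins_per_tr=cfg.microtime_bins)
        pd.DataFrame(X.X, columns=list(X.labels)).to_csv(
            d / "design.tsv", sep="\t", index=False, float_format="%.12g")


def stage_extract(cfg: PipelineConfig, n_voxels: int = 20,
                  voxel_noise_sd: float = 0.008) -> None:
    """GLM fit, effects-of-interest adjustment, and eigenvariate extraction.

    Synthetic voxel blocks are built around each simulated region series
    with a shared motion artifact; the adjusted principal eigenvariate is
    written per subject as the DCM-ready series.
    """
    manifest = load_manifest(cfg)
    for si, entry in manifest.iterrows():
        d = Path(cfg.data_dir) / entry["subject"]
        events = io.read_events(_require(d / "events.tsv", "simulate"))
        bold = io.read_timeseries(_require(d / "bold_regions.tsv", "simulate"))
        T = bold.n_samples
        seed = synthetic.subject_seed(cfg.cohort.master_seed, 20_000 + si)
        motion = synthetic.generate_motion(T, seed=seed)
        X = design.build_design_matrix(events, motion, T, tr=cfg.tr,
                                       bins_per_tr=cfg.microtime_bins)
        eig, frac = np.zeros((T, len(REGIONS))), []
        for r, region in enumerate(REGIONS):
            block = synthetic.generate_roi_voxels(
                bold.Y[:, r], n_voxels=n_voxels, noise_sd=voxel_noise_sd,
                seed=seed + r + 1, artifact=0.002 * motion[:, 0])
            fit = glm.fit_glm(block.Y, X)
            adjusted = glm.adjust_effects_of_interest(block.Y, fit, KEEP_EFFECTS)
            series, f = glm.principal_eigenvariate(
                glm.VoxelBlock(Y=adjusted, offsets_mm=block.offsets_mm,
                               radius_mm=block.radius_mm))
            eig[:, r] = series
            frac.append(f)
        ts = RegionTimeSeries(Y=eig, tr=cfg.tr)
        io.write_timeseries(ts, d / "eigenvariates.tsv")
        io.write_json({"explained_variance": dict(zip(REGIONS, frac))},
                      d / "extraction.json")


def stage_fit(cfg: PipelineConfig, source: str = "bold_regions.tsv",
              models=None) -> pd.DataFrame:
    """Invert every candidate model for every subject; write the evidence
    table and per-subject posteriors."""
    manifest = load_manifest(cfg)
    results_dir = Path(cfg.results_dir)
    results_dir.mkdir(parents=True, exist_ok=True)
    space = {s.name: s
             for s in build_model_space(cfg.include_block2_input)}
    names = models or cfg.models
    opts = InversionOptions(max_iter=cfg.inversion.max_iter,
                            tol=cfg.inversion.tol,
                            ar_coef=cfg.inversion.ar_coef,
                            fd_step=cfg.inversion.fd_step,
                            bins_per_tr=cfg.microtime_bins)
    rows = []
    for _, entry in manifest.iterrows():
        d = Path(cfg.data_dir) / entry["subject"]
        data = io.read_timeseries(_require(d / source, "simulate/extract"))
        events = io.read_events(_require(d / "events.tsv", "simulate"))
        inputs = design.build_stimulus_functions(
            events, include_block2_input=cfg.include_block2_input)
        for name in names:
            post = variational_laplace(space[name], data, inputs, opts)
            post.subject = entry["subject"]
            post.cohort = entry["cohort"]
            io.write_posterior(post, d / f"posterior_{name}.json")
            rows.append({"subject": entry["subject"], "cohort": entry["cohort"],
                         "model": name, "free_energy": post.free_energy,
                         "converged": post.converged,
                         **{f"r2_{reg}": float(post.r2[k])
                            for k, reg in enumerate(REGIONS)}})
            log.info("fit %s %s F=%.1f", entry["subject"], name,
                     post.free_energy)
    table = pd.DataFrame(rows)
    io.write_evidence(table[["subject", "cohort", "model", "free_energy"]],
                      results_dir / "evidence.tsv")
    table.to_csv(results_dir / "fits.tsv", sep="\t", index=False,
                 float_format="%.12g")
    return table


def load_posteriors(cfg: PipelineConfig, model: str = "model1"):
    manifest = load_manifest(cfg)
    posts = []
    for _, entry in manifest.iterrows():
        path = _require(Path(cfg.data_dir) / entry["subject"]
                        / f"posterior_{model}.json", "fit-dcm")
        posts.append(io.read_posterior(path))
    return posts


def stage_bms(cfg: PipelineConfig) -> dict:
    """Random-effects BMS (all subjects and per cohort) plus group tests."""
    results_dir = Path(cfg.results_dir)
    evidence = io.read_evidence(_require(results_dir / "evidence.tsv",
                                         "fit-dcm"))
    out = {}
    for label, sub in (("all", evidence),
                       ("young", evidence[evidence.cohort == "young"]),
                       ("older", evidence[evidence.cohort == "older"])):
        res = bms.rfx_bms(sub, prior_concentration=cfg.bms.prior_concentration,
                          seed=cfg.bms.seed, n_draws=cfg.bms.n_draws)
        io.write_bms_result(res, results_dir / f"bms_{label}.json")
        counts = bms.subject_winning_counts(res)
        out[label] = {"exceedance": dict(zip(res.models,
                                             map(float, res.exceedance))),
                      "winning_counts": counts}
    posts = load_posteriors(cfg, "model1")
    mtg_lin = "B[preswitch_block3][MTG->LIN]"
    group = {}
    for cohort in ("young", "older"):
        group[cohort] = bms.group_parameter_test(posts, mtg_lin, cohort=cohort)
    hemo = bms.hemodynamic_group_compare(posts, REGIONS)
    hemo.to_csv(results_dir / "hemodynamic_tests.tsv", sep="\t", index=False,
                float_format="%.12g")
    out["group_mtg_lin"] = group
    io.write_json(out, results_dir / "bms_summary.json")
    return out


def stage_report(cfg: PipelineConfig) -> dict:
    """Aggregate behavior, fit quality, BMS, and group tests into one
    machine-readable summary plus a Markdown report."""
    results_dir = Path(cfg.results_dir)
    import json
    behavior_stats = json.loads(
        _require(results_dir / "behavior_stats.json", "behavior").read_text())
    fits = pd.read_csv(_require(results_dir / "fits.tsv", "fit-dcm"), sep="\t")
    bms_summary = json.loads(
        _require(results_dir / "bms_summary.json", "bms").read_text())
    r2 = (fits[fits.model == "model1"]
          .groupby("cohort")[[f"r2_{r}" for r in REGIONS]].mean())
    summary = {
        "behavior": behavior_stats,
        "r2_model1_by_cohort": {c: {reg: float(r2.loc[c, f"r2_{reg}"])
                                    for reg in REGIONS}
                                for c in r2.index},
        "bms": bms_summary,
        "config_hash": cfg.config_hash(),
    }
    io.write_json(summary, results_dir / "summary.json")
    lines = ["# Pipeline report", "",
             f"Config hash: `{cfg.config_hash()}`", "",
             "## Behavior",
             f"- mean bias ratio young: "
             f"{behavior_stats['bias_ratio_mean']['young']:.3f}",
             f"- mean bias ratio older: "
             f"{behavior_stats['bias_ratio_mean']['older']:.3f}",
             f"- cohort comparison p = "
             f"{behavior_stats['cohort_compare']['p']:.2g}, Cohen's d = "
             f"{behavior_stats['cohort_compare']['cohens_d']:.2f}", "",
             "## Model-1 fit quality (mean R^2 per region)"]
    for c in r2.index:
        vals = ", ".join(f"{reg}: {r2.loc[c, f'r2_{reg}']:.2f}"
                         for reg in REGIONS)
        lines.append(f"- {c}: {vals}")
    lines += ["", "## Bayesian model selection (exceedance probabilities)"]
    for label, block in bms_summary.items():
        if label == "group_mtg_lin":
            continue
        ex = ", ".join(f"{m}: {v:.4f}" for m, v in block["exceedance"].items())
        lines.append(f"- {label}: {ex}")
    lines += ["", "## MTG->LIN post-training modulation (model 1)"]
    for cohort, res in bms_summary["group_mtg_lin"].items():
        lines.append(f"- {cohort}: mean {res['mean']:.3f} Hz, "
                     f"t = {res['t']:.2f}, p = {res['p']:.2g}")
    (results_dir / "report.md").write_text("\n".join(lines) + "\n")
    return summary
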