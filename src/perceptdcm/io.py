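"""Readers and writers for the pipeline's plain-text artifact formats.

Events use the BIDS events.tsv dialect (tab-delimited, '.' decimal, 'n/a'
for missing); time series are wide TSV with a time column; model
specifications, posteriors, and BMS results are JSON.  All round trips are
lossless at 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import design
from .bms import BMSResult, validate_evidence
from .dcm import DCMParams, DCMSpec, RegionTimeSeries
from .inversion import Posterior

FLOAT_FMT = "%.12g"


def write_events(events: pd.DataFrame, path) -> None:
    design.validate_events(events)
    out = events.copy()
    out = out.rename(columns={"trial_type": "trial_type"})
    out.to_csv(path, sep="\t", index=False, na_rep="n/a",
               float_format=FLOAT_FMT)


def read_events(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", na_values=["n/a"],
                         keep_default_na=False,
                         dtype={"onset": float, "duration": float,
                                "trial_type": str, "percept": object})
    except ValueError as exc:
        raise ValueError(f"malformed events file {path}: {exc}") from exc
    if "trial_index" in df.columns:
        df["trial_index"] = df["trial_index"].astype("Int64")
    df["percept"] = df["percept"].where(df["percept"].notna(), None)
    return design.validate_events(df)


def write_timeseries(ts: RegionTimeSeries, path) -> None:
    df = pd.DataFrame(ts.Y, columns=list(ts.region_names))
    df.insert(0, "time", (np.arange(1, ts.n_samples + 1) * ts.tr))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_timeseries(path) -> RegionTimeSeries:
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns or len(df) < 2:
        raise ValueError(f"malformed time-series file {path}")
    tr = float(df["time"].iloc[1] - df["time"].iloc[0])
    regions = tuple(c for c in df.columns if c != "time")
    return RegionTimeSeries(Y=df[list(regions)].to_numpy(), tr=tr,
                            region_names=regions)


def write_model_spec(spec: DCMSpec, path) -> None:
    payload = {
        "name": spec.name,
        "region_names": list(spec.region_names),
        "driving_names": list(spec.driving_names),
        "modulatory_names": list(spec.modulatory_names),
        "A_mask": np.asarray(spec.A_mask, dtype=int).tolist(),
        "B_masks": np.asarray(spec.B_masks, dtype=int).tolist(),
        "C_mask": np.asarray(spec.C_mask, dtype=int).tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_model_spec(path) -> DCMSpec:
    d = json.loads(Path(path).read_text())
    return DCMSpec(name=d["name"],
                   A_mask=np.asarray(d["A_mask"], dtype=bool),
                   B_masks=np.asarray(d["B_masks"], dtype=bool),
                   C_mask=np.asarray(d["C_mask"], dtype=bool),
                   region_names=tuple(d["region_names"]),
                   driving_names=tuple(d["driving_names"]),
                   modulatory_names=tuple(d["modulatory_names"]))


def write_params(params: DCMParams, path) -> None:
    payload = {k: np.asarray(getattr(params, k)).tolist()
               for k in ("A", "B", "C", "kappa", "gamma", "tau",
                         "alpha", "rho", "V0")}
    payload["innovation_sd"] = params.innovation_sd
    payload["obs_noise_sd"] = params.obs_noise_sd
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_params(path) -> DCMParams:
    d = json.loads(Path(path).read_text())
    return DCMParams(**{k: (np.asarray(v) if isinstance(v, list) else v)
                        for k, v in d.items()})


def write_posterior(post: Posterior, path) -> None:
    payload = {
        "means": post.means.tolist(),
        "cov": post.cov.tolist(),
        "free_energy": post.free_energy,
        "r2": np.asarray(post.r2).tolist(),
        "labels": list(post.labels),
        "spec_name": post.spec_name,
        "converged": post.converged,
        "trace": [float(f) for f in post.trace],
        "subject": post.subject,
        "cohort": post.cohort,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_posterior(path) -> Posterior:
    d = json.loads(Path(path).read_text())
    return Posterior(means=np.asarray(d["means"]), cov=np.asarray(d["cov"]),
                     free_energy=d["free_energy"], r2=np.asarray(d["r2"]),
                     labels=tuple(d["labels"]), spec_name=d["spec_name"],
                     converged=d["converged"], trace=d["trace"],
                     subject=d.get("subject"), cohort=d.get("cohort"))


def write_evidence(evidence: pd.DataFrame, path) -> None:
    validate_evidence(evidence)
    evidence.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_evidence(path) -> pd.DataFrame:
    return validate_evidence(pd.read_csv(path, sep="\t"))


def write_bms_result(result: BMSResult, path) -> None:
    payload = {
        "alpha": result.alpha.tolist(),
        "expected_frequency": result.expected_frequency.tolist(),
        "exceedance": result.exceedance.tolist(),
        "responsibilities": result.responsibilities.tolist(),
        "subjects": list(result.subjects),
        "models": list(result.models),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_bms_result(path) -> BMSResult:
    d = json.loads(Path(path).read_text())
    return BMSResult(alpha=np.asarray(d["alpha"]),
                     expected_frequency=np.asarray(d["expected_frequency"]),
                     exceedance=np.asarray(d["exceedance"]),
                     responsibilities=np.asarray(d["responsibilities"]),
                     subjects=tuple(d["subjects"]), models=tuple(d["models"]))


def write_json(payload: dict, path) -> None:
    """Deterministic JSON (sorted keys, fixed float repr) for summaries."""
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
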