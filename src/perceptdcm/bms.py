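"""Fixed- and random-effects Bayesian model selection and group statistics.

Random-effects BMS treats the model identity as a random variable across
subjects with a Dirichlet population prior; the variational updates on the
Dirichlet concentration follow the standard fixed-point scheme, and
exceedance probabilities (the posterior probability that each model is the
most frequent in the population) are estimated by Monte-Carlo sampling of
the Dirichlet posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, softmax


@dataclass
class BMSResult:
    """Dirichlet posterior over model frequencies and derived summaries."""

    alpha: np.ndarray                  # Dirichlet concentration, length M
    expected_frequency: np.ndarray
    exceedance: np.ndarray
    responsibilities: np.ndarray       # (N, M) per-subject model posteriors
    subjects: tuple[str, ...]
    models: tuple[str, ...]

    def winning_model(self, subject: str) -> str:
        u = self.responsibilities[self.subjects.index(subject)]
        return self.models[int(np.argmax(u))]


def validate_evidence(evidence: pd.DataFrame) -> pd.DataFrame:
    """Evidence table: one row per subject x model with columns
    (subject, cohort, model, free_energy)."""
    need = {"subject", "cohort", "model", "free_energy"}
    missing = need - set(evidence.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    if not np.isfinite(evidence["free_energy"]).all():
        raise ValueError("free energies must be finite")
    return evidence


def _evidence_matrix(evidence: pd.DataFrame):
    validate_evidence(evidence)
    pivot = evidence.pivot(index="subject", columns="model", values="free_energy")
    if pivot.isna().any().any():
        raise ValueError("every subject needs an evidence for every model")
    return pivot.to_numpy(), tuple(pivot.index), tuple(pivot.columns)


def exceedance_probabilities(alpha: np.ndarray, n_draws: int = 1_000_000,
                             seed=None) -> np.ndarray:
    """Monte-Carlo P(model k has the largest population frequency)."""
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_draws)
    wins = np.bincount(np.argmax(draws, axis=1), minlength=alpha.size)
    return wins / n_draws


def rfx_bms(evidence: pd.DataFrame, prior_concentration: float = 1.0,
            seed=None, n_draws: int = 1_000_000, tol: float = 1e-6,
            max_iter: int = 10_000) -> BMSResult:
    """Random-effects BMS via variational Dirichlet-multinomial updates.

    Subject responsibilities u_nk ∝ exp(F_nk + psi(alpha_k) - psi(sum alpha));
    alpha_k = alpha0 + sum_n u_nk, iterated to |d alpha| < tol.
    """
    F, subjects, models = _evidence_matrix(evidence)
    N, M = F.shape
    if M < 2:
        raise ValueError("random-effects BMS needs at least two models")
    alpha = np.full(M, float(prior_concentration))
    for _ in range(max_iter):
        logu = F + digamma(alpha) - digamma(alpha.sum())
        u = softmax(logu, axis=1)
        alpha_new = prior_concentration + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    logu = F + digamma(alpha) - digamma(alpha.sum())
    u = softmax(logu, axis=1)
    return BMSResult(
        alpha=alpha,
        expected_frequency=alpha / alpha.sum(),
        exceedance=exceedance_probabilities(alpha, n_draws=n_draws, seed=seed),
        responsibilities=u,
        subjects=subjects,
        models=models,
    )


def ffx_bms(evidence: pd.DataFrame):
    """Fixed-effects BMS: group log-evidence column sums and posterior model
    probabilities under a uniform model prior."""
    F, _, models = _evidence_matrix(evidence)
    group = F.sum(axis=0)
    post = softmax(group)
    return pd.DataFrame({"model": models, "log_evidence": group,
                         "posterior": post})


def subject_winning_counts(result: BMSResult,
                           cohort_of: dict[str, str] | None = None,
                           cohort: str | None = None) -> dict[str, int]:
    """Per-model tallies of subjects' argmax posterior model probabilities.

    Exact ties break deterministically to the lowest model index (warned).
    """
    counts = {m: 0 for m in result.models}
    for i, subj in enumerate(result.subjects):
        if cohort is not None and cohort_of is not None \
                and cohort_of[subj] != cohort:
            continue
        u = result.responsibilities[i]
        best = int(np.argmax(u))
        if np.sum(u == u[best]) > 1:
            warnings.warn(f"tied model posteriors for subject {subj}; "
                          "breaking tie to the lowest model index", stacklevel=2)
        counts[result.models[best]] += 1
    return counts


def _address_values(posteriors, address: str) -> np.ndarray:
    vals = []
    for p in posteriors:
        if address not in p.labels:
            raise KeyError(f"parameter {address!r} is not free in model "
                           f"{p.spec_name}")
        vals.append(p[address])
    return np.asarray(vals)


def group_parameter_test(posteriors, address: str,
                         cohort: str | None = None) -> dict:
    """One-sample two-sided t-test of posterior means against zero.

    The classical summary-statistic approach: each subject contributes the
    posterior mean of the addressed parameter (e.g.
    ``B[preswitch_block3][MTG->LIN]``).  Also reports Cohen's d = mean / sd.
    """
    if cohort is not None:
        posteriors = [p for p in posteriors if p.cohort == cohort]
    if len(posteriors) < 2:
        raise ValueError("need at least two subjects for a group test")
    x = _address_values(posteriors, address)
    sd = x.std(ddof=1)
    degenerate = sd == 0
    if degenerate:
        t, p = (np.inf if x.mean() != 0 else 0.0), (0.0 if x.mean() != 0 else 1.0)
        d = np.inf if x.mean() != 0 else 0.0
    else:
        t, p = stats.ttest_1samp(x, 0.0)
        d = x.mean() / sd
    return {"t": float(t), "p": float(p), "mean": float(x.mean()),
            "cohens_d": float(d), "n": len(x), "degenerate": bool(degenerate)}


HEMO_PARAMS = ("log_kappa", "log_tau")  # signal decay and transit time


def hemodynamic_group_compare(posteriors, region_names) -> pd.DataFrame:
    """Welch two-sample tests of decay and transit time between cohorts.

    Eight tests (2 hemodynamic parameters x 4 regions) on the per-subject
    posterior means; p-values are reported uncorrected.
    """
    cohorts = sorted({p.cohort for p in posteriors})
    if len(cohorts) != 2:
        raise ValueError("exactly two cohorts required")
    rows = []
    for par in HEMO_PARAMS:
        for region in region_names:
            address = f"{par}[{region}]"
            groups = [
                _address_values([p for p in posteriors if p.cohort == c], address)
                for c in cohorts
            ]
            if min(len(g) for g in groups) < 2:
                raise ValueError("both cohorts need at least two subjects")
            if np.allclose(groups[0].std(), 0) and np.allclose(groups[1].std(), 0) \
                    and np.allclose(groups[0].mean(), groups[1].mean()):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
            rows.append({"parameter": par, "region": region,
                         "t": float(t), "p_uncorrected": float(p),
                         f"mean_{cohorts[0]}": float(groups[0].mean()),
                         f"mean_{cohorts[1]}": float(groups[1].mean())})
    return pd.DataFrame(rows)
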