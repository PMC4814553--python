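"""Variational-Laplace inversion of the deterministic DCM forward model.

Endogenous neuronal fluctuations in the generative (stochastic) model are
absorbed at inversion time by an AR(1)-correlated observation-noise model
with a single shared log-precision hyperparameter.  Estimation maximizes the
Laplace free energy

    F = log p(y | theta) - KL terms  (accuracy minus complexity),

by Gauss-Newton ascent with Levenberg-Marquardt damping and monotone step
rejection; gradients of the forward model are obtained by central finite
differences integrated in one batch.  F is the model-evidence bound used for
Bayesian model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dcm
from .dcm import (DCMParams, DCMSpec, RegionTimeSeries, SELF_CONNECTION_SCALE,
                  StimulusFunctions, integrate_batch)

# Prior variances of the free parameters.
PRIOR_VAR_A_OFFDIAG = 1.0 / 16.0
PRIOR_VAR_A_SELF = 1.0 / 16.0
PRIOR_VAR_B = 1.0 / 4.0
PRIOR_VAR_C = 1.0
PRIOR_VAR_HEMO = 1.0 / 64.0
PRIOR_MEAN_LOGPREC = 4.0
PRIOR_VAR_LOGPREC = 1.0 / 2.0
LOG_PRECISION_LABEL = "log_precision"


class ParamPacker:
    """Bijection between a model's free-parameter vector and DCMParams.

    Layout: off-diagonal A entries, self-connection log-scalings
    (A_ii = -0.5 exp(theta)), B entries per modulator, C entries, per-region
    log-scalings of signal decay kappa and transit time tau.  The shared
    observation log-precision is appended by ``pack_priors`` but handled as a
    hyperparameter by the optimizer.
    """

    def __init__(self, spec: DCMSpec):
        self.spec = spec
        n = spec.n_regions
        regions = spec.region_names
        self.labels: list[str] = []
        self._a_off: list[tuple[int, int]] = []
        offdiag = ~np.eye(n, dtype=bool)
        for i in range(n):
            for j in range(n):
                if offdiag[i, j] and spec.A_mask[i, j]:
                    self._a_off.append((i, j))
                    self.labels.append(f"A[{regions[j]}->{regions[i]}]")
        for r in regions:
            self.labels.append(f"A_self[{r}]")
        self._b: list[tuple[int, int, int]] = []
        for m, mod in enumerate(spec.modulatory_names):
            for i in range(n):
                for j in range(n):
                    if spec.B_masks[m, i, j]:
                        self._b.append((m, i, j))
                        self.labels.append(f"B[{mod}][{regions[j]}->{regions[i]}]")
        self._c: list[tuple[int, int]] = []
        for d, drv in enumerate(spec.driving_names):
            for i in range(n):
                if spec.C_mask[i, d]:
                    self._c.append((i, d))
                    self.labels.append(f"C[{drv}][{regions[i]}]")
        for r in regions:
            self.labels.append(f"log_kappa[{r}]")
        for r in regions:
            self.labels.append(f"log_tau[{r}]")
        self.n_free = len(self.labels)
        na, ns, nb, nc = len(self._a_off), n, len(self._b), len(self._c)
        self.sl_a_off = slice(0, na)
        self.sl_a_self = slice(na, na + ns)
        self.sl_b = slice(na + ns, na + ns + nb)
        self.sl_c = slice(na + ns + nb, na + ns + nb + nc)
        self.sl_kappa = slice(na + ns + nb + nc, na + ns + nb + nc + n)
        self.sl_tau = slice(na + ns + nb + nc + n, na + ns + nb + nc + 2 * n)

    def prior_moments(self) -> tuple[np.ndarray, np.ndarray]:
        mean = np.zeros(self.n_free)
        var = np.empty(self.n_free)
        var[self.sl_a_off] = PRIOR_VAR_A_OFFDIAG
        var[self.sl_a_self] = PRIOR_VAR_A_SELF
        var[self.sl_b] = PRIOR_VAR_B
        var[self.sl_c] = PRIOR_VAR_C
        var[self.sl_kappa] = PRIOR_VAR_HEMO
        var[self.sl_tau] = PRIOR_VAR_HEMO
        return mean, var

    def to_arrays(self, Theta: np.ndarray):
        """Batched (P, ...) parameter arrays for the integration kernel."""
        Theta = np.atleast_2d(Theta)
        P = Theta.shape[0]
        n = self.spec.n_regions
        M = len(self.spec.modulatory_names)
        Jd = len(self.spec.driving_names)
        A = np.zeros((P, n, n))
        for k, (i, j) in enumerate(self._a_off):
            A[:, i, j] = Theta[:, self.sl_a_off][:, k]
        selfs = SELF_CONNECTION_SCALE * np.exp(Theta[:, self.sl_a_self])
        for r in range(n):
            A[:, r, r] = selfs[:, r]
        B = np.zeros((P, M, n, n))
        for k, (m, i, j) in enumerate(self._b):
            B[:, m, i, j] = Theta[:, self.sl_b][:, k]
        C = np.zeros((P, n, Jd))
        for k, (i, d) in enumerate(self._c):
            C[:, i, d] = Theta[:, self.sl_c][:, k]
        kappa = dcm.DEFAULT_KAPPA * np.exp(Theta[:, self.sl_kappa])
        tau = dcm.DEFAULT_TAU * np.exp(Theta[:, self.sl_tau])
        gamma = np.full((P, n), dcm.DEFAULT_GAMMA)
        alpha = np.full((P, n), dcm.DEFAULT_ALPHA)
        rho = np.full((P, n), dcm.DEFAULT_RHO)
        V0 = np.full((P, n), dcm.DEFAULT_V0)
        return A, B, C, kappa, gamma, tau, alpha, rho, V0

    def to_params(self, theta: np.ndarray, innovation_sd: float = 0.0,
                  obs_noise_sd: float = 0.0) -> DCMParams:
        A, B, C, kappa, gamma, tau, alpha, rho, V0 = self.to_arrays(theta)
        return DCMParams(A=A[0], B=B[0], C=C[0], kappa=kappa[0], gamma=gamma[0],
                         tau=tau[0], alpha=alpha[0], rho=rho[0], V0=V0[0],
                         innovation_sd=innovation_sd, obs_noise_sd=obs_noise_sd)

    def from_params(self, params: DCMParams) -> np.ndarray:
        """Free vector reproducing ``params`` (connectivity and kappa/tau)."""
        theta = np.zeros(self.n_free)
        th = theta  # alias
        th[self.sl_a_off] = [params.A[i, j] for i, j in self._a_off]
        th[self.sl_a_self] = np.log(np.diag(params.A) / SELF_CONNECTION_SCALE)
        th[self.sl_b] = [params.B[m, i, j] for m, i, j in self._b]
        th[self.sl_c] = [params.C[i, d] for i, d in self._c]
        th[self.sl_kappa] = np.log(params.kappa / dcm.DEFAULT_KAPPA)
        th[self.sl_tau] = np.log(params.tau / dcm.DEFAULT_TAU)
        return theta

    def prior_variance_of(self, kind: str, *address) -> float:
        """Prior variance for any candidate entry; structurally absent -> 0.

        ``kind`` is 'A', 'B' or 'C'; the address is (i, j), (m, i, j) or
        (i, d) in matrix index form.
        """
        if kind == "A":
            i, j = address
            if i == j:
                return PRIOR_VAR_A_SELF
            return PRIOR_VAR_A_OFFDIAG if self.spec.A_mask[i, j] else 0.0
        if kind == "B":
            m, i, j = address
            return PRIOR_VAR_B if self.spec.B_masks[m, i, j] else 0.0
        if kind == "C":
            i, d = address
            return PRIOR_VAR_C if self.spec.C_mask[i, d] else 0.0
        raise ValueError(f"unknown parameter kind {kind!r}")


def pack_priors(spec: DCMSpec):
    """Prior moments over the full free-parameter vector (incl. log-precision).

    Returns (packer, mean, variance) where the last element of mean/variance
    is the shared observation log-precision.
    """
    packer = ParamPacker(spec)
    mean, var = packer.prior_moments()
    mean = np.append(mean, PRIOR_MEAN_LOGPREC)
    var = np.append(var, PRIOR_VAR_LOGPREC)
    return packer, mean, var


@dataclass
class InversionOptions:
    max_iter: int = 64
    tol: float = 1e-2           # nats; converged after 3 successive small steps
    fd_step: float = 1e-4       # central finite-difference step
    ar_coef: float = 0.8        # fixed AR(1) coefficient of the noise model
                            # (matches the lag-1 autocorrelation of
                            # innovation-driven BOLD residuals at TR 2 s)
    fix_noise_log_precision: float | None = None
    bins_per_tr: int = dcm.MICROTIME_BINS_PER_TR
    init: np.ndarray | None = None
    seed: int | None = None     # reserved for stochastic restarts


@dataclass
class Posterior:
    """Posterior moments, free energy, and fit diagnostics for one model."""

    means: np.ndarray             # free parameters + log-precision (last)
    cov: np.ndarray
    free_energy: float
    r2: np.ndarray                # per-region coefficient of determination
    labels: tuple[str, ...]
    spec_name: str
    converged: bool
    trace: list = field(default_factory=list)
    prediction: np.ndarray | None = None
    subject: str | None = None
    cohort: str | None = None

    def __getitem__(self, label: str) -> float:
        return float(self.means[self.labels.index(label)])


def _whiten(R: np.ndarray, a: float) -> np.ndarray:
    """AR(1) whitening along axis 0: first sample scaled, then lag-1 diffs."""
    W = np.empty_like(R)
    W[0] = np.sqrt(1.0 - a * a) * R[0]
    W[1:] = R[1:] - a * R[:-1]
    return W


def laplace_fit(forward_batch, prior_mean: np.ndarray, prior_var: np.ndarray,
                Y: np.ndarray, options: InversionOptions) -> dict:
    """Gauss-Newton/EM ascent on the Laplace free energy.

    ``forward_batch`` maps a (P, d) parameter matrix to (P, T, n)
    predictions; priors are over the d model parameters.  The observation
    log-precision hyperparameter is updated analytically unless fixed via
    ``options.fix_noise_log_precision``.  Returns a dict with the posterior
    moments over the model parameters, the log-precision moments, F, and the
    iteration trace.
    """
    Y = np.asarray(Y, dtype=float)
    T, n = Y.shape
    nT = T * n
    a = options.ar_coef
    mu = np.asarray(prior_mean, dtype=float)
    Pi = np.diag(1.0 / np.asarray(prior_var, dtype=float))
    d = mu.size
    theta = mu.copy() if options.init is None else np.asarray(options.init, float).copy()
    h_fixed = options.fix_noise_log_precision is not None
    h = options.fix_noise_log_precision if h_fixed else PRIOR_MEAN_LOGPREC
    pi_h = 1.0 / PRIOR_VAR_LOGPREC
    const = -0.5 * nT * np.log(2.0 * np.pi) + 0.5 * n * np.log(1.0 - a * a)

    def forward_and_jacobian(th):
        step = options.fd_step
        Theta = np.vstack([th, th + step * np.eye(d), th - step * np.eye(d)])
        G = forward_batch(Theta)
        g0 = G[0]
        J = (G[1:d + 1] - G[d + 1:]) / (2.0 * step)  # (d, T, n)
        Jw = _whiten(np.moveaxis(J, 0, -1), a).reshape(nT, d)
        return g0, Jw

    def update_h(h0, rss, trJJ_term):
        if h_fixed:
            return h0
        hh = h0
        for _ in range(12):
            E = rss + np.exp(-hh) * trJJ_term(hh)
            val = nT - 2.0 * pi_h * (hh - PRIOR_MEAN_LOGPREC)
            if val <= 0:
                break
            new = np.log(val / E)
            if abs(new - hh) < 1e-9:
                hh = new
                break
            hh = new
        return hh

    def free_energy(dtheta, rss, hh, H_logdet, H_for_trace, JtJ):
        F = -0.5 * np.exp(hh) * rss + 0.5 * nT * hh + const
        F += -0.5 * dtheta @ Pi @ dtheta
        F += -0.5 * H_logdet + 0.5 * np.sum(np.log(np.diag(Pi)))
        if not h_fixed:
            Sig = np.linalg.inv(H_for_trace)
            Ebar = rss + np.trace(Sig @ JtJ)
            post_var_h = 1.0 / (0.5 * np.exp(hh) * Ebar + pi_h)
            F += (-0.5 * pi_h * (hh - PRIOR_MEAN_LOGPREC) ** 2
                  + 0.5 * np.log(post_var_h) + 0.5 * np.log(pi_h))
        return F

    g0, Jw = forward_and_jacobian(theta)
    rw = _whiten(Y - g0, a).ravel()
    rss = float(rw @ rw)
    JtJ = Jw.T @ Jw

    def trJJ_term(hh):
        Sig = np.linalg.inv(np.exp(hh) * JtJ + Pi)
        return np.exp(hh) * np.trace(Sig @ JtJ)

    h = update_h(h, rss, trJJ_term)
    H = np.exp(h) * JtJ + Pi
    logdetH = np.linalg.slogdet(H)[1]
    F = free_energy(theta - mu, rss, h, logdetH, H, np.exp(h) * JtJ)
    trace = [F]
    lm = 1e-4
    converged = False
    small_steps = 0
    for _ in range(options.max_iter):
        grad = np.exp(h) * (Jw.T @ rw) - Pi @ (theta - mu)
        accepted = False
        for _attempt in range(9):
            Hd = H + lm * np.diag(np.diag(H))
            try:
                step = np.linalg.solve(Hd, grad)
            except np.linalg.LinAlgError:
                lm *= 8.0
                continue
            cand = theta + step
            try:
                g_c = forward_batch(cand[None])[0]
            except FloatingPointError:
                lm *= 8.0  # candidate left the stable regime
                continue
            rw_c = _whiten(Y - g_c, a).ravel()
            rss_c = float(rw_c @ rw_c)
            h_c = update_h(h, rss_c, trJJ_term)
            F_c = free_energy(cand - mu, rss_c, h_c, logdetH, H, np.exp(h_c) * JtJ)
            if F_c > F:
                accepted = True
                lm = max(lm / 4.0, 1e-8)
                break
            lm *= 8.0
        if not accepted:
            # no damped step improves F: the scheme is at a local maximum
            converged = True
            break
        dF = F_c - F
        state = (theta, h, F, g0, Jw, rw, rss, JtJ, H, logdetH)
        theta, h, F = cand, h_c, F_c
        try:
            g0, Jw = forward_and_jacobian(theta)
        except FloatingPointError:
            # accepted point sits at the edge of stability; keep the last
            # iterate whose curvature we could evaluate
            theta, h, F, g0, Jw, rw, rss, JtJ, H, logdetH = state
            break
        rw = _whiten(Y - g0, a).ravel()
        rss = float(rw @ rw)
        JtJ = Jw.T @ Jw
        H = np.exp(h) * JtJ + Pi
        logdetH = np.linalg.slogdet(H)[1]
        F = free_energy(theta - mu, rss, h, logdetH, H, np.exp(h) * JtJ)
        trace.append(F)
        small_steps = small_steps + 1 if abs(dF) < options.tol else 0
        if small_steps >= 3:
            converged = True
            break
    else:
        converged = small_steps >= 3

    cov_theta = np.linalg.inv(H)
    if h_fixed:
        means = theta
        cov = cov_theta
    else:
        Ebar = rss + np.trace(cov_theta @ (np.exp(h) * JtJ))
        var_h = 1.0 / (0.5 * np.exp(h) * Ebar + pi_h)
        means = np.append(theta, h)
        cov = np.zeros((d + 1, d + 1))
        cov[:d, :d] = cov_theta
        cov[d, d] = var_h
    return {"means": means, "cov": cov, "free_energy": float(F),
            "prediction": g0, "trace": trace, "converged": converged}


def variational_laplace(spec: DCMSpec, data: RegionTimeSeries,
                        inputs: StimulusFunctions,
                        options: InversionOptions | None = None) -> Posterior:
    """Invert one subject's region time series under one candidate model."""
    options = options or InversionOptions()
    packer = ParamPacker(spec)
    mean, var = packer.prior_moments()
    T = data.n_samples
    dt = data.tr / options.bins_per_tr
    if abs(inputs.dt - dt) > 1e-12:
        raise ValueError("stimulus grid must match TR / bins_per_tr")
    S = T * options.bins_per_tr
    if inputs.U.shape[0] < S:
        raise ValueError("inputs do not cover the data")
    names = [*spec.driving_names, *spec.modulatory_names]
    U = np.column_stack([inputs.column(nm) for nm in names])[:S]
    U = np.ascontiguousarray(U)

    def forward_batch(Theta):
        A, B, C, kappa, gamma, tau, alpha, rho, V0 = packer.to_arrays(Theta)
        return integrate_batch(A, B, C, U, kappa, gamma, tau, alpha, rho, V0,
                               dt, options.bins_per_tr, None, T)

    res = laplace_fit(forward_batch, mean, var, data.Y, options)
    labels = tuple(packer.labels) + ((LOG_PRECISION_LABEL,)
                                     if options.fix_noise_log_precision is None else ())
    post = Posterior(means=res["means"], cov=res["cov"],
                     free_energy=res["free_energy"],
                     r2=np.zeros(spec.n_regions), labels=labels,
                     spec_name=spec.name, converged=res["converged"],
                     trace=res["trace"], prediction=res["prediction"])
    post.r2 = fit_metrics(post, data)
    return post


def fit_metrics(posterior: Posterior, data: RegionTimeSeries) -> np.ndarray:
    """Per-region coefficient of determination R^2 = 1 - RSS/TSS.

    Computed from the posterior-mean prediction; negative values (fits worse
    than the data mean) are reported as-is.
    """
    if posterior.prediction is None:
        raise ValueError("posterior carries no prediction")
    Y = data.Y
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    if np.any(tss == 0):
        raise ValueError("zero-variance data series")
    rss = ((Y - posterior.prediction) ** 2).sum(axis=0)
    return 1.0 - rss / tss
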