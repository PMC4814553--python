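"""Bilinear DCM data model and the stochastic neuronal/hemodynamic forward model.

The network has four regions — lingual gyrus (LIN), precuneus (PRE), middle
temporal gyrus (MTG), inferior orbitofrontal cortex (IOF) — reciprocally
connected except between MTG and IOF.  Two driving inputs (ambiguous-stimulus
boxcars of the pre- and post-training blocks) enter all regions; two
modulatory inputs (2-s pre-switch windows of the same two blocks) gate
specific connections, and the four candidate gating patterns define the model
space.

Neuronal dynamics are bilinear,

    dz/dt = (A + sum_j u_j B^(j)) z + C u_driving + innovations,

and each region's activity drives a balloon-Windkessel hemodynamic cascade
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q) read
out through the classical nonlinear BOLD equation.  Integration is
Euler-Maruyama on a microtime grid of TR/16; the deterministic model is the
zero-innovation limit of the same scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

REGIONS = ("LIN", "PRE", "MTG", "IOF")
MNI_PEAKS = {
    "LIN": (-6.0, -68.0, -2.0),
    "PRE": (-12.0, -70.0, 36.0),
    "MTG": (50.0, 30.0, -6.0),
    "IOF": (62.0, -22.0, -6.0),
}
DRIVING_INPUTS = ("amb_block1", "amb_block3")
MODULATORY_INPUTS = ("preswitch_block1", "preswitch_block3")
N_REGIONS = 4
MICROTIME_BINS_PER_TR = 16

# Directed edges (to, from) with region order LIN, PRE, MTG, IOF.
BOTTOM_UP_EDGES = ((2, 0), (3, 0), (2, 1), (3, 1))
TOP_DOWN_EDGES = ((0, 2), (1, 2), (0, 3), (1, 3))

# Balloon-Windkessel defaults: signal decay kappa (1/s), flow feedback gamma
# (1/s), transit time tau (s), stiffness alpha, resting O2 extraction rho,
# resting venous volume fraction V0; classical 1.5T-style BOLD coefficients.
DEFAULT_KAPPA = 0.64
DEFAULT_GAMMA = 0.32
DEFAULT_TAU = 2.0
DEFAULT_ALPHA = 0.32
DEFAULT_RHO = 0.32
DEFAULT_V0 = 0.04
SELF_CONNECTION_SCALE = -0.5  # A_ii = -0.5 * exp(theta_self), structurally stable


def bold_coefficients(rho: float) -> tuple[float, float, float]:
    """BOLD readout coefficients k1, k2, k3 for resting extraction ``rho``."""
    return 7.0 * rho, 2.0, 2.0 * rho - 0.2


@dataclass(frozen=True)
class DCMSpec:
    """Structure of one candidate model: masks over A, B, C plus metadata."""

    name: str
    A_mask: np.ndarray  # (n, n) bool
    B_masks: np.ndarray  # (n_mod, n, n) bool
    C_mask: np.ndarray  # (n, n_driving) bool
    region_names: tuple[str, ...] = REGIONS
    driving_names: tuple[str, ...] = DRIVING_INPUTS
    modulatory_names: tuple[str, ...] = MODULATORY_INPUTS

    def __post_init__(self) -> None:
        n = len(self.region_names)
        A = np.asarray(self.A_mask, dtype=bool)
        if A.shape != (n, n):
            raise ValueError("A_mask shape mismatch")
        if not A.diagonal().all():
            raise ValueError("A_mask diagonal must be all True (self-connections)")
        if not np.array_equal(A, A.T):
            raise ValueError("A_mask sparsity must be symmetric (reciprocal connections)")
        for m, Bm in enumerate(np.asarray(self.B_masks, dtype=bool)):
            if Bm[~A].any():
                raise ValueError(f"B_mask[{m}] allows an edge absent from A_mask")
            if Bm.diagonal().any():
                raise ValueError(f"B_mask[{m}] may not modulate self-connections")
        C = np.asarray(self.C_mask, dtype=bool)
        if C.shape != (n, len(self.driving_names)):
            raise ValueError("C_mask shape mismatch")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def region_index(self, name: str) -> int:
        return self.region_names.index(name)


@dataclass
class DCMParams:
    """Numeric parameters of one model realization.

    Connectivity rates are in Hz; hemodynamic parameters are per region.
    ``innovation_sd`` scales endogenous neuronal fluctuations (Hz^0.5, i.e.
    the diffusion coefficient of the Euler-Maruyama innovations) and
    ``obs_noise_sd`` is additive white observation noise in BOLD signal units.
    """

    A: np.ndarray
    B: np.ndarray  # (n_mod, n, n)
    C: np.ndarray  # (n, n_driving)
    kappa: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, DEFAULT_KAPPA))
    gamma: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, DEFAULT_GAMMA))
    tau: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, DEFAULT_TAU))
    alpha: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, DEFAULT_ALPHA))
    rho: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, DEFAULT_RHO))
    V0: np.ndarray = field(default_factory=lambda: np.full(N_REGIONS, DEFAULT_V0))
    innovation_sd: float = 0.0
    obs_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "V0"):
            setattr(self, name, np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (self.A.shape[0],)).copy())
        self.validate()

    def validate(self) -> None:
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("A diagonal must be strictly negative for stability")
        for name in ("kappa", "gamma", "tau", "V0"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if np.any((self.alpha <= 0) | (self.alpha >= 1)):
            raise ValueError("alpha must lie in (0, 1)")
        if np.any((self.rho <= 0) | (self.rho >= 1)):
            raise ValueError("rho must lie in (0, 1)")
        if self.innovation_sd < 0 or self.obs_noise_sd < 0:
            raise ValueError("noise scales must be nonnegative")

    def conform(self, spec: DCMSpec) -> None:
        """Raise if any parameter outside the spec masks is nonzero."""
        offdiag = ~np.eye(spec.n_regions, dtype=bool)
        if np.any(self.A[offdiag & ~spec.A_mask] != 0):
            raise ValueError("A has entries outside the spec mask")
        for m in range(self.B.shape[0]):
            if np.any(self.B[m][~spec.B_masks[m]] != 0):
                raise ValueError(f"B[{m}] has entries outside the spec mask")
        if np.any(self.C[~spec.C_mask] != 0):
            raise ValueError("C has entries outside the spec mask")

    def copy(self) -> "DCMParams":
        return replace(
            self,
            A=self.A.copy(), B=self.B.copy(), C=self.C.copy(),
            kappa=self.kappa.copy(), gamma=self.gamma.copy(), tau=self.tau.copy(),
            alpha=self.alpha.copy(), rho=self.rho.copy(), V0=self.V0.copy(),
        )


@dataclass
class NeuronalState:
    """Neuronal activity plus the four hemodynamic states per region.

    Rest is z = 0, s = 0, f = v = q = 1; f, v, q must stay positive.
    """

    z: np.ndarray
    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @classmethod
    def rest(cls, n: int = N_REGIONS) -> "NeuronalState":
        return cls(z=np.zeros(n), s=np.zeros(n),
                   f=np.ones(n), v=np.ones(n), q=np.ones(n))


@dataclass
class StimulusFunctions:
    """Unconvolved {0,1} input step functions on a shared microtime grid."""

    dt: float
    names: tuple[str, ...]
    U: np.ndarray  # (n_bins, n_inputs) values in {0, 1}
    offset: float = 0.0  # alignment (s) of grid start to the first BOLD sample

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        if self.U.ndim != 2 or self.U.shape[1] != len(self.names):
            raise ValueError("U must be (n_bins, n_inputs)")
        if not np.isin(self.U, (0.0, 1.0)).all():
            raise ValueError("stimulus functions must be binary")

    def column(self, name: str) -> np.ndarray:
        return self.U[:, self.names.index(name)]

    @property
    def duration(self) -> float:
        return self.U.shape[0] * self.dt


@dataclass
class RegionTimeSeries:
    """BOLD samples (T, n_regions) at a fixed repetition time."""

    Y: np.ndarray
    tr: float
    region_names: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != len(self.region_names):
            raise ValueError("Y must be (T, n_regions)")

    @property
    def n_samples(self) -> int:
        return self.Y.shape[0]


def _edge_mask(edges) -> np.ndarray:
    M = np.zeros((N_REGIONS, N_REGIONS), dtype=bool)
    for i, j in edges:
        M[i, j] = True
    return M


def build_model_space(include_block2_input: bool = False) -> list[DCMSpec]:
    """The four candidate models over pre-switch modulation direction.

    Model 1: bottom-up gating pre-training, top-down gating post-training.
    Model 2: both directions in both blocks.  Model 3: bottom-up only in
    both.  Model 4: top-down only in both.  A and C structure is shared.

    By default the non-ambiguous training block contributes no input and
    the full session is modeled; ``include_block2_input`` adds its boxcar
    as a third driving input to all regions.
    """
    A_mask = np.ones((N_REGIONS, N_REGIONS), dtype=bool)
    mtg, iof = REGIONS.index("MTG"), REGIONS.index("IOF")
    A_mask[mtg, iof] = A_mask[iof, mtg] = False
    driving = DRIVING_INPUTS + (("nonamb_block2",) if include_block2_input
                                else ())
    C_mask = np.ones((N_REGIONS, len(driving)), dtype=bool)

    bu = _edge_mask(BOTTOM_UP_EDGES)
    td = _edge_mask(TOP_DOWN_EDGES)
    both = bu | td
    patterns = {
        "model1": (bu, td),
        "model2": (both, both),
        "model3": (bu, bu),
        "model4": (td, td),
    }
    return [
        DCMSpec(name=name, A_mask=A_mask, B_masks=np.stack([b1, b3]),
                C_mask=C_mask, driving_names=driving)
        for name, (b1, b3) in patterns.items()
    ]


def neuronal_drift(state: NeuronalState, u: np.ndarray, params: DCMParams) -> np.ndarray:
    """dz/dt = (A + sum_j u_mod_j B_j) z + C u_driving.

    ``u`` holds driving inputs first, then modulatory inputs, matching the
    spec's input ordering.
    """
    n_drv = params.C.shape[1]
    u = np.asarray(u, dtype=float)
    if u.shape != (n_drv + params.B.shape[0],):
        raise ValueError("input vector length mismatch")
    u_drv, u_mod = u[:n_drv], u[n_drv:]
    Aeff = params.A + np.tensordot(u_mod, params.B, axes=1)
    return Aeff @ state.z + params.C @ u_drv


def hemodynamic_drift(state: NeuronalState, params: DCMParams) -> tuple[np.ndarray, ...]:
    """Balloon-Windkessel derivatives (ds, df, dv, dq)/dt per region."""
    if np.any(state.f <= 0) or np.any(state.v <= 0) or np.any(state.q <= 0):
        raise FloatingPointError("hemodynamic states f, v, q must stay positive")
    s, f, v, q = state.s, state.f, state.v, state.q
    ds = state.z - params.kappa * s - params.gamma * (f - 1.0)
    df = s
    fv = v ** (1.0 / params.alpha)  # outflow
    dv = (f - fv) / params.tau
    E = 1.0 - (1.0 - params.rho) ** (1.0 / f)  # oxygen extraction at inflow f
    dq = (f * E / params.rho - fv * q / v) / params.tau
    return ds, df, dv, dq


def bold_observation(state: NeuronalState, params: DCMParams) -> np.ndarray:
    """Nonlinear BOLD readout; exactly zero at rest (v = q = 1)."""
    y = np.empty(len(state.v))
    for i in range(len(state.v)):
        k1, k2, k3 = bold_coefficients(params.rho[i])
        y[i] = params.V0[i] * (
            k1 * (1.0 - state.q[i])
            + k2 * (1.0 - state.q[i] / state.v[i])
            + k3 * (1.0 - state.v[i])
        )
    return y


@njit(cache=True)
def _integrate_kernel(A, B, C, U, kappa, gamma, tau, alpha, rho, V0,
                      dt, stride, noise, y_out):  # pragma: no cover - jit
    """Euler-Maruyama integration for a batch of parameter sets.

    A: (P,n,n); B: (P,M,n,n); C: (P,n,Jd); U: (S, Jd+M) driving then
    modulatory; noise: (S,n) pre-scaled innovations shared across the batch;
    y_out: (P,T,n) BOLD sampled every ``stride`` microtime steps.

    The hemodynamic states f, v, q are integrated in log space so their
    positivity is structural (the drift of log x is dx/dt / x); the scheme
    agrees with plain Euler to first order and keeps the forward model
    well-defined for arbitrary candidate parameters during inversion.
    Returns 0 on success, 2 on divergence.
    """
    P, n, _ = A.shape
    M = B.shape[1]
    Jd = C.shape[2]
    S = U.shape[0]
    dz = np.zeros(n)
    for p in range(P):
        z = np.zeros(n)
        s = np.zeros(n)
        lf = np.zeros(n)  # log inflow
        lv = np.zeros(n)  # log volume
        lq = np.zeros(n)  # log deoxyhemoglobin
        k = 0
        for t in range(S):
            for i in range(n):
                acc = 0.0
                for j in range(n):
                    a = A[p, i, j]
                    for m in range(M):
                        a += U[t, Jd + m] * B[p, m, i, j]
                    acc += a * z[j]
                for d in range(Jd):
                    acc += C[p, i, d] * U[t, d]
                dz[i] = acc
            for i in range(n):
                # derivatives from pre-update states
                f = np.exp(lf[i])
                v = np.exp(lv[i])
                q = np.exp(lq[i])
                fv = v ** (1.0 / alpha[p, i])
                E = 1.0 - (1.0 - rho[p, i]) ** (1.0 / f)
                ds = z[i] - kappa[p, i] * s[i] - gamma[p, i] * (f - 1.0)
                dlf = s[i] / f
                dlv = (f - fv) / (tau[p, i] * v)
                dlq = (f * E / rho[p, i] - fv * q / v) / (tau[p, i] * q)
                z[i] += dt * dz[i] + noise[t, i]
                s[i] += dt * ds
                lf[i] += dt * dlf
                lv[i] += dt * dlv
                lq[i] += dt * dlq
                if abs(z[i]) > 1e6 or abs(lf[i]) > 20.0 or abs(lv[i]) > 20.0 \
                        or abs(lq[i]) > 20.0:
                    return 2
            if (t + 1) % stride == 0:
                for i in range(n):
                    k1 = 7.0 * rho[p, i]
                    k2 = 2.0
                    k3 = 2.0 * rho[p, i] - 0.2
                    v = np.exp(lv[i])
                    q = np.exp(lq[i])
                    y_out[p, k, i] = V0[p, i] * (
                        k1 * (1.0 - q)
                        + k2 * (1.0 - q / v)
                        + k3 * (1.0 - v)
                    )
                k += 1
    return 0


def integrate_batch(A, B, C, U, kappa, gamma, tau, alpha, rho, V0,
                    dt: float, stride: int, noise: np.ndarray | None,
                    n_samples: int) -> np.ndarray:
    """Integrate a batch of parameter sets over shared inputs; returns (P,T,n)."""
    A = np.ascontiguousarray(A, dtype=float)
    P, n = A.shape[0], A.shape[1]
    if noise is None:
        noise = np.zeros((U.shape[0], n))
    y = np.zeros((P, n_samples, n))
    status = _integrate_kernel(
        A, np.ascontiguousarray(B, dtype=float), np.ascontiguousarray(C, dtype=float),
        np.ascontiguousarray(U, dtype=float),
        np.ascontiguousarray(kappa, dtype=float), np.ascontiguousarray(gamma, dtype=float),
        np.ascontiguousarray(tau, dtype=float), np.ascontiguousarray(alpha, dtype=float),
        np.ascontiguousarray(rho, dtype=float), np.ascontiguousarray(V0, dtype=float),
        float(dt), int(stride), np.ascontiguousarray(noise, dtype=float), y)
    if status == 2:
        raise FloatingPointError(
            "neuronal states diverged; A is likely unstable (check its eigenvalues "
            "and B modulation magnitudes)")
    return y


def simulate_bold(spec: DCMSpec, params: DCMParams, inputs: StimulusFunctions,
                  duration: float, tr: float, seed=None,
                  bins_per_tr: int = MICROTIME_BINS_PER_TR) -> RegionTimeSeries:
    """Simulate region BOLD at repetition time ``tr`` from a model realization.

    Neuronal innovations of scale ``params.innovation_sd`` enter the neuronal
    states only; observation noise of scale ``params.obs_noise_sd`` is added
    to the sampled BOLD.  The same seed with the same inputs yields
    bit-identical output.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    params.conform(spec)
    dt = tr / bins_per_tr
    if abs(inputs.dt - dt) > 1e-12:
        raise ValueError(f"stimulus grid step {inputs.dt} must equal TR/{bins_per_tr}")
    n_samples = int(round(duration / tr))
    S = n_samples * bins_per_tr
    if inputs.U.shape[0] < S:
        raise ValueError("stimulus functions do not cover the requested duration")
    expected = [*spec.driving_names, *spec.modulatory_names]
    U = np.column_stack([inputs.column(name) for name in expected])[:S]

    rng = np.random.default_rng(seed)
    n = spec.n_regions
    if params.innovation_sd > 0:
        noise = params.innovation_sd * np.sqrt(dt) * rng.standard_normal((S, n))
    else:
        noise = np.zeros((S, n))
    y = integrate_batch(
        params.A[None], params.B[None], params.C[None], U,
        params.kappa[None], params.gamma[None], params.tau[None],
        params.alpha[None], params.rho[None], params.V0[None],
        dt, bins_per_tr, noise, n_samples)[0]
    if params.obs_noise_sd > 0:
        y = y + params.obs_noise_sd * rng.standard_normal(y.shape)
    return RegionTimeSeries(Y=y, tr=tr, region_names=spec.region_names)


def simulate_neuronal(params: DCMParams, inputs: StimulusFunctions,
                      n_steps: int | None = None) -> np.ndarray:
    """Neuronal trajectory z(t) on the microtime grid (deterministic Euler).

    Uses the same explicit-Euler recursion as the full integrator,
    z_{t+1} = z_t + dt ((A + sum u_mod B) z_t + C u_drv); useful for
    checking the linear regime against its matrix-exponential closed form.
    """
    n_drv = params.C.shape[1]
    U = inputs.U if n_steps is None else inputs.U[:n_steps]
    z = np.zeros(params.A.shape[0])
    out = np.empty((U.shape[0], z.size))
    for t in range(U.shape[0]):
        u_drv, u_mod = U[t, :n_drv], U[t, n_drv:]
        Aeff = params.A + np.tensordot(u_mod, params.B, axes=1)
        z = z + inputs.dt * (Aeff @ z + params.C @ u_drv)
        out[t] = z
    return out


def check_stability(params: DCMParams) -> None:
    """Warn if the intrinsic coupling matrix has a non-negative eigenvalue."""
    lam = np.linalg.eigvals(params.A).real
    if lam.max() >= 0:
        warnings.warn(f"A has a non-negative eigenvalue ({lam.max():.3f}); "
                      "simulations may diverge", stacklevel=2)
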