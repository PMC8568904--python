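"""Heterogeneous dynamic mean-field model on a structural connectome.

Each cortical region is described by a single synaptic gating variable
``S_i`` obeying a reduced (Wong-Wang type) neural-mass equation

    dS_i/dt = -S_i/tau_s + r (1 - S_i) H(x_i) + sigma_i v_i(t)

with sigmoidal-rational transfer function ``H`` and total input current

    x_i = w_i J S_i + G J sum_j C_ij S_j + I_i.

The *parametric* mean-field model (pMFM) constrains the regional recurrent
strength ``w_i``, external input ``I_i`` and noise amplitude ``sigma_i`` to
be linear combinations of two cortical gradient maps (a T1w/T2w myelin-like
map and the principal FC gradient), leaving 10 free quantities: three
coefficients per parameter plus the global coupling ``G``. Neural activity
is converted to BOLD with the nonlinear Balloon-Windkessel hemodynamic
model and downsampled to the fMRI repetition time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .exceptions import (
    DivergenceError,
    InfeasibleParametersError,
    InvalidInputError,
)

__all__ = [
    "ModelConstants",
    "HemodynamicConstants",
    "Connectome",
    "SpatialMap",
    "LinearCoefficients",
    "RegionalParameters",
    "SimulationConfig",
    "NeuralTrajectory",
    "BoldTimeseries",
    "transfer_function",
    "build_regional_parameters",
    "integrate_mfm",
    "balloon_windkessel",
    "simulate_bold",
    "n_free_parameters",
    "relaxed_state",
    "jacobian_abscissa",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed circuit constants of the mean-field equations.

    Defaults follow the mean-field reduction of the spiking attractor
    network commonly used for whole-brain modelling: synaptic coupling
    J = 0.2609 nA, gain a = 270 n/C, threshold b = 108 Hz, curvature
    d = 0.154 s, kinetic rate r = 0.641 and synaptic time constant
    tau_s = 0.1 s.
    """

    J: float = 0.2609
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    r_kin: float = 0.641
    tau_s: float = 0.1

    def __post_init__(self) -> None:
        for name in ("J", "a", "b", "d", "r_kin", "tau_s"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"model constant {name} must be strictly positive")


@dataclass(frozen=True)
class HemodynamicConstants:
    """Balloon-Windkessel constants (3 T BOLD coefficients).

    kappa: vasodilatory signal decay rate (s^-1); gamma: flow-dependent
    feedback rate (s^-1); tau: hemodynamic transit time (s); alpha:
    Grubb's vessel stiffness exponent; rho: resting oxygen extraction
    fraction; V0: resting venous blood volume fraction; k1..k3: field-
    strength-dependent BOLD signal coefficients.
    """

    kappa: float = 0.65
    gamma: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    rho: float = 0.34
    V0: float = 0.02
    k1: float = 3.72
    k2: float = 0.527
    k3: float = 0.53

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "V0"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"hemodynamic constant {name} must be positive")


@dataclass(frozen=True)
class Connectome:
    """Structural-connectivity matrix with region labels.

    ``C`` must be square, nonnegative, symmetric (within 1e-9) with a zero
    diagonal; ``region_ids`` fixes the region ordering shared by every
    other per-region object.
    """

    C: np.ndarray
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "C", C)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise InvalidInputError(f"connectome must be square, got shape {C.shape}")
        if C.shape[0] < 2:
            raise InvalidInputError("connectome needs at least 2 regions")
        if not np.all(np.isfinite(C)):
            raise InvalidInputError("connectome contains non-finite entries")
        if np.any(C < 0):
            raise InvalidInputError("connectome weights must be nonnegative")
        if np.any(np.abs(np.diag(C)) > 0):
            raise InvalidInputError("connectome diagonal must be zero")
        if not np.allclose(C, C.T, atol=1e-9, rtol=0):
            raise InvalidInputError("connectome must be symmetric within 1e-9")
        if not self.region_ids:
            object.__setattr__(
                self, "region_ids", tuple(f"region_{i}" for i in range(C.shape[0]))
            )
        elif len(self.region_ids) != C.shape[0]:
            raise InvalidInputError("region_ids length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.C.shape[0]


@dataclass(frozen=True)
class SpatialMap:
    """One scalar value per region, in connectome region order."""

    values: np.ndarray
    name: str = "map"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise InvalidInputError("spatial map must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError(f"spatial map {self.name!r} has non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LinearCoefficients:
    """The 10 free quantities of the pMFM.

    Each regional parameter is an affine function of the two maps, e.g.
    w_i = a_w * Mye_i + b_w * Grad_i + c_w; G is the global coupling.
    """

    a_w: float = 0.0
    b_w: float = 0.0
    c_w: float = 0.0
    a_I: float = 0.0
    b_I: float = 0.0
    c_I: float = 0.0
    a_sigma: float = 0.0
    b_sigma: float = 0.0
    c_sigma: float = 0.0
    G: float = 0.0

    N_FREE = 10

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise InvalidInputError("coefficients must be finite")
        if self.G < 0:
            raise InvalidInputError("global coupling G must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a_w, self.b_w, self.c_w, self.a_I, self.b_I, self.c_I,
             self.a_sigma, self.b_sigma, self.c_sigma, self.G]
        )

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "LinearCoefficients":
        x = np.asarray(x, dtype=float)
        if x.shape != (10,):
            raise InvalidInputError("expected exactly 10 coefficient values")
        return cls(*x)


@dataclass(frozen=True)
class RegionalParameters:
    """Per-region circuit parameters plus the global coupling G."""

    w: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    G: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        I = np.asarray(self.I, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "I", I)
        object.__setattr__(self, "sigma", sigma)
        n = w.shape[0]
        if I.shape != (n,) or sigma.shape != (n,):
            raise InvalidInputError("w, I, sigma must share one length")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(I)) and np.all(np.isfinite(sigma))):
            raise InfeasibleParametersError("regional parameters contain non-finite values")
        if np.any(w <= 0):
            raise InfeasibleParametersError("all recurrent strengths w_i must be > 0")
        if np.any(sigma <= 0):
            raise InfeasibleParametersError("all noise amplitudes sigma_i must be > 0")
        if not self.G >= 0:
            raise InfeasibleParametersError("global coupling G must be >= 0")

    @property
    def n_regions(self) -> int:
        return self.w.shape[0]

    def concatenated_maps(self) -> np.ndarray:
        """Concatenated (w, I, sigma) vector used for map-similarity checks."""
        return np.concatenate([self.w, self.I, self.sigma])


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and sampling protocol.

    dt: Euler step (s); t_total: simulated duration (s); t_burn: BOLD
    prefix discarded (s); tr: fMRI sampling period (s), an integer
    multiple of dt; seed: RNG seed for noise and initial conditions.
    Defaults reproduce the 16.4-min protocol with a 2-min burn-in and
    TR = 0.72 s, yielding 1200 output frames.
    """

    dt: float = 0.01
    t_total: float = 16.4 * 60.0
    t_burn: float = 2.0 * 60.0
    tr: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise InvalidInputError("dt must be positive")
        ratio = self.tr / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise InvalidInputError(
                f"tr={self.tr} must be a positive integer multiple of dt={self.dt}"
            )
        if not (0 <= self.t_burn < self.t_total):
            raise InvalidInputError("require 0 <= t_burn < t_total")

    @property
    def steps_per_frame(self) -> int:
        return round(self.tr / self.dt)

    @property
    def n_steps(self) -> int:
        return round(self.t_total / self.dt)

    @property
    def n_frames(self) -> int:
        """Output frames: one per TR boundary after the burn-in."""
        return int(np.floor((self.t_total - self.t_burn) / self.tr + 1e-9))


@dataclass(frozen=True)
class NeuralTrajectory:
    """Synaptic gating S (N x K, integrator resolution, entries in [0,1])."""

    S: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        if S.ndim != 2:
            raise InvalidInputError("trajectory must be 2-D (regions x steps)")
        if np.any(S < -1e-12) or np.any(S > 1 + 1e-12):
            raise InvalidInputError("gating values must lie in [0, 1]")


@dataclass(frozen=True)
class BoldTimeseries:
    """Region x frame BOLD matrix sampled at period ``tr`` seconds."""

    B: np.ndarray
    tr: float
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        object.__setattr__(self, "B", B)
        if B.ndim != 2 or B.shape[1] < 2:
            raise InvalidInputError("BOLD matrix must be 2-D with at least 2 frames")
        if not np.all(np.isfinite(B)):
            raise InvalidInputError("BOLD matrix has non-finite entries")
        if not self.region_ids:
            object.__setattr__(
                self, "region_ids", tuple(f"region_{i}" for i in range(B.shape[0]))
            )

    @property
    def n_regions(self) -> int:
        return self.B.shape[0]

    @property
    def n_frames(self) -> int:
        return self.B.shape[1]


def transfer_function(x, constants: ModelConstants = ModelConstants()):
    """Population transfer function H(x) = (a x - b) / (1 - exp(-d (a x - b))).

    Continuous at the removable singularity a*x = b where H = 1/d. Accepts
    scalars or arrays; strictly positive and strictly increasing, with
    H(x) -> a x - b for large inputs.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("transfer_function requires finite input currents")
    u = constants.a * x - constants.b
    with np.errstate(over="ignore"):
        denom = 1.0 - np.exp(-constants.d * u)
    out = np.where(np.abs(u) < 1e-9, 1.0 / constants.d, u / np.where(denom == 0, 1.0, denom))
    return out if out.ndim else float(out)


def n_free_parameters(n_regions: int, parametric: bool = True) -> int:
    """Free-parameter count: 10 for the pMFM (3 coefficients per regional
    parameter plus G), 3*N + 1 for the unconstrained heterogeneous model
    where w, I and sigma vary independently per region."""
    if parametric:
        return LinearCoefficients.N_FREE
    return 3 * n_regions + 1


def build_regional_parameters(
    coeffs: LinearCoefficients,
    myelin: SpatialMap,
    gradient: SpatialMap,
) -> RegionalParameters:
    """Expand the 10 linear coefficients into per-region (w, I, sigma).

    Raises :class:`InfeasibleParametersError` if any resulting w_i or
    sigma_i is non-positive; the fitting layer converts that into a
    sentinel cost.
    """
    if len(myelin) != len(gradient):
        raise InvalidInputError("myelin and gradient maps must share length")
    mye, grad = myelin.values, gradient.values
    w = coeffs.a_w * mye + coeffs.b_w * grad + coeffs.c_w
    I = coeffs.a_I * mye + coeffs.b_I * grad + coeffs.c_I
    sigma = coeffs.a_sigma * mye + coeffs.b_sigma * grad + coeffs.c_sigma
    return RegionalParameters(w=w, I=I, sigma=sigma, G=coeffs.G)


def _initial_state(n_regions: int, rng: np.random.Generator) -> np.ndarray:
    # random initialization of the gating variables
    return rng.uniform(0.0, 1.0, size=n_regions)


def integrate_mfm(
    params: RegionalParameters,
    sc: Connectome,
    constants: ModelConstants = ModelConstants(),
    config: SimulationConfig = SimulationConfig(),
    s0: np.ndarray | None = None,
    noise: np.ndarray | None = None,
) -> NeuralTrajectory:
    """Euler-Maruyama integration of the coupled mean-field equations.

    The Gaussian increments are pre-drawn from ``config.seed`` (unless an
    explicit ``noise`` array of shape (N, n_steps) is supplied, e.g. for
    counterfactual perturbation runs); the update is
    S_{t+dt} = clip(S_t + dt*drift + sigma_i*sqrt(dt)*xi, 0, 1).
    """
    n = params.n_regions
    if sc.n_regions != n:
        raise InvalidInputError(
            f"parameter length {n} does not match connectome size {sc.n_regions}"
        )
    rng = np.random.default_rng(config.seed)
    if s0 is None:
        s0 = _initial_state(n, rng)
    else:
        s0 = np.asarray(s0, dtype=float)
        if s0.shape != (n,):
            raise InvalidInputError("initial state length mismatch")
    if noise is None:
        noise = rng.standard_normal((n, config.n_steps))
    else:
        noise = np.asarray(noise, dtype=float)
        if noise.shape != (n, config.n_steps):
            raise InvalidInputError("noise array must have shape (N, n_steps)")
    S = _kernels.euler_maruyama_mfm(
        np.ascontiguousarray(s0),
        np.ascontiguousarray(noise),
        np.ascontiguousarray(sc.C),
        np.ascontiguousarray(params.w),
        np.ascontiguousarray(params.I),
        np.ascontiguousarray(params.sigma),
        float(params.G),
        constants.J,
        constants.a,
        constants.b,
        constants.d,
        constants.r_kin,
        constants.tau_s,
        config.dt,
    )
    if not np.all(np.isfinite(S)):
        bad = int(np.argwhere(~np.all(np.isfinite(S), axis=0))[0, 0])
        raise DivergenceError(f"non-finite neural state at step {bad}", step=bad)
    return NeuralTrajectory(S=S, dt=config.dt)


def balloon_windkessel(
    neural: NeuralTrajectory,
    hemo_constants: HemodynamicConstants = HemodynamicConstants(),
    dt: float | None = None,
) -> np.ndarray:
    """Convert synaptic gating to BOLD at integrator resolution.

    Per region, integrates the vasodilatory signal s, inflow f, volume v
    and deoxyhemoglobin q from rest (s=0, f=v=q=1) with Euler steps, then
    reads out BOLD = V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v)). Deterministic
    given the neural input; regions are independent.
    """
    if dt is None:
        dt = neural.dt
    z = np.ascontiguousarray(neural.S)
    bold = _kernels.euler_balloon(
        z, float(dt),
        hemo_constants.kappa, hemo_constants.gamma, hemo_constants.tau,
        hemo_constants.alpha, hemo_constants.rho, hemo_constants.V0,
        hemo_constants.k1, hemo_constants.k2, hemo_constants.k3,
    )
    if not np.all(np.isfinite(bold)):
        bad = int(np.argwhere(~np.all(np.isfinite(bold), axis=0))[0, 0])
        raise DivergenceError(f"hemodynamic state left its admissible range at step {bad}", step=bad)
    return bold


def downsample_bold(
    bold_fine: np.ndarray,
    config: SimulationConfig,
    region_ids: tuple[str, ...] = (),
) -> BoldTimeseries:
    """Discard the burn-in and keep the instantaneous sample at every TR
    boundary: frame m (1-based) is the sample at t = t_burn + m*tr."""
    spf = config.steps_per_frame
    burn_steps = round(config.t_burn / config.dt)
    idx = burn_steps + spf * np.arange(1, config.n_frames + 1)
    if idx[-1] >= bold_fine.shape[1]:
        raise InvalidInputError("trajectory shorter than the configured protocol")
    return BoldTimeseries(B=bold_fine[:, idx], tr=config.tr, region_ids=region_ids)


def relaxed_state(
    params: RegionalParameters,
    sc: Connectome,
    constants: ModelConstants = ModelConstants(),
    t_relax: float = 40.0,
    s0: float = 0.5,
) -> np.ndarray:
    """Noiseless attractor reached from a uniform initial state.

    Integrates the deterministic drift for ``t_relax`` seconds from
    S(0) = s0 and returns the terminal gating vector — the operating
    point the stochastic simulation fluctuates around.
    """
    cfg = SimulationConfig(dt=0.01, t_total=t_relax, t_burn=0.0, tr=0.72, seed=0)
    traj = integrate_mfm(
        params, sc, constants, cfg,
        s0=np.full(params.n_regions, s0),
        noise=np.zeros((params.n_regions, cfg.n_steps)),
    )
    return traj.S[:, -1]


def jacobian_abscissa(
    params: RegionalParameters,
    sc: Connectome,
    constants: ModelConstants = ModelConstants(),
    state: np.ndarray | None = None,
) -> float:
    """Spectral abscissa (largest real eigenvalue part) of the drift
    Jacobian at ``state`` (default: the noiseless relaxed state).

    Values near zero mean slow, spatially structured fluctuations — the
    near-critical regime where the simulated BOLD carries strong
    functional-connectivity structure.
    """
    if state is None:
        state = relaxed_state(params, sc, constants)
    S = np.asarray(state, dtype=float)
    c = constants
    W = np.diag(params.w * c.J) + params.G * c.J * sc.C
    x = W @ S + params.I
    H = np.asarray(transfer_function(x, c))
    eps = 1e-6
    Hd = (np.asarray(transfer_function(x + eps, c))
          - np.asarray(transfer_function(x - eps, c))) / (2 * eps)
    Jm = np.diag(-1.0 / c.tau_s - c.r_kin * H) + (c.r_kin * (1 - S) * Hd)[:, None] * W
    return float(np.linalg.eigvals(Jm).real.max())


def simulate_bold(
    coeffs: LinearCoefficients,
    sc: Connectome,
    maps: tuple[SpatialMap, SpatialMap],
    constants: ModelConstants = ModelConstants(),
    config: SimulationConfig = SimulationConfig(),
    hemo_constants: HemodynamicConstants = HemodynamicConstants(),
) -> BoldTimeseries:
    """Full forward model: coefficients -> regional parameters -> neural
    trajectory -> Balloon-Windkessel BOLD -> burn-in removal and TR
    downsampling. Bit-reproducible for a fixed config seed."""
    myelin, gradient = maps
    params = build_regional_parameters(coeffs, myelin, gradient)
    neural = integrate_mfm(params, sc, constants, config)
    bold_fine = balloon_windkessel(neural, hemo_constants, config.dt)
    return downsample_bold(bold_fine, config, sc.region_ids)
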