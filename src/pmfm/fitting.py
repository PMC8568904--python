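"""CMA-ES inversion of the pMFM against target FC and FCD.

The 10 free quantities (three linear coefficients for each of w, I, sigma
plus the global coupling G) are estimated by minimizing the overall cost
(1 - r) + KS on training targets. Optimization is repeated from several
random initializations; all evaluated candidates are pooled, re-scored on
validation targets, and a small diverse top set is selected greedily,
skipping candidates whose regional parameter maps are nearly collinear
(correlation >= 0.98) with an already selected one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import cmaes
from .dynamics import (
    Connectome,
    LinearCoefficients,
    ModelConstants,
    SimulationConfig,
    SpatialMap,
    build_regional_parameters,
    simulate_bold,
)
from .exceptions import (
    DivergenceError,
    FitFailureError,
    InfeasibleParametersError,
    InvalidInputError,
)
from .observables import (
    DEFAULT_WINDOW,
    FCMatrix,
    FcdPdf,
    average_fcd_pdf,
    fc_agreement,
    ks_distance,
    sliding_window_fcd,
    static_fc,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitTargets",
    "Candidate",
    "CandidateSet",
    "ParameterBounds",
    "evaluate_candidate",
    "fit_cmaes",
    "select_top_diverse",
]

#: cost assigned to infeasible or diverging parameter sets (the maximum of
#: the default-weight cost (1 - r) + KS)
SENTINEL_COST = 3.0


@dataclass(frozen=True)
class FitTargets:
    """Target observables plus the substrate they are evaluated on."""

    fc_target: FCMatrix
    fcd_pdf_target: FcdPdf
    sc: Connectome
    maps: tuple[SpatialMap, SpatialMap]

    def __post_init__(self) -> None:
        n = self.sc.n_regions
        if self.fc_target.n_regions != n:
            raise InvalidInputError("target FC size does not match connectome")
        if len(self.maps[0]) != n or len(self.maps[1]) != n:
            raise InvalidInputError("spatial map length does not match connectome")


@dataclass(frozen=True)
class Candidate:
    coeffs: LinearCoefficients
    train_cost: float
    validation_cost: float | None = None
    restart: int = 0
    iteration: int = 0


@dataclass
class CandidateSet:
    candidates: list[Candidate] = field(default_factory=list)

    def feasible(self) -> list[Candidate]:
        return [c for c in self.candidates if c.train_cost < SENTINEL_COST]

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class ParameterBounds:
    """Search box for the 10 coefficients.

    Regional values are kept in physiological ranges w in (0, 10),
    I in (0, 1), sigma in (0.0005, 0.05), G in (0, 8); offsets (c terms)
    span the value range while slopes (a, b terms, applied to z-scored
    maps) span plus/minus half the range.
    """

    w_range: tuple[float, float] = (0.0, 10.0)
    I_range: tuple[float, float] = (0.0, 1.0)
    sigma_range: tuple[float, float] = (0.0005, 0.05)
    G_range: tuple[float, float] = (0.0, 8.0)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lower, upper = [], []
        for lo, hi in (self.w_range, self.I_range, self.sigma_range):
            half = (hi - lo) / 2
            lower += [-half, -half, lo]
            upper += [half, half, hi]
        # reorder: groups are (a, b, c) per parameter, then G
        lower.append(self.G_range[0])
        upper.append(self.G_range[1])
        return np.array(lower), np.array(upper)


def evaluate_candidate(
    coeffs: LinearCoefficients,
    targets: FitTargets,
    n_sims: int = 3,
    seed: int = 0,
    config: SimulationConfig = SimulationConfig(),
    constants: ModelConstants = ModelConstants(),
    fcd_window: int = DEFAULT_WINDOW,
    weight_fc: float = 1.0,
    weight_fcd: float = 1.0,
) -> tuple[float, float, float]:
    """Score one coefficient set: (r, KS, cost).

    Runs ``n_sims`` simulations with the fixed seed schedule seed, seed+1,
    ..., averages the simulated FC matrices entrywise and the FCD pdfs,
    and compares them with the targets. Infeasible coefficients (some
    w_i or sigma_i <= 0) and diverging simulations return the sentinel
    cost without/despite simulation.
    """
    if n_sims < 1:
        raise InvalidInputError("n_sims must be >= 1")
    myelin, gradient = targets.maps
    try:
        build_regional_parameters(coeffs, myelin, gradient)
    except InfeasibleParametersError:
        return np.nan, np.nan, SENTINEL_COST
    fcs, pdfs = [], []
    try:
        for i in range(n_sims):
            cfg = SimulationConfig(
                dt=config.dt, t_total=config.t_total, t_burn=config.t_burn,
                tr=config.tr, seed=seed + i,
            )
            bold = simulate_bold(coeffs, targets.sc, targets.maps, constants, cfg)
            fcs.append(static_fc(bold).values)
            pdfs.append(sliding_window_fcd(bold, window=fcd_window).pdf())
    except DivergenceError as exc:
        logger.warning("simulation diverged for candidate %s: %s", coeffs, exc)
        return np.nan, np.nan, SENTINEL_COST
    fc_mean = np.mean(fcs, axis=0)
    np.fill_diagonal(fc_mean, 1.0)
    fc_sim = FCMatrix(values=np.clip(fc_mean, -1, 1), region_ids=targets.sc.region_ids)
    pdf_sim = average_fcd_pdf(pdfs)
    r = fc_agreement(fc_sim, targets.fc_target)
    ks = ks_distance(pdf_sim, targets.fcd_pdf_target)
    total = weight_fc * (1.0 - r) + weight_fcd * ks
    return float(r), float(ks), float(total)


def fit_cmaes(
    targets: FitTargets,
    iterations: int = 500,
    restarts: int = 10,
    seed: int = 0,
    bounds: ParameterBounds = ParameterBounds(),
    popsize: int | None = None,
    n_sims: int = 3,
    config: SimulationConfig = SimulationConfig(),
    constants: ModelConstants = ModelConstants(),
    fcd_window: int = DEFAULT_WINDOW,
    weight_fc: float = 1.0,
    weight_fcd: float = 1.0,
) -> CandidateSet:
    """Run CMA-ES ``restarts`` times for ``iterations`` generations each,
    from random initial means inside the search box, logging every
    evaluated candidate with its training cost."""
    if iterations < 1 or restarts < 1:
        raise InvalidInputError("iterations and restarts must be >= 1")
    lower, upper = bounds.arrays()
    out = CandidateSet()
    for rep in range(restarts):
        rng = np.random.default_rng(seed + 1000 * rep)
        x0 = rng.uniform(lower, upper)
        sigma0 = 0.2 * (upper - lower)

        def objective(x):
            _, _, c = evaluate_candidate(
                LinearCoefficients.from_array(x), targets,
                n_sims=n_sims, seed=seed, config=config, constants=constants,
                fcd_window=fcd_window, weight_fc=weight_fc, weight_fcd=weight_fcd,
            )
            return c

        res = cmaes.minimize(
            objective, x0, sigma0, iterations,
            seed=seed + 1000 * rep + 1, popsize=popsize, bounds=(lower, upper),
        )
        for x, f, it in res.candidates:
            out.candidates.append(
                Candidate(
                    coeffs=LinearCoefficients.from_array(x),
                    train_cost=float(f), restart=rep, iteration=it,
                )
            )
    if not out.feasible():
        raise FitFailureError("every evaluated candidate was infeasible")
    return out


def _similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of concatenated z-scored (w, I, sigma) maps."""
    if np.array_equal(a, b):
        return 1.0
    if a.std() < 1e-15 or b.std() < 1e-15:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _zmap(params) -> np.ndarray:
    parts = []
    for v in (params.w, params.I, params.sigma):
        sd = v.std()
        parts.append((v - v.mean()) / sd if sd > 1e-15 else np.zeros_like(v))
    return np.concatenate(parts)


def select_top_diverse(
    candidates: CandidateSet,
    validation: FitTargets,
    k: int = 10,
    similarity_threshold: float = 0.98,
    n_sims: int = 3,
    seed: int = 0,
    config: SimulationConfig = SimulationConfig(),
    constants: ModelConstants = ModelConstants(),
    fcd_window: int = DEFAULT_WINDOW,
    max_rescore: int | None = None,
) -> list[Candidate]:
    """Validation re-ranking with a map-diversity constraint.

    All feasible candidates (optionally only the ``max_rescore`` best by
    training cost) are re-scored on the validation targets, then selected
    greedily by ascending validation cost; a candidate is skipped when its
    concatenated z-scored (w, I, sigma) regional maps correlate at or
    above ``similarity_threshold`` with any already selected candidate.
    Returns at most k candidates (fewer, with a warning, if diversity
    exhausts the pool).
    """
    pool = candidates.feasible()
    if not pool:
        raise FitFailureError("no feasible candidate to select from")
    pool = sorted(pool, key=lambda c: c.train_cost)
    if max_rescore is not None:
        pool = pool[:max_rescore]
    myelin, gradient = validation.maps
    rescored = []
    for c in pool:
        _, _, vc = evaluate_candidate(
            c.coeffs, validation, n_sims=n_sims, seed=seed, config=config,
            constants=constants, fcd_window=fcd_window,
        )
        rescored.append(
            Candidate(coeffs=c.coeffs, train_cost=c.train_cost,
                      validation_cost=vc, restart=c.restart, iteration=c.iteration)
        )
    rescored.sort(key=lambda c: c.validation_cost)
    selected: list[Candidate] = []
    selected_maps: list[np.ndarray] = []
    for c in rescored:
        if len(selected) == k:
            break
        try:
            zm = _zmap(build_regional_parameters(c.coeffs, myelin, gradient))
        except InfeasibleParametersError:
            continue
        if any(_similarity(zm, m) >= similarity_threshold for m in selected_maps):
            continue
        selected.append(c)
        selected_maps.append(zm)
    if len(selected) < k:
        logger.warning(
            "diversity rule exhausted the pool: selected %d of %d requested",
            len(selected), k,
        )
    return selected
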