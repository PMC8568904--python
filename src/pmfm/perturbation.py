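"""Causal perturbation of the synaptic gating variables.

The experiment asks whether pushing the neural signals of chosen regions
during an incoherent (low FCD mean) episode kicks the network into the
coherent state. Within a simulated run, maximal low-FCD-mean segments of
sufficient length are located; at the segment midpoint the gating
variables of the target regions are driven toward the extremes of their
segment-local range for a fixed number of integrator steps (one TR), and
the run is then continued with the *same* noise realization as the
unperturbed run, so a zero-strength perturbation reproduces the baseline
bit-exactly. The FCD mean before versus after the perturbation quantifies
the state change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .dynamics import (
    BoldTimeseries,
    Connectome,
    HemodynamicConstants,
    LinearCoefficients,
    ModelConstants,
    NeuralTrajectory,
    SimulationConfig,
    SpatialMap,
    balloon_windkessel,
    build_regional_parameters,
    downsample_bold,
    integrate_mfm,
)
from .exceptions import InvalidInputError
from .observables import DEFAULT_WINDOW, fcd_mean_timecourse, sliding_window_fcd

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationConfig",
    "Segment",
    "find_incoherent_segments",
    "perturb_gating",
    "run_perturbation_experiment",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Perturbation protocol parameters.

    factor: fraction of the distance to the segment extreme applied per
    step (0.8); n_iter: number of perturbed integrator steps (72 steps of
    10 ms = one TR at 0.72 s); fcd_mean_threshold: FCD-mean value below
    which a window counts as incoherent (0.6); min_segment: minimum
    incoherent run length in windows/frames (200 TRs); post_windows:
    length of the evaluation epoch after the perturbation onset, in
    windows (default one window length, 83).
    """

    factor: float = 0.8
    n_iter: int = 72
    fcd_mean_threshold: float = 0.6
    min_segment: int = 200
    post_windows: int = 83

    def __post_init__(self) -> None:
        if not (0.0 <= self.factor <= 1.0):
            raise InvalidInputError("factor must lie in [0, 1]")
        if self.n_iter < 1:
            raise InvalidInputError("n_iter must be >= 1")
        if self.min_segment < 1:
            raise InvalidInputError("min_segment must be >= 1")


@dataclass(frozen=True)
class Segment:
    """Half-open window interval [start, end) of one run."""

    run_id: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidInputError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def find_incoherent_segments(
    fcd_mean: np.ndarray,
    config: PerturbationConfig = PerturbationConfig(),
    run_id: int = 0,
) -> list[Segment]:
    """Maximal runs of windows with FCD mean below the incoherence
    threshold, keeping only runs of at least ``min_segment`` windows."""
    x = np.asarray(fcd_mean, dtype=float).ravel()
    low = x < config.fcd_mean_threshold
    if x.size == 0:
        return []
    padded = np.concatenate([[False], low, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    return [
        Segment(run_id=run_id, start=int(s), end=int(e))
        for s, e in zip(starts, ends)
        if e - s >= config.min_segment
    ]


def perturb_gating(
    s: np.ndarray,
    regions: np.ndarray,
    s_min: float,
    s_max: float,
    factor: float,
) -> np.ndarray:
    """One perturbation update of the gating vector.

    Regions whose gating is below the midpoint of [s_min, s_max] are
    pushed up, S <- S + factor * (s_max - S); regions above it are pushed
    down, S <- S - factor * (S - s_min). Values stay inside
    [s_min, s_max] for factor in [0, 1].
    """
    out = s.copy()
    mid = 0.5 * (s_min + s_max)
    sel = out[regions]
    low = sel <= mid
    sel = np.where(low, sel + factor * (s_max - sel), sel - factor * (sel - s_min))
    out[regions] = sel
    return out


def _frame_to_step(frame: int, config: SimulationConfig) -> int:
    """Integrator step index of (1-based sample of) frame ``frame`` (0-based)."""
    burn_steps = round(config.t_burn / config.dt)
    return burn_steps + config.steps_per_frame * (frame + 1)


def run_perturbation_experiment(
    coeffs: LinearCoefficients,
    sc: Connectome,
    maps: tuple[SpatialMap, SpatialMap],
    target_regions,
    config: PerturbationConfig = PerturbationConfig(),
    n_trials: int = 30,
    seed: int = 0,
    sim_config: SimulationConfig = SimulationConfig(),
    constants: ModelConstants = ModelConstants(),
    hemo_constants: HemodynamicConstants = HemodynamicConstants(),
    fcd_window: int = DEFAULT_WINDOW,
) -> dict:
    """Run the perturbation census and report pre/post FCD means.

    For each trial: simulate a run; locate the longest incoherent segment;
    perturb the target regions for ``config.n_iter`` steps starting at the
    segment midpoint; continue integrating with the *baseline* noise
    realization; and compare the mean FCD mean over the
    ``config.post_windows`` windows following the perturbation onset in
    the perturbed run (``post``) against the same windows of the
    unperturbed baseline run (``pre``). A zero-strength perturbation
    therefore yields post == pre exactly. Trials without a qualifying
    segment are skipped with a log entry.

    Returns dict with arrays ``pre``, ``post`` (one entry per successful
    trial), ``skipped`` (count), and the per-trial segments used.
    """
    regions = np.asarray(target_regions, dtype=int)
    if regions.size == 0:
        raise InvalidInputError("target_regions must be nonempty")
    if np.any(regions < 0) or np.any(regions >= sc.n_regions):
        raise InvalidInputError("target region index out of range")
    params = build_regional_parameters(coeffs, *maps)
    pre_list, post_list, segments_used = [], [], []
    skipped = 0
    for trial in range(n_trials):
        trial_seed = seed + trial
        rng = np.random.default_rng(trial_seed)
        s0 = rng.uniform(0.0, 1.0, size=sc.n_regions)
        noise = rng.standard_normal((sc.n_regions, sim_config.n_steps))
        cfg = SimulationConfig(
            dt=sim_config.dt, t_total=sim_config.t_total,
            t_burn=sim_config.t_burn, tr=sim_config.tr, seed=trial_seed,
        )
        neural = integrate_mfm(params, sc, constants, cfg, s0=s0, noise=noise)
        bold = downsample_bold(
            balloon_windkessel(neural, hemo_constants, cfg.dt), cfg, sc.region_ids
        )
        fcd = sliding_window_fcd(bold, window=fcd_window)
        fcd_mean = fcd_mean_timecourse(fcd)
        segs = find_incoherent_segments(fcd_mean, config, run_id=trial)
        if not segs:
            skipped += 1
            logger.info("trial %d: no incoherent segment of length >= %d",
                        trial, config.min_segment)
            continue
        seg = max(segs, key=lambda s: s.length)
        # windows index frames; perturb at the segment's midpoint frame
        mid_window = seg.start + seg.length // 2
        t_p = _frame_to_step(mid_window, cfg)
        S = neural.S
        s_seg = S[:, _frame_to_step(seg.start, cfg): _frame_to_step(seg.end - 1, cfg) + 1]
        s_max = float(s_seg.max())
        s_min = float(s_seg.min())
        # apply n_iter perturbed Euler steps from the baseline state at t_p,
        # re-using the baseline noise so factor=0 reproduces the baseline
        s_run = S[:, t_p].copy()
        per_cfg_steps = config.n_iter
        S_pert = S.copy()
        for k in range(per_cfg_steps):
            step_noise = noise[:, t_p + k : t_p + k + 1]
            one = _kernels.euler_maruyama_mfm(
                np.ascontiguousarray(s_run), np.ascontiguousarray(step_noise),
                np.ascontiguousarray(sc.C),
                np.ascontiguousarray(params.w), np.ascontiguousarray(params.I),
                np.ascontiguousarray(params.sigma), float(params.G),
                constants.J, constants.a, constants.b, constants.d,
                constants.r_kin, constants.tau_s, cfg.dt,
            )
            s_run = one[:, 1]
            if config.factor > 0:
                s_run = perturb_gating(s_run, regions, s_min, s_max, config.factor)
            S_pert[:, t_p + k + 1] = s_run
        # continue unperturbed to the end of the run with the same noise
        rest = S.shape[1] - 1 - (t_p + per_cfg_steps)
        if rest > 0:
            cont = _kernels.euler_maruyama_mfm(
                np.ascontiguousarray(s_run),
                np.ascontiguousarray(noise[:, t_p + per_cfg_steps :]),
                np.ascontiguousarray(sc.C),
                np.ascontiguousarray(params.w), np.ascontiguousarray(params.I),
                np.ascontiguousarray(params.sigma), float(params.G),
                constants.J, constants.a, constants.b, constants.d,
                constants.r_kin, constants.tau_s, cfg.dt,
            )
            S_pert[:, t_p + per_cfg_steps :] = cont
        neural_pert = NeuralTrajectory(S=S_pert, dt=cfg.dt)
        bold_pert = downsample_bold(
            balloon_windkessel(neural_pert, hemo_constants, cfg.dt), cfg, sc.region_ids
        )
        fcd_pert = sliding_window_fcd(bold_pert, window=fcd_window)
        fm_pert = fcd_mean_timecourse(fcd_pert)
        n_windows = fm_pert.size
        # evaluation epoch: every window whose frames sample the
        # perturbation onset or its aftermath
        lo = max(seg.start, mid_window - fcd_window + 1)
        hi = min(mid_window + config.post_windows, n_windows)
        if hi <= lo:
            skipped += 1
            continue
        pre_list.append(float(np.mean(fcd_mean[lo:hi])))
        post_list.append(float(np.mean(fm_pert[lo:hi])))
        segments_used.append(seg)
    return {
        "pre": np.asarray(pre_list),
        "post": np.asarray(post_list),
        "skipped": skipped,
        "segments": segments_used,
    }
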