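"""Covariance matrix adaptation evolution strategy (CMA-ES).

A self-contained (mu/mu_w, lambda) CMA-ES with cumulative step-size
adaptation and rank-one plus rank-mu covariance updates, following the
standard parameterization (Hansen's tutorial settings for weights,
learning rates and damping). Box constraints are handled by projecting
sampled candidates onto the feasible box before evaluation; the objective
sees only feasible points.

The optimizer is derivative-free and ask/tell-style internally; the
:func:`minimize` driver records every evaluated candidate, which the
fitting layer uses to build its candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CmaesResult", "minimize"]


@dataclass
class CmaesResult:
    x_best: np.ndarray
    f_best: float
    candidates: list  # (x, f, iteration) for every evaluation, in order
    n_iter: int


def default_popsize(dim: int) -> int:
    return 4 + int(3 * np.log(dim))


def minimize(
    objective,
    x0: np.ndarray,
    sigma0: float | np.ndarray,
    iterations: int,
    seed: int = 0,
    popsize: int | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> CmaesResult:
    """Minimize ``objective`` over ``iterations`` generations.

    Parameters
    ----------
    objective : callable mapping a 1-D parameter vector to a finite float
        (use a large sentinel for infeasible points).
    x0 : initial mean.
    sigma0 : initial step size; a vector is interpreted as per-coordinate
        scales (applied as a diagonal scaling of the search space).
    bounds : optional (lower, upper) arrays; candidates are clipped into
        the box before evaluation and the mean is kept inside it.
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    rng = np.random.default_rng(seed)
    lam = popsize if popsize is not None else default_popsize(dim)
    mu = lam // 2
    # log-linear recombination weights
    raw = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    weights = raw / raw.sum()
    mueff = 1.0 / np.sum(weights**2)

    scales = np.broadcast_to(np.asarray(sigma0, dtype=float), (dim,)).copy()
    sigma = 1.0  # global step size acts on top of the diagonal scaling

    cc = (4 + mueff / dim) / (dim + 4 + 2 * mueff / dim)
    cs = (mueff + 2) / (dim + mueff + 5)
    c1 = 2 / ((dim + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((dim + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (dim + 1)) - 1) + cs
    chiN = np.sqrt(dim) * (1 - 1 / (4 * dim) + 1 / (21 * dim**2))

    mean = x0.copy()
    if bounds is not None:
        lower, upper = (np.asarray(b, dtype=float) for b in bounds)
        mean = np.clip(mean, lower, upper)
    pc = np.zeros(dim)
    ps = np.zeros(dim)
    C = np.eye(dim)
    B = np.eye(dim)
    D = np.ones(dim)
    invsqrtC = np.eye(dim)
    eigen_stale = 0

    candidates: list = []
    x_best = mean.copy()
    f_best = np.inf

    for it in range(iterations):
        z = rng.standard_normal((lam, dim))
        y = z @ (B * D).T  # y ~ N(0, C)
        xs = mean[None, :] + sigma * scales[None, :] * y
        if bounds is not None:
            xs_eval = np.clip(xs, lower, upper)
        else:
            xs_eval = xs
        fs = np.array([float(objective(x)) for x in xs_eval])
        for x, f in zip(xs_eval, fs):
            candidates.append((x.copy(), float(f), it))
        order = np.argsort(fs)
        if fs[order[0]] < f_best:
            f_best = float(fs[order[0]])
            x_best = xs_eval[order[0]].copy()

        # recombination in the unscaled coordinate system
        y_sel = ((xs_eval - mean[None, :]) / (sigma * scales[None, :]))[order[:mu]]
        y_w = weights @ y_sel
        mean = mean + sigma * scales * y_w

        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (invsqrtC @ y_w)
        hsig = float(
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (it + 1))) / chiN
            < 1.4 + 2 / (dim + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w
        rank_mu = (y_sel * weights[:, None]).T @ y_sel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chiN - 1))
        sigma = float(np.clip(sigma, 1e-12, 1e6))

        eigen_stale += 1
        if eigen_stale > max(1, int(1 / ((c1 + cmu) * dim * 10))):
            eigen_stale = 0
            C = (C + C.T) / 2
            evals, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(evals, 1e-20))
            invsqrtC = B @ np.diag(1 / D) @ B.T
        if bounds is not None:
            mean = np.clip(mean, lower, upper)

    return CmaesResult(x_best=x_best, f_best=f_best, candidates=candidates, n_iter=iterations)
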