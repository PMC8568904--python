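"""Static and dynamic functional-connectivity observables.

Static FC is the full-run Pearson correlation matrix of regional BOLD time
courses. Functional connectivity dynamics (FCD) correlates sliding-window
FC patterns across windows; the distribution of its upper-triangle entries
is the fitting target for the temporal structure, compared with a
Kolmogorov-Smirnov distance, while static FC is compared with a Pearson
correlation of Fisher z-transformed entries. The multi-stability analyses
(FCD mean time course, sliding-window signal amplitude, two-Gaussian state
classification, FCD-STD coupling maps and their permutation null) live
here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .dynamics import BoldTimeseries
from .exceptions import DegenerateSignalError, FitFailureError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "FCMatrix",
    "FCDMatrix",
    "FcdPdf",
    "StateLabels",
    "static_fc",
    "sliding_window_fcd",
    "fc_agreement",
    "ks_distance",
    "average_fcd_pdf",
    "cost",
    "fcd_mean_timecourse",
    "sliding_window_std",
    "classify_states",
    "fcd_std_correlation_map",
    "permutation_null_fcd_std",
]

#: default sliding window, in frames (~60 s at TR = 0.72 s)
DEFAULT_WINDOW = 83
#: default histogram grid for FCD-entry distributions
DEFAULT_BINS = 200


@dataclass(frozen=True)
class FCMatrix:
    """N x N Pearson correlation matrix of regional time courses."""

    values: np.ndarray
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidInputError("FC matrix must be square")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise InvalidInputError("FC entries must lie in [-1, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise InvalidInputError("FC diagonal must be 1")
        if not np.allclose(v, v.T, atol=1e-9, rtol=0):
            raise InvalidInputError("FC matrix must be symmetric")
        if not self.region_ids:
            object.__setattr__(
                self, "region_ids", tuple(f"region_{i}" for i in range(v.shape[0]))
            )

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class FCDMatrix:
    """W x W correlations between vectorized sliding-window FC patterns."""

    values: np.ndarray
    window_length: int
    stride: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidInputError("FCD matrix must be square")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_windows, k=1)
        return self.values[iu]

    def pdf(self, n_bins: int = DEFAULT_BINS) -> "FcdPdf":
        """Normalized histogram of the upper-triangle entries on [-1, 1]."""
        edges = np.linspace(-1.0, 1.0, n_bins + 1)
        counts, _ = np.histogram(np.clip(self.upper_triangle(), -1, 1), bins=edges)
        total = counts.sum()
        if total == 0:
            raise InvalidInputError("FCD has no off-diagonal entries to histogram")
        return FcdPdf(bin_edges=edges, masses=counts / total)


@dataclass(frozen=True)
class FcdPdf:
    """Binned probability mass function of FCD entries on [-1, 1]."""

    bin_edges: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "masses", m)
        if e.ndim != 1 or m.shape != (e.shape[0] - 1,):
            raise InvalidInputError("bin_edges must bound masses (len(edges) = len(masses)+1)")
        if np.any(m < -1e-15):
            raise InvalidInputError("pdf masses must be nonnegative")
        if abs(m.sum() - 1.0) > 1e-12:
            raise InvalidInputError("pdf masses must sum to 1 within 1e-12")

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.masses)


@dataclass(frozen=True)
class StateLabels:
    """Two-state labelling of FCD-mean windows.

    ``labels`` holds True for coherent (high FCD mean) windows;
    ``dwell_times`` maps each state to the lengths of its maximal
    contiguous runs, in windows.
    """

    threshold: float
    labels: np.ndarray
    dwell_times: dict
    component_means: tuple[float, float] = (np.nan, np.nan)


def static_fc(bold: BoldTimeseries) -> FCMatrix:
    """Full-run Pearson correlation matrix of the regional time courses."""
    B = bold.B
    if B.shape[1] < 3:
        raise InvalidInputError("need at least 3 frames for static FC")
    sd = B.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise DegenerateSignalError(
            f"region {bold.region_ids[bad]!r} has a constant time course"
        )
    fc = np.corrcoef(B)
    np.fill_diagonal(fc, 1.0)
    return FCMatrix(values=np.clip(fc, -1, 1), region_ids=bold.region_ids)


def _window_fc_vectors(B: np.ndarray, window: int, stride: int) -> np.ndarray:
    """Strictly-upper-triangle FC vectors for each sliding window (W x P)."""
    n, T = B.shape
    W = (T - window) // stride + 1
    iu = np.triu_indices(n, k=1)
    out = np.empty((W, iu[0].size))
    for k in range(W):
        seg = B[:, k * stride : k * stride + window]
        out[k] = np.corrcoef(seg)[iu]
    return out


def sliding_window_fcd(
    bold: BoldTimeseries, window: int = DEFAULT_WINDOW, stride: int = 1
) -> FCDMatrix:
    """FCD: correlation between the vectorized FC patterns of all windows.

    Window k covers frames [k*stride, k*stride + window); FC patterns are
    vectorized over the strictly-upper triangle. With stride 1 a T-frame
    run yields W = T - window + 1 windows.
    """
    if window < 3:
        raise InvalidInputError("window must be at least 3 frames")
    if stride < 1:
        raise InvalidInputError("stride must be >= 1")
    if bold.n_frames < window:
        raise InvalidInputError(
            f"run of {bold.n_frames} frames is shorter than window {window}"
        )
    vecs = _window_fc_vectors(bold.B, window, stride)
    if vecs.shape[0] == 1:
        values = np.ones((1, 1))
    else:
        values = np.corrcoef(vecs)
        np.fill_diagonal(values, 1.0)
        values = np.clip(values, -1, 1)
    return FCDMatrix(values=values, window_length=window, stride=stride)


def fc_agreement(fc_sim: FCMatrix, fc_emp: FCMatrix) -> float:
    """Pearson correlation of Fisher z-transformed upper-triangle FC entries."""
    if fc_sim.n_regions != fc_emp.n_regions:
        raise InvalidInputError("FC matrices differ in size")
    a, b = fc_sim.upper_triangle(), fc_emp.upper_triangle()
    if np.any(np.abs(a) >= 1) or np.any(np.abs(b) >= 1):
        raise InvalidInputError(
            "off-diagonal FC entries must lie strictly inside (-1, 1) for the z-transform"
        )
    za, zb = np.arctanh(a), np.arctanh(b)
    return float(np.corrcoef(za, zb)[0, 1])


def _as_cdf_grid(x) -> tuple[np.ndarray, np.ndarray]:
    """Return (grid, cdf-at-grid) for raw samples or a binned pdf."""
    if isinstance(x, FcdPdf):
        return x.bin_edges[1:], x.cdf()
    s = np.sort(np.asarray(x, dtype=float).ravel())
    if s.size == 0:
        raise InvalidInputError("ks_distance requires nonempty samples")
    return s, np.arange(1, s.size + 1) / s.size


def ks_distance(a, b) -> float:
    """Kolmogorov-Smirnov sup-distance between two distributions.

    Inputs may be raw samples (ECDF) or :class:`FcdPdf` objects
    (cumulative-sum CDFs evaluated at bin edges), in any combination.
    """
    ga, Fa = _as_cdf_grid(a)
    gb, Fb = _as_cdf_grid(b)
    grid = np.union1d(ga, gb)
    # CDF value at each grid point: step functions, right-continuous
    Fa_g = np.concatenate([[0.0], Fa])[np.searchsorted(ga, grid, side="right")]
    Fb_g = np.concatenate([[0.0], Fb])[np.searchsorted(gb, grid, side="right")]
    return float(np.max(np.abs(Fa_g - Fb_g)))


def average_fcd_pdf(fcds) -> FcdPdf:
    """Arithmetic mean of per-run FCD pdfs (runs cannot be averaged in the
    matrix domain because there is no temporal correspondence across runs).

    Accepts FCDMatrix or FcdPdf items; all pdfs must share one bin grid.
    """
    items = list(fcds)
    if not items:
        raise InvalidInputError("need at least one FCD")
    pdfs = [x.pdf() if isinstance(x, FCDMatrix) else x for x in items]
    edges = pdfs[0].bin_edges
    for p in pdfs[1:]:
        if p.bin_edges.shape != edges.shape or not np.allclose(p.bin_edges, edges):
            raise InvalidInputError("FCD pdfs use mismatched bin grids")
    mean = np.mean([p.masses for p in pdfs], axis=0)
    return FcdPdf(bin_edges=edges, masses=mean / mean.sum())


def cost(
    fc_sim: FCMatrix,
    fc_emp: FCMatrix,
    fcd_sim_pdf: FcdPdf,
    fcd_emp_pdf: FcdPdf,
    weight_fc: float = 1.0,
    weight_fcd: float = 1.0,
) -> float:
    """Overall fitting cost weight_fc * (1 - r) + weight_fcd * KS.

    With default weights the cost lies in [0, 3]; ``weight_fcd = 0``
    recovers FC-only fitting.
    """
    if weight_fc < 0 or weight_fcd < 0:
        raise InvalidInputError("cost weights must be nonnegative")
    r = fc_agreement(fc_sim, fc_emp)
    ks = ks_distance(fcd_sim_pdf, fcd_emp_pdf)
    return float(weight_fc * (1.0 - r) + weight_fcd * ks)


def fcd_mean_timecourse(fcd: FCDMatrix, include_diagonal: bool = False) -> np.ndarray:
    """Per-window mean similarity to all other windows (FCD row means).

    The diagonal self-correlation (always 1) is excluded by default to
    avoid a constant upward bias.
    """
    v = fcd.values
    if v.shape[0] < 2:
        raise InvalidInputError("need at least 2 windows")
    if include_diagonal:
        return v.mean(axis=1)
    W = v.shape[0]
    return (v.sum(axis=1) - np.diag(v)) / (W - 1)


def sliding_window_std(
    bold: BoldTimeseries, window: int = DEFAULT_WINDOW, stride: int = 1, ddof: int = 0
) -> np.ndarray:
    """Per-region, per-window standard deviation of the BOLD signal (SW-STD).

    Uses the population convention (ddof=0) by default; the windowing
    matches :func:`sliding_window_fcd` so columns align with FCD windows.
    """
    if window < 2:
        raise InvalidInputError("window must be at least 2 frames")
    if bold.n_frames < window:
        raise InvalidInputError("run shorter than window")
    sw = np.lib.stride_tricks.sliding_window_view(bold.B, window, axis=1)[:, ::stride, :]
    return sw.std(axis=2, ddof=ddof)


def _gaussian_crossover(m1, s1, w1, m2, s2, w2) -> float | None:
    """Crossing point of two weighted Gaussian densities between their means.

    Solves w1 N(x|m1,s1) = w2 N(x|m2,s2) (a quadratic in x) and returns the
    root lying between the means, or None if no such root exists.
    """
    A = 1.0 / (2 * s2**2) - 1.0 / (2 * s1**2)
    B = m1 / s1**2 - m2 / s2**2
    Cc = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + np.log((w1 * s2) / (w2 * s1))
    lo, hi = sorted((m1, m2))
    if abs(A) < 1e-15:
        if abs(B) < 1e-15:
            return None
        root = -Cc / B
        return root if lo <= root <= hi else None
    disc = B**2 - 4 * A * Cc
    if disc < 0:
        return None
    roots = [(-B + np.sqrt(disc)) / (2 * A), (-B - np.sqrt(disc)) / (2 * A)]
    inside = [r for r in roots if lo <= r <= hi]
    return min(inside, key=lambda r: abs(r - (lo + hi) / 2)) if inside else None


def _run_lengths(labels: np.ndarray) -> dict:
    out = {"coherent": [], "incoherent": []}
    if labels.size == 0:
        return out
    changes = np.flatnonzero(np.diff(labels.astype(int))) + 1
    bounds = np.concatenate([[0], changes, [labels.size]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        out["coherent" if labels[lo] else "incoherent"].append(int(hi - lo))
    return out


def classify_states(fcd_mean: np.ndarray, seed: int = 0) -> StateLabels:
    """Two-Gaussian mixture classification of the FCD mean time course.

    Fits a univariate two-component Gaussian mixture (EM); the cross-over
    point of the two component densities between the means is the
    coherent/incoherent threshold. Windows above the threshold are
    coherent (high FCD mean). If the densities do not cross between the
    means the midpoint of the means is used and a warning is logged.
    """
    x = np.asarray(fcd_mean, dtype=float).ravel()
    if x.size < 20:
        raise InvalidInputError("need at least 20 windows to classify states")
    if x.std() < 1e-12:
        raise InvalidInputError("FCD mean has degenerate variance")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=5, random_state=seed,
        max_iter=500,
    ).fit(x[:, None])
    if not gm.converged_:
        raise FitFailureError("EM for the two-Gaussian mixture did not converge")
    means = gm.means_.ravel()
    stds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = stds[order]
    w1, w2 = weights[order]
    thr = _gaussian_crossover(m1, s1, w1, m2, s2, w2)
    if thr is None:
        thr = 0.5 * (m1 + m2)
        logger.warning(
            "mixture densities do not cross between the means; using their midpoint %.4f",
            thr,
        )
    labels = x > thr
    return StateLabels(
        threshold=float(thr),
        labels=labels,
        dwell_times=_run_lengths(labels),
        component_means=(float(m1), float(m2)),
    )


def fcd_std_correlation_map(fcd_mean: np.ndarray, sw_std: np.ndarray) -> np.ndarray:
    """Per-region correlation between the first derivatives of the FCD mean
    and SW-STD time courses (forward differences).

    Regions whose difference series has zero variance get NaN.
    """
    fcd_mean = np.asarray(fcd_mean, dtype=float).ravel()
    sw_std = np.asarray(sw_std, dtype=float)
    if sw_std.ndim != 2 or sw_std.shape[1] != fcd_mean.size:
        raise InvalidInputError("sw_std must be N x W with W matching fcd_mean")
    df = np.diff(fcd_mean)
    ds = np.diff(sw_std, axis=1)
    out = np.full(sw_std.shape[0], np.nan)
    sd_f = df.std()
    if sd_f == 0:
        return out
    for i in range(sw_std.shape[0]):
        if ds[i].std() == 0:
            continue
        out[i] = np.corrcoef(df, ds[i])[0, 1]
    return out


def permutation_null_fcd_std(
    runs, n_perm: int = 1000, seed: int = 0, fdr_q: float = 0.05
):
    """Permutation test of the region-averaged FCD-STD correlations.

    ``runs`` is a list of (fcd_mean, sw_std) pairs, one per fMRI run. The
    observed statistic is the per-region mean over runs of the FCD-STD
    derivative correlation. Each permutation re-pairs the FCD-mean series
    of one run with the SW-STD series of another (a random permutation of
    run indices) and recomputes the region-averaged correlations, yielding
    one null value per region per permutation. One-sided add-one p-values
    p = (1 + #{null >= obs}) / (1 + n_perm) are corrected across regions
    with Benjamini-Hochberg FDR.

    Returns dict with observed (N,), null (n_perm x N), p_values (N,),
    significant (N, bool at ``fdr_q``).
    """
    runs = list(runs)
    if len(runs) < 2:
        raise InvalidInputError("need at least 2 runs to permute")
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    fcd_means = [np.asarray(fm, dtype=float).ravel() for fm, _ in runs]
    sw_stds = [np.asarray(ss, dtype=float) for _, ss in runs]
    n_regions = sw_stds[0].shape[0]

    def region_average(pairing):
        acc = np.zeros(n_regions)
        cnt = np.zeros(n_regions)
        for i_f, i_s in pairing:
            fm, ss = fcd_means[i_f], sw_stds[i_s]
            W = min(fm.size, ss.shape[1])
            r = fcd_std_correlation_map(fm[:W], ss[:, :W])
            ok = np.isfinite(r)
            acc[ok] += r[ok]
            cnt[ok] += 1
        with np.errstate(invalid="ignore"):
            return acc / np.where(cnt == 0, np.nan, cnt)

    identity = [(i, i) for i in range(len(runs))]
    observed = region_average(identity)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_regions))
    for p in range(n_perm):
        perm = rng.permutation(len(runs))
        null[p] = region_average([(i, int(perm[i])) for i in range(len(runs))])
    pvals = (1 + np.sum(null >= observed[None, :], axis=0)) / (1 + n_perm)
    significant = multipletests(pvals, alpha=fdr_q, method="fdr_bh")[0]
    return {
        "observed": observed,
        "null": null,
        "p_values": pvals,
        "significant": significant,
    }
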