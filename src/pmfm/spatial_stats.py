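"""Spatial-map statistics on parcellated cortical data.

Correlates model-derived spatial maps (FCD-STD coupling maps, fitted
parameter maps) with gene-expression-derived maps, with two nulls: the
spin test, which preserves spatial autocorrelation by randomly rotating
the parcellation on the sphere, and a random-gene-pair null testing the
specificity of a marker-gene contrast (e.g. PVALB - SST) against
arbitrary gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .dynamics import SpatialMap
from .exceptions import InvalidInputError

__all__ = [
    "ExpressionMatrix",
    "ParcelCentroids",
    "differential_expression_map",
    "map_correlation",
    "spin_test",
    "random_gene_pair_test",
    "expression_pc1_map",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x regions expression table with labels."""

    values: np.ndarray
    gene_ids: tuple[str, ...]
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        if v.ndim != 2:
            raise InvalidInputError("expression matrix must be 2-D (genes x regions)")
        if v.shape[0] < 2:
            raise InvalidInputError("need at least 2 genes")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("expression values must be finite")
        if len(self.gene_ids) != v.shape[0] or len(self.region_ids) != v.shape[1]:
            raise InvalidInputError("label lengths do not match matrix shape")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene_id)]
        except ValueError:
            raise InvalidInputError(f"gene {gene_id!r} not in expression matrix") from None


@dataclass(frozen=True)
class ParcelCentroids:
    """Unit-sphere centroid per region (stand-in for cortical geometry)."""

    xyz: np.ndarray
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.xyz, dtype=float)
        object.__setattr__(self, "xyz", p)
        if p.ndim != 2 or p.shape[1] != 3:
            raise InvalidInputError("centroids must be an N x 3 array")
        norms = np.linalg.norm(p, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InvalidInputError("centroids must have unit norm within 1e-9")
        if not self.region_ids:
            object.__setattr__(
                self, "region_ids", tuple(f"region_{i}" for i in range(p.shape[0]))
            )

    @property
    def n_regions(self) -> int:
        return self.xyz.shape[0]


def _zscore_rows(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=1, keepdims=True)
    if np.any(sd < 1e-15):
        raise InvalidInputError("degenerate normalization: a gene is constant across regions")
    return (v - v.mean(axis=1, keepdims=True)) / sd


def differential_expression_map(
    expr: ExpressionMatrix, gene_a: str, gene_b: str
) -> SpatialMap:
    """Difference of z-normalized expression profiles, z(a) - z(b).

    Each gene is z-normalized across regions before subtraction, matching
    the construction of marker contrasts such as PVALB - SST.
    """
    if expr.n_regions < 2:
        raise InvalidInputError("degenerate normalization: need at least 2 regions")
    a = expr.gene(gene_a)
    b = expr.gene(gene_b)
    if gene_a == gene_b:
        return SpatialMap(values=np.zeros(expr.n_regions), name=f"{gene_a}-{gene_b}")
    z = _zscore_rows(np.vstack([a, b]))
    return SpatialMap(values=z[0] - z[1], name=f"{gene_a}-{gene_b}")


def map_correlation(map_a: SpatialMap, map_b: SpatialMap) -> float:
    """Pearson correlation between two region-aligned spatial maps."""
    a, b = map_a.values, map_b.values
    if a.size != b.size:
        raise InvalidInputError("maps differ in length")
    if a.size < 3:
        raise InvalidInputError("need at least 3 regions")
    if a.std() == 0 or b.std() == 0:
        raise InvalidInputError("map has zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation: QR of a Gaussian matrix, sign-fixed and
    corrected to determinant +1."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def spin_permutation(centroids: ParcelCentroids, rotation: np.ndarray) -> np.ndarray:
    """Region reassignment induced by one rotation of the parcellation.

    Region j inherits the value of the parcel whose rotated centroid lands
    nearest to region j's original position; the identity rotation yields
    the identity assignment.
    """
    rotated = centroids.xyz @ np.asarray(rotation, dtype=float).T
    _, assign = cKDTree(rotated).query(centroids.xyz)
    return assign


def spin_test(
    map_a: SpatialMap,
    map_b: SpatialMap,
    centroids: ParcelCentroids,
    n_rot: int = 1000,
    seed: int = 0,
) -> dict:
    """Spatial-autocorrelation-preserving permutation test.

    For each random rotation the parcellation is rotated on the sphere and
    each region inherits map_b's value from the nearest rotated centroid;
    the correlation with map_a over rotations forms the null. Two-sided
    add-one p-value: p = (1 + #{|null| >= |observed|}) / (1 + n_rot).
    """
    if n_rot < 1:
        raise InvalidInputError("n_rot must be >= 1")
    n = centroids.n_regions
    if len(map_a) != n or len(map_b) != n:
        raise InvalidInputError("maps must match centroid count")
    # duplicate centroids would make nearest-neighbour reassignment ambiguous
    d = np.linalg.norm(centroids.xyz[:, None, :] - centroids.xyz[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-9:
        raise InvalidInputError("duplicate parcel centroids")
    observed = map_correlation(map_a, map_b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_rot)
    for i in range(n_rot):
        Rm = random_rotation(rng)
        assign = spin_permutation(centroids, Rm)
        null[i] = np.corrcoef(map_a.values, map_b.values[assign])[0, 1]
    p = (1 + np.sum(np.abs(null) >= abs(observed))) / (1 + n_rot)
    return {"observed": observed, "null": null, "p": float(p)}


def random_gene_pair_test(
    map_a: SpatialMap,
    expr: ExpressionMatrix,
    n_pairs: int = 1000,
    seed: int = 0,
    exclude: tuple[str, str] | None = None,
    observed_r: float | None = None,
) -> dict:
    """Specificity null from random gene-pair difference maps.

    Draws ``n_pairs`` random ordered pairs of distinct genes (never the
    excluded reference pair, in either order), builds each pair's
    z-difference map, and correlates it with ``map_a``. If ``exclude`` is
    given, the observed correlation is the one with the reference pair's
    difference map unless ``observed_r`` overrides it. Two-sided add-one
    p-value as in the spin test.
    """
    if expr.n_genes < 3:
        raise InvalidInputError("need at least 3 genes for a random-pair null")
    if n_pairs < 1:
        raise InvalidInputError("n_pairs must be >= 1")
    if observed_r is None:
        if exclude is None:
            raise InvalidInputError("provide exclude= reference pair or observed_r=")
        ref = differential_expression_map(expr, *exclude)
        observed_r = map_correlation(map_a, ref)
    excluded = {exclude, (exclude[1], exclude[0])} if exclude else set()
    rng = np.random.default_rng(seed)
    null = np.empty(n_pairs)
    z = _zscore_rows(expr.values)
    k = 0
    while k < n_pairs:
        i, j = rng.choice(expr.n_genes, size=2, replace=False)
        pair = (expr.gene_ids[i], expr.gene_ids[j])
        if pair in excluded:
            continue
        diff = z[i] - z[j]
        if diff.std() == 0:
            continue
        null[k] = np.corrcoef(map_a.values, diff)[0, 1]
        k += 1
    p = (1 + np.sum(np.abs(null) >= abs(observed_r))) / (1 + n_pairs)
    return {"observed": float(observed_r), "null": null, "p": float(p)}


def expression_pc1_map(expr: ExpressionMatrix) -> SpatialMap:
    """First principal component of gene-standardized expression across
    regions.

    Each gene is z-scored across regions; the PC1 region scores are the
    leading right singular vector of the standardized genes x regions
    matrix. The sign is fixed intrinsically (largest-magnitude score made
    positive), so relabelling or globally negating the gene values leaves
    the returned map unchanged.
    """
    if expr.n_regions < 3:
        raise InvalidInputError("need at least 3 regions for a principal component")
    z = _zscore_rows(expr.values)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] <= 1e-12:
        raise InvalidInputError("expression matrix has rank 0 after standardization")
    pc1 = vt[0]
    if pc1[int(np.argmax(np.abs(pc1)))] < 0:
        pc1 = -pc1
    return SpatialMap(values=pc1, name="expression_pc1")
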