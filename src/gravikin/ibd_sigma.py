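"""Isolation-by-distance analysis and the dispersal kernel spread sigma.

Under spatially limited dispersal, pairwise genetic distance increases with
geographic distance.  With close kin removed, the slope b of the regression of
PCA genetic distance on linear geographic distance combines with the effective
density D of breeding individuals to give the spread of the dispersal kernel:

    sigma = sqrt(1 / (4 * pi * D * b))

Significance of the genetic-geographic association is assessed with Mantel's
matrix-permutation test (and a partial Mantel controlling for temporal
distance between captures, since capture date can also structure genetic
distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .spatial_io import GenotypeTable


class IBDError(ValueError):
    pass


@dataclass
class GeneticDistanceMatrix:
    individual_ids: list[str]
    matrix: np.ndarray
    metric_name: str = "pca_euclidean"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.individual_ids):
            raise IBDError("genetic distance matrix must be square over the id list")
        self.matrix = m


@dataclass
class MantelResult:
    r: float
    ci: tuple[float, float] | None
    p: float
    n_perm: int


@dataclass
class IBDRegression:
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    r_squared: float
    n_pairs: int
    mantel: MantelResult | None = None


@dataclass
class SigmaEstimate:
    sigma: float
    ci: tuple[float, float] | None
    b_used: float
    d_used: float
    method_label: str = ""


def pca_genetic_distance(g: GenotypeTable, exclude: set[str] | None = None,
                         n_axes: int | None = None) -> GeneticDistanceMatrix:
    """Euclidean distance over principal-component scores of the genotypes.

    Missing calls are imputed with the per-site mean dosage before centering.
    With all axes retained (the default) the PC rotation is distance-preserving,
    so the result equals the Euclidean distance between the centered, imputed
    genotype rows.
    """
    exclude = exclude or set()
    keep = [i for i in g.individual_ids if i not in exclude]
    if len(keep) < 3:
        raise IBDError("need at least 3 individuals after close-kin exclusion")
    sub = g.subset(keep)
    x = sub.calls.astype(float)
    x[sub.calls == -1] = np.nan
    col_ok = ~np.isnan(x).all(axis=0)
    x = x[:, col_ok]
    mu = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = mu[inds[1]]
    x -= x.mean(axis=0)
    # thin SVD: scores = U @ diag(s) span all non-null axes
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    if n_axes is not None:
        scores = scores[:, :n_axes]
    diff = scores[:, None, :] - scores[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return GeneticDistanceMatrix(keep, d, "pca_euclidean")


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju]


def _check_conformable(*mats: np.ndarray) -> int:
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise IBDError("distance matrices are not conformable")
    return n


def _perm_correlations(gd: np.ndarray, geo_vec: np.ndarray, n_perm: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Pearson r between permuted gd (rows+cols jointly) and fixed geo pairs."""
    n = gd.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    vals = gd[perms[:, iu], perms[:, ju]]  # n_perm x n_pairs
    geo_c = geo_vec - geo_vec.mean()
    v_c = vals - vals.mean(axis=1, keepdims=True)
    num = v_c @ geo_c
    den = np.sqrt((v_c ** 2).sum(axis=1) * (geo_c ** 2).sum())
    return num / den


def mantel_test(gd: GeneticDistanceMatrix | np.ndarray, geo: np.ndarray,
                n_perm: int = 1000, n_boot: int = 1000,
                seed: int | None = None) -> MantelResult:
    """Mantel correlation between genetic and geographic distance matrices.

    r is the Pearson correlation over lower-triangle entries; the p-value
    comes from joint row/column permutations of the genetic matrix, and the
    95% CI from bootstrap resampling of individuals (n_boot=0 skips the CI).
    """
    gmat = gd.matrix if isinstance(gd, GeneticDistanceMatrix) else np.asarray(gd, float)
    geo = np.asarray(geo, dtype=float)
    n = _check_conformable(gmat, geo)
    if n < 5:
        raise IBDError("need at least 5 individuals for a Mantel test")
    gv, ov = _lower_triangle(gmat), _lower_triangle(geo)
    if gv.std() == 0 or ov.std() == 0:
        raise IBDError("zero-variance distance matrix")
    r = float(np.corrcoef(gv, ov)[0, 1])
    rng = np.random.default_rng(seed)
    perm_r = _perm_correlations(gmat, ov, n_perm, rng)
    p = (1.0 + float((np.abs(perm_r) >= abs(r) - 1e-12).sum())) / (n_perm + 1.0)
    ci = None
    if n_boot:
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            gb = _lower_triangle(gmat[np.ix_(idx, idx)])
            ob = _lower_triangle(geo[np.ix_(idx, idx)])
            distinct = idx[np.triu_indices(n, k=1)[0]] != idx[np.triu_indices(n, k=1)[1]]
            gb, ob = gb[distinct], ob[distinct]
            if gb.std() > 0 and ob.std() > 0:
                boots.append(np.corrcoef(gb, ob)[0, 1])
        if boots:
            ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return MantelResult(r=r, ci=ci, p=p, n_perm=n_perm)


def partial_mantel_test(gd: GeneticDistanceMatrix | np.ndarray, geo: np.ndarray,
                        temporal: np.ndarray, n_perm: int = 1000,
                        seed: int | None = None) -> tuple[float, float]:
    """Partial Mantel: gd ~ geo controlling for temporal distance.

    The partial correlation is computed from the three pairwise lower-triangle
    correlations; significance by permuting individuals of the genetic matrix.
    """
    gmat = gd.matrix if isinstance(gd, GeneticDistanceMatrix) else np.asarray(gd, float)
    geo = np.asarray(geo, dtype=float)
    temporal = np.asarray(temporal, dtype=float)
    n = _check_conformable(gmat, geo, temporal)
    if n < 5:
        raise IBDError("need at least 5 individuals")
    gv, ov, tv = (_lower_triangle(m) for m in (gmat, geo, temporal))
    if gv.std() == 0 or ov.std() == 0:
        raise IBDError("zero-variance distance matrix")

    def _partial(gvec):
        rxy = np.corrcoef(gvec, ov)[0, 1]
        if tv.std() == 0:
            return rxy
        rxz = np.corrcoef(gvec, tv)[0, 1]
        ryz = np.corrcoef(ov, tv)[0, 1]
        den = math.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        return (rxy - rxz * ryz) / den if den > 0 else np.nan

    r_obs = float(_partial(gv))
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = gmat[perm[iu], perm[ju]]
        if abs(_partial(gp)) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return r_obs, p


def ibd_slope(gd: GeneticDistanceMatrix | np.ndarray, geo: np.ndarray) -> IBDRegression:
    """OLS regression of pairwise genetic distance on geographic distance."""
    import statsmodels.api as sm

    gmat = gd.matrix if isinstance(gd, GeneticDistanceMatrix) else np.asarray(gd, float)
    geo = np.asarray(geo, dtype=float)
    _check_conformable(gmat, geo)
    y, x = _lower_triangle(gmat), _lower_triangle(geo)
    if len(y) < 10:
        raise IBDError("need at least 10 pairs for the IBD regression")
    if np.unique(x).size < 2:
        raise IBDError("degenerate regressor: a single distinct geographic distance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return IBDRegression(
        slope=float(model.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n_pairs=len(y),
    )


def sigma_from_slope_density(b: float, D: float,
                             b_ci: tuple[float, float] | None = None,
                             D_ci: tuple[float, float] | None = None,
                             method_label: str = "") -> SigmaEstimate:
    """Dispersal kernel spread sigma = sqrt(1 / (4 pi D b)).

    sigma is strictly decreasing in both b and D, so the 95% interval is the
    cross-combination [sigma(b_hi, D_hi), sigma(b_lo, D_lo)] of the input CIs.
    """
    if not (b > 0 and D > 0):
        raise IBDError("IBD signal absent or density invalid (need b > 0 and D > 0)")
    sigma = (4.0 * math.pi * D * b) ** -0.5
    ci = None
    if b_ci is not None and D_ci is not None:
        b_lo, b_hi = sorted(b_ci)
        d_lo, d_hi = sorted(D_ci)
        if min(b_lo, d_lo) <= 0:
            raise IBDError("CI bounds for b and D must be positive")
        ci = ((4.0 * math.pi * d_hi * b_hi) ** -0.5,
              (4.0 * math.pi * d_lo * b_lo) ** -0.5)
    return SigmaEstimate(sigma=sigma, ci=ci, b_used=b, d_used=D,
                         method_label=method_label)
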