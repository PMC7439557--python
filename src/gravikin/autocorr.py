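"""Multivariate spatial genetic autocorrelation and genetic patch size.

Squared pairwise genetic distances are Gower double-centered into a
covariance-form matrix C.  For each 50-m geographic distance class the
autocorrelation coefficient is

    r = sum_{(i,j) in class} c_ij / sum_{(i,j) in class} (c_ii + c_jj) / 2,

i.e. the between-individual cross-products normalized by the corresponding
within-individual terms.  A 95% null envelope comes from shuffling individuals
among their capture locations (25th/975th ranked of 1000 permutations), and a
95% CI of the observed r from 1000 bootstrap draws of individuals with
replacement.  The x-intercept of the correlogram (where r stops being
significantly positive and crosses zero) approximates the side of the
"genetic patch" -- the spatial extent of localized dispersal and breeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ibd_sigma import GeneticDistanceMatrix


class AutocorrError(ValueError):
    pass


@dataclass
class Correlogram:
    class_ends: np.ndarray       # upper bound of each (lo, hi] class, meters
    r: np.ndarray                # NaN where n_pairs < min_pairs
    perm_lo: np.ndarray
    perm_hi: np.ndarray
    boot_lo: np.ndarray
    boot_hi: np.ndarray
    n_pairs: np.ndarray
    class_width: float


@dataclass
class XIntercept:
    bracket: tuple[float, float]   # (last significantly-positive end, crossing end]
    point: float                   # linear interpolation of the zero crossing


def _cov_form(gd: np.ndarray) -> np.ndarray:
    """Gower double-centering of squared distances into covariance form."""
    sq = np.asarray(gd, dtype=float) ** 2
    row = sq.mean(axis=1, keepdims=True)
    col = sq.mean(axis=0, keepdims=True)
    return -0.5 * (sq - row - col + sq.mean())


def _class_r(c: np.ndarray, labels: np.ndarray, pair_i: np.ndarray,
             pair_j: np.ndarray, n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    num = np.bincount(labels, weights=c[pair_i, pair_j], minlength=n_classes)
    diag = np.diag(c)
    den = np.bincount(labels, weights=0.5 * (diag[pair_i] + diag[pair_j]),
                      minlength=n_classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den != 0, num / den, np.nan), np.bincount(labels, minlength=n_classes)


def correlogram(gd: GeneticDistanceMatrix | np.ndarray, geo: np.ndarray,
                class_width: float = 50.0, n_perm: int = 1000, n_boot: int = 1000,
                seed: int | None = None, min_pairs: int = 10) -> Correlogram:
    """Spatial autocorrelation coefficient per geographic distance class."""
    gmat = gd.matrix if isinstance(gd, GeneticDistanceMatrix) else np.asarray(gd, float)
    geo = np.asarray(geo, dtype=float)
    n = gmat.shape[0]
    if geo.shape != (n, n):
        raise AutocorrError("genetic and geographic matrices are not conformable")
    if n < 3:
        raise AutocorrError("need at least 3 individuals")

    c = _cov_form(gmat)
    iu, ju = np.triu_indices(n, k=1)
    dist = geo[iu, ju]
    n_classes = max(int(math.ceil(dist.max() / class_width)), 1)
    # half-open classes (lo, hi]: distance exactly at a boundary joins the lower class
    labels = np.clip(np.ceil(dist / class_width).astype(int) - 1, 0, n_classes - 1)
    ends = class_width * np.arange(1, n_classes + 1)

    r_obs, counts = _class_r(c, labels, iu, ju, n_classes)
    r_obs = np.where(counts >= min_pairs, r_obs, np.nan)

    rng = np.random.default_rng(seed)
    perm_r = np.full((n_perm, n_classes), np.nan)
    for k in range(n_perm):
        p = rng.permutation(n)
        perm_r[k], _ = _class_r(c, labels, p[iu], p[ju], n_classes)
    # 25th/975th ranked permutation values per class (95% null envelope)
    lo_idx = max(int(round(0.025 * n_perm)) - 1, 0)
    hi_idx = min(int(round(0.975 * n_perm)) - 1, n_perm - 1)
    srt = np.sort(perm_r, axis=0)
    perm_lo, perm_hi = srt[lo_idx], srt[hi_idx]

    boot_r = np.full((n_boot, n_classes), np.nan)
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        distinct = idx[iu] != idx[ju]
        cb = _cov_form(gmat[np.ix_(idx, idx)])
        db = geo[idx[:, None], idx[None, :]][iu, ju][distinct]
        lb = np.clip(np.ceil(db / class_width).astype(int) - 1, 0, n_classes - 1)
        boot_r[k], _ = _class_r(cb, lb, iu[distinct], ju[distinct], n_classes)
    boot_lo = np.nanpercentile(boot_r, 2.5, axis=0)
    boot_hi = np.nanpercentile(boot_r, 97.5, axis=0)

    empty = counts < min_pairs
    for arr in (perm_lo, perm_hi, boot_lo, boot_hi):
        arr[empty] = np.nan
    return Correlogram(class_ends=ends, r=r_obs, perm_lo=perm_lo, perm_hi=perm_hi,
                       boot_lo=boot_lo, boot_hi=boot_hi, n_pairs=counts,
                       class_width=class_width)


def x_intercept(c: Correlogram) -> XIntercept:
    """Bracket and interpolate where the correlogram crosses the x-axis.

    The bracket runs from the last class-end whose r is significantly positive
    (bootstrap CI above zero) to the first later class-end where r <= 0 or is
    significantly negative (below the permutation envelope).
    """
    defined = ~np.isnan(c.r)
    if defined.sum() < 2:
        raise AutocorrError("need at least 2 classes with defined r")
    pos = defined & (c.boot_lo > 0) & (c.r > 0)
    if not pos.any():
        raise AutocorrError("no patch signal: r never significantly positive")
    last_pos = int(np.where(pos)[0].max())
    crossing = None
    for k in range(last_pos + 1, len(c.r)):
        if not defined[k]:
            continue
        if c.r[k] <= 0 or (not np.isnan(c.perm_lo[k]) and c.r[k] < c.perm_lo[k]):
            crossing = k
            break
    if crossing is None:
        raise AutocorrError("no patch signal: correlogram never crosses zero")
    x0, y0 = c.class_ends[last_pos], c.r[last_pos]
    x1, y1 = c.class_ends[crossing], c.r[crossing]
    point = x0 + (0.0 - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x1
    return XIntercept(bracket=(float(x0), float(x1)), point=float(point))


@dataclass
class PatchSize:
    side: float        # meters, lower bracket bound ("at least side x side")
    area: float        # m^2
    statement: str


def patch_size(interval: XIntercept) -> PatchSize:
    """Genetic patch as an "at least L x L" square from the x-intercept bracket."""
    side = interval.bracket[0]
    return PatchSize(side=side, area=side * side,
                     statement=f"at least {side:g} x {side:g} m")
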