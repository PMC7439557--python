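"""Effective population size and effective density estimators.

Three routes to the effective density D = Ne / area used by the IBD sigma
formula:

1. PWoP ("parentage analysis without parents"): full- and half-sibling dyads
   among the sampled individuals are assembled into sibships, the implied
   per-parent offspring counts k are reconstructed, and Ne follows from the
   Crow-Denniston form  Ne = (k_bar * Np - 2) / (k_bar - 1 + Vk / k_bar).
2. LD-Ne: mean squared genotypic correlation between unlinked loci, corrected
   for the 1/S sampling contribution (Waples 2006 small-sample constants),
   gives Ne ~ 1 / (3 * r2'); the CI is a delete-one-locus jackknife.
3. Entomological survey: average monthly female catch per area, doubled for a
   1:1 sex ratio, gives breeding individuals per square meter directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial_io import GenotypeTable

SQ_METERS_PER_ACRE = 4046.8564224


class DensityError(ValueError):
    pass


class NeUnboundedError(DensityError):
    """The data contain no information bounding Ne (no sib dyads, or r2 <= 1/S)."""


@dataclass
class NeEstimate:
    ne: float
    ci: tuple[float, float] | None
    method: str
    flagged: bool = False
    note: str = ""


@dataclass
class DensityEstimate:
    d: float  # individuals per m^2
    ci: tuple[float, float] | None
    method: str


def crow_denniston_ne(k: np.ndarray) -> float:
    """Inbreeding effective size from a per-parent offspring-count vector."""
    k = np.asarray(k, dtype=float)
    if k.size == 0 or k.sum() == 0:
        raise NeUnboundedError("no parents with offspring: Ne unbounded by data")
    kbar = k.mean()
    vk = k.var()  # population variance, per Crow-Denniston
    denom = kbar - 1.0 + vk / kbar
    if denom <= 0:
        raise NeUnboundedError("offspring-count variance too low: Ne unbounded")
    return (kbar * k.size - 2.0) / denom


class _SibshipStructure:
    """Deterministic greedy assembly of sibships and parent slots from dyads.

    Full-sib dyads are union-found into sibships; each sibship owns a mother
    slot and a father slot.  Half-sib dyads merge the father slots of the two
    sibships involved (half sibs are taken as paternal).  Individuals in no
    dyad form singleton sibships.
    """

    def __init__(self, individuals: list[str], fs_pairs, hs_pairs):
        self.individuals = sorted(individuals)
        parent = {i: i for i in self.individuals}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in sorted(fs_pairs):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        self.sibship_of = {i: find(i) for i in self.individuals}
        roots = sorted(set(self.sibship_of.values()))
        # two parent slots per sibship, merged across sibships by HS links
        slot_parent = {}
        for r in roots:
            slot_parent[(r, "m")] = (r, "m")
            slot_parent[(r, "f")] = (r, "f")

        def sfind(x):
            while slot_parent[x] != x:
                slot_parent[x] = slot_parent[slot_parent[x]]
                x = slot_parent[x]
            return x

        for a, b in sorted(hs_pairs):
            ra, rb = self.sibship_of[a], self.sibship_of[b]
            if ra == rb:
                continue  # contradicts an FS link; FS takes precedence
            fa, fb = sfind((ra, "f")), sfind((rb, "f"))
            if fa != fb:
                slot_parent[max(fa, fb)] = min(fa, fb)
        self._sfind = sfind

    def offspring_counts(self, members_override: dict | None = None) -> np.ndarray:
        sizes: dict = {}
        if members_override is None:
            members = {}
            for i, r in self.sibship_of.items():
                members.setdefault(r, []).append(i)
        else:
            members = members_override
        counts: dict = {}
        for r, mem in members.items():
            n = len(mem)
            if n == 0:
                continue
            for slot in ((r, "m"), (r, "f")):
                root = self._sfind(slot)
                counts[root] = counts.get(root, 0) + n
        return np.array(sorted(counts.values()), dtype=float)


def _split_pairs(pairs: pd.DataFrame):
    fs = [tuple(sorted((r.id1, r.id2))) for r in pairs.itertuples() if r.category == "FS"]
    hs = [tuple(sorted((r.id1, r.id2))) for r in pairs.itertuples() if r.category == "SECOND"]
    return fs, hs


def ne_pwop(pairs: pd.DataFrame, individuals: list[str],
            n_resample: int = 100, seed: int | None = None) -> NeEstimate:
    """Sib-frequency (PWoP) effective size from classified kin pairs.

    ``pairs`` is a kin-pair table (id1, id2, category); FS dyads imply both
    parents shared, SECOND dyads one shared parent.  The 95% CI comes from
    ``n_resample`` perturbed datasets in which one randomly chosen individual
    is replaced by a duplicate of another (moved into its sibship).
    """
    fs, hs = _split_pairs(pairs)
    if not fs and not hs:
        raise NeUnboundedError("no sibling dyads detected: Ne unbounded by data")
    structure = _SibshipStructure(list(individuals), fs, hs)
    k = structure.offspring_counts()
    ne = crow_denniston_ne(k)
    n_sibs = max(len(m) for m in _members(structure).values())
    flagged = ne <= 4 or n_sibs >= 0.5 * len(individuals)

    rng = np.random.default_rng(seed)
    boots = []
    base_members = _members(structure)
    ids = structure.individuals
    for _ in range(n_resample):
        i = ids[rng.integers(len(ids))]
        j = ids[rng.integers(len(ids))]
        members = {r: list(m) for r, m in base_members.items()}
        members[structure.sibship_of[i]].remove(i)
        members[structure.sibship_of[j]].append(f"{j}_dup")
        try:
            boots.append(crow_denniston_ne(structure.offspring_counts(members)))
        except NeUnboundedError:
            continue
    ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else None
    return NeEstimate(ne=ne, ci=ci, method="PWoP", flagged=flagged,
                      note="small or sib-dominated sample" if flagged else "")


def _members(structure: _SibshipStructure) -> dict:
    members: dict = {}
    for i, r in structure.sibship_of.items():
        members.setdefault(r, []).append(i)
    return members


# ---------------------------------------------------------------------------
# LD-based Ne


def _waples_bias(S: float) -> float:
    if S >= 30:
        return 1.0 / S + 3.19 / S ** 2
    return 0.0018 + 0.907 / S + 4.44 / S ** 2


def ne_from_r2(r2_mean: float, S: float, correction: str = "waples06") -> float:
    """Ne from a mean squared genotypic correlation and sample size S.

    ``correction='none'`` uses the uncorrected 1 / (3 * (r2 - 1/S)); the
    default applies the Waples (2006) random-mating small-sample constants.
    """
    if correction == "none":
        excess = r2_mean - 1.0 / S
        if excess <= 0:
            raise NeUnboundedError("r2 <= 1/S: infinite Ne estimate")
        return 1.0 / (3.0 * excess)
    r2p = r2_mean - _waples_bias(S)
    if r2p <= 0:
        raise NeUnboundedError("r2 at or below its sampling expectation: infinite Ne")
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        return (1.0 / 3.0 + math.sqrt(max(disc, 0.0))) / (2.0 * r2p)
    disc = 0.308 ** 2 - 2.08 * r2p
    return (0.308 + math.sqrt(max(disc, 0.0))) / (2.0 * r2p)


def ne_ld(g: GenotypeTable, maf_min: float = 0.05, max_loci: int = 400,
          correction: str = "waples06", seed: int | None = None) -> NeEstimate:
    """LD effective size from the mean squared dosage correlation across loci.

    Loci below the MAF threshold are dropped; when more than ``max_loci``
    remain, a random subset (seeded) is used.  Missing calls are mean-imputed
    per locus for the correlation.  The 95% CI is a delete-one-locus jackknife.
    """
    x = g.calls.astype(float)
    x[g.calls == -1] = np.nan
    p_alt = np.nanmean(x, axis=0) / 2.0
    maf = np.minimum(p_alt, 1 - p_alt)
    keep = np.where(np.nan_to_num(maf) >= maf_min)[0]
    if keep.size < 50:
        raise DensityError(f"need >= 50 SNPs after MAF filter, have {keep.size}")
    if g.n_individuals < 20:
        raise DensityError("need >= 20 individuals for the LD estimator")
    rng = np.random.default_rng(seed)
    if keep.size > max_loci:
        keep = np.sort(rng.choice(keep, size=max_loci, replace=False))
    x = x[:, keep]
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = mu[idx[1]]
    S = float(g.n_individuals)
    c = np.corrcoef(x, rowvar=False)
    L = c.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    r2 = c[iu, ju] ** 2
    r2_mean = float(r2.mean())
    ne = ne_from_r2(r2_mean, S, correction)

    # delete-one-locus jackknife on the mean r2, mapped through the estimator
    sums_per_locus = np.zeros(L)
    np.add.at(sums_per_locus, iu, r2)
    np.add.at(sums_per_locus, ju, r2)
    total = r2.sum()
    n_pairs = len(r2)
    jack = []
    for l in range(L):
        m = (total - sums_per_locus[l]) / (n_pairs - (L - 1))
        try:
            jack.append(ne_from_r2(m, S, correction))
        except NeUnboundedError:
            jack.append(np.inf)
    jack = np.array(jack)
    theta_bar = jack[np.isfinite(jack)].mean() if np.isfinite(jack).any() else ne
    var = (L - 1) / L * ((np.where(np.isfinite(jack), jack, theta_bar) - theta_bar) ** 2).sum()
    se = math.sqrt(var)
    ci = (max(ne - 1.96 * se, 0.0), ne + 1.96 * se)
    return NeEstimate(ne=ne, ci=ci, method="LD")


def density_from_ne(ne: NeEstimate, area_m2: float) -> DensityEstimate:
    """Effective density D = Ne / study area (per m^2); CI scales identically."""
    if area_m2 <= 0:
        raise DensityError("area must be positive")
    ci = None
    if ne.ci is not None:
        ci = (ne.ci[0] / area_m2, ne.ci[1] / area_m2)
    return DensityEstimate(d=ne.ne / area_m2, ci=ci, method=f"ne_over_area[{ne.method}]")


def density_from_trap_survey(mean_females_per_month: float, area_acres: float,
                             female_range: tuple[float, float] | None = None) -> DensityEstimate:
    """Entomological density: 2 x monthly females / area (1:1 sex ratio)."""
    if area_acres <= 0:
        raise DensityError("area must be positive")
    if mean_females_per_month < 0:
        raise DensityError("female count must be nonnegative")
    area_m2 = area_acres * SQ_METERS_PER_ACRE
    d = 2.0 * mean_females_per_month / area_m2
    ci = None
    if female_range is not None:
        lo, hi = sorted(female_range)
        ci = (2.0 * lo / area_m2, 2.0 * hi / area_m2)
    return DensityEstimate(d=d, ci=ci, method="trap_survey")
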