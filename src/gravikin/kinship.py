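"""Allele-frequency-free pairwise relatedness statistics and kin classification.

For a pair of individuals the joint genotype tally counts, over sites called
in both, how often individual i carries dosage g1 while j carries g2.  Three
statistics summarize the tally:

* KING-robust kinship  phi = (n11 - 2*n_opp) / (het_i + het_j)
* R0 = n_opp / n11   (opposite homozygotes per shared heterozygote)
* R1 = n11 / n_discordant (shared heterozygotes per discordant-genotype site)

where n11 counts sites with both individuals heterozygous, n_opp counts
opposite homozygotes (0/2 and 2/0) and het_* count heterozygous sites of each
individual over the shared sites.  None of these require population allele
frequencies.  Classification into kin categories uses threshold bands on the
kinship coefficient at the geometric midpoints between expected values
(0.25 full sib / parent-offspring, 0.125 second degree, 0.0625 third degree),
with parent-offspring split from full siblings by R0 ~ 0 (true PO pairs
cannot show opposite homozygotes barring genotyping error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial_io import GenotypeTable

CATEGORIES = ("PO", "FS", "SECOND", "THIRD", "UNRELATED", "DUPLICATE", "UNASSIGNED")
CLOSE_KIN_CATEGORIES = ("PO", "FS", "SECOND", "THIRD")


class KinshipError(ValueError):
    pass


@dataclass
class JointGenotypeTally:
    """3x3 joint dosage counts for one pair over sites called in both."""

    counts: np.ndarray  # counts[g1, g2]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise KinshipError("joint tally must be a nonnegative 3x3 count matrix")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_both_het(self) -> int:
        return int(self.counts[1, 1])

    @property
    def n_opposite_hom(self) -> int:
        return int(self.counts[0, 2] + self.counts[2, 0])

    @property
    def het_i(self) -> int:
        return int(self.counts[1, :].sum())

    @property
    def het_j(self) -> int:
        return int(self.counts[:, 1].sum())

    @property
    def n_discordant(self) -> int:
        return int(self.n_total - np.trace(self.counts))

    def transpose(self) -> "JointGenotypeTally":
        return JointGenotypeTally(self.counts.T)


@dataclass(frozen=True)
class KinshipThresholds:
    """Classification bands; defaults are the geometric-midpoint KING bands."""

    duplicate: float = 2 ** -1.5        # ~0.354
    first_degree: float = 2 ** -2.5     # ~0.177
    second_degree: float = 2 ** -3.5    # ~0.0884
    third_degree: float = 2 ** -4.5     # ~0.0442
    po_r0_max: float = 0.005            # R0 below this splits PO from FS
    min_sites: int = 500


DEFAULT_THRESHOLDS = KinshipThresholds()


def tally_joint_genotypes(g: GenotypeTable, i: str, j: str,
                          min_sites: int = 500) -> JointGenotypeTally:
    """Joint genotype tally for individuals i and j over pairwise-complete sites."""
    if i == j:
        raise KinshipError("a pair requires two distinct individuals")
    idx = {iid: k for k, iid in enumerate(g.individual_ids)}
    gi, gj = g.calls[idx[i]], g.calls[idx[j]]
    ok = (gi >= 0) & (gj >= 0)
    n_total = int(ok.sum())
    if n_total < min_sites:
        raise KinshipError(
            f"insufficient overlap for pair ({i}, {j}): {n_total} < {min_sites} sites"
        )
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (gi[ok], gj[ok]), 1)
    return JointGenotypeTally(counts)


def king_robust(t: JointGenotypeTally, het_i: int | None = None,
                het_j: int | None = None) -> float:
    """KING-robust kinship coefficient from a joint tally.

    Heterozygote counts default to the tally margins (i.e. counted over the
    pairwise-complete sites, which keeps the statistic symmetric).
    """
    het_i = t.het_i if het_i is None else het_i
    het_j = t.het_j if het_j is None else het_j
    denom = het_i + het_j
    if denom <= 0:
        raise KinshipError("no heterozygous sites: KING kinship undefined")
    return (t.n_both_het - 2.0 * t.n_opposite_hom) / denom


def r0_statistic(t: JointGenotypeTally) -> float:
    """R0 = opposite homozygotes / shared heterozygotes."""
    if t.n_both_het == 0:
        raise KinshipError("undefined statistic: no doubly heterozygous sites")
    return t.n_opposite_hom / t.n_both_het


def r1_statistic(t: JointGenotypeTally) -> float:
    """R1 = shared heterozygotes / discordant-genotype sites."""
    if t.n_discordant == 0:
        raise KinshipError("undefined statistic: no discordant sites")
    return t.n_both_het / t.n_discordant


def classify_kinship(king: float, r0: float,
                     thresholds: KinshipThresholds = DEFAULT_THRESHOLDS) -> str:
    """Deterministic kin category from (KING kinship, R0) threshold bands."""
    if not np.isfinite(king):
        return "UNASSIGNED"
    if king >= thresholds.duplicate:
        return "DUPLICATE"
    if king >= thresholds.first_degree:
        return "PO" if (np.isfinite(r0) and r0 < thresholds.po_r0_max) else "FS"
    if king >= thresholds.second_degree:
        return "SECOND"
    if king >= thresholds.third_degree:
        return "THIRD"
    return "UNRELATED"


def all_pairs_kinship(g: GenotypeTable,
                      thresholds: KinshipThresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Kinship statistics and category for every unordered pair of individuals.

    Returns a DataFrame with columns id1, id2, king, r0, r1, n_sites, category.
    Statistics are computed on pairwise-complete sites via dense matrix
    products, so the whole-cohort sweep is a handful of matmuls.
    """
    if g.n_individuals < 2:
        raise KinshipError("need at least two individuals")
    calls = g.calls
    called = (calls >= 0).astype(np.float32)
    is_het = (calls == 1).astype(np.float32)
    is_rr = (calls == 0).astype(np.float32)
    is_aa = (calls == 2).astype(np.float32)

    n_total = called @ called.T
    n11 = is_het @ is_het.T
    n02 = is_rr @ is_aa.T
    n00 = is_rr @ is_rr.T
    n22 = is_aa @ is_aa.T
    het_i = is_het @ called.T          # het sites of i among pair-complete sites
    n_opp = n02 + n02.T
    n_conc = n00 + n11 + n22
    n_disc = n_total - n_conc
    het_sum = het_i + het_i.T

    with np.errstate(divide="ignore", invalid="ignore"):
        king = np.where(het_sum > 0, (n11 - 2.0 * n_opp) / het_sum, np.nan)
        r0 = np.where(n11 > 0, n_opp / n11, np.nan)
        r1 = np.where(n_disc > 0, n11 / n_disc, np.nan)

    iu, ju = np.triu_indices(g.n_individuals, k=1)
    ids = np.asarray(g.individual_ids)
    records = pd.DataFrame({
        "id1": ids[iu], "id2": ids[ju],
        "king": king[iu, ju], "r0": r0[iu, ju], "r1": r1[iu, ju],
        "n_sites": n_total[iu, ju].astype(int),
    })
    cats = [
        "UNASSIGNED" if n < thresholds.min_sites else classify_kinship(k, z, thresholds)
        for k, z, n in zip(records["king"], records["r0"], records["n_sites"])
    ]
    records["category"] = cats
    return records


def close_kin_ids(pairs: pd.DataFrame) -> set[str]:
    """Individuals appearing in at least one close-kin pair (for IBD exclusion)."""
    ck = pairs[pairs["category"].isin(CLOSE_KIN_CATEGORIES)]
    return set(ck["id1"]) | set(ck["id2"])
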