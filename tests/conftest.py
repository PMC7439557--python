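"""Shared fixtures: small simulated datasets and direct Mendelian pedigrees."""

import numpy as np
import pytest

from gravikin.spatial_io import GenotypeTable
from gravikin.simulate import SimConfig, simulate_population


def hwe_genotypes(rng, freqs, n):
    return rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8)


def mendelian_child(rng, gm, gf):
    a = (rng.random(gm.shape) < gm / 2.0).astype(np.int8)
    b = (rng.random(gf.shape) < gf / 2.0).astype(np.int8)
    return a + b


def kin_pair_cohort(rng, n_snps=10000, n_pairs=100, category="FS"):
    """Genotypes for ``n_pairs`` independent pairs of a given true category.

    Returns a GenotypeTable of 2*n_pairs individuals where individuals
    (2k, 2k+1) form the k-th pair; all pairs are mutually unrelated.
    """
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    rows = []
    for _ in range(n_pairs):
        if category == "FS":
            gm, gf = hwe_genotypes(rng, freqs, 2)
            rows += [mendelian_child(rng, gm, gf), mendelian_child(rng, gm, gf)]
        elif category == "PO":
            gm, gf = hwe_genotypes(rng, freqs, 2)
            rows += [gm, mendelian_child(rng, gm, gf)]
        elif category == "SECOND":  # paternal half siblings
            gf, gm1, gm2 = hwe_genotypes(rng, freqs, 3)
            rows += [mendelian_child(rng, gm1, gf), mendelian_child(rng, gm2, gf)]
        elif category == "THIRD":  # first cousins via full-sib mothers
            ggm, ggf, f1, f2 = hwe_genotypes(rng, freqs, 4)
            m1 = mendelian_child(rng, ggm, ggf)
            m2 = mendelian_child(rng, ggm, ggf)
            rows += [mendelian_child(rng, m1, f1), mendelian_child(rng, m2, f2)]
        elif category == "UNRELATED":
            rows += list(hwe_genotypes(rng, freqs, 2))
        else:
            raise ValueError(category)
    calls = np.vstack(rows)
    ids = [f"{category}_{k}" for k in range(len(rows))]
    return GenotypeTable(ids, [f"s{j}" for j in range(n_snps)], calls)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated landscape shared across read-only tests."""
    cfg = SimConfig(seed=11, n_snps=3000, n_founders=400, max_captures=100,
                    n_generations=3)
    return simulate_population(cfg)
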