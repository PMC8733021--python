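"""Shared fixtures: small hand-checkable datasets, brute-force oracles and
a session-scoped gene-drop replicate study used by the statistical tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ibdcoef as ib

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def sharing_mean_bruteforce(dosages: np.ndarray) -> np.ndarray:
    """O(n^2) pair enumeration of the mean between-individual sharing."""
    X = np.asarray(dosages, dtype=float)
    n, L = X.shape
    out = np.zeros(L)
    for l in range(L):
        vals = []
        for j in range(n):
            for k in range(j + 1, n):
                vals.append((1.0 + (X[j, l] - 1.0) * (X[k, l] - 1.0)) / 2.0)
        out[l] = np.mean(vals)
    return out


def roh_bruteforce(calls, bp, min_snps, min_kb, max_het, max_missing):
    """Exhaustive ROH enumeration: all windows within the het/missing budget
    with homozygous endpoints that pass both filters, selected greedily by
    smallest start then longest extent, overlaps discarded."""
    m = len(calls)
    candidates = []
    for s in range(m):
        if calls[s] != 0:
            continue
        het = miss = 0
        for e in range(s + 1, m + 1):
            c = calls[e - 1]
            het += c == 1
            miss += c == 2
            if het > max_het or miss > max_missing:
                break
            if calls[e - 1] != 0:
                continue
            if e - s >= min_snps and (bp[e - 1] - bp[s]) / 1000.0 >= min_kb:
                candidates.append((s, e))
    chosen = []
    taken_until = -1  # sorted by (start, -end): first hit per start is longest
    for s, e in sorted(candidates, key=lambda t: (t[0], -t[1])):
        if s > taken_until:
            chosen.append((s, e))
            taken_until = e - 1
    return chosen


# ---------------------------------------------------------------------------
# small datasets
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_genotypes() -> ib.GenotypeMatrix:
    """The 3-individual, 2-locus worked example used throughout."""
    return ib.GenotypeMatrix(np.array([[0, 1], [1, 1], [2, 2]]))


@pytest.fixture
def random_genotypes() -> ib.GenotypeMatrix:
    rng = np.random.default_rng(7)
    p = rng.uniform(0.05, 0.95, size=500)
    X = rng.binomial(2, p, size=(20, 500))
    return ib.GenotypeMatrix(X)


@pytest.fixture
def fullsib_pedigree() -> ib.Pedigree:
    return ib.Pedigree.from_records(
        [("A", None, None), ("B", None, None), ("C", "A", "B"),
         ("D", "A", "B"), ("E", "C", "D")]
    )


# ---------------------------------------------------------------------------
# gene-drop study (paper-style design at one tenth of the marker density)
# ---------------------------------------------------------------------------

@dataclass
class GeneDropStudy:
    ped: ib.Pedigree
    gmap: ib.GeneticMap
    non_founders: np.ndarray
    ped_params: "ib.TrueParams"
    small_subset: np.ndarray          # 20 non-founders for the n=20 bias check
    small_ped_params: "ib.TrueParams"
    replicates: list[dict]            # per-replicate estimates and gold values


def _one_replicate(ped, gmap, non_founders, small_subset, seed_pair):
    drop_seed, hap_seed = seed_pair
    res = ib.drop_gametes(ped, gmap, seed=drop_seed)
    hap = ib.generate_founder_haplotypes(
        int(ped.is_founder.sum()), gmap.n_markers, seed=hap_seed
    )
    G = ib.paint_genotypes(res, hap)
    Gn = G.subset_samples(non_founders)
    stats = ib.compute_sharing_stats(Gn)
    gold = ib.gold_coefficients(res, non_founders)
    out = {
        "f_AS": ib.estimate_f_as(Gn, stats=stats)[0],
        "psi_AS": ib.estimate_psi_as(Gn, stats=stats),
        "f_UNI_w": ib.estimate_f_uni(Gn, "weighted", stats=stats),
        "f_STD_w": ib.estimate_f_std(Gn, "weighted", stats=stats),
        "gold": gold,
    }
    G20 = G.subset_samples(small_subset)
    out["f_HOM_n20"] = ib.estimate_f_hom(G20)[0]
    out["gold20"] = ib.gold_coefficients(res, small_subset)
    return out


@pytest.fixture(scope="session")
def genedrop_study() -> GeneDropStudy:
    """50 founders, 5 generations, 2,000 markers, 200 gene-drop replicates.

    The pedigree is fixed; each replicate redraws gametes and founder SNP
    haplotypes, giving independent realizations of both genetic and
    statistical sampling around the same pedigree expectations.
    """
    ped = ib.simulate_random_mating_pedigree(50, 5, mean_offspring=2.0, seed=2021)
    gmap = ib.GeneticMap.uniform(n_chrom=20, length_cm=100.0, spacing_cm=1.0)
    non_founders = np.flatnonzero(~ped.is_founder)
    C = ib.coancestry_matrix(ped)
    ped_params = ib.within_population_params(C, non_founders)

    rng = np.random.default_rng(20210402)
    small_subset = np.sort(rng.choice(non_founders, size=20, replace=False))
    small_ped_params = ib.within_population_params(C, small_subset)

    seeds = rng.integers(2**31, size=(200, 2))
    reps = [
        _one_replicate(ped, gmap, non_founders, small_subset, tuple(s))
        for s in seeds
    ]
    return GeneDropStudy(
        ped=ped,
        gmap=gmap,
        non_founders=non_founders,
        ped_params=ped_params,
        small_subset=small_subset,
        small_ped_params=small_ped_params,
        replicates=reps,
    )
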