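"""Estimator hand values, algebraic identities, linearity and rank
invariance, expectation formulas, transforms and ranks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import ibdcoef as ib

dosage_matrices = arrays(
    np.int8,
    shape=st.tuples(st.integers(3, 10), st.integers(2, 15)),
    elements=st.integers(0, 2),
)


def _polymorphic(X) -> bool:
    p = X.mean(axis=0) / 2.0
    return bool(np.any((p > 0) & (p < 1)))


# ---------------------------------------------------------------------------
# hand-derived values on the 3 x 2 worked example
# ---------------------------------------------------------------------------

def test_f_as_hand_values(tiny_genotypes):
    f, f_W = ib.estimate_f_as(tiny_genotypes)
    assert np.allclose(np.round(f, 4), [0.1429, -0.7143, 1.0])
    assert f_W == pytest.approx(f.mean())


def test_psi_as_hand_values(tiny_genotypes):
    psi = ib.estimate_psi_as(tiny_genotypes)
    assert np.allclose(np.round(psi, 4), [-0.0588, -0.0588, 0.1176])
    assert psi.sum() == pytest.approx(0.0, abs=1e-12)


def test_f_hom_hand_value(tiny_genotypes):
    f, _ = ib.estimate_f_hom(tiny_genotypes)
    assert round(f[0], 4) == -0.0588


def test_f_uni_hand_value(tiny_genotypes):
    f = ib.estimate_f_uni(tiny_genotypes, "weighted")
    assert round(f[0], 4) == 0.0588


def test_f_std_hand_value(tiny_genotypes):
    f = ib.estimate_f_std(tiny_genotypes, "weighted")
    assert round(f[0], 4) == pytest.approx(0.1765)


def test_psi_std_hand_value(tiny_genotypes):
    K = ib.kinship_std_matrix(tiny_genotypes)
    assert round(K.values[0, 1], 4) == 0.0588


def test_all_homozygous_individual_estimates_one():
    G = ib.GenotypeMatrix(np.array([[0, 2, 0], [1, 1, 2], [2, 1, 1]]))
    f, _ = ib.estimate_f_as(G)
    assert f[0] == pytest.approx(1.0)


def test_uni_heterozygote_per_locus_term():
    """A heterozygote at p = 0.5 contributes a per-locus ratio of -1."""
    G = ib.GenotypeMatrix(np.array([[1], [0], [2], [1]]))
    f = ib.estimate_f_uni(G, "unweighted")
    assert f[0] == pytest.approx(-1.0)


def test_single_snp_hom_estimates_one_or_negative():
    G = ib.GenotypeMatrix(np.array([[2], [1], [0], [1]]))
    f, _ = ib.estimate_f_hom(G)
    assert f[0] == pytest.approx(1.0)
    assert f[1] < 0


# ---------------------------------------------------------------------------
# identities and invariances
# ---------------------------------------------------------------------------

def test_ladder_identities_random(random_genotypes):
    """f_UNI^w + 2 psi_AS = f_HOM and f_STD^w + 4 psi_AS = f_HOM exactly."""
    G = random_genotypes
    psi = ib.estimate_psi_as(G)
    f_hom, _ = ib.estimate_f_hom(G)
    assert np.allclose(ib.estimate_f_uni(G) + 2 * psi, f_hom, atol=1e-10)
    assert np.allclose(ib.estimate_f_std(G) + 4 * psi, f_hom, atol=1e-10)


@given(dosage_matrices)
def test_ladder_identities_property(X):
    if not _polymorphic(X):
        return
    G = ib.GenotypeMatrix(X)
    psi = ib.estimate_psi_as(G)
    f_hom, _ = ib.estimate_f_hom(G)
    assert np.allclose(ib.estimate_f_uni(G) + 2 * psi, f_hom, atol=1e-10)
    assert np.allclose(ib.estimate_f_std(G) + 4 * psi, f_hom, atol=1e-10)


def test_pairwise_kinship_identity(random_genotypes):
    """psi_AS_jj' (large-sample form) = psi_STD_jj' + psi_AS_j + psi_AS_j'."""
    G = random_genotypes
    psi = ib.estimate_psi_as(G)
    K_as = ib.kinship_as_matrix(G, mode="large_sample").values
    K_std = ib.kinship_std_matrix(G).values
    expect = K_std + psi[:, None] + psi[None, :]
    off = ~np.eye(G.n, dtype=bool)
    assert np.allclose(K_as[off], expect[off], atol=1e-10)


def test_as_kinship_offdiagonal_mean_zero(random_genotypes):
    K = ib.kinship_as_matrix(random_genotypes, mode="exact")
    assert K.off_diagonal_mean == pytest.approx(0.0, abs=1e-12)
    f_as, _ = ib.estimate_f_as(random_genotypes)
    assert np.allclose(np.diag(K.values), (1 + f_as) / 2)


def test_psi_exact_mode_is_mean_of_pairwise(random_genotypes):
    K = ib.kinship_as_matrix(random_genotypes, mode="exact").values
    M = K.copy()
    np.fill_diagonal(M, np.nan)
    assert np.allclose(
        ib.estimate_psi_as(random_genotypes, mode="exact"),
        np.nanmean(M, axis=1),
    )


def test_std_kinship_diagonal_and_duplicate():
    rng = np.random.default_rng(11)
    X = rng.integers(0, 3, size=(8, 60))
    G = ib.GenotypeMatrix(X)
    ref = list(range(8))
    K = ib.kinship_std_matrix(G)
    f_std = ib.estimate_f_std(G)
    assert np.allclose(2 * np.diag(K.values) - 1, f_std)
    # duplicating an individual: with the original sample as reference its
    # pair entry equals the self-kinship (1 + f_STD)/2
    Gdup = ib.GenotypeMatrix(np.vstack([X, X[:1]]))
    Kdup = ib.kinship_std_matrix(Gdup, reference=ref)
    f_dup = ib.estimate_f_std(Gdup, reference=ref)
    assert Kdup.values[0, 8] == pytest.approx((1 + f_dup[0]) / 2)


def test_monomorphic_loci_included_for_as_excluded_for_unweighted():
    X = np.array([[0, 2, 1], [1, 2, 0], [2, 2, 2]])  # locus 1 monomorphic
    G = ib.GenotypeMatrix(X)
    f_with, _ = ib.estimate_f_as(G)
    f_u = ib.estimate_f_uni(G, "unweighted")
    # unweighted UNI equals the mean per-locus ratio over polymorphic loci only
    Gpoly = ib.GenotypeMatrix(X[:, [0, 2]])
    # frequencies differ per locus, so compare against direct computation
    p = G.allele_freqs()
    poly = (p > 0) & (p < 1)
    pp, Xp = p[poly], X[:, poly]
    terms = (Xp**2 - (1 + 2 * pp) * Xp + 2 * pp**2) / (2 * pp * (1 - pp))
    assert np.allclose(f_u, terms.mean(axis=1))
    # weighted forms keep the monomorphic locus without changing the result
    f_uw = ib.estimate_f_uni(G, "weighted")
    f_uw_drop = ib.estimate_f_uni(Gpoly, "weighted")
    assert np.allclose(f_uw, f_uw_drop)
    assert np.all(np.isfinite(f_with))


def test_all_monomorphic_raises():
    G = ib.GenotypeMatrix(np.array([[2, 2], [2, 2], [2, 2]]))
    with pytest.raises(ValueError):
        ib.estimate_f_as(G)
    with pytest.raises(ValueError):
        ib.estimate_f_hom(G)
    with pytest.raises(ValueError):
        ib.estimate_f_uni(G, "unweighted")


def test_linearity_in_total_homozygosity(random_genotypes):
    """f_AS_j = a_S + b_S * (total homozygosity of j), b_S > 0, with the
    constants fitted from two individuals predicting all the rest."""
    G = random_genotypes
    f, _ = ib.estimate_f_as(G)
    A_tot = ib.compute_sharing_stats(G).A_within.sum(axis=1)
    k = int(np.flatnonzero(A_tot != A_tot[0])[0])
    b = (f[k] - f[0]) / (A_tot[k] - A_tot[0])
    a = f[0] - b * A_tot[0]
    assert b > 0
    assert np.allclose(f, a + b * A_tot, atol=1e-10)


@given(dosage_matrices, st.integers(1, 4))
def test_rank_invariance_under_augmentation(X, n_extra):
    """Appending individuals never reorders f_AS for the original sample."""
    rng = np.random.default_rng(12345)
    extra = rng.integers(0, 3, size=(n_extra, X.shape[1]))
    G = ib.GenotypeMatrix(X)
    Gaug = ib.GenotypeMatrix(np.vstack([X, extra]))
    try:
        f_small, _ = ib.estimate_f_as(G)
        f_big, _ = ib.estimate_f_as(Gaug)
    except ValueError:
        return  # degenerate (all-sharing) sample
    n = X.shape[0]
    # tie-aware ranks; rounding guards against float noise on exact ties
    from scipy.stats import rankdata

    assert np.array_equal(
        rankdata(np.round(f_small, 9)), rankdata(np.round(f_big[:n], 9))
    )


# ---------------------------------------------------------------------------
# MLE
# ---------------------------------------------------------------------------

def test_mle_bounds_on_single_locus():
    G = ib.GenotypeMatrix(np.array([[0], [1], [2], [2]]))
    f = ib.estimate_f_mle(G)
    assert f[0] == 1.0   # homozygote: likelihood increasing in f
    assert f[1] == -1.0  # heterozygote: decreasing, smallest valid point


def test_population_mle_equals_moment_estimate_single_locus():
    """Maximizing the joint one-locus likelihood over a common f recovers
    the moment estimate 1 - H/(2pq) to within a grid step."""
    X = np.array([[1], [0], [1], [0], [2], [0]])
    G = ib.GenotypeMatrix(X)
    p = G.allele_freqs()[0]
    het = (X[:, 0] == 1).sum()
    hom = (X[:, 0] != 1).sum()
    fs = np.arange(-0.999, 1.0, 0.001)
    loglik = het * np.log(1 - fs) + hom * np.log(1 - 2 * p * (1 - p) * (1 - fs))
    f_mle = fs[np.argmax(loglik)]
    f_mom = 1 - (het / len(X)) / (2 * p * (1 - p))
    assert abs(f_mle - f_mom) <= 0.001 + 1e-9


def test_mle_tie_and_validity_handling():
    # all grid points invalid: heterozygous individual with grid at f >= 1
    G = ib.GenotypeMatrix(np.array([[1, 1], [0, 2], [2, 0]]))
    with pytest.raises(ValueError, match="no valid grid point"):
        ib.estimate_f_mle(G, grid=(1.0, 1.0, 0.5))


# ---------------------------------------------------------------------------
# expectation formulas
# ---------------------------------------------------------------------------

def _params(f, psi, theta_S=0.0):
    f = np.asarray(f, float)
    psi = np.asarray(psi, float)
    F = f * (1 - theta_S) + theta_S
    Psi = psi * (1 - theta_S) + theta_S
    return ib.TrueParams(
        ids=[str(i) for i in range(f.size)], F=F, Psi=Psi,
        F_W=float(F.mean()), theta_S=theta_S,
    )


def test_expected_value_hom_small_sample():
    """f_j = f_W = 0 at n = 10 gives E[f_HOM_j] = -1/19."""
    params = _params([0.0, 0.0], [0.0, 0.0])
    ev = ib.expected_value(params, 10, "HOM_j")
    assert np.allclose(ev, -1 / 19)


def test_expected_value_large_sample_limits():
    params = _params([0.1, -0.05], [0.0, 0.0])
    assert np.allclose(ib.expected_value(params, np.inf, "UNI_w_j"), params.f)
    assert np.allclose(ib.expected_value(params, np.inf, "HOM_j"), params.f)
    assert np.allclose(ib.expected_value(params, 7, "AS_j"), params.f)
    psi = np.array([0.02, -0.02])
    params2 = _params([0.1, 0.1], psi)
    assert np.allclose(
        ib.expected_value(params2, np.inf, "STD_w_j"), params2.f - 4 * psi
    )
    with pytest.raises(ValueError, match="unknown estimator"):
        ib.expected_value(params, 10, "nope")


def test_hom_expectation_matches_hwe_simulation():
    """Unrelated non-inbred sample: mean f_HOM over loci-rich simulation
    falls within 3 Monte-Carlo s.e. of the finite-n expectation."""
    rng = np.random.default_rng(99)
    n, L, reps = 30, 4000, 30
    params = _params(np.zeros(n), np.zeros(n))
    expect = float(np.mean(ib.expected_value(params, n, "HOM_W")))
    means = []
    for _ in range(reps):
        p = rng.uniform(0.1, 0.9, size=L)
        X = rng.binomial(2, p, size=(n, L))
        means.append(ib.estimate_f_hom(ib.GenotypeMatrix(X))[1])
    means = np.array(means)
    se = means.std(ddof=1) / np.sqrt(reps)
    assert abs(means.mean() - expect) < 3 * se


# ---------------------------------------------------------------------------
# transforms and ranks
# ---------------------------------------------------------------------------

def test_rescale_nonnegative_values_and_properties():
    out = ib.rescale_nonnegative([-0.5, 0.0, 0.5])
    assert np.allclose(out, [0.0, 1 / 3, 2 / 3])
    assert out.min() == 0.0
    rng = np.random.default_rng(5)
    f = rng.uniform(-1, 1, size=25)
    out = ib.rescale_nonnegative(f)
    assert np.array_equal(np.argsort(out), np.argsort(f))
    with pytest.raises(ValueError):
        ib.rescale_nonnegative([1.0, 1.0])


def test_rank_estimates_groups_and_ties():
    df = pd.DataFrame(
        {"f": [-0.009, 0.001, -0.130, 0.5, 0.5, 0.5]},
        index=[f"s{i}" for i in range(6)],
    )
    groups = ["a", "a", "a", "b", "b", "b"]
    ranked = ib.rank_estimates(df, groups)
    assert list(ranked["f"][:3]) == [2, 3, 1]
    assert list(ranked["f"][3:]) == [2, 2, 2]  # (k+1)/2 for all-ties


def test_estimate_table_columns_and_psi_sum(random_genotypes):
    table = ib.estimate_table(random_genotypes)
    assert list(table.columns) == list(ib.ESTIMATOR_NAMES)
    assert (table.drop(columns="psi_AS") <= 1 + 1e-12).all().all()
    assert table["psi_AS"].sum() == pytest.approx(0.0, abs=1e-10)


def test_reference_flip_invariance(random_genotypes):
    """Counting the other allele leaves every estimator unchanged."""
    G = random_genotypes
    Gflip = ib.GenotypeMatrix(2 - G.dosages)
    a = ib.estimate_table(G, estimators=["f_AS", "f_HOM", "f_UNI_w", "f_STD_w"])
    b = ib.estimate_table(Gflip, estimators=["f_AS", "f_HOM", "f_UNI_w", "f_STD_w"])
    assert np.allclose(a.values, b.values, atol=1e-10)
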