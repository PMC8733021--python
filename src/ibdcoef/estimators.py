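"""SNP-by-SNP inbreeding and kinship estimators.

Two families are implemented side by side:

* **Allele-sharing estimators** (``f_AS``, ``psi_AS``) compare an
  individual's homozygosity to the average sharing between pairs of
  individuals in a reference set,

      f_AS_j = sum_l (A_j[l] - A_S[l]) / sum_l (1 - A_S[l]).

  They are unbiased for the within-population inbreeding coefficient
  ``f_j`` at every sample size, need no minor-allele-frequency filtering,
  and are *rank invariant*: for fixed genotypes, ``f_AS_j`` is a strictly
  increasing linear function of j's total homozygosity, so enlarging the
  reference set rescales but never reorders the estimates.

* **Frequency-based estimators** (``f_HOM``, ``f_UNI``, ``f_STD``,
  ``f_MLE``) plug the sample allele frequency into moment or likelihood
  formulas.  Their large-sample expectations are confounded by each
  individual's average kinship ``psi_j`` with the rest of the sample
  (``f_UNI -> f_j - 2 psi_j``, ``f_STD -> f_j - 4 psi_j``), so their
  rankings move when the reference sample changes.

All ratio estimators combine loci as "ratios of averages" (sum numerators
and denominators before dividing); the unweighted UNI/STD variants average
per-locus ratios instead and must drop monomorphic loci.  Missing genotypes
are handled by per-locus pairwise deletion throughout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genotypes import GenotypeMatrix, SharingStats, compute_sharing_stats
from .pedigree import TrueParams

ESTIMATOR_NAMES = (
    "f_AS",
    "psi_AS",
    "f_HOM",
    "f_UNI_w",
    "f_UNI_u",
    "f_STD_w",
    "f_STD_u",
    "f_MLE",
)


def _prep(G: GenotypeMatrix, reference, stats: SharingStats | None):
    if stats is None:
        stats = compute_sharing_stats(G, reference=reference)
    X = G.dosages[:, stats.kept_loci].astype(float)
    obs = X >= 0
    X[~obs] = np.nan
    return stats, X, obs


# ---------------------------------------------------------------------------
# allele-sharing family
# ---------------------------------------------------------------------------

def estimate_f_as(
    G: GenotypeMatrix,
    reference: Sequence[int] | None = None,
    stats: SharingStats | None = None,
) -> tuple[np.ndarray, float]:
    """Allele-sharing inbreeding estimates and their sample mean.

    Returns ``(f_AS per individual, f_AS_W)``.  Monomorphic loci are kept:
    they contribute equally to numerator and denominator shifts and the
    estimator needs no frequency filtering.
    """
    stats, X, obs = _prep(G, reference, stats)
    num = np.nansum(stats.A_within - stats.A_between_mean, axis=1)
    den = obs @ (1.0 - stats.A_between_mean)
    if np.any(den <= 0):
        raise ValueError(
            "zero allele-sharing denominator: every locus has between-"
            "individual sharing 1 (degenerate reference sample)"
        )
    f = num / den
    return f, float(f.mean())


def estimate_psi_as(
    G: GenotypeMatrix,
    reference: Sequence[int] | None = None,
    mode: str = "large_sample",
    stats: SharingStats | None = None,
) -> np.ndarray:
    """Individual-specific average kinship ``psi_AS_j``.

    ``mode="large_sample"`` uses the closed dosage form

        psi_AS_j = - sum_l (X_jl - 2 p_l)(1 - 2 p_l) / sum_l 4 p_l (1 - p_l)

    which sums to zero exactly over the reference individuals and satisfies
    the ladder identities with f_HOM/f_UNI/f_STD.  ``mode="exact"`` averages
    the exact pairwise allele-sharing kinship of j with every other
    individual instead.
    """
    if mode == "exact":
        K = kinship_as_matrix(G, reference=reference, mode="exact", stats=stats)
        M = K.values.copy()
        np.fill_diagonal(M, np.nan)
        return np.nanmean(M, axis=1)
    if mode != "large_sample":
        raise ValueError("mode must be 'large_sample' or 'exact'")
    stats, X, obs = _prep(G, reference, stats)
    p = stats.p_hat
    num = -np.nansum((X - 2.0 * p) * (1.0 - 2.0 * p), axis=1)
    den = obs @ (4.0 * p * (1.0 - p))
    if np.any(den <= 0):
        raise ValueError("no polymorphic loci: psi_AS denominator is zero")
    return num / den


class KinshipMatrix:
    """Symmetric kinship estimates; diagonal is self-kinship ``(1+f_j)/2``."""

    def __init__(self, ids: list[str], values: np.ndarray, kind: str):
        self.ids = list(ids)
        self.values = np.asarray(values, dtype=float)
        self.kind = kind

    @property
    def off_diagonal_mean(self) -> float:
        n = len(self.ids)
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())


def kinship_as_matrix(
    G: GenotypeMatrix,
    reference: Sequence[int] | None = None,
    mode: str = "exact",
    stats: SharingStats | None = None,
) -> KinshipMatrix:
    """Pairwise allele-sharing kinship ``psi_AS_jj'``.

    ``mode="exact"`` computes ``sum_l (A_jj'[l] - A_S[l]) / sum_l (1 - A_S[l])``
    whose off-diagonal mean is zero by construction when the reference is the
    whole sample.  ``mode="large_sample"`` replaces ``1 - A_S[l]`` by its
    large-n approximation ``2 p_l (1 - p_l)``, which is the form that equals
    ``psi_STD_jj' + psi_AS_j + psi_AS_j'`` identically.
    """
    stats, X, obs = _prep(G, reference, stats)
    C = np.where(obs, X - 1.0, 0.0)
    O = obs.astype(float)
    cross = C @ C.T  # sum over co-observed loci of (X_j-1)(X_j'-1)

    if mode == "exact":
        shift = 0.5 - stats.A_between_mean
        den_w = 1.0 - stats.A_between_mean
    elif mode == "large_sample":
        two_pq = 2.0 * stats.p_hat * (1.0 - stats.p_hat)
        shift = two_pq - 0.5
        den_w = two_pq
    else:
        raise ValueError("mode must be 'exact' or 'large_sample'")

    num = 0.5 * cross + (O * shift) @ O.T
    den = (O * den_w) @ O.T
    if np.any(den <= 0):
        raise ValueError("zero kinship denominator for at least one pair")
    K = num / den
    # diagonal convention: self-kinship (1 + f_AS_j) / 2
    f_as, _ = estimate_f_as(G, reference=reference, stats=stats)
    np.fill_diagonal(K, (1.0 + f_as) / 2.0)
    return KinshipMatrix(G.sample_ids, K, kind="AS")


# ---------------------------------------------------------------------------
# frequency-based family
# ---------------------------------------------------------------------------

def estimate_f_hom(
    G: GenotypeMatrix,
    mode: str = "weighted",
    reference: Sequence[int] | None = None,
    stats: SharingStats | None = None,
):
    """Homozygosity-based moment estimator (PLINK ``--het`` style).

    ``mode="weighted"`` returns the ratio-of-averages per individual,

        f_HOM_j = 1 - sum_l H_jl / sum_l 2 p_l (1 - p_l),

    as ``(per-individual array, population mean)``.  ``mode="per_locus"``
    returns the diagnostic n x L matrix of single-locus estimates
    ``1 - H_jl / (2 p_l (1 - p_l))`` with NaN at monomorphic loci.
    """
    stats, X, obs = _prep(G, reference, stats)
    p = stats.p_hat
    two_pq = 2.0 * p * (1.0 - p)
    H = stats.het_indicator
    if mode == "per_locus":
        with np.errstate(invalid="ignore", divide="ignore"):
            per = 1.0 - H / np.where(two_pq > 0, two_pq, np.nan)
        return per
    if mode != "weighted":
        raise ValueError("mode must be 'weighted' or 'per_locus'")
    den = obs @ two_pq
    if np.any(den <= 0):
        raise ValueError("all loci monomorphic: f_HOM denominator is zero")
    f = 1.0 - np.nansum(H, axis=1) / den
    return f, float(f.mean())


def _uni_terms(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    return X**2 - (1.0 + 2.0 * p) * X + 2.0 * p**2


def estimate_f_uni(
    G: GenotypeMatrix,
    weighting: str = "weighted",
    reference: Sequence[int] | None = None,
    stats: SharingStats | None = None,
) -> np.ndarray:
    """Correlation-of-uniting-gametes estimator (GCTA ``--ibc`` Fhat3).

    Weighted form sums numerators and denominators over loci; unweighted
    form averages per-locus ratios, dropping monomorphic loci whose ratio
    is undefined.
    """
    stats, X, obs = _prep(G, reference, stats)
    p = stats.p_hat
    two_pq = 2.0 * p * (1.0 - p)
    terms = _uni_terms(X, p)
    if weighting == "weighted":
        den = obs @ two_pq
        if np.any(den <= 0):
            raise ValueError("all loci monomorphic: f_UNI denominator is zero")
        return np.nansum(terms, axis=1) / den
    if weighting != "unweighted":
        raise ValueError("weighting must be 'weighted' or 'unweighted'")
    poly = two_pq > 0
    if not poly.any():
        raise ValueError("all loci monomorphic: unweighted f_UNI undefined")
    with np.errstate(invalid="ignore"):
        ratios = terms[:, poly] / two_pq[poly]
    return np.nanmean(ratios, axis=1)


def estimate_f_std(
    G: GenotypeMatrix,
    weighting: str = "weighted",
    reference: Sequence[int] | None = None,
    stats: SharingStats | None = None,
) -> np.ndarray:
    """VanRaden GRM-diagonal estimator (GCTA Fhat1, ``f_GCTA1``)."""
    stats, X, obs = _prep(G, reference, stats)
    p = stats.p_hat
    two_pq = 2.0 * p * (1.0 - p)
    sq = (X - 2.0 * p) ** 2
    if weighting == "weighted":
        den = obs @ two_pq
        if np.any(den <= 0):
            raise ValueError("all loci monomorphic: f_STD denominator is zero")
        return np.nansum(sq, axis=1) / den - 1.0
    if weighting != "unweighted":
        raise ValueError("weighting must be 'weighted' or 'unweighted'")
    poly = two_pq > 0
    if not poly.any():
        raise ValueError("all loci monomorphic: unweighted f_STD undefined")
    with np.errstate(invalid="ignore"):
        ratios = sq[:, poly] / two_pq[poly]
    return np.nanmean(ratios, axis=1) - 1.0


def kinship_std_matrix(
    G: GenotypeMatrix,
    reference: Sequence[int] | None = None,
    stats: SharingStats | None = None,
) -> KinshipMatrix:
    """VanRaden first-method GRM elements as kinship estimates.

    Off-diagonal ``psi_STD_jj' = sum_l (X_jl - 2p_l)(X_j'l - 2p_l) /
    sum_l 4 p_l (1 - p_l)``; diagonal set to ``(1 + f_STD_j) / 2`` so the
    GRM is ``2 *`` this matrix.
    """
    stats, X, obs = _prep(G, reference, stats)
    p = stats.p_hat
    four_pq = 4.0 * p * (1.0 - p)
    D = np.where(obs, X - 2.0 * p, 0.0)
    O = obs.astype(float)
    num = D @ D.T
    den = (O * four_pq) @ O.T
    if np.any(den <= 0):
        raise ValueError("zero kinship denominator for at least one pair")
    K = num / den
    f_std = estimate_f_std(G, "weighted", reference=reference, stats=stats)
    np.fill_diagonal(K, (1.0 + f_std) / 2.0)
    return KinshipMatrix(G.sample_ids, K, kind="STD")


def estimate_f_mle(
    G: GenotypeMatrix,
    grid: tuple[float, float, float] = (-1.0, 1.0, 0.001),
    reference: Sequence[int] | None = None,
    stats: SharingStats | None = None,
) -> np.ndarray:
    """Grid-search maximum-likelihood estimate of each ``f_j``.

    Maximizes ``sum_l { H_jl ln(1-f) + (1-H_jl) ln[1 - 2 p_l (1-p_l)(1-f)] }``
    over grid points where every log argument is positive; ties break toward
    the smaller ``f``.  Uses sample frequencies in place of the unknown
    allele probabilities, so like f_HOM it targets ``f_j``, not ``F_j``.
    """
    lo, hi, step = grid
    if step <= 0:
        raise ValueError("grid step must be positive")
    fs = np.round(np.arange(lo, hi + step / 2.0, step), 12)
    fs = fs[fs <= 1.0]
    if fs.size == 0:
        raise ValueError("empty grid")

    stats, X, obs = _prep(G, reference, stats)
    p = stats.p_hat
    two_pq = 2.0 * p * (1.0 - p)
    H = np.where(obs, stats.het_indicator, 0.0)
    n_het = H.sum(axis=1)
    B = np.where(obs, 1.0 - stats.het_indicator, 0.0)  # homozygous & observed

    # args[g, l] = 1 - 2p(1-p)(1-f_g); log valid only where > 0
    args = 1.0 - np.outer(1.0 - fs, two_pq)
    valid_l = args > 0.0
    W = np.where(valid_l, np.log(np.where(valid_l, args, 1.0)), 0.0)
    loglik = B @ W.T  # n x G
    # a grid point is invalid for j if any observed homozygous locus has arg <= 0
    invalid = (B @ (~valid_l).T.astype(float)) > 0.0
    # heterozygote term: n_het * ln(1 - f); 0 * ln(0) := 0 at f = 1
    with np.errstate(divide="ignore", invalid="ignore"):
        het_term = np.log1p(-fs)
        het_part = np.outer(n_het, het_term)
    het_part[np.isnan(het_part)] = 0.0  # 0 * -inf at f=1 with no hets
    loglik = loglik + het_part
    loglik[invalid] = -np.inf
    loglik[np.isneginf(het_part) & (n_het[:, None] > 0)] = -np.inf

    best = np.argmax(loglik, axis=1)  # first max -> smallest f on ties
    if np.any(np.isneginf(loglik[np.arange(len(best)), best])):
        j = int(np.flatnonzero(np.isneginf(loglik[np.arange(len(best)), best]))[0])
        raise ValueError(
            f"no valid grid point for individual {G.sample_ids[j]}: "
            "widen the grid below its validity bound"
        )
    return fs[best]


# ---------------------------------------------------------------------------
# expectations, transforms, ranks
# ---------------------------------------------------------------------------

def expected_value(params: TrueParams, n: float, estimator: str) -> np.ndarray | float:
    """Large-number-of-loci expectation of a weighted estimator.

    Evaluates the finite-sample expectation formulas in terms of the
    parametric ``f_j``, ``f_W`` and ``psi_j`` of the reference sample of
    size ``n`` (``n = inf`` gives the large-sample limits).  AS estimators
    are unbiased for ``f`` at every ``n``.
    """
    f, f_W, psi = params.f, params.f_W, params.psi
    inv2n = 0.0 if np.isinf(n) else 1.0 / (2.0 * float(n))
    if not np.isinf(n) and n < 2:
        raise ValueError("sample size must be >= 2")
    denom = 1.0 - inv2n * (1.0 + f_W)

    if estimator == "AS_j":
        return f.copy()
    if estimator == "AS_W":
        return f_W
    if estimator == "HOM_j":
        return (f - inv2n * (1.0 + f_W)) / denom
    if estimator == "HOM_W":
        return (f_W - inv2n * (1.0 + f_W)) / denom
    if estimator == "UNI_w_j":
        return (f - 2.0 * psi - inv2n * (3.0 + 4.0 * f - 8.0 * psi - f_W)) / denom
    if estimator == "STD_w_j":
        return (f - 4.0 * psi - inv2n * (3.0 + 4.0 * f - 8.0 * psi - f_W)) / denom
    if estimator in ("UNI_w_W", "STD_w_W"):
        return (f_W - 3.0 * inv2n * (1.0 + f_W)) / denom
    raise ValueError(f"unknown estimator name {estimator!r}")


def rescale_nonnegative(f_values) -> np.ndarray:
    """Map estimates onto [0, 1] via ``(f - f_min) / (1 - f_min)``.

    A monotone transform: the minimum maps to 0 and ranks are preserved.
    """
    f = np.asarray(f_values, dtype=float)
    if f.size == 0:
        raise ValueError("no values")
    if np.any(f > 1.0):
        raise ValueError("inbreeding estimates cannot exceed 1")
    fmin = f.min()
    if fmin >= 1.0:
        raise ValueError("all estimates equal 1: transform undefined")
    return (f - fmin) / (1.0 - fmin)


def rank_estimates(
    estimates: pd.DataFrame, group_labels: Sequence | None = None
) -> pd.DataFrame:
    """Within-group ranks (1..k ascending, ties averaged) per column."""
    if group_labels is None:
        group_labels = ["all"] * len(estimates)
    groups = pd.Series(list(group_labels), index=estimates.index, name="group")
    ranked = estimates.groupby(groups, sort=False).transform(
        lambda col: rankdata(col, method="average")
    )
    ranked.insert(0, "group", groups)
    return ranked


def estimate_table(
    G: GenotypeMatrix,
    estimators: Sequence[str] = ESTIMATOR_NAMES,
    reference: Sequence[int] | None = None,
    reference_label: str = "all",
    mle_grid: tuple[float, float, float] = (-1.0, 1.0, 0.001),
) -> pd.DataFrame:
    """One row per individual, one column per requested estimator."""
    stats = compute_sharing_stats(G, reference=reference)
    cols: dict[str, np.ndarray] = {}
    for name in estimators:
        if name == "f_AS":
            cols[name] = estimate_f_as(G, stats=stats)[0]
        elif name == "psi_AS":
            cols[name] = estimate_psi_as(G, stats=stats)
        elif name == "f_HOM":
            cols[name] = estimate_f_hom(G, stats=stats)[0]
        elif name == "f_UNI_w":
            cols[name] = estimate_f_uni(G, "weighted", stats=stats)
        elif name == "f_UNI_u":
            cols[name] = estimate_f_uni(G, "unweighted", stats=stats)
        elif name == "f_STD_w":
            cols[name] = estimate_f_std(G, "weighted", stats=stats)
        elif name == "f_STD_u":
            cols[name] = estimate_f_std(G, "unweighted", stats=stats)
        elif name == "f_MLE":
            cols[name] = estimate_f_mle(G, grid=mle_grid, stats=stats)
        else:
            raise ValueError(f"unknown estimator {name!r}")
    out = pd.DataFrame(cols, index=pd.Index(G.sample_ids, name="sample_id"))
    out.attrs["reference_label"] = reference_label
    return out
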