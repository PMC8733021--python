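"""Genotype dosage matrices and allele-sharing summary statistics.

The substrate of every estimator in this package is an ``n x L`` matrix of
reference- (or alternate-) allele dosages ``X[j, l] in {0, 1, 2}`` for ``n``
individuals at ``L`` biallelic SNPs.  Missing genotypes are encoded with a
negative sentinel and every statistic uses per-locus pairwise deletion: the
sample frequency and sharing averages at locus ``l`` are computed over the
individuals genotyped at ``l``.

Allele sharing is the probability that alleles drawn at random from one or
two individuals match.  Within an individual it is the homozygosity
indicator ``A[j, l] = (X[j, l] - 1)**2``; between two individuals it is
``A[j, j', l] = (1 + (X[j, l] - 1) * (X[j', l] - 1)) / 2`` (1 for identical
homozygotes, 0 for opposite homozygotes, 0.5 otherwise).  The average of the
pairwise sharing over all distinct pairs in a reference set, ``A_S[l]``,
anchors the zero point of the within-population estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING = -1


def _as_dosage_array(dosages) -> np.ndarray:
    X = np.asarray(dosages)
    if X.ndim != 2:
        raise ValueError("dosages must be a 2-D (individuals x loci) array")
    if not np.issubdtype(X.dtype, np.integer):
        Xf = np.asarray(X, dtype=float)
        X = np.where(np.isnan(Xf), MISSING, Xf).astype(np.int16)
    else:
        X = X.astype(np.int16, copy=False)
    ok = (X == MISSING) | ((X >= 0) & (X <= 2))
    if not ok.all():
        bad = np.argwhere(~ok)[0]
        raise ValueError(
            f"dosage out of range at individual {bad[0]}, locus {bad[1]}: "
            f"{X[bad[0], bad[1]]} (must be 0, 1, 2 or {MISSING}/NaN for missing)"
        )
    return X


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a sample of individuals.

    Parameters
    ----------
    dosages
        ``n x L`` integer array with entries in ``{0, 1, 2}``; missing
        genotypes as ``-1`` (or NaN in a float input).
    sample_ids, locus_ids
        Row and column labels; generated if omitted.
    chrom, pos
        Optional per-locus chromosome labels and base-pair positions
        (required by the ROH caller, ignored by the SNP-by-SNP estimators).
    """

    dosages: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    locus_ids: list[str] = field(default=None)  # type: ignore[assignment]
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = _as_dosage_array(self.dosages)
        n, L = self.dosages.shape
        if self.sample_ids is None:
            self.sample_ids = [f"ind{j}" for j in range(n)]
        if self.locus_ids is None:
            self.locus_ids = [f"snp{l}" for l in range(L)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(s) for s in self.locus_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match dosage columns")
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom)
            if self.chrom.shape != (L,):
                raise ValueError("chrom must have one entry per locus")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=np.int64)
            if self.pos.shape != (L,):
                raise ValueError("pos must have one entry per locus")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_freqs(self, subset: Sequence[int] | None = None) -> np.ndarray:
        """Per-locus sample frequency of the counted allele.

        Computed over the non-missing individuals of ``subset`` (default:
        everyone); loci with no genotyped individual in the subset get NaN.
        """
        X = self.dosages if subset is None else self.dosages[np.asarray(subset)]
        obs = X != MISSING
        n_l = obs.sum(axis=0)
        total = np.where(obs, X, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_l > 0, total / (2.0 * n_l), np.nan)

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx],
            [self.sample_ids[i] for i in idx],
            list(self.locus_ids),
            self.chrom,
            self.pos,
        )

    def indices_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[str(s)] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample id {exc} not in genotype matrix") from exc


@dataclass
class SharingStats:
    """Per-locus allele-sharing summaries for a genotype matrix.

    ``A_within[j, l]`` is the homozygosity indicator (NaN where missing),
    ``A_between_mean[l]`` the average pairwise sharing over the reference
    individuals, ``p_hat[l]`` the reference sample allele frequency and
    ``n_ref[l]`` the number of genotyped reference individuals at ``l``.
    """

    A_within: np.ndarray
    A_between_mean: np.ndarray
    het_indicator: np.ndarray
    p_hat: np.ndarray
    n_ref: np.ndarray
    reference: np.ndarray  # indices of the reference individuals
    kept_loci: np.ndarray  # indices into the original locus axis


def compute_sharing_stats(
    G: GenotypeMatrix,
    reference: Sequence[int] | None = None,
    on_unusable_locus: str = "error",
) -> SharingStats:
    """Within-individual and mean between-individual sharing per locus.

    The pair average ``A_S[l]`` is evaluated in O(n) per locus through the
    identity ``sum_pairs c_j c_j' = (S**2 - Q) / 2`` with ``c_j = X_j - 1``,
    ``S = sum_j c_j`` and ``Q = sum_j c_j**2``, restricted to reference
    individuals genotyped at ``l``.

    Parameters
    ----------
    reference
        Indices of the individuals anchoring ``A_S`` and ``p_hat``
        (default: all).  Sharing indicators are still returned for every
        individual, which is what makes reference-swap analyses possible.
    on_unusable_locus
        ``"error"`` (default) or ``"drop"`` for loci with fewer than two
        genotyped reference individuals.
    """
    n, L = G.dosages.shape
    if n < 2:
        raise ValueError("allele sharing needs at least two individuals")
    if L < 1:
        raise ValueError("no loci")
    ref = np.arange(n) if reference is None else np.unique(np.asarray(reference))
    if ref.size < 2:
        raise ValueError("reference set needs at least two individuals")

    X = G.dosages.astype(float)
    X[G.missing_mask] = np.nan
    C = X - 1.0

    Xr = X[ref]
    Cr = C[ref]
    obs = ~np.isnan(Xr)
    n_l = obs.sum(axis=0)
    usable = n_l >= 2
    if not usable.all():
        if on_unusable_locus == "drop":
            pass
        else:
            bad = int(np.flatnonzero(~usable)[0])
            raise ValueError(
                f"locus {G.locus_ids[bad]} has fewer than two genotyped "
                "reference individuals (pass on_unusable_locus='drop' to skip)"
            )
    kept = np.flatnonzero(usable)

    S = np.nansum(Cr, axis=0)
    Q = np.nansum(Cr**2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A_S = 0.5 + (S**2 - Q) / (2.0 * n_l * (n_l - 1.0))
        p_hat = np.nansum(Xr, axis=0) / (2.0 * n_l)

    A_within = C**2  # NaN propagates through missing entries
    return SharingStats(
        A_within=A_within[:, kept],
        A_between_mean=A_S[kept],
        het_indicator=1.0 - A_within[:, kept],
        p_hat=p_hat[kept],
        n_ref=n_l[kept],
        reference=ref,
        kept_loci=kept,
    )


def pairwise_sharing(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Between-individual sharing ``(1 + (x-1)(y-1)) / 2`` for dosage vectors."""
    return (1.0 + (np.asarray(x, float) - 1.0) * (np.asarray(y, float) - 1.0)) / 2.0
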