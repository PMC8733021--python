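"""Gene-dropping simulation with exact identity-by-descent tracking.

The workflow mirrors a classic forward-in-time validation design for
inbreeding estimators:

1. simulate a random-mating pedigree of hermaphroditic individuals
   (monogamous pairs, Poisson offspring numbers, no selfing);
2. give each founder two uniquely labelled alleles and drop gametes down
   the pedigree with recombination on a genetic map (Haldane model: a
   Poisson number of crossovers per chromosome, no interference);
3. read off *gold-standard* realized inbreeding and coancestry as the
   proportion of markers at which allele labels match — ibd relative to the
   founders is observed, not inferred;
4. paint founder SNP haplotypes onto the labels to emit genotypes whose
   true ibd structure is known exactly.

Because every label traces to one founder allele, ibd implies identity in
state at every painted marker by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotypes import GenotypeMatrix
from .pedigree import FOUNDER, Pedigree, TrueParams, wright_transform


@dataclass
class GeneticMap:
    """Marker positions in centiMorgans, per chromosome.

    ``positions_cm`` holds one strictly increasing array per chromosome.
    Base-pair positions are carried alongside for ROH length filters; the
    default uniform map uses 100 kb per cM (10 Mb chromosomes of 1 Morgan).
    """

    chrom_names: list[str]
    positions_cm: list[np.ndarray]
    positions_bp: list[np.ndarray] = field(default=None)  # type: ignore[assignment]
    marker_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions_cm = [np.asarray(p, dtype=float) for p in self.positions_cm]
        for name, p in zip(self.chrom_names, self.positions_cm):
            if p.size and np.any(np.diff(p) <= 0):
                raise ValueError(f"map positions not strictly increasing on {name}")
        if self.positions_bp is None:
            self.positions_bp = [
                np.round(p * 1e5).astype(np.int64) + 1 for p in self.positions_cm
            ]
        else:
            self.positions_bp = [
                np.asarray(p, dtype=np.int64) for p in self.positions_bp
            ]
        if self.marker_ids is None:
            self.marker_ids = [
                f"{c}:{bp}"
                for c, bps in zip(self.chrom_names, self.positions_bp)
                for bp in bps
            ]

    @property
    def n_markers(self) -> int:
        return sum(p.size for p in self.positions_cm)

    @property
    def chrom_lengths_morgans(self) -> np.ndarray:
        return np.array(
            [(p[-1] - p[0]) / 100.0 if p.size > 1 else 0.0 for p in self.positions_cm]
        )

    @property
    def total_length_morgans(self) -> float:
        return float(self.chrom_lengths_morgans.sum())

    def marker_chrom(self) -> np.ndarray:
        return np.concatenate(
            [
                np.repeat(name, p.size)
                for name, p in zip(self.chrom_names, self.positions_cm)
            ]
        )

    def marker_bp(self) -> np.ndarray:
        return np.concatenate(self.positions_bp)

    @classmethod
    def uniform(
        cls, n_chrom: int = 20, length_cm: float = 100.0, spacing_cm: float = 0.1
    ) -> "GeneticMap":
        """Evenly spaced markers: the default is 20 chromosomes of 1 Morgan
        with a marker every 0.1 cM (20,000 markers on a 20 Morgan map).

        Exactly ``length_cm / spacing_cm`` markers per chromosome, at
        positions 0, spacing, 2*spacing, ...
        """
        n = int(round(length_cm / spacing_cm))
        pos = np.arange(n) * spacing_cm
        return cls(
            chrom_names=[f"chr{i + 1}" for i in range(n_chrom)],
            positions_cm=[pos.copy() for _ in range(n_chrom)],
        )


@dataclass
class GeneDropResult:
    """Founder-allele-labelled haplotypes for every pedigree member.

    ``haplotypes[j, a, l]`` is the founder allele identifier carried by
    haplotype ``a`` of individual ``j`` at marker ``l``; founder ``i``
    carries labels ``2i`` and ``2i + 1`` everywhere.
    """

    ped: Pedigree
    gmap: GeneticMap
    haplotypes: np.ndarray  # (n, 2, L) int32

    @property
    def gold_F(self) -> np.ndarray:
        """Realized inbreeding: proportion of markers with matching labels."""
        return (self.haplotypes[:, 0, :] == self.haplotypes[:, 1, :]).mean(axis=1)

    def gold_theta(self, subset: Sequence[int] | None = None) -> np.ndarray:
        """Realized coancestry matrix over ``subset`` (default: everyone).

        ``theta[j, j']`` is the marker average of the fraction of the four
        cross-haplotype label comparisons that match; the diagonal is
        ``(1 + gold_F) / 2`` as for parametric coancestries.
        """
        H = self.haplotypes if subset is None else self.haplotypes[np.asarray(subset)]
        n, _, L = H.shape
        theta = np.zeros((n, n))
        chunk = max(1, int(2e7) // max(n * n, 1))
        for start in range(0, L, chunk):
            sl = slice(start, start + chunk)
            for a in (0, 1):
                for b in (0, 1):
                    theta += (H[:, None, a, sl] == H[None, :, b, sl]).sum(axis=2)
        theta /= 4.0 * L
        gf = (H[:, 0, :] == H[:, 1, :]).mean(axis=1)
        np.fill_diagonal(theta, (1.0 + gf) / 2.0)
        return theta

    def gold_psi_components(
        self, subset: Sequence[int]
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """(gold_F, gold_Psi, gold_theta_S) for a subset, in O(n L) time.

        Per marker, the number of label matches between ``j`` and everyone
        else is ``t[h_j1] + t[h_j2] - (self matches)`` where ``t`` counts
        each label over the subset's haplotypes — no pairwise loop needed.
        """
        idx = np.asarray(subset)
        H = self.haplotypes[idx]
        n, _, L = H.shape
        K = int(self.haplotypes.max()) + 1
        t = np.zeros((L, K), dtype=np.int32)
        cols = np.arange(L)
        for a in (0, 1):
            np.add.at(t, (cols[None, :], H[:, a, :]), 1)
        h1, h2 = H[:, 0, :], H[:, 1, :]
        self_match = np.where(h1 == h2, 4, 2)
        cross = t[cols, h1] + t[cols, h2]  # label matches of j vs all (incl. self)
        Psi = (cross - self_match).sum(axis=1) / (4.0 * L * (n - 1))
        gold_F = (h1 == h2).mean(axis=1)
        return gold_F, Psi, float(Psi.mean())


def simulate_random_mating_pedigree(
    n_founders: int,
    n_generations: int,
    mean_offspring: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> Pedigree:
    """Random-mating pedigree of hermaphrodites, selfing excluded.

    Each generation the current individuals are shuffled into monogamous
    pairs (an odd one stays unpaired) and each pair produces a
    Poisson(``mean_offspring``) number of offspring; the next generation is
    the union of all offspring.  Halts with an error if a generation has
    fewer than two members.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    if mean_offspring <= 0:
        raise ValueError("mean_offspring must be positive")
    rng = np.random.default_rng(seed)

    records: list[tuple[str, str | None, str | None]] = []
    gen_index: list[int] = []
    current = [f"G0-{i + 1}" for i in range(n_founders)]
    for iid in current:
        records.append((iid, None, None))
        gen_index.append(0)

    for g in range(1, n_generations + 1):
        if len(current) < 2:
            raise RuntimeError(
                f"generation {g - 1} has {len(current)} individual(s); "
                "random mating cannot continue"
            )
        order = rng.permutation(len(current))
        children: list[str] = []
        child_no = 0
        for k in range(0, len(order) - 1, 2):
            mum, dad = current[order[k]], current[order[k + 1]]
            for _ in range(rng.poisson(mean_offspring)):
                child_no += 1
                cid = f"G{g}-{child_no}"
                records.append((cid, mum, dad))
                gen_index.append(g)
                children.append(cid)
        current = children

    ped = Pedigree.from_records(records)
    gen = dict(zip((r[0] for r in records), gen_index))
    ped.generation = np.array([gen[i] for i in ped.ids])
    return ped


def _meiosis(
    parent_hap: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a (2, L) parental pair: Haldane crossovers per
    chromosome, random start haplotype, switch at each crossover."""
    out = np.empty(parent_hap.shape[1], dtype=parent_hap.dtype)
    offset = 0
    for pos in gmap.positions_cm:
        m = pos.size
        cols = np.arange(offset, offset + m)
        length_m = (pos[-1] - pos[0]) / 100.0 if m > 1 else 0.0
        start = int(rng.integers(2))
        n_x = rng.poisson(length_m) if length_m > 0 else 0
        if n_x:
            xs = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
            # haplotype index flips at every crossover to the left of a marker
            which = (start + np.searchsorted(xs, pos, side="left")) % 2
            out[cols] = parent_hap[which, cols]
        else:
            out[cols] = parent_hap[start, cols]
        offset += m
    return out


def drop_gametes(
    ped: Pedigree, gmap: GeneticMap, seed: int | np.random.Generator = 0
) -> GeneDropResult:
    """Drop uniquely labelled founder alleles through the pedigree."""
    rng = np.random.default_rng(seed)
    L = gmap.n_markers
    n = ped.n
    H = np.empty((n, 2, L), dtype=np.int32)
    founder_no = 0
    for j in range(n):
        a, b = ped.parent1[j], ped.parent2[j]
        if a == FOUNDER:
            H[j, 0, :] = 2 * founder_no
            H[j, 1, :] = 2 * founder_no + 1
            founder_no += 1
        else:
            H[j, 0, :] = _meiosis(H[a], gmap, rng)
            H[j, 1, :] = _meiosis(H[b], gmap, rng)
    return GeneDropResult(ped=ped, gmap=gmap, haplotypes=H)


def gold_coefficients(
    res: GeneDropResult, subset: Sequence[int] | Sequence[str] | None = None
) -> TrueParams:
    """Gold-standard within-population parameters for a subset.

    Realized ``F_j``, ``Psi_j`` and ``theta_S`` come straight from label
    matching; the within-population ``f_j``, ``psi_j`` and the composite
    UNI/STD targets ``f - 2 psi`` and ``f - 4 psi`` follow by the Wright
    transform.
    """
    if subset is None:
        idx = np.arange(res.ped.n)
    else:
        subset = list(subset)
        if subset and not isinstance(subset[0], (int, np.integer)):
            idx = res.ped.indices_of(subset)
        else:
            idx = np.asarray(subset, dtype=int)
    gold_F, Psi, theta_S = res.gold_psi_components(idx)
    return TrueParams(
        ids=[res.ped.ids[i] for i in idx],
        F=gold_F,
        Psi=Psi,
        F_W=float(gold_F.mean()),
        theta_S=theta_S,
    )


@dataclass
class FounderHaplotypes:
    """Binary founder haplotypes; row ``k`` belongs to founder label ``k``."""

    alleles: np.ndarray  # (2 * n_founders, L) of 0/1

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("founder haplotypes must be a 2-D matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("founder haplotype entries must be 0/1")
        if self.alleles.shape[0] % 2:
            raise ValueError("haplotype rows must come in founder pairs")

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]


def generate_founder_haplotypes(
    n_founders: int,
    L: int,
    model: str = "frequency_spectrum",
    seed: int | np.random.Generator = 0,
    supplied: np.ndarray | None = None,
) -> FounderHaplotypes:
    """Founder SNP haplotypes for genotype painting.

    The default model emulates a neutral site-frequency spectrum: per-locus
    ancestral frequencies ``pi_l`` with density proportional to ``1/x``,
    truncated to ``[1/(4 n_founders), 1 - 1/(4 n_founders)]``, and haplotype
    alleles drawn i.i.d. Bernoulli(``pi_l``).  ``model="supplied"`` wraps an
    externally produced matrix (e.g. coalescent output) unchanged.
    """
    if L < 1:
        raise ValueError("need at least one locus")
    if model == "supplied":
        if supplied is None:
            raise ValueError("model='supplied' requires a haplotype matrix")
        mat = np.asarray(supplied)
        if mat.shape[0] != 2 * n_founders:
            raise ValueError(
                f"supplied matrix has {mat.shape[0]} rows; expected "
                f"{2 * n_founders} (two per founder)"
            )
        if mat.shape[1] < L:
            raise ValueError(f"supplied matrix has fewer than {L} loci")
        return FounderHaplotypes(mat[:, :L])
    if model != "frequency_spectrum":
        raise ValueError("model must be 'frequency_spectrum' or 'supplied'")
    rng = np.random.default_rng(seed)
    lo = 1.0 / (4.0 * n_founders)
    hi = 1.0 - lo
    u = rng.uniform(size=L)
    pi = lo * (hi / lo) ** u  # inverse CDF of density ~ 1/x on [lo, hi]
    alleles = (rng.uniform(size=(2 * n_founders, L)) < pi).astype(np.int8)
    return FounderHaplotypes(alleles)


def paint_genotypes(res: GeneDropResult, hap: FounderHaplotypes) -> GenotypeMatrix:
    """Replace founder allele labels by founder SNP alleles; emit dosages.

    One marker corresponds to one SNP by index, so identity by descent
    implies identity in state at every marker.
    """
    L = res.gmap.n_markers
    if hap.n_loci != L:
        raise ValueError(
            f"founder haplotypes have {hap.n_loci} loci but the map has {L} markers"
        )
    if int(res.haplotypes.max()) >= hap.alleles.shape[0]:
        raise ValueError("founder allele identifier missing from haplotype mapping")
    cols = np.arange(L)
    alleles = hap.alleles[res.haplotypes, cols]  # (n, 2, L)
    dosage = alleles.sum(axis=1).astype(np.int16)
    return GenotypeMatrix(
        dosage,
        sample_ids=list(res.ped.ids),
        locus_ids=list(res.gmap.marker_ids),
        chrom=res.gmap.marker_chrom(),
        pos=res.gmap.marker_bp(),
    )
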