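"""Pedigree coancestry algebra.

Coancestry (kinship) ``theta[j, j']`` is the probability that an allele
drawn at random from individual ``j`` is identical by descent (ibd) to one
drawn from ``j'``, with the pedigree founders as the reference population.
It is computed by the standard tabular recursion

    theta(j, k)  = [theta(p1(j), k) + theta(p2(j), k)] / 2   (k not a descendant)
    theta(j, j)  = [1 + theta(p1(j), p2(j))] / 2

so that an individual's inbreeding coefficient is ``F_j = 2 theta[j, j] - 1``,
the coancestry of its parents.  An independent path-counting evaluation of
Wright's formula ``F_j = sum over paths (1/2)^n (1 + F_A)`` is provided as a
cross-check oracle for the recursion.

Within-population ("relative") parameters rescale ibd probabilities against
the average coancestry ``theta_S`` of a chosen reference set:

    f_j = (F_j - theta_S) / (1 - theta_S)
    psi_j = (Psi_j - theta_S) / (1 - theta_S)

where ``Psi_j`` is j's mean coancestry with the other members.  The ``psi_j``
average to zero by construction, and ``f_j`` may be negative for individuals
less inbred than the sample is related on average.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Sequence

import numpy as np

FOUNDER = -1


@dataclass
class Pedigree:
    """Validated pedigree in topological (parents-first) order.

    ``parent1``/``parent2`` hold row indices into ``ids``; founders carry
    ``-1`` for both.  Individuals with exactly one recorded parent are
    rejected unless ``allow_single_parent`` promoted the missing side to a
    new unique founder at construction time.
    """

    ids: list[str]
    parent1: np.ndarray
    parent2: np.ndarray
    generation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parent1 = np.asarray(self.parent1, dtype=int)
        self.parent2 = np.asarray(self.parent2, dtype=int)
        n = len(self.ids)
        if self.parent1.shape != (n,) or self.parent2.shape != (n,):
            raise ValueError("parent arrays must match ids length")
        for j in range(n):
            for p in (self.parent1[j], self.parent2[j]):
                if p != FOUNDER and not (0 <= p < j):
                    raise ValueError(
                        f"pedigree not in topological order at {self.ids[j]}"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.parent1 == FOUNDER) & (self.parent2 == FOUNDER)

    @property
    def founder_ids(self) -> list[str]:
        return [s for s, f in zip(self.ids, self.is_founder) if f]

    def indices_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.ids)}
        return np.array([lookup[str(s)] for s in ids], dtype=int)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str | None, str | None]],
        allow_single_parent: bool = False,
    ) -> "Pedigree":
        """Build a pedigree from (id, parent1, parent2) triples.

        ``0``, empty string or ``None`` mean "parent unknown".  Records may
        appear in any order; a topological sort is applied and cycles are
        reported with an offending member named.
        """
        def norm(x) -> str | None:
            if x is None:
                return None
            x = str(x).strip()
            return None if x in ("", "0", "NA", ".") else x

        recs: dict[str, tuple[str | None, str | None]] = {}
        order: list[str] = []
        for iid, p1, p2 in records:
            iid = str(iid).strip()
            if iid in ("", "0"):
                raise ValueError("invalid individual id in pedigree record")
            if iid in recs:
                raise ValueError(f"duplicate pedigree record for {iid}")
            recs[iid] = (norm(p1), norm(p2))
            order.append(iid)

        # one-known-parent handling
        synth = 0
        for iid in order:
            p1, p2 = recs[iid]
            if (p1 is None) != (p2 is None):
                if not allow_single_parent:
                    raise ValueError(
                        f"individual {iid} has exactly one known parent; "
                        "pass allow_single_parent=True to treat the missing "
                        "parent as a unique founder"
                    )
                synth += 1
                new = f"_founder{synth}"
                while new in recs:
                    synth += 1
                    new = f"_founder{synth}"
                recs[new] = (None, None)
                order.insert(0, new)
                recs[iid] = (p1 or new, p2 or new)

        for iid in order:
            for p in recs[iid]:
                if p is not None and p not in recs:
                    raise ValueError(f"unknown parent id {p!r} for {iid}")

        graph = {iid: [p for p in recs[iid] if p is not None] for iid in order}
        try:
            topo = list(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            member = exc.args[1][0] if len(exc.args) > 1 and exc.args[1] else "?"
            raise ValueError(f"pedigree contains a cycle through {member}") from exc

        idx = {iid: j for j, iid in enumerate(topo)}
        p1 = np.array(
            [FOUNDER if recs[i][0] is None else idx[recs[i][0]] for i in topo]
        )
        p2 = np.array(
            [FOUNDER if recs[i][1] is None else idx[recs[i][1]] for i in topo]
        )
        return cls(topo, p1, p2)


@dataclass
class CoancestryMatrix:
    """Symmetric coancestry ``theta`` with diagonal ``(1 + F_j) / 2``."""

    ids: list[str]
    theta: np.ndarray

    @property
    def inbreeding(self) -> np.ndarray:
        """F_j = 2 theta_jj - 1."""
        return 2.0 * np.diag(self.theta) - 1.0

    def indices_of(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.ids)}
        return np.array([lookup[str(s)] for s in ids], dtype=int)


@dataclass
class TrueParams:
    """Parametric (or gold-standard) inbreeding and kinship quantities.

    Absolute ibd probabilities ``F_j``, ``Psi_j``, ``theta_S``, ``F_W`` and
    their within-population transforms ``f_j``, ``psi_j``, ``f_W``.  Also
    carries the composite targets ``f_j - 2 psi_j`` and ``f_j - 4 psi_j``
    that the frequency-based UNI and STD estimators converge to.
    """

    ids: list[str]
    F: np.ndarray
    Psi: np.ndarray
    F_W: float
    theta_S: float
    f: np.ndarray = field(default=None)  # type: ignore[assignment]
    psi: np.ndarray = field(default=None)  # type: ignore[assignment]
    f_W: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.Psi = np.asarray(self.Psi, dtype=float)
        if self.theta_S >= 1.0:
            raise ValueError("theta_S = 1: degenerate reference set")
        if self.f is None:
            self.f = wright_transform(self.F, self.theta_S)
        if self.psi is None:
            self.psi = wright_transform(self.Psi, self.theta_S)
        if self.f_W is None:
            self.f_W = float(wright_transform(self.F_W, self.theta_S))

    @property
    def f_uni_target(self) -> np.ndarray:
        return self.f - 2.0 * self.psi

    @property
    def f_std_target(self) -> np.ndarray:
        return self.f - 4.0 * self.psi


def wright_transform(F, theta_S: float):
    """Within-population rescaling ``(F - theta_S) / (1 - theta_S)``.

    Applies to individual inbreeding, average inbreeding and average
    kinship alike; vectorized over ``F``.
    """
    if theta_S >= 1.0:
        raise ValueError("theta_S = 1: transform undefined")
    return (np.asarray(F, dtype=float) - theta_S) / (1.0 - theta_S)


def coancestry_matrix(
    ped: Pedigree, founder_kinship: np.ndarray | None = None
) -> CoancestryMatrix:
    """Full coancestry matrix by the tabular recursion.

    Founders are unrelated and non-inbred unless ``founder_kinship`` (a
    symmetric matrix over the founders, in pedigree founder order) says
    otherwise.
    """
    n = ped.n
    theta = np.zeros((n, n))
    founders = np.flatnonzero(ped.is_founder)
    if founder_kinship is None:
        theta[founders, founders] = 0.5
    else:
        fk = np.asarray(founder_kinship, dtype=float)
        if fk.shape != (founders.size, founders.size):
            raise ValueError("founder_kinship shape does not match founder count")
        if not np.allclose(fk, fk.T):
            raise ValueError("founder_kinship must be symmetric")
        theta[np.ix_(founders, founders)] = fk

    for j in range(n):
        a, b = ped.parent1[j], ped.parent2[j]
        if a == FOUNDER:
            continue  # founder rows preset
        # parents precede j, so theta rows a and b are complete
        row = 0.5 * (theta[a, :j] + theta[b, :j])
        theta[j, :j] = row
        theta[:j, j] = row
        theta[j, j] = 0.5 * (1.0 + theta[a, b])
    return CoancestryMatrix(list(ped.ids), theta)


def path_counting_inbreeding(ped: Pedigree) -> np.ndarray:
    """Wright's path-counting evaluation of every ``F_j``.

    For offspring of parents ``a`` and ``b``, sums ``(1/2)**n (1 + F_A)``
    over every common ancestor ``A`` and every pair of ancestral paths from
    ``a`` and ``b`` to ``A`` that share no individual besides ``A``; ``n``
    is the number of individuals in the joined path.  Exponential-time by
    design — this is the independent oracle for the tabular recursion and is
    meant for desk-scale pedigrees.
    """
    F = np.zeros(ped.n)

    def paths_up(j: int) -> list[tuple[int, ...]]:
        """All ancestral chains starting at j (j included)."""
        out = [(j,)]
        for p in (ped.parent1[j], ped.parent2[j]):
            if p != FOUNDER:
                out.extend((j,) + q for q in paths_up(p))
        return out

    for j in range(ped.n):
        a, b = ped.parent1[j], ped.parent2[j]
        if a == FOUNDER:
            continue
        total = 0.0
        for pa, pb in itertools.product(paths_up(a), paths_up(b)):
            if pa[-1] != pb[-1]:
                continue  # not joined at a common ancestor
            if set(pa[:-1]) & set(pb):
                continue  # paths may only meet at the ancestor
            n_path = len(pa) + len(pb) - 1
            total += 0.5**n_path * (1.0 + F[pa[-1]])
        F[j] = total
    return F


def within_population_params(
    C: CoancestryMatrix, subset: Sequence[str] | Sequence[int] | None = None
) -> TrueParams:
    """Average-coancestry-anchored parameters for a reference subset.

    ``F_W`` is the mean inbreeding over the subset, ``Psi_j`` the mean
    coancestry of ``j`` with the other subset members, ``theta_S`` the mean
    of the ``Psi_j``; the within-population ``f``/``psi`` values follow from
    the Wright transform.
    """
    if subset is None:
        idx = np.arange(len(C.ids))
    else:
        subset = list(subset)
        if subset and isinstance(subset[0], (int, np.integer)):
            idx = np.asarray(subset, dtype=int)
        else:
            idx = C.indices_of(subset)
    if idx.size < 2:
        raise ValueError("subset must contain at least two individuals")

    sub = C.theta[np.ix_(idx, idx)]
    F = 2.0 * np.diag(sub) - 1.0
    k = idx.size
    Psi = (sub.sum(axis=1) - np.diag(sub)) / (k - 1.0)
    theta_S = float(Psi.mean())
    if theta_S >= 1.0:
        raise ValueError("theta_S = 1: degenerate subset")
    return TrueParams(
        ids=[C.ids[i] for i in idx],
        F=F,
        Psi=Psi,
        F_W=float(F.mean()),
        theta_S=theta_S,
    )
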