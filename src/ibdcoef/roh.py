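"""Runs of homozygosity and the genomic inbreeding estimate F_ROH.

A run of homozygosity is a contiguous stretch of homozygous SNP calls long
enough that the most plausible explanation is a chromosomal block inherited
identical by descent from both parents.  This module uses a deterministic
consecutive-run scan (rather than a sliding-window vote): per individual and
chromosome it reports maximal non-overlapping runs that contain at most
``max_het`` heterozygous and ``max_missing`` missing calls, trimmed to start
and end on homozygous calls, and discards runs shorter than ``min_snps``
SNPs or ``min_kb`` kilobases.

``F_ROH`` is the fraction of the genome covered by the reported segments.
Unlike the SNP-by-SNP estimators it targets the absolute inbreeding
coefficient ``F`` — but its value depends on the calling parameters, so its
expectation has no closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

DEFAULT_PARAMS = dict(min_snps=100, min_kb=100.0, max_het=0, max_missing=2)

SEGMENT_COLUMNS = [
    "sample_id",
    "chrom",
    "start_idx",
    "end_idx",
    "start_bp",
    "end_bp",
    "n_snps",
    "n_het",
    "n_missing",
    "length_kb",
]


@dataclass
class _Run:
    start: int
    end: int  # half-open marker indices within the chromosome


def _scan_chromosome(
    calls: np.ndarray,
    bp: np.ndarray,
    min_snps: int,
    min_kb: float,
    max_het: int,
    max_missing: int,
) -> list[_Run]:
    """Greedy left-to-right maximal-run scan.

    ``calls``: 0 = homozygous, 1 = heterozygous, 2 = missing.  From each
    candidate start the window is extended as far as the het/missing budget
    allows (a two-pointer sweep, O(m)); a window passing both length filters
    is reported, trimmed to homozygous endpoints, and the scan resumes after
    it.  Because every valid sub-run of a failing maximal window is shorter
    in SNPs and in bp, greedy acceptance of maximal windows cannot miss a
    passing run.
    """
    m = calls.size
    runs: list[_Run] = []
    i = j = 0
    het = miss = 0  # counts within the current window [i, j)
    while i < m:
        # candidate runs always start on a homozygous call; skipping a
        # non-homozygous start also refunds its budget to the window
        if calls[i] != 0:
            if i < j:
                het -= calls[i] == 1
                miss -= calls[i] == 2
            i += 1
            continue
        if j < i:
            j = i
            het = miss = 0
        # extend the window as far as the budget allows
        while j < m:
            c = calls[j]
            if (c == 1 and het + 1 > max_het) or (c == 2 and miss + 1 > max_missing):
                break
            het += c == 1
            miss += c == 2
            j += 1
        # trim the end to a homozygous call; [i, e) is then the longest
        # valid run starting at i, because extension past j is blocked by
        # the budget and no homozygote lies in [e, j)
        e = j
        while e > i and calls[e - 1] != 0:
            e -= 1
        if e - i >= max(min_snps, 1) and (bp[e - 1] - bp[i]) / 1000.0 >= min_kb:
            runs.append(_Run(i, e))
            i = j
            het = miss = 0
        else:
            i += 1  # calls[i] == 0, so window counts are unchanged
    return runs


def detect_roh(
    G: GenotypeMatrix,
    min_snps: int = 100,
    min_kb: float = 100.0,
    max_het: int = 0,
    max_missing: int = 2,
) -> pd.DataFrame:
    """Call ROH segments for every individual.

    Requires ``G.chrom`` and ``G.pos``; positions must be sorted within each
    chromosome.  Returns one row per segment with half-open marker indices
    (relative to the chromosome), bp bounds and length in kb.
    """
    if G.chrom is None or G.pos is None:
        raise ValueError("ROH calling needs per-locus chromosome and bp positions")
    rows: list[list] = []
    # loci grouped by chromosome, in input order
    order: dict[str, np.ndarray] = {}
    for c in pd.unique(G.chrom):
        idx = np.flatnonzero(G.chrom == c)
        bp = G.pos[idx]
        if np.any(np.diff(bp) < 0):
            raise ValueError(f"positions not sorted on chromosome {c}")
        order[str(c)] = idx

    for row_j, sid in enumerate(G.sample_ids):
        x = G.dosages[row_j]
        for c, idx in order.items():
            xc = x[idx]
            calls = np.where(xc == MISSING, 2, np.where(xc == 1, 1, 0)).astype(np.int8)
            bp = G.pos[idx]
            for run in _scan_chromosome(
                calls, bp, min_snps, min_kb, max_het, max_missing
            ):
                seg = calls[run.start : run.end]
                rows.append(
                    [
                        sid,
                        c,
                        run.start,
                        run.end,
                        int(bp[run.start]),
                        int(bp[run.end - 1]),
                        run.end - run.start,
                        int((seg == 1).sum()),
                        int((seg == 2).sum()),
                        (bp[run.end - 1] - bp[run.start]) / 1000.0,
                    ]
                )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def genome_length_bp(G: GenotypeMatrix) -> int:
    """Sum of per-chromosome spans (last bp minus first bp)."""
    if G.chrom is None or G.pos is None:
        raise ValueError("genotype matrix carries no positions")
    total = 0
    for c in pd.unique(G.chrom):
        bp = G.pos[G.chrom == c]
        total += int(bp.max() - bp.min())
    return total


def f_roh(
    segments: pd.DataFrame,
    genome_length: int,
    sample_ids: list[str] | None = None,
) -> pd.Series:
    """Per-individual F_ROH: total segment bp over genome length, in [0, 1]."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    if len(segments):
        for (sid, c), grp in segments.groupby(["sample_id", "chrom"], sort=False):
            g = grp.sort_values("start_bp")
            if (g["start_bp"].values[1:] <= g["end_bp"].values[:-1]).any():
                raise ValueError(
                    f"overlapping ROH segments for {sid} on {c}: upstream bug"
                )
        lengths = (
            (segments["end_bp"] - segments["start_bp"])
            .groupby(segments["sample_id"], sort=False)
            .sum()
        )
    else:
        lengths = pd.Series(dtype=float)
    if sample_ids is not None:
        lengths = lengths.reindex(sample_ids, fill_value=0)
    out = (lengths / genome_length).clip(0.0, 1.0)
    out.name = "F_ROH"
    out.index.name = "sample_id"
    return out
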