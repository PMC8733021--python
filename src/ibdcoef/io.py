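"""Readers and writers: VCF, genotype/pedigree/map TSV, estimate tables,
kinship matrices (square TSV and GCTA-GRM-style triples).

Conventions: marker indices are 0-based half-open internally; VCF positions
are 1-based per the standard.  Dosage counts the ALT allele by default (the
"reference allele" of the estimator formulas is just a labelling choice —
every estimator is invariant to flipping it).  Floats are written at 6
decimal places with a commented metadata header.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .estimators import KinshipMatrix
from .genedrop import GeneticMap
from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree, TrueParams

logger = logging.getLogger("ibdcoef")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path: str | Path, allele: str = "alt") -> GenotypeMatrix:
    """Load biallelic SNP dosages from a VCF (GT field).

    Multi-allelic and non-SNP records are skipped with a logged count.
    ``allele`` chooses which allele the dosage counts ("alt" default).
    """
    from cyvcf2 import VCF

    if allele not in ("alt", "ref"):
        raise ValueError("allele must be 'alt' or 'ref'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    locus_ids: list[str] = []
    chroms: list[str] = []
    poss: list[int] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        gts = rec.genotype.array()[:, :2]
        dos = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        if allele == "ref":
            dos = np.where(dos == MISSING, MISSING, 2 - dos)
        rows.append(dos.astype(np.int16))
        locus_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
    if skipped:
        logger.info("skipped %d multi-allelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(
        np.column_stack(rows),
        sample_ids=samples,
        locus_ids=locus_ids,
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
    )


def write_genotypes_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 writer; dosage is the ALT allele count."""
    if G.chrom is None or G.pos is None:
        chrom = np.repeat("1", G.n_loci)
        pos = np.arange(1, G.n_loci + 1, dtype=np.int64)
    else:
        chrom, pos = G.chrom, G.pos
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=ibdcoef {__version__}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(np.asarray(chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for l in range(G.n_loci):
            gts = "\t".join(gt_strings[int(x)] for x in G.dosages[:, l])
            fh.write(
                f"{chrom[l]}\t{pos[l]}\t{G.locus_ids[l]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    """Genotype TSV: rows = individuals, columns = loci, entries 0/1/2/NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] == 0:
        raise ValueError(f"no loci in {path}")
    vals = df.to_numpy(dtype=float)
    return GenotypeMatrix(
        vals, sample_ids=[str(i) for i in df.index], locus_ids=list(df.columns)
    )


def write_genotypes_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        np.where(G.missing_mask, np.nan, G.dosages),
        index=pd.Index(G.sample_ids, name="sample_id"),
        columns=G.locus_ids,
    )
    df.to_csv(path, sep="\t", float_format="%.0f", na_rep="NA")


# ---------------------------------------------------------------------------
# pedigree / map / params
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path, allow_single_parent: bool = False) -> Pedigree:
    """3-column TSV (id, parent1, parent2); 0 or blank means unknown."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, comment="#", keep_default_na=False
    )
    if df.shape[1] < 3:
        raise ValueError("pedigree TSV needs 3 columns: id, parent1, parent2")
    recs = [(r[0], r[1], r[2]) for r in df.itertuples(index=False)]
    return Pedigree.from_records(recs, allow_single_parent=allow_single_parent)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tparent1\tparent2\n")
        for j, iid in enumerate(ped.ids):
            p1 = ped.ids[ped.parent1[j]] if ped.parent1[j] >= 0 else "0"
            p2 = ped.ids[ped.parent2[j]] if ped.parent2[j] >= 0 else "0"
            fh.write(f"{iid}\t{p1}\t{p2}\n")


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Map TSV with columns chrom, marker_id, cM (optional bp)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    for need in ("chrom", "cm"):
        if need not in cols:
            raise ValueError(f"map TSV is missing a '{need}' column")
    names, pos_cm, pos_bp = [], [], []
    for c, grp in df.groupby(cols["chrom"], sort=False):
        names.append(str(c))
        pos_cm.append(grp[cols["cm"]].to_numpy(float))
        if "bp" in cols:
            pos_bp.append(grp[cols["bp"]].to_numpy(np.int64))
    return GeneticMap(names, pos_cm, positions_bp=pos_bp or None)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tmarker_id\tcM\tbp\n")
        k = 0
        for name, cm, bp in zip(
            gmap.chrom_names, gmap.positions_cm, gmap.positions_bp
        ):
            for x, b in zip(cm, bp):
                fh.write(f"{name}\t{gmap.marker_ids[k]}\t{x:g}\t{b}\n")
                k += 1


def write_true_params(params: TrueParams, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "F": params.F,
            "Psi": params.Psi,
            "f": params.f,
            "psi": params.psi,
            "f_uni_target": params.f_uni_target,
            "f_std_target": params.f_std_target,
        },
        index=pd.Index(params.ids, name="id"),
    )
    with open(path, "w") as fh:
        fh.write(f"# ibdcoef {__version__}\n")
        fh.write(
            f"# F_W={params.F_W:.6f} theta_S={params.theta_S:.6f} "
            f"f_W={params.f_W:.6f}\n"
        )
        df.to_csv(fh, sep="\t", float_format="%.6f")


# ---------------------------------------------------------------------------
# estimates / matrices
# ---------------------------------------------------------------------------

def _metadata_header(metadata: dict | None) -> str:
    lines = [f"# ibdcoef {__version__}"]
    for k, v in (metadata or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def write_estimates(
    estimates: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    meta = dict(metadata or {})
    meta.setdefault("reference_label", estimates.attrs.get("reference_label", "all"))
    with open(path, "w") as fh:
        fh.write(_metadata_header(meta))
        estimates.to_csv(fh, sep="\t", float_format="%.6f")


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_kinship_square(
    K: KinshipMatrix, path: str | Path, metadata: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_header({**(metadata or {}), "kind": K.kind}))
        pd.DataFrame(
            K.values, index=pd.Index(K.ids, name="id"), columns=K.ids
        ).to_csv(fh, sep="\t", float_format="%.6f")


def read_kinship_square(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_kinship_grm(K: KinshipMatrix, n_loci: int, path: str | Path) -> None:
    """GCTA-GRM-style lower triangle: i, j (1-based), n_loci, value."""
    with open(path, "w") as fh:
        for i in range(len(K.ids)):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{n_loci}\t{K.values[i, j]:.6f}\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
    )
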