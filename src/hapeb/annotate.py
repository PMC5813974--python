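"""Gene and QTL annotation of significant blocks.

Each SNP of a block is assigned its nearest gene within a +/-50 kb
window ("Within" when the SNP falls inside the gene interval); block
intervals are intersected with trait-associated QTL regions; and the
direction of each SNP's substitution effect identifies the "favorite"
allele, reported together with whether it is the major allele.

Coordinates are 1-based inclusive throughout and must share the genome
build of the genotype map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import HaplotypeBlock
from .ebmodel import KinshipEigen, TransformedData, _init_lambda, fit_transformed
from .genio import PhasedGenotypes, compute_maf

__all__ = [
    "GeneFeature",
    "QTLInterval",
    "read_gff3_genes",
    "read_bed_genes",
    "read_qtl_table",
    "nearest_gene",
    "qtl_overlap",
    "allele_direction",
]

logger = logging.getLogger(__name__)

WITHIN = "Within"


@dataclass(frozen=True)
class GeneFeature:
    gene_name: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_name}: start > end")


@dataclass(frozen=True)
class QTLInterval:
    trait_description: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"QTL {self.trait_description!r}: start > end")


def read_gff3_genes(path: str | Path) -> list[GeneFeature]:
    """Gene-type features of a GFF3 file (Name, else gene, else ID attribute)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for f in db.features_of_type("gene"):
        name = (
            f.attributes.get("Name", [None])[0]
            or f.attributes.get("gene", [None])[0]
            or f.id
            or "."
        )
        genes.append(
            GeneFeature(
                gene_name=str(name),
                chrom=str(f.seqid),
                start_bp=int(f.start),
                end_bp=int(f.end),
                strand=f.strand if f.strand in "+-" else "+",
            )
        )
    return genes


def read_bed_genes(path: str | Path) -> list[GeneFeature]:
    """4-column BED+name file; BED starts are 0-based half-open on disk."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=range(4),
    )
    return [
        GeneFeature(
            gene_name=str(r.name_), chrom=str(r.chrom),
            start_bp=int(r.start) + 1, end_bp=int(r.end),
        )
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def read_qtl_table(path: str | Path) -> list[QTLInterval]:
    """Headered TSV with columns trait_description, chrom, start_bp, end_bp."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        QTLInterval(
            trait_description=str(r.trait_description), chrom=str(r.chrom),
            start_bp=int(r.start_bp), end_bp=int(r.end_bp),
        )
        for r in df.itertuples(index=False)
    ]


def nearest_gene(
    chrom: str,
    pos: int,
    genes: list[GeneFeature],
    window: int = 50_000,
) -> tuple[GeneFeature | None, int | None]:
    """Closest gene to a SNP within ``window`` bp.

    Distance is 0 when the SNP lies inside the gene interval (report it
    as "Within"), else the gap to the nearer interval boundary.  Ties
    go to the gene with the smaller start coordinate; ``(None, None)``
    when no gene on that chromosome is within the window.
    """
    best: tuple[int, int, GeneFeature] | None = None
    found_chrom = False
    for g in genes:
        if g.chrom != chrom:
            continue
        found_chrom = True
        if g.start_bp <= pos <= g.end_bp:
            d = 0
        elif pos < g.start_bp:
            d = g.start_bp - pos
        else:
            d = pos - g.end_bp
        if d > window:
            continue
        key = (d, g.start_bp)
        if best is None or key < (best[0], best[1]):
            best = (d, g.start_bp, g)
    if best is None:
        if not found_chrom:
            logger.info("no annotated genes on chromosome %s", chrom)
        return None, None
    return best[2], best[0]


def qtl_overlap(
    block: HaplotypeBlock, qtls: list[QTLInterval]
) -> list[QTLInterval]:
    """QTL intervals intersecting the block span (closed intervals)."""
    return [
        q
        for q in qtls
        if q.chrom == block.chrom
        and q.start_bp <= block.end_bp
        and block.start_bp <= q.end_bp
    ]


def allele_direction(
    geno: PhasedGenotypes,
    phen: pd.Series,
    kinship: KinshipEigen,
    marker_indices: np.ndarray | list[int],
) -> pd.DataFrame:
    """Favorite-allele call per SNP from a kinship-adjusted single-marker fit.

    Each marker is fitted as a one-column random effect (same machinery
    as the single-locus scan); the allele whose substitution effect on
    the phenotype is positive is the "favorite".  A zero point estimate
    defaults the favorite to the major allele.  Monomorphic markers are
    skipped with a log entry.

    Returns a DataFrame with columns id, chrom, pos, effect (per copy
    of the ALT allele), favorite_allele, favorite_is_major.
    """
    y = phen.loc[geno.individual_ids].to_numpy(float)
    Ut = kinship.U.T
    y_star = Ut @ y
    X_star = Ut @ np.ones((geno.n, 1))
    dose = geno.dosage().astype(float)
    maf = compute_maf(geno)
    rows = []
    for j in marker_indices:
        j = int(j)
        mk = maf.iloc[j]
        d = dose[:, j]
        if d.std() == 0:
            logger.info("skipping monomorphic marker %s", mk["id"])
            continue
        td = TransformedData(y_star=y_star, X_star=X_star, Z_star=Ut @ d[:, None])
        fit = fit_transformed(td, kinship.D)
        effect = float(fit.gamma_hat[0])  # per ALT-allele copy
        alt_is_major = mk["alt_freq"] > 0.5
        if effect > 0:
            favorite = mk["alt"]
            is_major = bool(alt_is_major)
        elif effect < 0:
            favorite = mk["ref"]
            is_major = bool(not alt_is_major)
        else:
            favorite = mk["major_allele"]
            is_major = True
        rows.append(
            {
                "id": mk["id"], "chrom": mk["chrom"], "pos": int(mk["pos"]),
                "maf": float(mk["maf"]), "effect": effect,
                "favorite_allele": favorite, "favorite_is_major": is_major,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "pos", "maf", "effect", "favorite_allele", "favorite_is_major"],
    )
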