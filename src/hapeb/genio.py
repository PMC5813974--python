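"""Phased genotype and phenotype I/O plus marker-frequency filters.

Genotypes are held as two haploid allele-code matrices (one per inherited
chromosome) over biallelic SNPs.  Allele code 0 is the VCF REF allele,
code 1 the single ALT allele; haplotype labels downstream are built from
these codes.  All coordinates are 1-based inclusive, matching VCF.

Missing or unphased genotypes are rejected at load time: phasing and
imputation are upstream concerns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeError",
    "PhasedGenotypes",
    "read_phased_vcf",
    "write_phased_vcf",
    "compute_maf",
    "maf_filter",
    "read_phenotypes",
    "write_phenotypes",
]


class GenotypeError(ValueError):
    """Raised for malformed genotype input (unphased, missing, multiallelic)."""


@dataclass
class PhasedGenotypes:
    """n individuals x m biallelic markers with known haplotype phase.

    Attributes
    ----------
    individual_ids : list of str
    markers : DataFrame with columns chrom, pos, id, ref, alt
        ``pos`` is 1-based and strictly increasing within each chromosome.
    hap1, hap2 : (n, m) uint8 arrays
        Allele codes (0 = REF, 1 = ALT) for the two phased chromosomes.
    """

    individual_ids: list[str]
    markers: pd.DataFrame
    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.individual_ids)
        m = len(self.markers)
        for name, h in (("hap1", self.hap1), ("hap2", self.hap2)):
            if h.shape != (n, m):
                raise GenotypeError(
                    f"{name} has shape {h.shape}, expected ({n}, {m})"
                )
            if h.size and (h.min() < 0 or h.max() > 1):
                raise GenotypeError(f"{name} contains allele codes outside {{0,1}}")
        pos = self.markers["pos"].to_numpy()
        chrom = self.markers["chrom"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def m(self) -> int:
        return len(self.markers)

    def dosage(self) -> np.ndarray:
        """ALT-allele dosage matrix (n, m) with entries in {0, 1, 2}."""
        return self.hap1.astype(np.int16) + self.hap2.astype(np.int16)

    def subset_markers(self, index: np.ndarray) -> "PhasedGenotypes":
        """New container restricted to the given marker indices (order kept)."""
        index = np.asarray(index)
        return PhasedGenotypes(
            individual_ids=list(self.individual_ids),
            markers=self.markers.iloc[index].reset_index(drop=True),
            hap1=self.hap1[:, index].copy(),
            hap2=self.hap2[:, index].copy(),
        )


def read_phased_vcf(path: str | Path) -> PhasedGenotypes:
    """Load a phased, biallelic, GT-only VCF.

    Every genotype must be phased (``|`` separator) and called; any
    unphased, missing or multiallelic site is a hard error naming the
    offending site and sample.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, h1, h2 = [], [], []
    for v in vcf:
        site = f"{v.CHROM}:{v.POS}"
        if len(v.ALT) != 1:
            raise GenotypeError(f"multiallelic site {site}")
        gts = v.genotypes  # per sample: [allele1, allele2, phased]
        a1 = np.empty(len(samples), dtype=np.uint8)
        a2 = np.empty(len(samples), dtype=np.uint8)
        for j, g in enumerate(gts):
            if len(g) < 3 or not g[2]:
                raise GenotypeError(
                    f"unphased genotype at {site} for sample {samples[j]}"
                )
            if g[0] < 0 or g[1] < 0:
                raise GenotypeError(
                    f"missing genotype at {site} for sample {samples[j]}"
                )
            if g[0] > 1 or g[1] > 1:
                raise GenotypeError(
                    f"non-biallelic allele code at {site} for sample {samples[j]}"
                )
            a1[j], a2[j] = g[0], g[1]
        rows.append((v.CHROM, v.POS, v.ID or ".", v.REF, v.ALT[0]))
        h1.append(a1)
        h2.append(a2)
    vcf.close()
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    if not rows:
        hap1 = np.zeros((len(samples), 0), dtype=np.uint8)
        hap2 = np.zeros((len(samples), 0), dtype=np.uint8)
    else:
        hap1 = np.column_stack(h1)
        hap2 = np.column_stack(h2)
    return PhasedGenotypes(samples, markers, hap1, hap2)


def write_phased_vcf(geno: PhasedGenotypes, path: str | Path) -> None:
    """Write a minimal phased VCF (v4.2 subset, GT-only FORMAT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individual_ids)
            + "\n"
        )
        h1, h2 = geno.hap1, geno.hap2
        for j, row in enumerate(geno.markers.itertuples(index=False)):
            gts = "\t".join(
                f"{h1[i, j]}|{h2[i, j]}" for i in range(geno.n)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def compute_maf(geno: PhasedGenotypes) -> pd.DataFrame:
    """Per-marker allele-frequency table.

    Returns a DataFrame with marker columns plus ``alt_freq``,
    ``maf = min(f, 1 - f)`` (f = ALT count / 2n) and major/minor allele
    labels.  With f exactly 0.5 the REF allele is labelled major.
    """
    if geno.n < 1:
        raise GenotypeError("need at least one individual")
    alt_count = geno.hap1.sum(axis=0, dtype=np.int64) + geno.hap2.sum(
        axis=0, dtype=np.int64
    )
    f = alt_count / (2 * geno.n)
    out = geno.markers.copy()
    out["alt_freq"] = f
    out["maf"] = np.minimum(f, 1.0 - f)
    alt_major = f > 0.5
    out["major_allele"] = np.where(alt_major, out["alt"], out["ref"])
    out["minor_allele"] = np.where(alt_major, out["ref"], out["alt"])
    return out


def maf_filter(geno: PhasedGenotypes, min_maf: float = 0.05) -> PhasedGenotypes:
    """Drop markers with minor allele frequency below ``min_maf``.

    Order is preserved and the operation is idempotent; the result may
    contain zero markers.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    maf = compute_maf(geno)["maf"].to_numpy()
    keep = np.flatnonzero(maf >= min_maf)
    return geno.subset_markers(keep)


def read_phenotypes(path: str | Path, header: bool = True) -> pd.Series:
    """Read a two-column (id, value) TSV into a Series indexed by id."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if header else None,
        names=None if header else ["id", "value"],
        dtype={0: str},
    )
    df.columns = ["id", "value"]
    df["id"] = df["id"].astype(str)
    return pd.Series(df["value"].to_numpy(float), index=df["id"], name="value")


def write_phenotypes(phen: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"id": phen.index.astype(str), "value": phen.to_numpy()})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
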