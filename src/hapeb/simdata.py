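"""Synthetic dairy-population generator with ground-truth records.

Genotypes are organised in LD blocks of 2-4 SNPs.  Each block has a
small pool of ancestral haplotypes ("prefix" haplotypes 000, 100, 110,
111, ... whose pool frequencies are Dirichlet draws), and every
chromosome is an independent pool draw; with probability
``1 - block_ld`` each site of a drawn haplotype is resampled from its
marginal allele frequency, so ``block_ld = 1`` gives perfect within-
block LD (|D'| = 1 for every pair by construction, since prefix
haplotypes never produce all four gametes) and ``block_ld = 0`` gives
independent sites.  Markers in distinct blocks are always independent.
There is no pedigree: relatedness enters downstream analyses only via
the realised genomic relationship matrix.

Phenotypes follow the analysis model

    y = Z_c gamma_c (causal blocks) + xi + eps,
    xi ~ N(0, K phi^2),  eps ~ N(0, I sigma^2),

with K the realised GRM of the simulated markers.  Variance fractions
are controlled on the scale var(y) ~ 1.  Phenotypes are plain
quantitative values; the smoothness of real estimated breeding values
is deliberately not emulated, since the model accepts any numeric
vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ebmodel
from .blocks import enumerate_haplotypes
from .ebmodel import KinshipEigen, build_Z
from .genio import PhasedGenotypes

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "draw_phenotype",
    "block_marker_indices",
    "write_truth",
]

_MAX_REJECT = 2000


@dataclass
class SimConfig:
    """Population and trait architecture of one synthetic study.

    ``snps_per_block`` lists the admissible block sizes (drawn uniformly
    per block) unless its length equals ``n_blocks``, in which case it
    gives the size of each block in order.  ``block_ld`` in [0, 1]
    controls within-block haplotype correlation.  ``h2_block`` is the
    phenotypic variance fraction contributed by each causal block and
    ``h2_polygenic`` the polygenic fraction.  ``seed`` is mandatory and
    is the single source of randomness.
    """

    n_individuals: int = 500
    n_blocks: int = 50
    snps_per_block: tuple[int, ...] = (2, 3, 4)
    inter_block_spacing_bp: int = 50_000
    intra_block_spacing_bp: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_ld: float = 0.98
    n_causal_blocks: int = 1
    h2_block: float = 0.05
    h2_polygenic: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if lo < 0.05:
            raise ValueError("maf_range lower bound must be >= 0.05")
        if not 0.0 <= self.block_ld <= 1.0:
            raise ValueError("block_ld must be in [0, 1]")
        if any(s not in (2, 3, 4) for s in self.snps_per_block):
            raise ValueError("snps_per_block entries must be in {2, 3, 4}")
        if self.n_causal_blocks > self.n_blocks:
            raise ValueError("fewer blocks exist than n_causal_blocks")
        if self.h2_block * self.n_causal_blocks + self.h2_polygenic >= 1.0:
            raise ValueError("h2_block * n_causal_blocks + h2_polygenic must be < 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimTruth:
    """Ground truth of one phenotype draw, for parameter-recovery tests."""

    causal_block_ids: list[str]
    true_gamma: dict[str, list[float]]
    true_lambda: float
    true_lambda_k: list[float]
    true_sigma2: float

    def __post_init__(self) -> None:
        if self.true_lambda < 0 or any(l < 0 for l in self.true_lambda_k):
            raise ValueError("variance ratios must be nonnegative")
        if self.true_sigma2 <= 0:
            raise ValueError("true_sigma2 must be positive")


def _block_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.asarray(config.snps_per_block, dtype=int)
    if len(sizes) == config.n_blocks:
        return sizes
    return rng.choice(sizes, size=config.n_blocks, replace=True)


def _draw_block(
    s: int, n_chrom: int, maf_range: tuple[float, float], block_ld: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample (n_chrom, s) alleles for one block, rejecting until every
    site's realised MAF reaches the lower bound of maf_range."""
    lo, hi = maf_range
    for _ in range(_MAX_REJECT):
        w = rng.dirichlet(np.ones(s + 1))
        # prefix haplotype t has ones at sites < t; site j marginal ALT
        # frequency is the pool mass of haplotypes with t > j
        f = np.cumsum(w[::-1])[::-1][1:]
        maf_pool = np.minimum(f, 1.0 - f)
        if np.any(maf_pool < lo) or np.any(maf_pool > hi):
            continue
        pool = np.tril(np.ones((s + 1, s), dtype=np.uint8), k=-1)  # row t = prefix-t
        draws = rng.choice(s + 1, size=n_chrom, p=w)
        alleles = pool[draws]
        if block_ld < 1.0:
            mask = rng.random((n_chrom, s)) > block_ld
            indep = (rng.random((n_chrom, s)) < f).astype(np.uint8)
            alleles = np.where(mask, indep, alleles)
        realised = alleles.mean(axis=0)
        if np.all(np.minimum(realised, 1.0 - realised) >= lo):
            return alleles
    raise RuntimeError("rejection sampling failed; maf_range too tight for n")


def simulate_genotypes(config: SimConfig) -> PhasedGenotypes:
    """Generate phased genotypes for one chromosome of LD blocks.

    Marker IDs encode block membership ("b0007_s2"), which downstream
    helpers use to recover the planted block structure.  Deterministic
    given the config (all randomness flows from ``config.seed``).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_individuals
    sizes = _block_sizes(config, rng)
    h1_cols, h2_cols, rows = [], [], []
    pos = 1
    for b, s in enumerate(sizes):
        alleles = _draw_block(int(s), 2 * n, config.maf_range, config.block_ld, rng)
        h1_cols.append(alleles[:n])
        h2_cols.append(alleles[n:])
        for j in range(s):
            rows.append(("1", pos, f"b{b:04d}_s{j}", "A", "G"))
            pos += config.intra_block_spacing_bp
        pos += config.inter_block_spacing_bp
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return PhasedGenotypes(
        individual_ids=[f"ind{i:05d}" for i in range(n)],
        markers=markers,
        hap1=np.hstack(h1_cols),
        hap2=np.hstack(h2_cols),
    )


def block_marker_indices(geno: PhasedGenotypes) -> dict[str, np.ndarray]:
    """Planted block id -> marker indices, decoded from simulated marker IDs."""
    out: dict[str, list[int]] = {}
    for i, mid in enumerate(geno.markers["id"]):
        bid = str(mid).split("_")[0]
        out.setdefault(bid, []).append(i)
    return {k: np.asarray(v) for k, v in out.items()}


def draw_phenotype(
    kinship: KinshipEigen,
    Z_list: list[np.ndarray],
    gamma_list: list[np.ndarray],
    lambda_: float,
    sigma2: float,
    rng: np.random.Generator,
    intercept: float = 0.0,
) -> np.ndarray:
    """One draw of y = intercept + sum Z gamma + xi + eps.

    xi ~ N(0, K lambda sigma2) is drawn through the eigendecomposition
    of K; eps ~ N(0, I sigma2).
    """
    n = kinship.n
    y = np.full(n, float(intercept))
    for Z, g in zip(Z_list, gamma_list):
        y += Z @ g
    if lambda_ > 0:
        z = rng.standard_normal(n)
        y += kinship.U @ (np.sqrt(kinship.D * lambda_ * sigma2) * z)
    y += rng.standard_normal(n) * np.sqrt(sigma2)
    return y


def simulate_phenotypes(
    geno: PhasedGenotypes,
    config: SimConfig,
    kinship: KinshipEigen | None = None,
) -> tuple[pd.Series, SimTruth]:
    """Draw a phenotype with the architecture described by ``config``.

    Causal blocks are chosen among the planted blocks; each receives
    iid N(0, phi_k^2) haplotype effects with phi_k^2 scaled so the
    block's expected phenotypic variance share equals ``h2_block``.
    The polygenic term uses the realised GRM of all simulated markers.
    Returns the phenotype (indexed by individual id) and the ground
    truth (lambda = phi^2/sigma^2, per-block lambda_k = phi_k^2/sigma^2).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    block_idx = block_marker_indices(geno)
    if len(block_idx) < config.n_causal_blocks:
        raise ValueError("fewer blocks exist than n_causal_blocks")
    if kinship is None:
        kinship = ebmodel.grm(geno)

    sigma2 = 1.0 - config.h2_polygenic - config.h2_block * config.n_causal_blocks
    phi2 = config.h2_polygenic
    causal_ids = sorted(
        rng.choice(sorted(block_idx), size=config.n_causal_blocks, replace=False)
    )
    Z_list, gamma_list, lam_k_list, gamma_rec = [], [], [], {}
    for bid in causal_ids:
        blk = enumerate_haplotypes(geno, block_idx[bid])
        blk.block_id = bid
        Z = build_Z(blk, min_hap_count=1).Z
        C = np.cov(Z, rowvar=False, ddof=0)
        trc = float(np.trace(np.atleast_2d(C)))
        phi_k2 = config.h2_block / trc if trc > 0 else 0.0
        gamma = rng.standard_normal(Z.shape[1]) * np.sqrt(phi_k2)
        Z_list.append(Z)
        gamma_list.append(gamma)
        lam_k_list.append(phi_k2 / sigma2)
        gamma_rec[bid] = [float(g) for g in gamma]
    lam = phi2 / sigma2
    y = draw_phenotype(kinship, Z_list, gamma_list, lam, sigma2, rng)
    phen = pd.Series(y, index=pd.Index(geno.individual_ids, name="id"), name="value")
    truth = SimTruth(
        causal_block_ids=[str(b) for b in causal_ids],
        true_gamma=gamma_rec,
        true_lambda=lam,
        true_lambda_k=lam_k_list,
        true_sigma2=sigma2,
    )
    return phen, truth


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
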