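"""Haplotype-block detection and haplotype enumeration.

Blocks are defined by the Gabriel confidence-interval rule on |D'|
between marker pairs: a contiguous run of markers is a block when at
least 95% of its informative pairwise comparisons show "strong LD"
(CI lower bound > 0.70 and upper bound >= 0.98) and fewer than 5% show
"strong recombination" (upper bound < 0.90).  Confidence bounds come
from likelihood profiling of |D'| on a grid, the convention used by
Haploview.  Only blocks of 2-4 SNPs are emitted; longer runs are split
left to right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import PhasedGenotypes

__all__ = [
    "HaplotypeBlock",
    "GabrielConfig",
    "pair_counts",
    "dprime_ci",
    "gabriel_blocks",
    "enumerate_haplotypes",
    "blocks_table",
]

_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class HaplotypeBlock:
    """A run of 2-4 consecutive markers with its observed haplotypes.

    ``haplotypes`` are allele-code strings ("011", ...) ordered by
    descending chromosome frequency (lexicographic on ties); ``hap_pair``
    maps each individual's two chromosomes to indices into that list;
    ``counts``/``frequencies`` are exact chromosome tallies over 2n.
    """

    block_id: str
    chrom: str
    marker_indices: np.ndarray
    start_bp: int
    end_bp: int
    haplotypes: list[str]
    hap_pair: np.ndarray
    counts: np.ndarray
    frequencies: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.marker_indices)

    @property
    def labels(self) -> list[str]:
        """S2-style labels: 'H' + concatenated allele codes."""
        return ["H" + h for h in self.haplotypes]


@dataclass(frozen=True)
class GabrielConfig:
    """Thresholds of the Gabriel block rule (Haploview defaults)."""

    strong_low: float = 0.70   # CI lower bound must exceed this
    strong_high: float = 0.98  # CI upper bound must reach this
    recomb_high: float = 0.90  # upper bound below this = strong recombination
    strong_frac: float = 0.95  # informative pairs that must be strong LD
    max_snps: int = 4
    max_span_markers: int = 30  # longest candidate window examined


def pair_counts(geno: PhasedGenotypes, i: int, j: int) -> np.ndarray:
    """2x2 gamete count table for markers i, j over the 2n phased chromosomes.

    Entry [a, b] counts chromosomes carrying allele a at marker i and
    allele b at marker j.
    """
    ai = np.concatenate([geno.hap1[:, i], geno.hap2[:, i]])
    aj = np.concatenate([geno.hap1[:, j], geno.hap2[:, j]])
    table = np.zeros((2, 2), dtype=np.int64)
    np.add.at(table, (ai, aj), 1)
    return table


def dprime_ci(counts: np.ndarray) -> tuple[float, float, float]:
    """|D'| point estimate and likelihood-profile confidence bounds.

    ``counts`` is the 2x2 gamete table of two biallelic markers.  The
    bounds are obtained by evaluating the multinomial likelihood of the
    table on a 101-point |D'| grid (allele frequencies fixed at their
    sample values), normalising, and cutting 5% of the likelihood mass
    from each end.  Returns ``(point, lower, upper)`` with
    0 <= lower <= point <= upper <= 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2) or counts.min() < 0:
        raise ValueError("counts must be a nonnegative 2x2 table")
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if n == 0 or 0.0 in row or 0.0 in col:
        raise ValueError("degenerate 2x2 table: a marker is monomorphic in-sample")
    pa = row[1] / n  # freq of allele 1 at first marker
    pb = col[1] / n
    d_obs = counts[1, 1] / n - pa * pb
    if d_obs >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        # only possible at a boundary frequency, excluded above
        raise ValueError("degenerate allele frequencies")
    point = min(abs(d_obs) / dmax, 1.0)
    sign = 1.0 if d_obs >= 0 else -1.0

    d_vals = sign * _GRID * dmax
    p11 = pa * pb + d_vals
    p10 = pa * (1 - pb) - d_vals
    p01 = (1 - pa) * pb - d_vals
    p00 = (1 - pa) * (1 - pb) + d_vals
    probs = np.clip(np.stack([p00, p01, p10, p11], axis=1), 1e-12, None)
    c = np.array([counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]])
    loglik = (c * np.log(probs)).sum(axis=1)
    lik = np.exp(loglik - loglik.max())
    cum = np.cumsum(lik) / lik.sum()
    lower = _GRID[int(np.searchsorted(cum, 0.05, side="left"))]
    upper = _GRID[int(np.searchsorted(cum, 0.95, side="right"))]
    lower = min(lower, point)
    upper = max(upper, point)
    return point, lower, upper


def _pair_class(geno: PhasedGenotypes, i: int, j: int, cfg: GabrielConfig) -> int:
    """Classify a marker pair: 1 strong LD, -1 strong recombination, 0 uninformative."""
    try:
        _, lo, hi = dprime_ci(pair_counts(geno, i, j))
    except ValueError:
        return 0
    if lo > cfg.strong_low and hi >= cfg.strong_high:
        return 1
    if hi < cfg.recomb_high:
        return -1
    return 0


def gabriel_blocks(
    geno: PhasedGenotypes,
    config: GabrielConfig | None = None,
) -> list[HaplotypeBlock]:
    """Partition each chromosome into Gabriel haplotype blocks.

    All contiguous windows up to ``max_span_markers`` are scored against
    the strong-LD/recombination rule; qualifying windows are accepted
    greedily, largest first (ties to the leftmost window), without
    overlap.  Accepted runs longer than ``max_snps`` markers are split
    left to right into chunks of at most ``max_snps``; chunks of a
    single marker are never emitted.
    """
    cfg = config or GabrielConfig()
    chrom = geno.markers["chrom"].to_numpy()
    out: list[HaplotypeBlock] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        mc = len(idx)
        # pairwise classification, computed once per chromosome
        cls = np.zeros((mc, mc), dtype=np.int8)
        for a in range(mc):
            for b in range(a + 1, min(mc, a + cfg.max_span_markers)):
                cls[a, b] = _pair_class(geno, idx[a], idx[b], cfg)
        candidates = []
        for a in range(mc):
            for b in range(a + 1, min(mc, a + cfg.max_span_markers)):
                sub = cls[a : b + 1, a : b + 1]
                strong = int(np.count_nonzero(sub == 1))
                recomb = int(np.count_nonzero(sub == -1))
                informative = strong + recomb
                if informative == 0:
                    continue
                if strong / informative >= cfg.strong_frac:
                    candidates.append((a, b))
        # largest first; ties resolved leftmost
        candidates.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
        taken = np.zeros(mc, dtype=bool)
        accepted = []
        for a, b in candidates:
            if taken[a : b + 1].any():
                continue
            taken[a : b + 1] = True
            accepted.append((a, b))
        for a, b in sorted(accepted):
            for s in range(a, b + 1, cfg.max_snps):
                e = min(s + cfg.max_snps - 1, b)
                if e > s:  # never emit single-marker chunks
                    out.append(enumerate_haplotypes(geno, idx[s : e + 1]))
    for k, blk in enumerate(out):
        blk.block_id = f"B{k + 1:04d}"
    return out


def enumerate_haplotypes(
    geno: PhasedGenotypes, marker_indices: np.ndarray
) -> HaplotypeBlock:
    """Tally the distinct haplotypes of 2-4 consecutive markers.

    Haplotypes are ordered by descending frequency over the 2n
    chromosomes, ties broken lexicographically on the allele-code
    string; each frequency is an exact chromosome count over 2n.
    """
    marker_indices = np.asarray(marker_indices)
    s = len(marker_indices)
    if not 2 <= s <= 4:
        raise ValueError("a block must span 2-4 markers")
    if np.any(np.diff(marker_indices) != 1):
        raise ValueError("block markers must be consecutive on the map")
    sub = geno.markers.iloc[marker_indices]
    chroms = sub["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("block markers span multiple chromosomes")

    h1 = geno.hap1[:, marker_indices]
    h2 = geno.hap2[:, marker_indices]
    weights = (2 ** np.arange(s - 1, -1, -1)).astype(np.int64)
    code1 = h1 @ weights
    code2 = h2 @ weights
    codes, counts = np.unique(np.concatenate([code1, code2]), return_counts=True)
    strings = [format(int(v), f"0{s}b") for v in codes]
    order = sorted(range(len(codes)), key=lambda i: (-counts[i], strings[i]))
    haplotypes = [strings[i] for i in order]
    counts_sorted = counts[order]
    remap = np.full(2**s, -1, dtype=np.int64)
    for rank, i in enumerate(order):
        remap[codes[i]] = rank
    hap_pair = np.column_stack([remap[code1], remap[code2]])
    return HaplotypeBlock(
        block_id="",
        chrom=str(chroms[0]),
        marker_indices=marker_indices,
        start_bp=int(sub["pos"].iloc[0]),
        end_bp=int(sub["pos"].iloc[-1]),
        haplotypes=haplotypes,
        hap_pair=hap_pair,
        counts=counts_sorted,
        frequencies=counts_sorted / (2 * geno.n),
    )


def blocks_table(blocks: list[HaplotypeBlock], geno: PhasedGenotypes) -> pd.DataFrame:
    """Summary table of detected blocks (one row per block)."""
    rows = []
    pos = geno.markers["pos"].to_numpy()
    for blk in blocks:
        rows.append(
            {
                "block_id": blk.block_id,
                "chrom": blk.chrom,
                "start_bp": blk.start_bp,
                "end_bp": blk.end_bp,
                "n_snps": blk.n_snps,
                "snp_positions": ",".join(str(pos[i]) for i in blk.marker_indices),
                "haplotypes": ",".join(blk.labels),
                "frequencies": ",".join(f"{f:.6g}" for f in blk.frequencies),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id",
            "chrom",
            "start_bp",
            "end_bp",
            "n_snps",
            "snp_positions",
            "haplotypes",
            "frequencies",
        ],
    )
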