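"""Multiple-testing correction via an effective number of tests.

Block tests are correlated through LD, so dividing alpha by the raw
number of blocks (classical Bonferroni) overcorrects.  The modified
Bonferroni threshold divides alpha by an effective number of
independent tests m_eff estimated from the eigenvalues of a
test-correlation matrix — by default the Li & Ji (2005) estimator on
the correlation of block lead-SNP dosages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import HaplotypeBlock
from .ebmodel import ScanResult
from .genio import PhasedGenotypes, compute_maf

__all__ = [
    "ThresholdSet",
    "effective_tests",
    "thresholds",
    "call_significant",
    "lead_snp_correlation",
    "write_thresholds",
]

LABEL_NONE = "none"
LABEL_MBON = "Only mBon"
LABEL_BOTH = "Both Bon& mBon"


@dataclass
class ThresholdSet:
    alpha: float
    n_tests: int
    m_eff: float
    bon_threshold: float
    mbon_threshold: float


def effective_tests(corr: np.ndarray, method: str = "liji") -> float:
    """Effective number of independent tests from a correlation matrix.

    ``liji``: Li & Ji (2005), m_eff = sum_i [ I(|e_i| >= 1) + (|e_i| -
    floor(|e_i|)) ] over eigenvalues e_i.  ``simpleM``: Gao's estimator,
    the smallest k whose top-k eigenvalues carry 99.5% of the total
    eigenvalue mass.  The result is clamped to [1, dim].
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    m = corr.shape[0]
    evals = np.abs(np.linalg.eigvalsh(corr))
    if method == "liji":
        # guard floor() against eigenvalues that are integers up to round-off
        flo = np.floor(evals + 1e-10)
        meff = float(np.sum((evals >= 1.0 - 1e-10) + np.maximum(evals - flo, 0.0)))
    elif method == "simpleM":
        e = np.sort(evals)[::-1]
        cum = np.cumsum(e) / e.sum()
        meff = float(np.searchsorted(cum, 0.995) + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(min(max(meff, 1.0), m))


def thresholds(alpha: float, n_tests: int, m_eff: float) -> ThresholdSet:
    """Classical (alpha/n_tests) and modified (alpha/m_eff) Bonferroni cuts."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 1.0 <= m_eff <= n_tests:
        raise ValueError(f"m_eff must lie in [1, n_tests], got {m_eff}")
    return ThresholdSet(
        alpha=alpha,
        n_tests=int(n_tests),
        m_eff=float(m_eff),
        bon_threshold=alpha / n_tests,
        mbon_threshold=alpha / m_eff,
    )


def call_significant(scan: ScanResult, ts: ThresholdSet) -> ScanResult:
    """Label each block none / "Only mBon" / "Both Bon& mBon".

    p <= bon gives both corrections, bon < p <= mbon only the modified
    one; non-converged fits are never called significant.
    """
    table = scan.table.copy()
    p = table["p"].to_numpy(float)
    ok = table["converged"].to_numpy(bool) & np.isfinite(p)
    label = np.full(len(table), LABEL_NONE, dtype=object)
    label[ok & (p <= ts.mbon_threshold)] = LABEL_MBON
    label[ok & (p <= ts.bon_threshold)] = LABEL_BOTH
    table["significance"] = label
    return ScanResult(table=table, fits=scan.fits)


def lead_snp_correlation(
    geno: PhasedGenotypes, blocks: list[HaplotypeBlock]
) -> np.ndarray:
    """Correlation matrix of block lead-SNP dosages.

    The lead SNP of a block is its marker with the largest MAF (ties to
    the first).  Constant dosage columns get zero correlation with
    everything (diagonal kept at 1).
    """
    maf = compute_maf(geno)["maf"].to_numpy()
    lead = [int(b.marker_indices[int(np.argmax(maf[b.marker_indices]))]) for b in blocks]
    dose = geno.dosage().astype(float)[:, lead]
    sd = dose.std(axis=0)
    dose = (dose - dose.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    corr = (dose.T @ dose) / dose.shape[0]
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)


def write_thresholds(ts: ThresholdSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(ts), fh, indent=2, sort_keys=True)
        fh.write("\n")
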