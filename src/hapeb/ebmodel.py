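"""Empirical-Bayes variance-component association test for haplotype blocks.

The model for block k is

    y = X beta + Z_k gamma_k + xi + eps,
    gamma_k ~ N(0, I phi_k^2),  xi ~ N(0, K phi^2),  eps ~ N(0, I sigma^2),

so var(y) = (Z_k Z_k' lambda_k + K lambda + I) sigma^2 with
lambda = phi^2/sigma^2 and lambda_k = phi_k^2/sigma^2.  K is a
marker-derived genomic relationship matrix.  After the one-time
eigendecomposition K = U D U' the transformed data y* = U'y, X* = U'X,
Z* = U'Z_k have covariance (Z* Z*' lambda_k + R) sigma^2 with diagonal
R = D lambda + I, which makes every likelihood evaluation O(n h^2) by
the Woodbury identity — no n x n inverse is ever formed.

The profiled restricted log-likelihood (beta and sigma^2 eliminated) is

    L(lambda_k, lambda) = -1/2 ln|H| - 1/2 ln|X*' H^-1 X*|
                          - (n - r)/2 ln(y*' P y*)

with H = Z* Z*' lambda_k + R and P the REML projection.  It is
maximised by Newton-Raphson on log-parameters; the fitted lambda_k then
acts as an empirical-Bayes prior for the haplotype effects, whose BLUP
gamma_hat and posterior covariance feed a Wald statistic referred to
chi-square with 1 degree of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .blocks import HaplotypeBlock
from .genio import PhasedGenotypes

__all__ = [
    "KinshipEigen",
    "ModelData",
    "BlockDesign",
    "TransformedData",
    "VarianceParams",
    "BlockFit",
    "ScanResult",
    "TooFewHaplotypes",
    "grm",
    "build_Z",
    "transform",
    "profiled_reml_loglik",
    "eb_estimates",
    "fit_transformed",
    "fit_block",
    "wald_test",
    "scan",
    "single_snp_scan",
]

logger = logging.getLogger(__name__)

_LOG_CLAMP = 30.0  # log-scale bound; exp(-30) is numerically zero variance
_GRAD_TOL = 1e-6
_MAX_ITER = 100


class TooFewHaplotypes(ValueError):
    """Block has fewer than two haplotypes above the count threshold."""


@dataclass
class KinshipEigen:
    """Kinship matrix with its eigendecomposition K = U D U'.

    Eigenvalues are stored in descending order.
    """

    K: np.ndarray
    U: np.ndarray
    D: np.ndarray

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class ModelData:
    """Phenotype vector and fixed-effect design aligned with genotypes."""

    y: np.ndarray
    X: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n, r = self.X.shape
        if len(self.y) != n:
            raise ValueError("y and X have inconsistent lengths")
        if np.linalg.matrix_rank(self.X) < r:
            raise ValueError("X is rank deficient")
        if n <= r:
            raise ValueError("need more individuals than fixed effects")


@dataclass
class BlockDesign:
    """Haplotype-inheritance matrix Z (n x h): copies of each haplotype carried."""

    Z: np.ndarray
    labels: list[str]


@dataclass
class TransformedData:
    """Eigen-rotated data: y* = U'y, X* = U'X, Z* = U'Z."""

    y_star: np.ndarray
    X_star: np.ndarray
    Z_star: np.ndarray


@dataclass
class VarianceParams:
    lambda_: float
    lambda_k: float
    sigma2: float

    @property
    def theta(self) -> tuple[float, float]:
        return (self.lambda_k, self.lambda_)


@dataclass
class BlockFit:
    """Result of one block's REML fit and empirical-Bayes test."""

    params: VarianceParams
    beta_hat: np.ndarray
    gamma_hat: np.ndarray
    gamma_cov: np.ndarray
    W: float
    p: float
    loglik: float
    converged: bool
    n_iter: int
    labels: list[str] = field(default_factory=list)


@dataclass
class ScanResult:
    """Per-block association results plus the fitted objects."""

    table: pd.DataFrame
    fits: list[BlockFit | None] = field(default_factory=list)


# ---------------------------------------------------------------------------
# kinship


def grm(geno: PhasedGenotypes) -> KinshipEigen:
    """VanRaden method-1 genomic relationship matrix with eigendecomposition.

    K = W W' / (2 sum_j p_j (1 - p_j)) where W is the column-centred
    ALT-dosage matrix and p_j the ALT frequency of marker j.
    """
    if geno.m < 2:
        raise ValueError("need at least 2 markers to build a kinship matrix")
    M = geno.dosage().astype(float)
    p = M.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers are monomorphic; kinship undefined")
    W = M - 2.0 * p
    K = (W @ W.T) / denom
    K = 0.5 * (K + K.T)
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    D = np.maximum(evals[order], 0.0)  # clip tiny negative round-off
    U = evecs[:, order]
    return KinshipEigen(K=K, U=U, D=D)


# ---------------------------------------------------------------------------
# design matrices


def build_Z(block: HaplotypeBlock, min_hap_count: int = 5) -> BlockDesign:
    """Haplotype-inheritance design for a block.

    Column j counts the copies of haplotype j carried by each
    individual, so each row has at most two nonzero entries and sums to
    exactly 2.  Haplotypes observed on fewer than ``min_hap_count``
    chromosomes are pooled into a trailing "rare" column rather than
    dropped, preserving the row-sum invariant.  A block with fewer than
    two common haplotypes raises :class:`TooFewHaplotypes`.
    """
    counts = np.asarray(block.counts)
    common = np.flatnonzero(counts >= min_hap_count)
    if len(common) < 2:
        raise TooFewHaplotypes(
            f"block {block.block_id}: {len(common)} haplotype(s) with "
            f"count >= {min_hap_count}"
        )
    h = len(common)
    rare = len(common) < len(counts)
    col_of = np.full(len(counts), h, dtype=int)  # rare bucket by default
    col_of[common] = np.arange(h)
    n = block.hap_pair.shape[0]
    Z = np.zeros((n, h + 1 if rare else h))
    rows = np.arange(n)
    np.add.at(Z, (rows, col_of[block.hap_pair[:, 0]]), 1.0)
    np.add.at(Z, (rows, col_of[block.hap_pair[:, 1]]), 1.0)
    labels = [block.labels[i] for i in common] + (["rare"] if rare else [])
    return BlockDesign(Z=Z, labels=labels)


def transform(ke: KinshipEigen, y: np.ndarray, X: np.ndarray, Z: np.ndarray) -> TransformedData:
    """Rotate data into the kinship eigenbasis."""
    Ut = ke.U.T
    return TransformedData(
        y_star=Ut @ np.asarray(y, float).ravel(),
        X_star=Ut @ np.atleast_2d(np.asarray(X, float)),
        Z_star=Ut @ np.atleast_2d(np.asarray(Z, float)),
    )


# ---------------------------------------------------------------------------
# likelihood machinery (Woodbury on diagonal R + rank-h update)


def _core(td: TransformedData, D: np.ndarray, theta: tuple[float, float]) -> dict:
    """Shared O(n h^2) pieces: solves with H = lam_k Z*Z*' + diag(D lam + 1).

    H^-1 B = R^-1 B - lam_k R^-1 Z (I + lam_k Z' R^-1 Z)^-1 Z' R^-1 B and
    ln|H| = ln|R| + ln|I + lam_k Z' R^-1 Z|.
    """
    lam_k, lam = theta
    if lam_k < 0 or lam < 0:
        raise ValueError(f"variance ratios must be nonnegative, got {theta}")
    y, X, Z = td.y_star, td.X_star, td.Z_star
    n, r = X.shape
    h = Z.shape[1]
    rinv = 1.0 / (D * lam + 1.0)

    RiZ = Z * rinv[:, None]
    M = np.eye(h) + lam_k * (Z.T @ RiZ)  # h x h capacitance
    Mc = np.linalg.cholesky(M)

    def hsolve(B: np.ndarray) -> np.ndarray:
        B2 = np.atleast_2d(B.T).T if B.ndim == 1 else B
        RiB = B2 * rinv[:, None]
        t = np.linalg.solve(Mc.T, np.linalg.solve(Mc, RiZ.T @ B2))
        out = RiB - lam_k * (RiZ @ t)
        return out.ravel() if B.ndim == 1 else out

    logdet_H = -np.sum(np.log(rinv)) + 2.0 * np.sum(np.log(np.diag(Mc)))
    HiX = hsolve(X)
    Hiy = hsolve(y)
    XtHiX = X.T @ HiX
    sgn, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sgn <= 0:
        raise FloatingPointError(f"X*'H^-1X* not positive definite at theta={theta}")
    XtHiy = X.T @ Hiy
    beta = np.linalg.solve(XtHiX, XtHiy)
    Py = Hiy - HiX @ beta  # = P y*
    yPy = float(y @ Py)
    return {
        "hsolve": hsolve,
        "logdet_H": float(logdet_H),
        "logdet_XtHiX": float(logdet_XtHiX),
        "XtHiX": XtHiX,
        "HiX": HiX,
        "beta": beta,
        "Py": Py,
        "yPy": yPy,
        "n": n,
        "r": r,
    }


def profiled_reml_loglik(
    td: TransformedData, D: np.ndarray, theta: tuple[float, float]
) -> float:
    """Profiled restricted log-likelihood L(lambda_k, lambda).

    L = -1/2 ln|H| - 1/2 ln|X*'H^-1 X*| - (n-r)/2 ln(y*' P y*), with all
    determinants and solves done through the diagonal-plus-rank-h
    structure of H.
    """
    c = _core(td, D, theta)
    if c["yPy"] <= 0:
        raise FloatingPointError(f"nonpositive residual quadratic form at theta={theta}")
    L = (
        -0.5 * c["logdet_H"]
        - 0.5 * c["logdet_XtHiX"]
        - 0.5 * (c["n"] - c["r"]) * np.log(c["yPy"])
    )
    if not np.isfinite(L):
        raise FloatingPointError(f"non-finite restricted log-likelihood at theta={theta}")
    return float(L)


def eb_estimates(
    td: TransformedData, D: np.ndarray, theta: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """GLS fixed effects and empirical-Bayes block effects at given theta.

    Returns ``(beta_hat, gamma_hat, gamma_cov, sigma2)`` where
    sigma2 = y*'P y*/(n-r), gamma_hat = lambda_k Z*' P y* (the BLUP of
    gamma under the fitted prior) and gamma_cov is the posterior
    covariance sigma2 * lambda_k (I - lambda_k Z*' P Z*), identical to
    the gamma block of the inverse mixed-model-equation matrix.
    """
    lam_k, _ = theta
    c = _core(td, D, theta)
    Z = td.Z_star
    h = Z.shape[1]
    sigma2 = c["yPy"] / (c["n"] - c["r"])
    gamma = lam_k * (Z.T @ c["Py"])
    HiZ = c["hsolve"](Z)
    PZ = HiZ - c["HiX"] @ np.linalg.solve(c["XtHiX"], td.X_star.T @ HiZ)
    ZtPZ = Z.T @ PZ
    gamma_cov = sigma2 * lam_k * (np.eye(h) - lam_k * ZtPZ)
    return c["beta"], gamma, gamma_cov, float(sigma2)


# ---------------------------------------------------------------------------
# optimisation


def _objective(td, D, u):
    """Negative profiled REML as a function of u = log(theta)."""
    return -profiled_reml_loglik(td, D, tuple(np.exp(u)))


def _num_grad(f, u, h=1e-5):
    g = np.zeros_like(u)
    for i in range(len(u)):
        e = np.zeros_like(u)
        e[i] = h
        g[i] = (f(u + e) - f(u - e)) / (2 * h)
    return g


def _num_hess(f, u, h=1e-4):
    k = len(u)
    H = np.zeros((k, k))
    f0 = f(u)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (f(u + ei) - 2 * f0 + f(u - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(u + ei + ej) - f(u + ei - ej) - f(u - ei + ej) + f(u - ei - ej)
            ) / (4 * h**2)
    return H


def _init_lambda(td: TransformedData, D: np.ndarray) -> float:
    """Grid-search the polygenic ratio on the null model (lambda_k ~ 0)."""
    best, best_l = -np.inf, 0.1
    for lam in (0.01, 0.1, 1.0, 10.0):
        try:
            L = profiled_reml_loglik(td, D, (np.exp(-_LOG_CLAMP), lam))
        except FloatingPointError:
            continue
        if L > best:
            best, best_l = L, lam
    return best_l


def fit_transformed(
    td: TransformedData,
    D: np.ndarray,
    labels: list[str] | None = None,
    wald_df: int | str = 1,
) -> BlockFit:
    """Maximise the profiled REML over theta = (lambda_k, lambda).

    Newton-Raphson on (log lambda_k, log lambda) with finite-difference
    gradient/Hessian and step-halving; convergence when the gradient
    max-norm drops below 1e-6 (or a parameter is pinned at the zero
    clamp exp(-30)).  If Newton-Raphson fails to move, a Nelder-Mead
    polish is attempted; a fit that still fails the gradient test is
    flagged ``converged=False``.
    """

    def f(u):
        try:
            return _objective(td, D, np.clip(u, -_LOG_CLAMP, _LOG_CLAMP))
        except FloatingPointError:
            return np.inf

    u = np.array([np.log(0.01), np.log(_init_lambda(td, D))])
    fu = f(u)
    # the finite-difference gradient cannot resolve below the rounding
    # noise of L, which scales with |L|; widen the tolerance accordingly
    grad_tol = max(_GRAD_TOL, 100.0 * np.finfo(float).eps * max(abs(fu), 1.0) / 1e-5)
    n_iter = 0
    converged = False
    for n_iter in range(1, _MAX_ITER + 1):
        g = _num_grad(f, u)
        if np.max(np.abs(g)) < grad_tol:
            converged = True
            break
        H = _num_hess(f, u)
        try:
            step = np.linalg.solve(H, -g)
            if g @ step > 0:  # not a descent direction
                step = -g
        except np.linalg.LinAlgError:
            step = -g
        norm = np.linalg.norm(step)
        if norm > 10.0:
            step *= 10.0 / norm
        improved = False
        for _ in range(30):
            u_new = np.clip(u + step, -_LOG_CLAMP, _LOG_CLAMP)
            fu_new = f(u_new)
            if fu_new < fu - 1e-12:
                u, fu = u_new, fu_new
                improved = True
                break
            step *= 0.5
        if not improved:
            # at the clamp the log-scale gradient vanishes with lambda
            at_bound = np.isclose(u, -_LOG_CLAMP)
            g_free = np.where(at_bound & (g > 0), 0.0, g)
            converged = bool(np.max(np.abs(g_free)) < grad_tol)
            break
    if not converged:
        res = minimize(f, u, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
        if res.fun < fu:
            u, fu = np.clip(res.x, -_LOG_CLAMP, _LOG_CLAMP), res.fun
        g = _num_grad(f, u)
        at_bound = np.isclose(u, -_LOG_CLAMP)
        g_free = np.where(at_bound & (g > 0), 0.0, g)
        converged = bool(np.max(np.abs(g_free)) < grad_tol)

    theta = tuple(np.exp(np.clip(u, -_LOG_CLAMP, _LOG_CLAMP)))
    beta, gamma, gamma_cov, sigma2 = eb_estimates(td, D, theta)
    W, p = wald_test(gamma, gamma_cov, df=wald_df)
    return BlockFit(
        params=VarianceParams(lambda_=theta[1], lambda_k=theta[0], sigma2=sigma2),
        beta_hat=beta,
        gamma_hat=gamma,
        gamma_cov=gamma_cov,
        W=W,
        p=p,
        loglik=-fu,
        converged=converged,
        n_iter=n_iter,
        labels=labels or [],
    )


def fit_block(
    td: TransformedData,
    D: np.ndarray,
    labels: list[str] | None = None,
    wald_df: int | str = 1,
) -> BlockFit:
    """Alias of :func:`fit_transformed` taking a block's transformed data."""
    return fit_transformed(td, D, labels=labels, wald_df=wald_df)


def wald_test(
    gamma_hat: np.ndarray,
    gamma_cov: np.ndarray,
    df: int | str = 1,
) -> tuple[float, float]:
    """Wald statistic W = gamma' pinv(cov) gamma and p = Pr(chi2_df > W).

    ``df`` defaults to 1 regardless of the number of haplotype columns;
    ``df="rank"`` refers W to chi-square with rank(gamma_cov) degrees
    of freedom instead.  The pseudo-inverse uses a relative rank
    tolerance of 1e-8; an all-zero covariance yields W = 0, p = 1.
    """
    gamma_hat = np.asarray(gamma_hat, float).ravel()
    gamma_cov = np.atleast_2d(np.asarray(gamma_cov, float))
    scale = np.max(np.abs(gamma_cov))
    if scale == 0.0 or not np.isfinite(scale):
        return 0.0, 1.0
    W = float(gamma_hat @ np.linalg.pinv(gamma_cov, rcond=1e-8) @ gamma_hat)
    W = max(W, 0.0)
    if df == "rank":
        df = int(np.linalg.matrix_rank(gamma_cov, tol=1e-8 * scale))
        df = max(df, 1)
    return W, float(chi2.sf(W, df=df))


# ---------------------------------------------------------------------------
# genome scans


def _check_alignment(geno_ids: list[str], phen: pd.Series) -> np.ndarray:
    missing = [i for i in geno_ids if i not in phen.index]
    extra = [i for i in phen.index if i not in geno_ids]
    if missing or extra:
        raise ValueError(
            "phenotype/genotype id mismatch; missing from phenotypes: "
            f"{missing[:5]}; unknown ids: {extra[:5]}"
        )
    return phen.loc[geno_ids].to_numpy(float)


def _make_X(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, float))
    return np.column_stack([np.ones(n), C])


def scan(
    geno: PhasedGenotypes,
    phen: pd.Series,
    blocks: list[HaplotypeBlock],
    kinship: KinshipEigen,
    covariates: np.ndarray | None = None,
    min_hap_count: int = 5,
    wald_df: int | str = 1,
) -> ScanResult:
    """Fit the empirical-Bayes model to every block.

    The eigen-rotation of y and X is computed once; each block only
    rotates its own Z.  Blocks with fewer than two common haplotypes
    are skipped (row kept, fit absent); deterministic given inputs.
    """
    y = _check_alignment(geno.individual_ids, phen)
    X = _make_X(geno.n, covariates)
    Ut = kinship.U.T
    y_star, X_star = Ut @ y, Ut @ X
    rows, fits = [], []
    for blk in blocks:
        row = {
            "block_id": blk.block_id,
            "chrom": blk.chrom,
            "start_bp": blk.start_bp,
            "end_bp": blk.end_bp,
            "n_snps": blk.n_snps,
        }
        try:
            design = build_Z(blk, min_hap_count=min_hap_count)
        except TooFewHaplotypes as exc:
            logger.info("skipping %s: %s", blk.block_id, exc)
            row.update(
                n_haplotypes=np.nan, **{"lambda": np.nan}, lambda_k=np.nan,
                sigma2=np.nan, W=np.nan, p=np.nan, converged=False, n_iter=0,
            )
            rows.append(row)
            fits.append(None)
            continue
        td = TransformedData(y_star=y_star, X_star=X_star, Z_star=Ut @ design.Z)
        fit = fit_transformed(td, kinship.D, labels=design.labels, wald_df=wald_df)
        row.update(
            n_haplotypes=design.Z.shape[1],
            **{"lambda": fit.params.lambda_},
            lambda_k=fit.params.lambda_k,
            sigma2=fit.params.sigma2,
            W=fit.W,
            p=fit.p,
            converged=fit.converged,
            n_iter=fit.n_iter,
        )
        rows.append(row)
        fits.append(fit)
    cols = [
        "block_id", "chrom", "start_bp", "end_bp", "n_snps", "n_haplotypes",
        "lambda", "lambda_k", "sigma2", "W", "p", "converged", "n_iter",
    ]
    return ScanResult(table=pd.DataFrame(rows, columns=cols), fits=fits)


def single_snp_scan(
    geno: PhasedGenotypes,
    phen: pd.Series,
    kinship: KinshipEigen,
    covariates: np.ndarray | None = None,
) -> ScanResult:
    """Single-locus scan: each marker is a one-column random effect.

    The ALT dosage vector plays the role of Z (h = 1) in the same
    likelihood machinery as the block scan.
    """
    y = _check_alignment(geno.individual_ids, phen)
    X = _make_X(geno.n, covariates)
    Ut = kinship.U.T
    y_star, X_star = Ut @ y, Ut @ X
    dose = geno.dosage().astype(float)
    rows, fits = [], []
    for j in range(geno.m):
        mk = geno.markers.iloc[j]
        td = TransformedData(
            y_star=y_star, X_star=X_star, Z_star=Ut @ dose[:, [j]]
        )
        fit = fit_transformed(td, kinship.D, labels=[str(mk["id"])])
        rows.append(
            {
                "block_id": str(mk["id"]),
                "chrom": mk["chrom"],
                "start_bp": int(mk["pos"]),
                "end_bp": int(mk["pos"]),
                "n_snps": 1,
                "n_haplotypes": 1,
                "lambda": fit.params.lambda_,
                "lambda_k": fit.params.lambda_k,
                "sigma2": fit.params.sigma2,
                "W": fit.W,
                "p": fit.p,
                "converged": fit.converged,
                "n_iter": fit.n_iter,
            }
        )
        fits.append(fit)
    cols = [
        "block_id", "chrom", "start_bp", "end_bp", "n_snps", "n_haplotypes",
        "lambda", "lambda_k", "sigma2", "W", "p", "converged", "n_iter",
    ]
    return ScanResult(table=pd.DataFrame(rows, columns=cols), fits=fits)
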