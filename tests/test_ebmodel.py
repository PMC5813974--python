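import numpy as np
import pandas as pd
import pytest

from hapeb import ebmodel, simdata
from hapeb.blocks import HaplotypeBlock, enumerate_haplotypes
from hapeb.ebmodel import (
    KinshipEigen,
    TooFewHaplotypes,
    TransformedData,
    build_Z,
    eb_estimates,
    fit_transformed,
    grm,
    profiled_reml_loglik,
    scan,
    single_snp_scan,
    transform,
    wald_test,
)
from hapeb.simdata import SimConfig, simulate_genotypes

from conftest import make_geno


def _random_Z(rng, n, h):
    """A valid haplotype-inheritance matrix: two unit draws per row."""
    Z = np.zeros((n, h))
    for i in range(n):
        for c in rng.choice(h, 2, replace=True):
            Z[i, c] += 1.0
    return Z


def dense_loglik(y, X, Z, K, theta):
    """Independent dense-covariance evaluation of the profiled REML."""
    lam_k, lam = theta
    n, r = X.shape
    V = lam_k * (Z @ Z.T) + lam * K + np.eye(n)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return (
        -0.5 * np.linalg.slogdet(V)[1]
        - 0.5 * np.linalg.slogdet(XtViX)[1]
        - 0.5 * (n - r) * np.log(y @ P @ y)
    )


class TestGRM:
    def test_duplicate_individuals(self, rng):
        base = rng.integers(0, 2, (1, 10))
        h = np.vstack([base, base, rng.integers(0, 2, (3, 10))]).astype(np.uint8)
        ke = grm(make_geno(h, h))
        assert ke.K[0, 1] == pytest.approx(ke.K[0, 0])
        assert ke.K[0, 1] == pytest.approx(ke.K[1, 1])

    def test_diagonal_normalisation(self):
        # VanRaden scaling: mean diagonal ~ 1 for unrelated individuals
        rng = np.random.default_rng(5)
        p = rng.uniform(0.1, 0.5, 400)
        dose = rng.binomial(2, p, size=(300, 400)).astype(np.uint8)
        h1 = np.minimum(dose, 1)
        h2 = dose - h1
        ke = grm(make_geno(h1, h2))
        assert np.mean(np.diag(ke.K)) == pytest.approx(1.0, rel=0.05)

    def test_eigendecomposition_reconstructs(self, small_geno):
        ke = grm(small_geno)
        recon = ke.U @ np.diag(ke.D) @ ke.U.T
        assert np.abs(recon - ke.K).max() < 1e-8
        assert np.all(np.diff(ke.D) <= 1e-12)  # descending

    def test_monomorphic_error(self):
        g = make_geno(np.zeros((5, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError, match="monomorphic"):
            grm(g)


def _block_from_pairs(hap_pair, n_haps):
    counts = np.bincount(np.asarray(hap_pair).ravel(), minlength=n_haps)
    order = np.arange(n_haps)  # already by construction
    return HaplotypeBlock(
        block_id="T", chrom="1", marker_indices=np.array([0, 1]),
        start_bp=1, end_bp=2,
        haplotypes=[format(i, "02b") for i in order],
        hap_pair=np.asarray(hap_pair),
        counts=counts, frequencies=counts / counts.sum(),
    )


class TestBuildZ:
    def test_worked_rows(self):
        # heterozygote for haplotypes 1,2 -> [1,1,0,0]; homozygote for
        # haplotype 3 -> [0,0,2,0]
        pairs = [[0, 1], [2, 2]] + [[i % 4, (i + 1) % 4] for i in range(12)]
        design = build_Z(_block_from_pairs(pairs, 4), min_hap_count=1)
        np.testing.assert_array_equal(design.Z[0], [1, 1, 0, 0])
        np.testing.assert_array_equal(design.Z[1], [0, 0, 2, 0])

    def test_row_invariants_on_simulation(self, small_geno):
        idx = simdata.block_marker_indices(small_geno)
        for bid in list(idx)[:6]:
            blk = enumerate_haplotypes(small_geno, idx[bid])
            try:
                Z = build_Z(blk, min_hap_count=5).Z
            except TooFewHaplotypes:
                continue
            assert np.all(Z.sum(axis=1) == 2.0)
            assert np.all((Z > 0).sum(axis=1) <= 2)

    def test_rare_pooling_keeps_row_sums(self):
        # haplotype 2 appears on a single chromosome: pooled, not dropped
        pairs = [[0, 1]] * 10 + [[0, 2]] + [[1, 1]] * 5
        design = build_Z(_block_from_pairs(pairs, 3), min_hap_count=5)
        assert design.labels[-1] == "rare"
        assert np.all(design.Z.sum(axis=1) == 2.0)

    def test_too_few_haplotypes(self):
        pairs = [[0, 0]] * 10 + [[0, 1]]
        with pytest.raises(TooFewHaplotypes):
            build_Z(_block_from_pairs(pairs, 2), min_hap_count=5)


@pytest.fixture(scope="module")
def instance():
    """One small instance with kinship, shared by likelihood tests."""
    rng = np.random.default_rng(77)
    geno = simulate_genotypes(SimConfig(n_individuals=40, n_blocks=10, seed=8))
    ke = grm(geno)
    X = np.ones((40, 1))
    Z = _random_Z(rng, 40, 4)
    y = rng.standard_normal(40) + Z @ rng.standard_normal(4) * 0.5
    return geno, ke, y, X, Z


class TestLikelihood:
    def test_identity_covariance_limit(self, instance):
        # theta = (0,0): H = I, so L reduces to the OLS REML value
        _, ke, y, X, Z = instance
        td = transform(ke, y, X, Z)
        L = profiled_reml_loglik(td, ke.D, (0.0, 0.0))
        n, r = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        expected = -0.5 * np.linalg.slogdet(X.T @ X)[1] - 0.5 * (n - r) * np.log(rss)
        assert L == pytest.approx(expected, abs=1e-8)

    def test_matches_dense_oracle(self, instance):
        _, ke, y, X, Z = instance
        td = transform(ke, y, X, Z)
        for theta in [(0.3, 0.7), (1.5, 0.05), (0.0, 2.0)]:
            L = profiled_reml_loglik(td, ke.D, theta)
            assert L == pytest.approx(dense_loglik(y, X, Z, ke.K, theta), abs=1e-8)

    def test_location_invariance(self, instance):
        # shifting y by a constant is absorbed by the intercept
        _, ke, y, X, Z = instance
        td1 = transform(ke, y, X, Z)
        td2 = transform(ke, y + 57.3, X, Z)
        for theta in [(0.2, 0.4), (1.0, 1.0)]:
            assert profiled_reml_loglik(td1, ke.D, theta) == pytest.approx(
                profiled_reml_loglik(td2, ke.D, theta), abs=1e-10
            )

    def test_negative_theta_rejected(self, instance):
        _, ke, y, X, Z = instance
        td = transform(ke, y, X, Z)
        with pytest.raises(ValueError):
            profiled_reml_loglik(td, ke.D, (-0.1, 0.5))


class TestFit:
    def test_optimality_and_sigma2(self, instance):
        _, ke, y, X, Z = instance
        td = transform(ke, y, X, Z)
        fit = fit_transformed(td, ke.D)
        assert fit.converged
        assert fit.loglik >= profiled_reml_loglik(td, ke.D, (0.0, 0.0)) - 1e-9
        assert fit.params.sigma2 > 0
        assert fit.W >= 0 and 0 < fit.p <= 1

    def test_null_block_estimates_near_boundary(self):
        # with no block effect the REML estimate of lambda_k collapses
        # toward zero for most blocks
        cfg = SimConfig(
            n_individuals=250, n_blocks=25, seed=21,
            n_causal_blocks=0, h2_block=0.0, h2_polygenic=0.3,
        )
        geno = simulate_genotypes(cfg)
        ke = grm(geno)
        phen, _ = simdata.simulate_phenotypes(geno, cfg, kinship=ke)
        idx = simdata.block_marker_indices(geno)
        blocks = [enumerate_haplotypes(geno, idx[b]) for b in sorted(idx)]
        for k, b in enumerate(blocks):
            b.block_id = f"B{k}"
        res = scan(geno, phen, blocks, ke)
        lamk = res.table["lambda_k"].dropna().to_numpy()
        assert np.mean(lamk < 0.05) > 0.5

    def test_single_snp_equals_one_column_block(self, instance):
        geno, ke, y, X, Z = instance
        phen = pd.Series(y, index=geno.individual_ids)
        res = single_snp_scan(geno, phen, ke)
        j = 2
        td = transform(ke, y, X, geno.dosage()[:, [j]].astype(float))
        fit = fit_transformed(td, ke.D)
        row = res.table.iloc[j]
        assert row["p"] == pytest.approx(fit.p, rel=1e-6)
        assert row["lambda_k"] == pytest.approx(fit.params.lambda_k, rel=1e-4, abs=1e-10)


class TestWald:
    def test_zero_effects(self):
        W, p = wald_test(np.zeros(3), np.zeros((3, 3)))
        assert W == 0.0 and p == 1.0

    def test_chi2_quantile(self):
        W, p = wald_test(np.array([np.sqrt(3.841459)]), np.eye(1))
        assert W == pytest.approx(3.841459)
        assert p == pytest.approx(0.05, abs=1e-4)


@pytest.fixture(scope="module")
def study():
    """20-block scan with one strong causal block."""
    cfg = SimConfig(
        n_individuals=300, n_blocks=20, seed=4, block_ld=0.95,
        n_causal_blocks=1, h2_block=0.4, h2_polygenic=0.1,
    )
    geno = simulate_genotypes(cfg)
    ke = grm(geno)
    phen, truth = simdata.simulate_phenotypes(geno, cfg, kinship=ke)
    idx = simdata.block_marker_indices(geno)
    blocks = []
    for bid in sorted(idx):
        b = enumerate_haplotypes(geno, idx[bid])
        b.block_id = bid
        blocks.append(b)
    return geno, ke, phen, truth, blocks


class TestScan:

    def test_zero_blocks_ok(self, study):
        geno, ke, phen, _, _ = study
        res = scan(geno, phen, [], ke)
        assert len(res.table) == 0

    def test_causal_block_attains_min_p(self, study):
        geno, ke, phen, truth, blocks = study
        res = scan(geno, phen, blocks, ke)
        best = res.table.loc[res.table["p"].idxmin(), "block_id"]
        assert best in truth.causal_block_ids

    def test_determinism(self, study):
        geno, ke, phen, _, blocks = study
        t1 = scan(geno, phen, blocks[:5], ke).table
        t2 = scan(geno, phen, blocks[:5], ke).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_id_mismatch_raises(self, study):
        geno, ke, phen, _, blocks = study
        bad = phen.rename(index={phen.index[0]: "stranger"})
        with pytest.raises(ValueError, match="stranger"):
            scan(geno, bad, blocks, ke)


def test_eb_estimates_match_mme(instance):
    # Henderson mixed-model equations as the independent oracle
    _, ke, y, X, Z = instance
    theta = (0.8, 0.4)
    lam_k, lam = theta
    n, r = X.shape
    h = Z.shape[1]
    Sigma = lam * ke.K + np.eye(n)
    Si = np.linalg.inv(Sigma)
    C = np.block(
        [
            [X.T @ Si @ X, X.T @ Si @ Z],
            [Z.T @ Si @ X, Z.T @ Si @ Z + np.eye(h) / lam_k],
        ]
    )
    sol = np.linalg.solve(C, np.concatenate([X.T @ Si @ y, Z.T @ Si @ y]))
    V = lam_k * (Z @ Z.T) + Sigma
    Vi = np.linalg.inv(V)
    P = Vi - Vi @ X @ np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi
    s2 = (y @ P @ y) / (n - r)
    pev = s2 * np.linalg.inv(C)[r:, r:]

    td = transform(ke, y, X, Z)
    beta, gamma, cov, sigma2 = eb_estimates(td, ke.D, theta)
    assert np.abs(beta - sol[:r]).max() < 1e-8
    assert np.abs(gamma - sol[r:]).max() < 1e-8
    assert np.abs(cov - pev).max() < 1e-8
    assert sigma2 == pytest.approx(s2, abs=1e-10)
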