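"""Mixed-model machinery: MME vs direct-GLS oracle, REML recovery,
scan calibration, stepwise selection, heritability and Cp."""

import numpy as np
import pandas as pd
import pytest

from divergescan import (
    CohortSpec,
    ModelMatrices,
    VarianceComponents,
    assemble_mme,
    build_model_matrices,
    estimate_varcomp,
    fit_mme,
    heritability,
    qtl_contribution,
    scan_snps,
    simulate_cohort,
    solve_mme,
    stepwise_select,
    vanraden_grm,
)
from divergescan.qtl import reml_loglik

from _oracles import gls_fit


def random_model(rng, n, with_cage=True, with_qtl=False, k=None):
    """A small random mixed-model instance with a well-conditioned K."""
    x = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    s = None
    if with_cage:
        n_cages = max(2, n // 4)
        codes = rng.integers(0, n_cages, n)
        s = np.zeros((n, n_cages))
        s[np.arange(n), codes] = 1.0
    w = rng.binomial(2, 0.5, (n, 1)).astype(float) if with_qtl else np.empty((n, 0))
    if k is None:
        a = rng.standard_normal((n, 2 * n))
        k = a @ a.T / (2 * n)
        k = k / np.diag(k).mean()
    z = np.eye(n)
    y = rng.standard_normal(n) * 2.0
    return ModelMatrices(y=y, X=x, S=s, Z=z, W=w, K=k,
                         sample_ids=[f"s{i}" for i in range(n)])


class TestMmeVsGls:
    @pytest.mark.parametrize("with_cage,with_qtl", [
        (False, False), (True, False), (False, True), (True, True),
    ])
    def test_solution_matches_direct_v_inversion(self, with_cage, with_qtl):
        """MME solution == GLS with V = sigma_c^2 SS' + sigma_g^2 ZKZ' + sigma_e^2 I."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(8, 50))
            m = random_model(rng, n, with_cage=with_cage, with_qtl=with_qtl)
            v = VarianceComponents(cage=0.5 if with_cage else 0.0,
                                   polygenic=0.8, residual=1.2)
            fit = fit_mme(m, v)
            vmat = v.residual * np.eye(n) + v.polygenic * m.Z @ m.K @ m.Z.T
            if with_cage:
                vmat = vmat + v.cage * m.S @ m.S.T
            beta, c_hat, g_hat = gls_fit(
                m.y, m.fixed, vmat, s=m.S, z=m.Z, k=m.K,
                sigma_c2=v.cage, sigma_g2=v.polygenic,
            )
            got = np.concatenate([fit.b_hat, fit.q_hat])
            np.testing.assert_allclose(got, beta, atol=1e-8)
            np.testing.assert_allclose(fit.g_hat, g_hat, atol=1e-8)
            if with_cage:
                np.testing.assert_allclose(fit.c_hat, c_hat, atol=1e-8)

    def test_k_identity_toy(self):
        """n=6 toy with K=I against the GLS oracle."""
        rng = np.random.default_rng(0)
        m = random_model(rng, 6, with_cage=True, k=np.eye(6))
        v = VarianceComponents(cage=0.3, polygenic=1.0, residual=0.7)
        fit = fit_mme(m, v)
        vmat = (v.residual * np.eye(6) + v.cage * m.S @ m.S.T
                + v.polygenic * np.eye(6))
        beta, c_hat, g_hat = gls_fit(m.y, m.X, vmat, s=m.S, z=m.Z, k=m.K,
                                     sigma_c2=v.cage, sigma_g2=v.polygenic)
        np.testing.assert_allclose(fit.b_hat, beta, atol=1e-8)
        np.testing.assert_allclose(fit.g_hat, g_hat, atol=1e-8)

    def test_no_random_terms_reduces_to_ols(self):
        """Vanishing polygenic variance (dropped term) gives plain OLS."""
        rng = np.random.default_rng(1)
        m = random_model(rng, 20, with_cage=False)
        v = VarianceComponents(cage=0.0, polygenic=0.0, residual=1.0)
        fit = fit_mme(m, v)
        ols = np.linalg.lstsq(m.X, m.y, rcond=None)[0]
        np.testing.assert_allclose(fit.b_hat, ols, atol=1e-10)
        np.testing.assert_allclose(fit.g_hat, 0.0)

    def test_large_lambda_shrinks_g_to_zero(self):
        rng = np.random.default_rng(2)
        m = random_model(rng, 15, with_cage=False)
        v = VarianceComponents(polygenic=1e-10, residual=1.0)
        fit = fit_mme(m, v)
        assert np.max(np.abs(fit.g_hat)) < 1e-6
        ols = np.linalg.lstsq(m.X, m.y, rcond=None)[0]
        np.testing.assert_allclose(fit.b_hat, ols, atol=1e-5)

    def test_gebv_identity_exact(self):
        rng = np.random.default_rng(3)
        m = random_model(rng, 25, with_cage=True, with_qtl=True)
        v = VarianceComponents(cage=0.4, polygenic=1.0, residual=1.0)
        fit = fit_mme(m, v)
        np.testing.assert_array_equal(fit.gebv, m.Z @ fit.g_hat + m.W @ fit.q_hat)

    def test_block_ordering_and_rhs(self):
        rng = np.random.default_rng(4)
        m = random_model(rng, 12, with_cage=True, with_qtl=True)
        v = VarianceComponents(cage=0.5, polygenic=1.0, residual=1.0)
        sys_ = assemble_mme(m, v)
        assert list(sys_.slices) == ["b", "q", "c", "g"]
        np.testing.assert_allclose(sys_.rhs[sys_.slices["b"]], m.X.T @ m.y)
        np.testing.assert_allclose(sys_.rhs[sys_.slices["q"]], m.W.T @ m.y)
        np.testing.assert_allclose(sys_.rhs[sys_.slices["c"]], m.S.T @ m.y)
        np.testing.assert_allclose(sys_.rhs[sys_.slices["g"]], m.Z.T @ m.y)
        # symmetric coefficient matrix
        np.testing.assert_allclose(sys_.coeff, sys_.coeff.T, atol=1e-10)

    def test_singular_k_advises_ridge(self):
        rng = np.random.default_rng(5)
        m = random_model(rng, 10, with_cage=False, k=np.ones((10, 10)))
        v = VarianceComponents(polygenic=1.0, residual=1.0)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            assemble_mme(m, v)
        import warnings as _warnings
        from scipy.linalg import LinAlgWarning

        with _warnings.catch_warnings():
            # the rank-1 K stays extreme even after the ridge; conditioning
            # complaints are expected here
            _warnings.simplefilter("ignore", LinAlgWarning)
            fit = fit_mme(m, v, ridge=1e-6)  # regularized solve succeeds
        assert np.all(np.isfinite(fit.g_hat))

    def test_nonfinite_rejected(self):
        rng = np.random.default_rng(6)
        m = random_model(rng, 8, with_cage=False)
        v = VarianceComponents(polygenic=1.0, residual=1.0)
        sys_ = assemble_mme(m, v)
        sys_.rhs[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            solve_mme(sys_)


class TestHeritability:
    @pytest.mark.parametrize("vq,vg,vc,ve,expected", [
        (15.58, 0.0, 0.0, 11.68, 0.57),   # body depth at 8 months
        (26.19, 0.0, 0.0, 44.28, 0.37),   # body width at 8 months
    ])
    def test_reported_variance_component_rows(self, vq, vg, vc, ve, expected):
        v = VarianceComponents(qtl=vq, polygenic=vg, cage=vc, residual=ve)
        assert round(heritability(v), 2) == expected

    def test_degenerate_limits(self):
        assert heritability(VarianceComponents(residual=1.0)) == 0.0
        assert heritability(VarianceComponents(polygenic=2.0, residual=0.0,
                                               cage=0.0)) == 1.0
        with pytest.raises(ValueError):
            heritability(VarianceComponents(cage=0, polygenic=0, residual=0))

    def test_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            v = VarianceComponents(*rng.uniform(0, 5, 4))
            if v.total > 0:
                assert 0.0 <= heritability(v) <= 1.0


class TestRemlEstimation:
    def test_pure_noise_residual_recovery(self):
        """Pure-noise data at n=250: the identified error variance is
        recovered within 15%.

        With K = I the polygenic and residual structures coincide
        (ZKZ' = I), so only their sum is identified; with no random
        structure at all, sigma_e^2 itself is.
        """
        rng = np.random.default_rng(8)
        n = 250
        totals, resids = [], []
        for _ in range(5):
            y = rng.standard_normal(n) * 2.0  # true sigma_e^2 = 4
            m = ModelMatrices(
                y=y, X=np.ones((n, 1)), S=None, Z=np.eye(n),
                W=np.empty((n, 0)), K=np.eye(n),
                sample_ids=[f"s{i}" for i in range(n)],
            )
            v = estimate_varcomp(m)
            totals.append(v.polygenic + v.residual)
            m2 = ModelMatrices(
                y=y, X=np.ones((n, 1)), S=None, Z=np.eye(n),
                W=np.empty((n, 0)), K=None,
                sample_ids=[f"s{i}" for i in range(n)],
            )
            resids.append(estimate_varcomp(m2).residual)
        assert abs(np.mean(totals) - 4.0) / 4.0 < 0.15
        assert abs(np.mean(resids) - 4.0) / 4.0 < 0.15

    def test_zero_polygenic_boundary(self):
        """sigma_g^2 = 0 cohorts put the estimate at/near the boundary."""
        hits = 0
        reps = 10
        for seed in range(reps):
            spec = CohortSpec(
                n_markers=800, seed=4000 + seed,
                varcomp_true=VarianceComponents(cage=0.0, polygenic=0.0,
                                                residual=1.0),
            )
            g, samples = simulate_cohort(spec)
            m = build_model_matrices(g, samples, "iBlen", vanraden_grm(g))
            v = estimate_varcomp(m)
            hits += v.polygenic <= 0.05 * v.residual
        assert hits >= 0.8 * reps

    def test_loglik_at_truth_not_above_optimum(self):
        """The REML optimum's restricted likelihood >= the truth's."""
        spec = CohortSpec(n_markers=800, seed=90)
        g, samples = simulate_cohort(spec)
        m = build_model_matrices(g, samples, "Bwt8m", vanraden_grm(g))
        v_hat = estimate_varcomp(m)
        ll_hat = reml_loglik(m, v_hat)
        ll_true = reml_loglik(m, spec.varcomp_true)
        assert ll_hat >= ll_true - 1e-6

    def test_too_few_samples_raises(self):
        m = ModelMatrices(y=np.zeros(2), X=np.ones((2, 1)), S=None,
                          Z=np.eye(2), W=np.empty((2, 0)), K=np.eye(2))
        with pytest.raises(ValueError, match="phenotyped samples"):
            estimate_varcomp(m)


@pytest.fixture(scope="module")
def planted():
    spec = CohortSpec(n_markers=1500, seed=95,
                      qtl_list=(("Bdp8m", 700, 1.2),))
    g, samples = simulate_cohort(spec)
    grm = vanraden_grm(g)
    m = build_model_matrices(g, samples, "Bdp8m", grm)
    v = estimate_varcomp(m)
    return spec, g, samples, grm, m, v


class TestScan:

    def test_planted_marker_is_top_hit(self, planted):
        spec, g, samples, grm, m, v = planted
        scan = scan_snps(m, g, v)
        j = int(np.nanargmin(scan["pvalue"].to_numpy()))
        assert scan.index[j] == g.markers.index[700]

    def test_monomorphic_marker_skipped(self, planted):
        spec, g, samples, grm, m, v = planted
        g2 = g.take_markers(np.arange(g.n_markers))
        g2.dosages[:, 3] = 2.0
        scan = scan_snps(m, g2, v)
        assert bool(scan["skipped"].iloc[3])
        assert np.isnan(scan["pvalue"].iloc[3])

    def test_pvalues_invariant_to_sample_relabeling(self, planted):
        spec, g, samples, grm, m, v = planted
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_samples)
        g2 = g.take_samples(perm)
        grm2 = vanraden_grm(g2)
        m2 = build_model_matrices(g2, samples, "Bdp8m", grm2)
        s1 = scan_snps(m, g, v)
        s2 = scan_snps(m2, g2, v)
        np.testing.assert_allclose(s1["pvalue"], s2["pvalue"], rtol=1e-6)

    def test_marker_identical_to_w_column_skipped(self, planted):
        spec, g, samples, grm, m, v = planted
        w = g.dosages[m.Z.argmax(axis=1), 700][:, None]
        m2 = m.with_qtl(w, [g.markers.index[700]])
        scan = scan_snps(m2, g, v)
        assert bool(scan["skipped"].iloc[700])


class TestStepwise:
    def test_alpha_zero_always_empty(self):
        spec = CohortSpec(n_markers=500, seed=96,
                          qtl_list=(("Bwt8m", 250, 2.0),))
        g, samples = simulate_cohort(spec)
        hits, fit = stepwise_select(g, samples, "Bwt8m", vanraden_grm(g), alpha=0.0)
        assert hits == []

    def test_two_unlinked_qtl_recovered(self):
        """Two strong planted QTL on different chromosomes are both found."""
        found = 0
        reps = 5
        for seed in range(reps):
            spec = CohortSpec(
                n_markers=1500, seed=5000 + seed,
                qtl_list=(("Blen8m", 200, 1.3), ("Blen8m", 1200, 1.3)),
            )
            g, samples = simulate_cohort(spec)
            hits, _ = stepwise_select(g, samples, "Blen8m", vanraden_grm(g))
            hit_ids = {h.marker_id for h in hits}
            planted = {g.markers.index[200], g.markers.index[1200]}
            near = 0
            for p_idx in (200, 1200):
                pc = g.markers["chrom"].iloc[p_idx]
                pp = g.markers["pos"].iloc[p_idx]
                near += any(
                    h.chrom == pc and abs(h.pos - pp) <= 100_000 for h in hits
                )
            found += near == 2
        assert found >= 0.6 * reps

    def test_min_distance_exclusion(self):
        """Accepted QTL suppress re-testing of markers within 1 Mb."""
        spec = CohortSpec(n_markers=1000, seed=97,
                          qtl_list=(("Bwd8m", 500, 2.0),))
        g, samples = simulate_cohort(spec)
        hits, _ = stepwise_select(g, samples, "Bwd8m", vanraden_grm(g),
                                  min_distance_bp=2_000_000)
        # whole chromosome excluded after the first hit: at most one per chrom
        per_chrom = pd.Series([h.chrom for h in hits]).value_counts()
        assert (per_chrom <= 1).all()

    def test_hit_fields_consistent(self):
        spec = CohortSpec(n_markers=800, seed=98,
                          qtl_list=(("Bdp8m", 400, 1.5),))
        g, samples = simulate_cohort(spec)
        hits, fit = stepwise_select(g, samples, "Bdp8m", vanraden_grm(g))
        assert len(hits) >= 1
        for h in hits:
            assert h.trait == "Bdp8m"
            assert 0.0 <= h.cp <= 1.0
            assert np.isfinite(h.effect)
        assert 0.0 <= fit.h2 <= 1.0
        assert fit.qtl_markers == [h.marker_id for h in
                                   sorted(hits, key=lambda h: h.marker_id)] or \
            set(fit.qtl_markers) == {h.marker_id for h in hits}


class TestQtlContribution:
    def test_zero_effect_zero_cp(self):
        v = VarianceComponents(polygenic=1.0, residual=1.0)
        w = np.random.default_rng(0).binomial(2, 0.5, 100).astype(float)
        assert qtl_contribution(w, 0.0, v) == 0.0

    def test_recovers_planted_contribution(self):
        """Estimated Cp tracks the planted share of phenotypic variance."""
        cps = []
        for seed in range(10):
            spec = CohortSpec(n_markers=800, seed=7000 + seed)
            fr_spec = spec
            from divergescan import simulate_founder_frequencies

            fr = simulate_founder_frequencies(fr_spec)
            p0 = fr.p_selection[400]
            # calibrate the allele-substitution effect to Cp = 0.2
            vq = 0.2 / 0.8 * spec.varcomp_true.total
            effect = np.sqrt(vq / (2 * p0 * (1 - p0)))
            spec = CohortSpec(n_markers=800, seed=7000 + seed,
                              qtl_list=(("Bwd8m", 400, float(effect)),))
            g, samples = simulate_cohort(spec)
            grm = vanraden_grm(g)
            m = build_model_matrices(g, samples, "Bwd8m", grm)
            w = g.dosages[m.Z.argmax(axis=1), 400]
            m = m.with_qtl(w[:, None], [g.markers.index[400]])
            v = estimate_varcomp(m)
            fit = fit_mme(m, v, ridge=1e-6)
            cps.append(qtl_contribution(w, float(fit.q_hat[0]), fit.varcomp))
        assert abs(np.mean(cps) - 0.2) < 0.07

    def test_zero_total_variance_raises(self):
        with pytest.raises(ValueError):
            qtl_contribution(np.ones(10), 1.0,
                             VarianceComponents(cage=0, polygenic=0, residual=0))
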