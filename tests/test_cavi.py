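"""Variational inference engine: update rules, ELBO, modes, stability."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from prskit import cavi, simulate
from prskit.cavi import (CaviWorkspace, NumericalInstabilityError,
                         PenaltySpec, SumstatsTable, VariationalState,
                         coordinate_update, fit, harmonize,
                         posterior_variance, standardize_sumstats)
from prskit.ld_store import QuantizationSpec, from_dense

from conftest import make_sumstats, random_banded_store


# ----------------------------------------------------------------------
# sumstats handling
# ----------------------------------------------------------------------

class TestStandardizeSumstats:
    def test_z_over_sqrt_n(self):
        raw = pd.DataFrame({"SNP": ["rs1", "rs2"], "A1": ["A", "C"],
                            "A2": ["G", "T"], "Z": [0.0, 5.0],
                            "N": [10000, 10000]})
        ss = standardize_sumstats(raw)
        assert ss.beta[0] == 0.0
        assert ss.beta[1] == pytest.approx(0.05)

    def test_beta_se_route_matches_z_route(self):
        raw = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "A2": ["G"],
                            "BETA": [0.2], "SE": [0.05], "N": [2500]})
        ss = standardize_sumstats(raw)
        assert ss.beta[0] == pytest.approx((0.2 / 0.05) / 50.0)

    def test_missing_n_rejected(self):
        raw = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "A2": ["G"],
                            "Z": [1.0]})
        with pytest.raises(ValueError, match="n"):
            standardize_sumstats(raw)


class TestHarmonize:
    def test_allele_flip_negates_effect(self, toy_store):
        meta = toy_store.metadata  # alleles are A/G
        ss = SumstatsTable(pd.DataFrame({
            "rsid": meta["rsid"], "a1": ["G", "A", "A"],
            "a2": ["A", "G", "G"], "beta": [0.1, 0.2, 0.3],
            "n": [100.0] * 3}))
        beta, n, include, report = harmonize(ss, toy_store)
        np.testing.assert_allclose(beta, [-0.1, 0.2, 0.3])
        assert report["n_flipped"] == 1

    def test_mismatched_alleles_dropped(self, toy_store):
        meta = toy_store.metadata
        ss = SumstatsTable(pd.DataFrame({
            "rsid": meta["rsid"], "a1": ["C", "A", "A"],
            "a2": ["T", "G", "G"], "beta": [0.1, 0.2, 0.3],
            "n": [100.0] * 3}))
        beta, _, include, report = harmonize(ss, toy_store)
        assert not include[0] and beta[0] == 0.0
        assert report["n_mismatched_dropped"] == 1

    def test_empty_intersection_rejected(self, toy_store):
        ss = make_sumstats([0.1], rsids=["rs_nowhere"])
        with pytest.raises(ValueError, match="no variants shared"):
            harmonize(ss, toy_store)


# ----------------------------------------------------------------------
# update rules
# ----------------------------------------------------------------------

class TestPosteriorVariance:
    def test_direct_evaluations(self):
        assert posterior_variance(100, 1.0, 1.0, 0.0) == \
            pytest.approx(1.0 / 101.0)
        assert posterior_variance(100, 1.0, 1.0, 1.0) == \
            pytest.approx(1.0 / 201.0)

    def test_decreasing_in_penalty_and_sample_size(self):
        lams = np.linspace(0, 50, 30)
        vals = posterior_variance(100, 0.8, 0.01, lams)
        assert np.all(np.diff(vals) < 0)
        ns = np.linspace(100, 100000, 30)
        vals_n = posterior_variance(ns, 0.8, 0.01, 0.0)
        assert np.all(np.diff(vals_n) < 0)
        # lambda -> infinity drives the variance to zero
        assert posterior_variance(100, 1.0, 1.0, 1e12) < 1e-13


class TestCoordinateUpdate:
    def _single_variant_ws(self, bhat=0.1, n=100.0):
        store = from_dense(np.eye(1), mask=np.eye(1, dtype=bool))
        ss = make_sumstats([bhat], n=n, meta=store.metadata)
        ws = CaviWorkspace(ss, store)
        ws.state = VariationalState.initial(1, pi=0.5, sigma_b2=1.0,
                                            sigma_e2=1.0)
        return ws

    def test_single_variant_conditional_mean(self):
        ws = self._single_variant_ws()
        coordinate_update(0, ws)
        # mu = (N s^2 / sigma_e^2)(bhat - q) = (100/101) * 0.1
        assert ws.state.mu[0] == pytest.approx(100.0 / 101.0 * 0.1)

    def test_centered_effect_gives_low_inclusion(self):
        ws = self._single_variant_ws(bhat=0.0)
        coordinate_update(0, ws)
        assert ws.state.mu[0] == 0.0
        # with s^2 < sigma_b^2 the log-odds shrink below the prior
        assert ws.state.gamma[0] < ws.state.pi

    def test_kernel_epoch_matches_python_reference(self):
        store = random_banded_store(40, 6, seed=10, base_rho=0.6)
        rng = np.random.default_rng(11)
        ss = make_sumstats(rng.normal(0, 0.02, 40), n=5000.0,
                           meta=store.metadata)
        ws_ref = CaviWorkspace(ss, store)
        ws_ker = CaviWorkspace(ss, store)
        for ws in (ws_ref, ws_ker):
            ws.state = VariationalState.initial(40, pi=0.1, sigma_e2=0.9)
        for _ in range(3):
            for j in range(40):
                coordinate_update(j, ws_ref)
            ws_ker.epoch_symmetric(1)
        np.testing.assert_allclose(ws_ker.state.eta, ws_ref.state.eta,
                                   atol=1e-12)
        np.testing.assert_allclose(ws_ker.state.q, ws_ref.state.q,
                                   atol=1e-12)

    def test_variational_matches_exact_single_variant_posterior(self):
        """For M=1 the factorized family is exact: gamma and eta must
        equal the true spike-and-slab posterior (numerical integration)."""
        bhat, n, pi, sb2, se2 = 0.04, 400.0, 0.3, 0.01, 1.0
        ws = self._single_variant_ws(bhat=bhat, n=n)
        ws.state.pi, ws.state.sigma_b2, ws.state.sigma_e2 = pi, sb2, se2
        coordinate_update(0, ws)

        # likelihood: bhat | beta ~ N(beta, se2/n)
        sd = math.sqrt(se2 / n)
        m_slab = quad(lambda b: norm.pdf(bhat, b, sd) * norm.pdf(
            b, 0, math.sqrt(sb2)), -1, 1)[0]
        m_spike = norm.pdf(bhat, 0, sd)
        post_incl = pi * m_slab / (pi * m_slab + (1 - pi) * m_spike)
        post_mean = pi * quad(lambda b: b * norm.pdf(bhat, b, sd) * norm.pdf(
            b, 0, math.sqrt(sb2)), -1, 1)[0] / \
            (pi * m_slab + (1 - pi) * m_spike)
        assert ws.state.gamma[0] == pytest.approx(post_incl, abs=1e-8)
        assert ws.state.eta[0] == pytest.approx(post_mean, abs=1e-8)


class TestExpectedMse:
    def test_null_model(self):
        store = from_dense(np.eye(3), mask=np.eye(3, dtype=bool))
        ss = make_sumstats([0.0, 0.0, 0.0], n=100.0, meta=store.metadata)
        ws = CaviWorkspace(ss, store)
        ws.state.eta[:] = 0
        ws.state.gamma[:] = 0
        assert ws.expected_mse() == pytest.approx(100.0)

    def test_single_variant_plugin(self):
        store = from_dense(np.eye(1), mask=np.eye(1, dtype=bool))
        bhat = 0.3
        ss = make_sumstats([bhat], n=100.0, meta=store.metadata)
        ws = CaviWorkspace(ss, store)
        st = ws.state
        st.gamma[:] = 1.0
        st.mu[:] = bhat
        st.eta[:] = bhat
        st.s2[:] = 0.0
        assert ws.expected_mse() == pytest.approx(100.0 * (1 - bhat ** 2))

    def test_runaway_direction_sign(self):
        # non-PSD toy: along the negative eigenvector the unpenalized
        # quadratic form dives below zero; |lambda_min| restores it
        R = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        store = from_dense(R, mask=R != 0)
        w, V = np.linalg.eigh(R)
        v_min = V[:, 0]
        ss = make_sumstats([0.0, 0.0, 0.0], n=100.0, meta=store.metadata)

        def mse_at(penalty, c):
            ws = CaviWorkspace(ss, store, penalty)
            st = ws.state
            st.gamma[:] = 1.0
            st.mu[:] = c * v_min
            st.eta[:] = c * v_min
            st.s2[:] = 0.0
            return ws.expected_mse()

        assert mse_at(PenaltySpec.none(), 10.0) < 0
        assert mse_at(PenaltySpec.global_penalty(abs(w[0])), 10.0) >= 0


class TestMStep:
    def test_slab_variance_fixed_point(self):
        store = from_dense(np.eye(4), mask=np.eye(4, dtype=bool))
        ss = make_sumstats([0.0] * 4, n=100.0, meta=store.metadata)
        ws = CaviWorkspace(ss, store)
        st = ws.state
        st.gamma[:] = 0.5
        st.mu[:] = 0.0
        st.s2[:] = st.sigma_b2
        before = st.sigma_b2
        ws.m_step(frozen=("pi", "sigma_e2"))
        assert st.sigma_b2 == pytest.approx(before)

    def test_frozen_pi_unchanged(self):
        store = random_banded_store(30, 4, seed=12)
        rng = np.random.default_rng(13)
        ss = make_sumstats(rng.normal(0, 0.02, 30), n=2000.0,
                           meta=store.metadata)
        model = fit(ss, store, fixed_pi=0.07)
        assert model.pi == 0.07

    def test_all_zero_gamma_rejected(self):
        store = from_dense(np.eye(3), mask=np.eye(3, dtype=bool))
        ss = make_sumstats([0.0] * 3, n=100.0, meta=store.metadata)
        ws = CaviWorkspace(ss, store)
        ws.state.gamma[:] = 0.0
        with pytest.raises(ValueError, match="inclusion"):
            ws.m_step()


# ----------------------------------------------------------------------
# epochs, modes, and full fits
# ----------------------------------------------------------------------

def _synthetic_instance(M=200, N=8000, seed=0, spec="int8"):
    cfg = simulate.SimulationConfig(n_samples=N, n_variants=M,
                                    block_size=max(M // 8, 10), rho=0.6,
                                    pi=0.05, h2=0.4, seed=seed)
    study = simulate.simulate_study(cfg, n_test=50,
                                    qspec=QuantizationSpec(spec))
    return study.sumstats, study.ld


class TestEpochs:
    def test_elbo_nondecreasing_serial(self):
        ss, ld = _synthetic_instance(M=50, N=4000, seed=20, spec="float64")
        ws = CaviWorkspace(ss, ld)
        prev = -np.inf
        for _ in range(25):
            ws.epoch_symmetric(1)
            ws.m_step()
            e = ws.elbo()
            assert e >= prev - 1e-6 * max(1.0, abs(prev))
            prev = e

    def test_triangular_matches_symmetric_serial(self):
        ss, ld = _synthetic_instance(M=500, N=8000, seed=21)
        ws_s = CaviWorkspace(ss, ld)
        ws_t = CaviWorkspace(ss, ld)
        for ep in range(10):
            ws_s.epoch_symmetric(1)
            ws_t.epoch_triangular()
            np.testing.assert_allclose(ws_t.state.eta, ws_s.state.eta,
                                       atol=1e-6)
            ws_s.m_step()
            ws_t.m_step()

    def test_identity_ld_q_stays_zero(self):
        store = from_dense(np.eye(20), mask=np.eye(20, dtype=bool))
        rng = np.random.default_rng(22)
        ss = make_sumstats(rng.normal(0, 0.05, 20), n=1000.0,
                           meta=store.metadata)
        ws = CaviWorkspace(ss, store)
        ws.epoch_triangular()
        np.testing.assert_allclose(ws.state.q, 0.0)

    def test_single_variant_triangular_equals_coordinate_update(self):
        store = from_dense(np.eye(1), mask=np.eye(1, dtype=bool))
        ss = make_sumstats([0.1], n=100.0, meta=store.metadata)
        ws1 = CaviWorkspace(ss, store)
        ws2 = CaviWorkspace(ss, store)
        ws1.epoch_triangular()
        coordinate_update(0, ws2)
        assert ws1.state.eta[0] == ws2.state.eta[0]

    def test_chunked_close_to_serial_on_well_conditioned_instance(self):
        ss, ld = _synthetic_instance(M=2000, N=20000, seed=23)
        serial = fit(ss, ld, mode="symmetric", n_chunks=1, tol=1e-7)
        chunked = fit(ss, ld, mode="symmetric", n_chunks=4, tol=1e-7)
        assert np.max(np.abs(serial.eta - chunked.eta)) < 1e-4

    def test_tiny_instance_triggers_chunk_decrement(self):
        M = 8
        R = np.full((M, M), 0.9)
        np.fill_diagonal(R, 1.0)
        store = from_dense(R)
        ss = make_sumstats(np.full(M, 0.3), n=5000.0, meta=store.metadata)
        model = fit(ss, store, mode="symmetric", n_chunks=M)
        assert model.converged
        assert any("reduced chunk concurrency" in ev["action"]
                   for ev in model.stability_log)


class TestFit:
    def test_identity_ld_matches_independent_closed_form(self):
        M = 40
        store = from_dense(np.eye(M), mask=np.eye(M, dtype=bool))
        rng = np.random.default_rng(30)
        bhat = rng.normal(0, 0.05, M)
        n = 2000.0
        ss = make_sumstats(bhat, n=n, meta=store.metadata)
        pi, sb2, se2 = 0.1, 0.003, 0.9
        model = fit(ss, store, fixed_pi=pi, fixed_sigma_b2=sb2,
                    fixed_sigma_e2=se2)
        s2 = se2 / (n + se2 / sb2)
        mu = n * s2 / se2 * bhat
        logit = (math.log(pi / (1 - pi)) + 0.5 * np.log(s2 / sb2)
                 + mu ** 2 / (2 * s2))
        gamma = 1.0 / (1.0 + np.exp(-logit))
        np.testing.assert_allclose(model.eta, gamma * mu, atol=1e-6)

    def test_penalty_increases_shrinkage(self):
        ss, ld = _synthetic_instance(M=100, N=4000, seed=31)
        norms = []
        for lam in (0.0, 0.5, 2.0, 8.0):
            pen = (PenaltySpec.global_penalty(lam) if lam
                   else PenaltySpec.none())
            model = fit(ss, ld, pen)
            norms.append(float(np.sum(model.eta ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_mode_equivalence_including_dqf(self, tmp_path):
        from prskit.ld_store import read_store, write_store

        ss, ld = _synthetic_instance(M=300, N=8000, seed=32)
        path = tmp_path / "ld.zarr"
        write_store(ld, path)
        eager = read_store(path, dequantize_eagerly=True)
        lazy = read_store(path, dequantize_eagerly=False)
        m_sym = fit(ss, eager, mode="symmetric")
        m_tri = fit(ss, eager, mode="triangular")
        m_dqf = fit(ss, lazy, mode="triangular")
        assert np.max(np.abs(m_sym.eta - m_tri.eta)) < 1e-5
        assert np.max(np.abs(m_tri.eta - m_dqf.eta)) < 1e-5
        assert np.max(np.abs(m_sym.gamma - m_dqf.gamma)) < 1e-5

    def test_nonpsd_band_diverges_then_penalty_rescues(self):
        cfg = simulate.SimulationConfig(n_samples=2000, n_variants=60,
                                        block_size=60, rho=0.97, pi=0.2,
                                        h2=0.6, seed=5)
        panel = simulate.simulate_genotypes(cfg)
        y, _ = simulate.simulate_phenotype(panel, cfg.pi, cfg.h2, seed=6)
        ss = simulate.marginal_gwas(panel, y)
        Z = simulate._standardized(panel.dosages)
        R = np.clip((Z.T @ Z).astype(np.float64) / len(y), -1, 1)
        band = np.abs(np.subtract.outer(np.arange(60), np.arange(60))) <= 5
        store = from_dense(R * band, mask=band)
        from prskit.spectral import extremal_eigenvalues
        lam_min = extremal_eigenvalues(store).lambda_min
        assert lam_min < -0.5
        with pytest.raises(NumericalInstabilityError, match="penalty"):
            fit(ss, store)
        model = fit(ss, store, PenaltySpec.global_penalty(abs(lam_min)))
        assert model.converged
        assert np.isfinite(model.elbo_trace[-1])

    def test_per_block_penalty_maps_to_variants(self):
        ss, ld = _synthetic_instance(M=100, N=4000, seed=33)
        blocks = [tuple(b) for b in ld.attrs["blocks"]]
        pen = PenaltySpec.per_block(blocks, [0.5] * len(blocks))
        ws = CaviWorkspace(ss, ld, pen)
        np.testing.assert_allclose(ws.lam, 0.5)

    def test_var_beta_nonnegative_throughout(self):
        ss, ld = _synthetic_instance(M=100, N=4000, seed=34)
        ws = CaviWorkspace(ss, ld)
        for _ in range(5):
            ws.epoch_triangular()
            ws.m_step()
            assert np.all(ws.state.var_beta() >= -1e-12)
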