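"""Fraction-constrained beta-VAE: ELBO terms, factor extraction,
generation and noise filtering."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import trajblend as tb
from trajblend.datamodel import RunConfig, ValidationError
from trajblend.generator_bvae import (_dense_lognorm, extract_type_factors,
                                      filter_noise_clusters, generate_cells,
                                      kl_gaussian, train_beta_vae)


class TestKLGaussian:
    def test_prior_equals_posterior(self):
        assert kl_gaussian([0.0], [0.0]) == 0.0

    def test_unit_mean_shift_closed_form(self):
        assert abs(kl_gaussian([1.0], [0.0]) - 0.5) < 1e-12

    def test_matches_monte_carlo_estimate(self):
        mu, sigma = 0.3, 1.5
        rng = np.random.default_rng(0)
        z = rng.normal(mu, sigma, size=1_000_000)
        # KL = E_q[log q(z) - log p(z)]
        logq = -0.5 * np.log(2 * np.pi * sigma**2) - (z - mu) ** 2 / (2 * sigma**2)
        logp = -0.5 * np.log(2 * np.pi) - z**2 / 2
        mc = (logq - logp).mean()
        exact = kl_gaussian([mu], [np.log(sigma**2)])
        assert abs(mc - exact) / exact < 0.01

    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mu = rng.normal(size=8)
            logvar = rng.normal(size=8)
            assert kl_gaussian(mu, logvar) >= 0


class TestTraining:
    def test_loss_terms_finite_and_decreasing(self, trained_vae):
        h = trained_vae.history
        assert np.isfinite(h["reconstruction"]).all()
        assert np.isfinite(h["kl"]).all()
        assert (np.array(h["kl"]) >= 0).all()
        assert h["reconstruction"][-1] < h["reconstruction"][0]

    def test_fraction_head_matches_labels(self, trained_vae, bridge_ref_lognorm):
        X = _dense_lognorm(bridge_ref_lognorm)
        mu, _ = trained_vae.encode(X)
        V = trained_vae.fraction_head(mu)
        pred = np.array(trained_vae.cell_types)[V.argmax(axis=1)]
        acc = (pred == bridge_ref_lognorm.cell_type).mean()
        assert acc >= 0.9

    def test_beta_zero_reduces_to_plain_autoencoder(self, bridge_ref_lognorm):
        small = bridge_ref_lognorm.subset_cells(np.arange(0, 2000, 4))
        plain = train_beta_vae(small, RunConfig(
            seed=0, beta=1e-9, generation_noise=0, vae_epochs=60))
        reg = train_beta_vae(small, RunConfig(seed=0, beta=4, vae_epochs=60))
        assert plain.history["reconstruction"][-1] <= reg.history["reconstruction"][-1]

    def test_final_kl_nonincreasing_in_beta(self, bridge_ref_lognorm):
        small = bridge_ref_lognorm.subset_cells(np.arange(0, 2000, 4))
        kls = [train_beta_vae(small, RunConfig(seed=0, beta=b, vae_epochs=60)
                              ).history["kl"][-1] for b in (1, 4, 16)]
        assert kls[1] <= kls[0] * 1.05
        assert kls[2] <= kls[1] * 1.05

    def test_deterministic_given_seed(self, bridge_ref_lognorm):
        small = bridge_ref_lognorm.subset_cells(np.arange(0, 2000, 10))
        cfg = RunConfig(seed=5, vae_epochs=3)
        a = train_beta_vae(small, cfg)
        b = train_beta_vae(small, cfg)
        assert a.history["reconstruction"] == b.history["reconstruction"]


class TestFactors:
    def test_separated_types_have_distinct_factors(self, vae_factors):
        W = vae_factors.W
        for i in range(len(W)):
            for j in range(i + 1, len(W)):
                assert np.linalg.norm(W[i] - W[j]) > 0

    def test_equals_direct_averaging_oracle(self, trained_vae, vae_factors,
                                            bridge_ref_lognorm):
        X = _dense_lognorm(bridge_ref_lognorm)
        mu, _ = trained_vae.encode(X)
        idx = bridge_ref_lognorm.cell_type == "type_0"
        direct = mu[idx].mean(axis=0)
        assert np.allclose(vae_factors.row("type_0"), direct)

    def test_duplicating_cells_leaves_w_unchanged(self, trained_vae,
                                                  bridge_ref_lognorm):
        import scipy.sparse as sp
        from trajblend.datamodel import AnnotatedExpressionMatrix
        src = bridge_ref_lognorm
        n = src.n_cells
        doubled = AnnotatedExpressionMatrix(
            counts=sp.vstack([src.counts, src.counts]).tocsr(),
            gene_ids=list(src.gene_ids),
            cell_ids=[f"{c}_{i}" for i in range(2) for c in src.cell_ids],
            cell_type=np.concatenate([src.cell_type, src.cell_type]),
            layers={"lognorm": sp.vstack(
                [sp.csr_matrix(src.layers["lognorm"])] * 2).tocsr()})
        a = extract_type_factors(trained_vae, src)
        b = extract_type_factors(trained_vae, doubled)
        assert np.allclose(a.W, b.W)


class TestGeneration:
    def test_even_fractions_even_allocation(self, trained_vae, vae_factors):
        frac = tb.CellFractionVector(["type_0", "type_1"], [0.5, 0.5])
        gen = generate_cells(trained_vae, vae_factors, frac, n_cells=100,
                             seed=0)
        assert gen.n_cells == 100
        assert int((gen.cell_type == "type_0").sum()) == 50

    def test_target_scale_overrides_allocation(self, trained_vae, vae_factors,
                                               generated_cells):
        # bridge reference abundance is 150; scale 2 requests 300
        assert int((generated_cells.cell_type == "bridge").sum()) == 300

    def test_generated_counts_nonnegative(self, generated_cells):
        assert (generated_cells.counts.data >= 0).all()

    def test_type_mean_expression_matches_reference(self, bridge_ref_lognorm,
                                                    generated_cells):
        X = _dense_lognorm(bridge_ref_lognorm)
        G = _dense_lognorm(generated_cells)
        for t in bridge_ref_lognorm.cell_types:
            a = X[bridge_ref_lognorm.cell_type == t].mean(axis=0)
            b = G[generated_cells.cell_type == t].mean(axis=0)
            assert pearsonr(a, b).statistic >= 0.8, t

    def test_absent_target_raises(self, trained_vae, vae_factors):
        frac = tb.CellFractionVector(["type_0", "type_1"], [0.5, 0.5])
        with pytest.raises(ValidationError, match="target absent"):
            generate_cells(trained_vae, vae_factors, frac,
                           target_type="ghost", seed=0)


class TestNoiseFilter:
    def _labelled(self, sizes):
        import scipy.sparse as sp
        from trajblend.datamodel import AnnotatedExpressionMatrix
        n = sum(sizes)
        labels = np.concatenate([[str(i)] * s for i, s in enumerate(sizes)])
        m = AnnotatedExpressionMatrix(
            counts=sp.csr_matrix(np.ones((n, 4), dtype=int)),
            gene_ids=[f"g{i}" for i in range(4)],
            cell_ids=[f"c{i}" for i in range(n)],
            cell_type=np.array(["A"] * n, dtype=object))
        return m, labels

    def test_threshold_is_strict_below_25(self):
        m, labels = self._labelled([40, 25, 24])
        out, report = filter_noise_clusters(m, min_cells=25, labels=labels)
        assert report.n_noise_clusters == 1
        assert report.cells_removed == 24
        assert out.n_cells == 65

    def test_exactly_25_kept(self):
        m, labels = self._labelled([25])
        out, report = filter_noise_clusters(m, min_cells=25, labels=labels)
        assert report.n_noise_clusters == 0
        assert out.n_cells == 25

    def test_min_cells_zero_is_identity(self):
        m, labels = self._labelled([3, 2])
        out, report = filter_noise_clusters(m, min_cells=0, labels=labels)
        assert out.n_cells == m.n_cells
        assert report.cells_removed == 0

    def test_conservation(self):
        m, labels = self._labelled([30, 10, 5])
        out, report = filter_noise_clusters(m, min_cells=25, labels=labels)
        assert out.n_cells + report.cells_removed == m.n_cells

    def test_all_noise_raises(self):
        m, labels = self._labelled([3, 4])
        with pytest.raises(ValidationError, match="noise"):
            filter_noise_clusters(m, min_cells=25, labels=labels)

    def test_leiden_path_removes_small_clusters(self, generated_cells):
        out, report = filter_noise_clusters(generated_cells, min_cells=25,
                                            seed=0)
        assert out.n_cells + report.cells_removed == generated_cells.n_cells
        assert all(s >= 25 or name in {k for k, v in
                                       report.cluster_sizes.items() if v < 25}
                   for name, s in report.cluster_sizes.items())
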