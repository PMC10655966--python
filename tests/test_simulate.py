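"""Tests of the scenario simulator: rates, demographies, sweeps, estimators."""

import numpy as np
import pytest

from popdann.demography import DemographyModel, bottleneck, equilibrium, european_demography
from popdann.simulate import (
    BackgroundSelectionConfig,
    SweepParams,
    apply_bgs_surrogate,
    equilibrium_ne,
    harmonic_number,
    simulate_region,
    simulate_relernn_example,
    watterson_theta,
)


class TestWattersonAndNe:
    def test_closed_form_example(self):
        # S=6, n=4 haploids, L=1: a_3 = 1 + 1/2 + 1/3 = 11/6
        assert watterson_theta(6, 4, 1.0) == pytest.approx(36 / 11)

    def test_zero_segregating_sites(self):
        assert watterson_theta(0, 10, 1000.0) == 0.0

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            watterson_theta(5, 1, 100.0)
        with pytest.raises(ValueError):
            equilibrium_ne(1e-4, 0.0)

    def test_equilibrium_ne_algebra(self):
        assert equilibrium_ne(5e-4, 1.25e-8) == pytest.approx(10_000.0)
        assert equilibrium_ne(0.0, 1e-8) == 0.0

    def test_estimator_consistency_at_equilibrium(self):
        # mean theta_W/(4 mu) across regions recovers the simulated Ne
        thetas = []
        for i in range(120):
            ts = simulate_region(
                equilibrium(10_000), 50_000, 1.25e-8, 1.25e-8, 32, seed=1000 + i
            )
            thetas.append(watterson_theta(ts.num_sites, 32, 50_000))
        ne = equilibrium_ne(float(np.mean(thetas)), 1.25e-8)
        assert ne == pytest.approx(10_000, rel=0.10)


class TestSimulateRegion:
    def test_neutral_diversity_matches_4_ne_mu(self):
        pis = [
            simulate_region(
                equilibrium(10_000), 50_000, 1.25e-8, 1.25e-8, 32, seed=i
            ).diversity()
            for i in range(150)
        ]
        # E[pi] = 4 Ne mu = 5e-4 per bp
        assert np.mean(pis) == pytest.approx(5e-4, rel=0.10)

    def test_zero_recombination_gives_single_tree(self):
        ts = simulate_region(equilibrium(5_000), 10_000, 1e-8, 0.0, 16, seed=5)
        assert ts.num_trees == 1

    def test_reproducible_from_seed(self):
        a = simulate_region(equilibrium(5_000), 20_000, 1e-8, 1e-8, 16, seed=11)
        b = simulate_region(equilibrium(5_000), 20_000, 1e-8, 1e-8, 16, seed=11)
        assert a.tables.equals(b.tables, ignore_provenance=True)

    def test_sweep_reduces_central_diversity(self):
        """Hitchhiking: diversity dips near the sweep site relative to flanks."""
        central, flank = [], []
        L = 100_000
        for i in range(200):
            sw = SweepParams(s=0.01, sweep_position=float(L // 2))
            ts = simulate_region(
                equilibrium(10_000), L, 1.25e-8, 1.25e-8, 32, sweep=sw, seed=3000 + i
            )
            w = ts.diversity(windows=[0, 10_000, L - 10_000, L])
            central.append(ts.diversity(windows=[0, 45_000, 55_000, L])[1])
            flank.append((w[0] + w[2]) / 2)
        # one-sided: central diversity below flanking diversity
        from popdann.metrics import welch_t

        t, df, p = welch_t(np.array(central), np.array(flank))
        assert t < 0 and p / 2 < 1e-6

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_region(equilibrium(1000), -1.0, 1e-8, 1e-8, 8, seed=0)
        with pytest.raises(ValueError):
            simulate_region(equilibrium(1000), 1000.0, 1e-8, 1e-8, 7, seed=0)

    def test_sweep_params_validation(self):
        with pytest.raises(ValueError):
            SweepParams(s=-0.01, sweep_position=10.0)
        with pytest.raises(ValueError):
            SweepParams(s=0.01, sweep_position=10.0, sampling="frequency")


class TestRelernnExamples:
    def test_label_is_drawn_rho_and_matrix_shapes_agree(self):
        ex = simulate_relernn_example(equilibrium(10_000), seed=42, L=50_000)
        assert 0 <= ex.rho <= 6.25e-8
        assert 1.875e-8 <= ex.mu <= 3.125e-8
        assert ex.genotypes.shape == (ex.num_sites, 32)
        assert len(ex.positions) == ex.num_sites

    def test_zero_recombination_label(self):
        ex = simulate_relernn_example(
            equilibrium(10_000), seed=1, L=20_000, rho_range=(0.0, 0.0)
        )
        assert ex.rho == 0.0
        assert ex.num_sites > 0

    def test_mean_drawn_rho_matches_uniform_expectation(self):
        rhos = [
            simulate_relernn_example(equilibrium(1_000), seed=i, L=1_000).rho
            for i in range(1000)
        ]
        assert np.mean(rhos) == pytest.approx(3.125e-8, rel=0.05)

    def test_site_count_increases_with_mutation_rate(self):
        """Watterson: E[S] is proportional to the drawn mu."""
        from scipy.stats import spearmanr

        mus, sites = [], []
        for i in range(300):
            ex = simulate_relernn_example(equilibrium(10_000), seed=5000 + i, L=20_000)
            mus.append(ex.mu)
            sites.append(ex.num_sites)
        r, p = spearmanr(mus, sites)
        assert r > 0 and p < 1e-3


class TestBgsSurrogate:
    def test_b_equal_one_is_identity(self):
        cfg = BackgroundSelectionConfig(genic_span=(45_000, 55_000))
        demog, b = apply_bgs_surrogate(cfg, equilibrium(10_000), b_factor=1.0)
        assert b == 1.0 and demog.epochs == equilibrium(10_000).epochs

    def test_diversity_scales_with_b(self):
        cfg = BackgroundSelectionConfig(genic_span=(45_000, 55_000))
        demog, b = apply_bgs_surrogate(cfg, equilibrium(10_000), b_factor=0.8)
        pis = [
            simulate_region(demog, 50_000, 1.25e-8, 1.25e-8, 32, seed=i).diversity()
            for i in range(150)
        ]
        assert np.mean(pis) == pytest.approx(0.8 * 5e-4, rel=0.10)

    def test_domain_signal_is_learnable(self):
        """A linear classifier separates BGS-surrogate and plain regions."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        cfg = BackgroundSelectionConfig(genic_span=(20_000, 30_000))
        rng = np.random.default_rng(0)
        feats, labels = [], []
        for i in range(120):
            demog, _ = apply_bgs_surrogate(cfg, equilibrium(10_000), rng=rng)
            for d, lab in ((equilibrium(10_000), 0), (demog, 1)):
                ts = simulate_region(d, 50_000, 1.25e-8, 1.25e-8, 32, seed=7000 + 2 * i + lab)
                pi = ts.diversity()
                thw = watterson_theta(ts.num_sites, 32, 50_000)
                feats.append([pi, (pi - thw) / max(thw, 1e-12)])
                labels.append(lab)
        X, y = np.array(feats), np.array(labels)
        train = (np.arange(len(y)) // 2) % 2 == 0  # alternate region pairs
        clf = make_pipeline(StandardScaler(), LogisticRegression())
        acc = clf.fit(X[train], y[train]).score(X[~train], y[~train])
        assert acc > 0.6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BackgroundSelectionConfig(genic_span=(0, 1), dfe_mean=0.01)
        cfg = BackgroundSelectionConfig(genic_span=(0, 1), mode="external")
        with pytest.raises(ValueError):
            apply_bgs_surrogate(cfg, equilibrium(1000), b_factor=0.9)


class TestDemographyModels:
    def test_epoch_validation(self):
        with pytest.raises(ValueError):
            DemographyModel(epochs=((1.0, 100.0),))
        with pytest.raises(ValueError):
            DemographyModel(epochs=((0.0, 100.0), (0.0, 50.0)))
        with pytest.raises(ValueError):
            DemographyModel(epochs=((0.0, -5.0),))

    def test_bottleneck_reduces_diversity(self):
        pis_eq, pis_bn = [], []
        for i in range(100):
            pis_eq.append(
                simulate_region(equilibrium(10_000), 30_000, 1.25e-8, 1.25e-8, 32, seed=i).diversity()
            )
            pis_bn.append(
                simulate_region(bottleneck(500.0), 30_000, 1.25e-8, 1.25e-8, 32, seed=i).diversity()
            )
        assert np.mean(pis_bn) < np.mean(pis_eq)

    def test_european_model_builds_and_simulates(self):
        ts = simulate_region(european_demography(), 10_000, 2.5e-8, 1e-8, 32, seed=1)
        assert ts.num_samples == 32

    def test_harmonic_number(self):
        assert harmonic_number(3) == pytest.approx(11 / 6)
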