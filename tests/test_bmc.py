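"""Benchmark-concentration engine: fits, BMC inversion, averaging, filters."""

import math

import numpy as np
import pytest

from txqivive import bmc, simulate


def _hill_y(x, a, b, k, n):
    return a + b * x**n / (k**n + x**n)


class TestFitModel:
    def test_zero_noise_hill_recovery(self, zero_noise_synthetic):
        """Noise-free Hill data: parameters recovered to 1e-4 relative."""
        ds, truth = zero_noise_synthetic
        x = ds.sample_concentrations
        for row in truth.genes[truth.genes["responsive"]].itertuples():
            y = ds.values.loc[row.gene_id].to_numpy()
            fit = bmc.fit_model(x, y, "hill")
            a, b, k, n = fit.params
            assert a == pytest.approx(row.baseline, rel=1e-4)
            assert abs(b) == pytest.approx(row.effect, rel=1e-4)
            assert k == pytest.approx(row.hill_k, rel=1e-4)
            assert n == pytest.approx(row.hill_n, rel=1e-4)
            assert (1 if b >= 0 else -1) == row.direction

    def test_true_family_attains_minimum_aic_on_zero_noise(
        self, zero_noise_synthetic
    ):
        ds, truth = zero_noise_synthetic
        x = ds.sample_concentrations
        row = truth.genes[truth.genes["responsive"]].iloc[0]
        y = ds.values.loc[row.gene_id].to_numpy()
        fits = {m: bmc.fit_model(x, y, m) for m in bmc.MODEL_IDS}
        best = min(fits, key=lambda m: fits[m].aic)
        assert best == "hill"

    def test_flat_data_has_negligible_effect(self, design_x):
        y = np.full_like(design_x, 7.5)
        fit = bmc.fit_model(design_x, y, "hill")
        a, b, _, _ = fit.params
        assert a == pytest.approx(7.5, abs=1e-6)
        assert abs(b) < 1e-6
        assert np.isnan(bmc.compute_bmd(fit, bmr=0.1))

    def test_decreasing_response_mirror(self, design_x):
        rng = np.random.default_rng(0)
        y_up = _hill_y(design_x, 8, 1.0, 2.0, 1.5) + rng.normal(0, 0.05,
                                                               len(design_x))
        y_dn = 16 - y_up
        up = bmc.fit_model(design_x, y_up, "hill")
        dn = bmc.fit_model(design_x, y_dn, "hill")
        assert up.direction == 1 and dn.direction == -1
        grid = np.linspace(0, 50, 50)
        assert (np.diff(up.predict(grid)) >= -1e-9).all()
        assert (np.diff(dn.predict(grid)) <= 1e-9).all()
        assert bmc.compute_bmd(up) == pytest.approx(bmc.compute_bmd(dn),
                                                    rel=0.05)

    def test_monotone_curves_all_families(self, design_x):
        rng = np.random.default_rng(5)
        y = _hill_y(design_x, 8, 1.0, 3.0, 2.0) + rng.normal(0, 0.1,
                                                             len(design_x))
        grid = np.linspace(0, 60, 200)
        for m in bmc.MODEL_IDS:
            fit = bmc.fit_model(design_x, y, m)
            if fit.converged:
                assert (np.diff(fit.predict(grid)) >= -1e-8).all()

    def test_too_few_concentrations_error(self):
        x = np.repeat([0.0, 1.0, 2.0, 5.0], 3)
        with pytest.raises(ValueError, match="4 distinct"):
            bmc.fit_model(x, np.ones_like(x), "hill")


class TestFitPvalue:
    def test_perfect_fit_p_one(self, design_x):
        y = _hill_y(design_x, 8, 1.0, 2.0, 1.5)
        fit = bmc.fit_model(design_x, y, "hill")
        assert bmc.fit_pvalue(fit, design_x, y) == pytest.approx(1.0,
                                                                 abs=1e-6)

    def test_gross_misspecification_rejected(self, design_x):
        """A power fit forced onto a steep saturating sigmoid lacks fit."""
        rng = np.random.default_rng(2)
        y = _hill_y(design_x, 8, 2.0, 0.5, 6.0) + rng.normal(0, 0.05,
                                                             len(design_x))
        fit = bmc.fit_model(design_x, y, "power")
        assert bmc.fit_pvalue(fit, design_x, y) < 0.001

    def test_no_replication_reports_one(self):
        x = np.array([0.0, 0.1, 1.0, 5.0, 20.0, 50.0])
        y = _hill_y(x, 8, 1, 2, 1.5)
        fit = bmc.fit_model(x, y, "hill")
        assert bmc.fit_pvalue(fit, x, y) == 1.0

    def test_calibration_uniform_under_truth(self, design_x):
        """Lack-of-fit p approximately uniform when the model is correct."""
        from scipy import stats

        rng = np.random.default_rng(42)
        ps = []
        for _ in range(300):
            y = _hill_y(design_x, 8, 1.0, 2.0, 1.5) + rng.normal(
                0, 0.15, len(design_x)
            )
            fit = bmc.fit_model(design_x, y, "hill", direction=1)
            ps.append(bmc.fit_pvalue(fit, design_x, y))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestComputeBmd:
    def test_linear_closed_form(self, design_x):
        """power with p = 1, slope 2: a 1-unit BMR is reached at x = 0.5."""
        y = 3.0 + 2.0 * design_x
        fit = bmc.fit_model(design_x, y, "power")
        assert bmc.compute_bmd(fit, bmr=1.0) == pytest.approx(0.5, rel=1e-6)

    def test_closed_form_matches_bracketed_root(self, design_x):
        rng = np.random.default_rng(9)
        y = _hill_y(design_x, 8, 1.2, 3.0, 2.0) + rng.normal(0, 0.1,
                                                             len(design_x))
        for m in bmc.MODEL_IDS:
            fit = bmc.fit_model(design_x, y, m)
            closed = bmc.compute_bmd(fit)
            numeric = bmc.compute_bmd_numeric(fit)
            if np.isfinite(closed):
                assert closed == pytest.approx(numeric, rel=1e-6)

    def test_unreachable_bmr_undefined(self, design_x):
        y = _hill_y(design_x, 8, 0.3, 2.0, 1.5)  # max effect 0.3
        fit = bmc.fit_model(design_x, y, "hill")
        assert np.isnan(bmc.compute_bmd(fit, bmr=0.5))

    def test_scale_equivariance(self, design_x):
        rng = np.random.default_rng(4)
        y = _hill_y(design_x, 8, 1.0, 2.0, 1.5) + rng.normal(0, 0.1,
                                                             len(design_x))
        c = 7.0
        for m in bmc.MODEL_IDS:
            f1 = bmc.fit_model(design_x, y, m)
            f2 = bmc.fit_model(design_x * c, y, m)
            b1, b2 = bmc.compute_bmd(f1), bmc.compute_bmd(f2)
            if np.isfinite(b1):
                assert b2 == pytest.approx(c * b1, rel=1e-4)


class TestModelAverage:
    def test_akaike_weights_closed_form(self):
        w = bmc.akaike_weights(np.array([0.0, 2.0]))
        assert w[0] == pytest.approx(1 / (1 + math.exp(-1)), rel=1e-12)
        assert w[1] == pytest.approx(math.exp(-1) / (1 + math.exp(-1)),
                                     rel=1e-12)

    def test_single_model_degenerate_mixture(self, design_x):
        rng = np.random.default_rng(3)
        y = _hill_y(design_x, 8, 1.0, 2.0, 2.0) + rng.normal(0, 0.1,
                                                             len(design_x))
        fit = bmc.fit_model(design_x, y, "hill")
        est = bmc.model_average([fit], design_x, y, n_boot=0)
        assert est.weights["hill"] == pytest.approx(
            1.0 - est.weights["flat"], rel=1e-12
        )
        assert est.bmd == pytest.approx(bmc.compute_bmd(fit), rel=1e-12)

    def test_interval_ordering_invariant(self, design_x):
        rng = np.random.default_rng(8)
        for _ in range(5):
            y = _hill_y(design_x, 8, 1.0, 2.0, 1.5) + rng.normal(
                0, 0.15, len(design_x)
            )
            fits = [bmc.fit_model(design_x, y, m) for m in bmc.MODEL_IDS]
            est = bmc.model_average(fits, design_x, y, n_boot=100, seed=1)
            if est.defined and np.isfinite(est.bmdl):
                assert est.bmdl <= est.bmd <= est.bmdu

    def test_bootstrap_percentiles_stable_when_doubled(self, design_x):
        rng = np.random.default_rng(12)
        y = _hill_y(design_x, 8, 1.0, 2.0, 1.5) + rng.normal(0, 0.05,
                                                             len(design_x))
        fits = [bmc.fit_model(design_x, y, m) for m in bmc.MODEL_IDS]
        e1 = bmc.model_average(fits, design_x, y, n_boot=200, seed=5)
        e2 = bmc.model_average(fits, design_x, y, n_boot=400, seed=5)
        assert abs(math.log(e2.bmdl / e1.bmdl)) < math.log(1.05)


class TestFiltersAndRanking:
    def _rec(self, gene, bmd=20.0, bmdl=10.0, bmdu=30.0, p=0.01):
        est = bmc.BMDEstimate(bmd, bmdl, bmdu)
        return bmc.GeneBMDRecord(
            gene, est, p,
            pass_fit_p=p > 0.001,
            pass_ratio=np.isfinite(bmdu) and bmdu / bmdl <= 40,
            pass_range=np.isfinite(bmd) and bmd <= 50.0,
        )

    def test_three_rules_applied(self):
        good = self._rec("a")
        assert good.responsive
        assert not self._rec("b", p=0.0005).responsive
        assert not self._rec("c", bmdl=1.0, bmdu=41.0).responsive
        assert not self._rec("d", bmd=55.0).responsive
        kept = bmc.filter_genes([good, self._rec("b", p=0.0005)])
        assert [r.gene_id for r in kept] == ["a"]

    def test_boundary_ratio_forty(self):
        assert self._rec("x", bmdl=1.0, bmdu=40.0).responsive
        r41 = self._rec("y", bmdl=1.0, bmdu=41.0)
        assert r41.pass_fit_p and r41.pass_range and not r41.pass_ratio

    def test_rank_genes_sort_ties_and_sentinels(self):
        recs = [
            self._rec("g1", bmdl=5.0),
            self._rec("g2", bmdl=1.0),
            self._rec("g3", bmdl=3.0),
            self._rec("g4", bmdl=3.0),
            self._rec("g0", bmd=np.nan, bmdl=np.nan, bmdu=np.nan),
        ]
        order = [r.gene_id for r in bmc.rank_genes(recs)]
        assert order == ["g2", "g3", "g4", "g1", "g0"]
        # permutation invariance
        order2 = [r.gene_id for r in bmc.rank_genes(recs[::-1])]
        assert order2 == order

    def test_responsive_fraction_recovered_near_truth(self):
        """Generator truth 14%: the three filters recover it within
        3 percentage points (averaged over seeds)."""
        fracs = []
        for seed in (0, 1):
            ds, truth = simulate.generate_expression_matrix(
                n_genes=250, responsive_fraction=0.14, seed=seed
            )
            recs = bmc.fit_dataset(ds, seed=seed)
            fracs.append(np.mean([r.responsive for r in recs]))
        assert abs(np.mean(fracs) - 0.14) <= 0.03
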