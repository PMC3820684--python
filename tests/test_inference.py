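"""Profile likelihood, initialisation, fitting and standard errors."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import sizesel as ss
from sizesel.data import CatchTableError
from sizesel.model import profile_mu


def make_table(counts, gears, lengths):
    df = pd.DataFrame(np.asarray(counts, float), index=np.asarray(lengths, float),
                      columns=[g.id for g in gears])
    return ss.CatchTable(df, gears)


TINY_GEARS = [ss.GearSpec("G14", "mesh", 14.0),
              ss.GearSpec("G25", "mesh", 25.0),
              ss.GearSpec("GC", "predator")]


def tiny_exact_table(params, lengths=np.arange(3.0, 26.0)):
    """Expected (noise-free) catches at known parameters, ~1000 fish total."""
    mu = np.full(len(lengths), 40.0)
    S = ss.selectivity_matrix(lengths, TINY_GEARS, params)
    return make_table(mu[:, None] * S, TINY_GEARS, lengths)


class TestProfileMu:
    def test_closed_form_arithmetic(self):
        mu = profile_mu(np.array([[3.0, 5.0]]), np.ones((1, 2)))
        assert mu.tolist() == [4.0]

    def test_zero_total_class(self):
        mu = profile_mu(np.array([[3.0, 5.0], [0.0, 0.0]]),
                        np.full((2, 2), 0.5))
        assert mu.tolist() == [8.0, 0.0]

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            profile_mu(np.ones((3, 2)), np.ones((2, 2)))

    def test_matches_per_class_numeric_maximisation(self, perch,
                                                    table2_params):
        """Each mu_j maximises its class's Poisson likelihood (1-D oracle)."""
        table = ss.normalize(perch)
        n = table.values
        S = ss.selectivity_matrix(table, params=table2_params)
        mu = profile_mu(n, S)
        for j in range(table.n_classes):
            if n[j].sum() == 0:
                assert mu[j] == 0
                continue

            def neg_ll(m, j=j):
                lam = m * S[j]
                return -(np.where(n[j] > 0, n[j] * np.log(lam), 0.0)
                         - lam).sum()

            best = minimize_scalar(neg_ll, bounds=(1e-12, 10.0),
                                   method="bounded",
                                   options={"xatol": 1e-12})
            assert mu[j] == pytest.approx(best.x, abs=1e-6)

    def test_perturbing_mu_never_helps(self, perch, table2_params):
        """Profile consistency: the closed form is a likelihood maximum."""
        table = ss.normalize(perch)
        n = table.values
        S = ss.selectivity_matrix(table, params=table2_params)
        mu = profile_mu(n, S)

        def kernel(muvec):
            lam = muvec[:, None] * S
            keep = n.sum(axis=1) > 0
            return (np.where(n > 0, n * np.log(lam), 0.0)
                    - lam)[keep].sum()

        base = kernel(mu)
        rng = np.random.default_rng(0)
        for _ in range(20):
            j = rng.integers(0, len(mu))
            if mu[j] == 0:
                continue
            pert = mu.copy()
            pert[j] *= rng.uniform(0.5, 1.5)
            assert kernel(pert) <= base + 1e-12


class TestNegativeLoglik:
    def test_matches_manual_recomputation(self, perch, table2_params):
        """Independent loop-based evaluation of the Poisson kernel."""
        model = ss.SelectivityModel(perch)
        n = model.table.values
        S = ss.selectivity_matrix(model.table, params=table2_params)
        mu = profile_mu(n, S)
        ll = 0.0
        for j in range(n.shape[0]):
            if n[j].sum() == 0:
                continue
            for i in range(n.shape[1]):
                lam = mu[j] * S[j, i]
                if n[j, i] > 0:
                    ll += n[j, i] * np.log(lam)
                ll -= lam
        assert model.nloglik(table2_params) == pytest.approx(-ll, rel=1e-12)

    def test_local_optimality_at_fit(self, perch, perch_fit):
        """Coordinate perturbations of the MLE only worsen the kernel."""
        model = ss.SelectivityModel(perch)
        x = perch_fit.params.to_array()
        base = model.nloglik(x)
        for k in range(4):
            for delta in (0.1, -0.1):
                pert = x.copy()
                pert[k] += delta
                assert model.nloglik(pert) > base

    def test_invalid_params_penalised(self, perch):
        model = ss.SelectivityModel(perch)
        with pytest.warns(RuntimeWarning):
            val = model.nloglik([-1.0, 12.0, 2.0, 0.4])
        assert val == 1e10

    def test_global_count_rescaling_preserves_mle(self, perch, perch_fit):
        """Scaling all counts by one constant leaves the argmax unchanged."""
        scaled = ss.CatchTable(perch.counts * 3.7, perch.gears)
        res_a = ss.SelectivityModel(perch, normalize=False).fit(
            compute_se=False)
        res_b = ss.SelectivityModel(scaled, normalize=False).fit(
            compute_se=False)
        np.testing.assert_allclose(res_a.params.to_array(),
                                   res_b.params.to_array(), atol=1e-4)


class TestInitialize:
    def test_bundled_heuristics(self, perch):
        init = ss.SelectivityModel(perch).initialize()
        # G14's modal class is 11 cm; occupied range 10-20 cm
        assert init.theta1 == pytest.approx(11 / 14)
        assert init.theta2 == pytest.approx((2 / 3) * 10)
        # initial lognormal mode equals the predator's modal class (8 cm)
        assert np.exp(init.theta3 - init.theta4**2) == pytest.approx(8.0)

    def test_all_positive(self, perch):
        init = ss.SelectivityModel(perch).initialize()
        assert np.all(init.to_array() > 0)

    def test_single_class_gear_falls_back(self):
        gears = [ss.GearSpec("G14", "mesh", 14.0),
                 ss.GearSpec("G25", "mesh", 25.0)]
        counts = [[7.0, 1.0], [0.0, 3.0], [0.0, 2.0]]
        init = ss.SelectivityModel(
            make_table(counts, gears, [10.0, 15.0, 18.0])).initialize()
        assert init.theta2 == 10.0


class TestFit:
    def test_exact_counts_recover_truth(self):
        """Noise-free expected counts reproduce the generating parameters."""
        truth = ss.SelectivityParams(0.71, 12.94, 2.13, 0.41)
        model = ss.SelectivityModel(tiny_exact_table(truth), normalize=False)
        res = model.fit(compute_se=False)
        assert res.converged
        np.testing.assert_allclose(res.params.to_array(), truth.to_array(),
                                   rtol=1e-3)
        # local grid oracle: no grid neighbour beats the optimum
        base = model.nloglik(res.params)
        for dx in np.ndindex(3, 3, 3, 3):
            x = res.params.to_array() * (1 + 0.02 * (np.array(dx) - 1))
            assert model.nloglik(x) >= base - 1e-9

    def test_multistart_agreement(self, perch, perch_fit):
        other = ss.SelectivityParams(0.5, 8.0, 2.5, 0.6)
        res = ss.SelectivityModel(perch).fit(start=other, compute_se=False)
        np.testing.assert_allclose(res.params.to_array(),
                                   perch_fit.params.to_array(), atol=1e-4)

    def test_mu_zero_exactly_for_empty_classes(self, perch, perch_fit):
        empty = perch.counts.sum(axis=1) == 0
        assert not empty.any()  # fixture has no empty class
        # add an empty class and refit cheaply at fixed params
        df = perch.counts.copy()
        df.loc[36.0] = 0.0
        t = ss.CatchTable(df.sort_index(), perch.gears)
        mu = ss.SelectivityModel(t).profile_abundance(perch_fit.params)
        assert mu.loc[36.0] == 0.0 and (mu.drop(36.0) > 0).all()

    def test_predator_free_table_fits_gamma_only(self):
        truth = ss.SelectivityParams(0.71, 12.94, 2.13, 0.41)
        gears = TINY_GEARS[:2]
        lengths = np.arange(3.0, 26.0)
        S = ss.selectivity_matrix(lengths, gears, truth)
        table = make_table(40.0 * S, gears, lengths)
        res = ss.SelectivityModel(table, normalize=False).fit(
            compute_se=False)
        np.testing.assert_allclose(
            [res.params.theta1, res.params.theta2], [0.71, 12.94], rtol=1e-3)

    def test_degenerate_table_rejected(self):
        df = pd.DataFrame([[3.0]], index=[10.0], columns=["G14"])
        with pytest.raises(CatchTableError):
            ss.SelectivityModel(
                ss.CatchTable(df, [ss.GearSpec("G14", "mesh", 14.0)]))

    def test_result_report_roundtrips_to_json(self, perch_fit, tmp_path):
        import json
        perch_fit.to_json(tmp_path / "fit.json")
        d = json.loads((tmp_path / "fit.json").read_text())
        assert d["converged"] is True
        assert d["params"]["theta1"] == pytest.approx(
            perch_fit.params.theta1)
        assert len(d["mu"]) == 34


class TestStandardErrors:
    def test_quadratic_objective_gives_exact_ses(self, perch):
        """With a known quadratic kernel, SEs equal sqrt(diag(H^-1))."""
        model = ss.SelectivityModel(perch)
        H = np.diag([2.0, 8.0, 18.0, 32.0])
        center = np.array([1.0, 2.0, 3.0, 4.0])
        model.nloglik = lambda x: 0.5 * (np.asarray(x) - center) @ H \
            @ (np.asarray(x) - center)
        bse, ok = model._standard_errors(center)
        assert ok
        np.testing.assert_allclose(bse, np.sqrt(1 / np.diag(H)), atol=1e-6)

    def test_fitted_ses_positive(self, perch_fit):
        assert perch_fit.hessian_ok
        assert np.all(perch_fit.bse > 0)

    def test_summary_mentions_all_parameters(self, perch_fit):
        text = perch_fit.summary()
        for name in ("theta1", "theta2", "theta3", "theta4"):
            assert name in text
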