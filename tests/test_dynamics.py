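"""Geometry of the dichromatism decomposition and its summary statistics."""

import numpy as np
import pandas as pd
import pytest

import dichroma as dc
from dichroma.dynamics import project_contributions
from dichroma.ridge import RidgeSolver

from conftest import make_centroids


class TestProjections:
    def test_pure_male_divergence(self):
        d = np.array([1.0, 0.0, 0.0])
        s_m, s_f, s, deg = project_contributions(2 * d, [0, 0, 0], d)
        assert (s_m[0], s_f[0], s[0]) == pytest.approx((2.0, 0.0, 2.0))
        assert not deg[0]

    def test_shared_drift_cancels(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=3)
        s_m, s_f, s, _ = project_contributions(v, v, rng.normal(size=3))
        assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_direction_flagged(self):
        s_m, s_f, s, deg = project_contributions([1, 0, 0], [0, 1, 0], [0, 0, 0])
        assert deg[0] and s_m[0] == s_f[0] == s[0] == 0.0

    def test_sum_identity_exact(self, small_analysis):
        table, _, _ = small_analysis
        assert np.abs(table["s"] - (table["s_m"] + table["s_f"])).max() < 1e-10

    def test_first_order_change_in_dichromatism(self):
        # s approximates d||D||/dt: evolve centroids by rate*dt and compare
        rng = np.random.default_rng(1)
        cm, cf = rng.normal(0, 10, 3), rng.normal(0, 10, 3)
        m, f = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
        s = project_contributions(m, f, cm - cf)[2][0]
        errs = []
        for dt in (1e-2, 1e-3, 1e-4):
            d1 = np.linalg.norm((cm + m * dt) - (cf + f * dt))
            d0 = np.linalg.norm(cm - cf)
            errs.append(abs((d1 - d0) / dt - s) / abs(s))
        assert errs[-1] < 1e-2 and errs[0] > errs[-1]


class TestSummaries:
    def test_identical_fits_ratio_one(self, small_darwinian):
        ds = small_darwinian
        solver = RidgeSolver(ds.index)
        y = ds.index.align_traits(
            ds.centroids[ds.centroids.sex == "male"].set_index("species_id")[["L", "a", "b"]]
        )
        fit = solver.fit(y, penalty=1.0)
        table = dc.branch_sex_table(fit, fit)
        assert dc.sex_rate_ratio(table) == pytest.approx(1.0)

    def test_doubled_male_traits_double_ratio(self, small_darwinian):
        ds = small_darwinian
        solver = RidgeSolver(ds.index)
        y = ds.index.align_traits(
            ds.centroids[ds.centroids.sex == "male"].set_index("species_id")[["L", "a", "b"]]
        )
        table = dc.branch_sex_table(solver.fit(2 * y, penalty=1.0), solver.fit(y, penalty=1.0))
        assert dc.sex_rate_ratio(table) == pytest.approx(2.0)

    def test_zero_female_rates_error(self, caterpillar_index):
        solver = RidgeSolver(caterpillar_index)
        flat = solver.fit(np.full((3, 3), 5.0), penalty=1.0)  # all rates 0
        varying = solver.fit(np.arange(9.0).reshape(3, 3), penalty=1.0)
        with pytest.raises(ValueError, match="female"):
            dc.sex_rate_ratio(dc.branch_sex_table(varying, flat))

    def test_constant_ratio_zero_slope(self):
        rng = np.random.default_rng(2)
        n = 40
        f = rng.uniform(0.5, 2.0, n)
        table = pd.DataFrame(
            {"m_mag": 2.0 * f, "f_mag": f, "anc_D_mag": rng.uniform(0, 30, n)}
        )
        line = dc.ratio_vs_dichromatism(table)
        assert line.slope == pytest.approx(0.0, abs=1e-12)

    def test_slope_equals_stacked_interaction(self, small_analysis):
        import statsmodels.formula.api as smf

        table, summary, _ = small_analysis
        ok = (table["m_mag"] > 1e-12) & (table["f_mag"] > 1e-12)
        sub = table[ok]
        stacked = pd.concat(
            [
                pd.DataFrame({"lograte": np.log(sub["m_mag"]), "D": sub["anc_D_mag"], "sex": 1.0}),
                pd.DataFrame({"lograte": np.log(sub["f_mag"]), "D": sub["anc_D_mag"], "sex": 0.0}),
            ]
        )
        res = smf.ols("lograte ~ D * sex", data=stacked).fit()
        assert abs(summary["ratio_slope"] - res.params["D:sex"]) < 1e-10

    def test_contribution_slopes_sum_to_one(self, small_analysis):
        table, _, _ = small_analysis
        male, female = dc.contribution_slopes(table)
        assert male.slope + female.slope == pytest.approx(1.0, abs=1e-10)

    def test_exact_half_split(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=30)
        table = pd.DataFrame(
            {"s": s, "s_m": 0.5 * s, "s_f": 0.5 * s, "degenerate_D": False}
        )
        male, female = dc.contribution_slopes(table)
        assert male.slope == pytest.approx(0.5) and female.slope == pytest.approx(0.5)

    def test_zero_variance_s_errors(self):
        table = pd.DataFrame({"s": np.ones(5), "s_m": np.ones(5) * 0.5,
                              "s_f": np.ones(5) * 0.5, "degenerate_D": False})
        with pytest.raises(ValueError, match="variance"):
            dc.contribution_slopes(table)


class TestSymmetries:
    def test_rotation_invariance(self, small_darwinian):
        ds = small_darwinian
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m = ds.centroids[ds.centroids.sex == "male"].set_index("species_id")[["L", "a", "b"]]
        f = ds.centroids[ds.centroids.sex == "female"].set_index("species_id")[["L", "a", "b"]]
        m, f = m.loc[ds.index.tip_labels].to_numpy(), f.loc[ds.index.tip_labels].to_numpy()
        t0, s0, _ = dc.analyze_dataset(ds.index, make_centroids(ds.index, m, f))
        t1, s1, _ = dc.analyze_dataset(
            ds.index, make_centroids(ds.index, m @ Q.T, f @ Q.T)
        )
        # the construction is purely geometric: common rotation changes nothing
        for col in ("s_m", "s_f", "s", "m_mag", "f_mag", "anc_D_mag"):
            assert np.allclose(t0[col], t1[col], atol=1e-8)
        assert s1["rate_ratio"] == pytest.approx(s0["rate_ratio"], abs=1e-10)

    def test_global_sex_swap_mirrors_outputs(self, small_darwinian):
        ds = small_darwinian
        swapped = ds.centroids.copy()
        swapped["sex"] = swapped["sex"].map({"male": "female", "female": "male"})
        _, s0, _ = dc.analyze_dataset(ds.index, ds.centroids)
        _, s1, _ = dc.analyze_dataset(ds.index, swapped)
        assert s1["rate_ratio"] == pytest.approx(1.0 / s0["rate_ratio"], abs=1e-10)
        assert s1["male_slope"] == pytest.approx(s0["female_slope"], abs=1e-10)
        assert s1["ratio_slope"] == pytest.approx(-s0["ratio_slope"], abs=1e-10)

    def test_monochromatic_everywhere_degenerate(self):
        ds = dc.simulate_dataset("shared_null", seed=5, n_tips=20,
                                 sigma_sex=0.0, mono_fraction=0.0)
        idx = ds.index
        solver = RidgeSolver(idx)
        fit_m, fit_f = dc.fit_sexes(idx, ds.centroids, penalty=1.0, solver=solver)
        table = dc.branch_sex_table(fit_m, fit_f)
        assert dc.sex_rate_ratio(table) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="degenerate|variance"):
            dc.contribution_slopes(table)
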