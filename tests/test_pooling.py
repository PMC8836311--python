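"""Pooling estimators, heterogeneity, subgroup tests and meta-regression."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from specmeta import (
    MetaDataset,
    MetaRegression,
    RandomEffectsMeta,
    SimConfig,
    pool,
    simulate_dataset,
    subgroup_test,
)
from specmeta.pooling import reml_tau2

from conftest import make_record


class TestFixedEffect:
    def test_hand_computed_two_studies(self):
        # z = (0, 1), v = (1, 1): mu = 0.5, se = sqrt(1/2), Q = 0.5
        res = pool([0.0, 1.0], [1.0, 1.0], "FE")
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert res.Q == pytest.approx(0.5, abs=1e-12)

    def test_weights_favor_precise_study(self):
        res = pool([0.0, 1.0], [0.01, 1.0], "FE")
        assert res.estimate < 0.05


class TestDerSimonianLaird:
    def test_no_dispersion(self):
        res = pool([0.3] * 5, [0.02] * 5, "DL")
        assert res.estimate == pytest.approx(0.3, abs=1e-12)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.I2 == 0.0

    def test_dl_equals_fe_when_q_below_df(self):
        rng = np.random.default_rng(5)
        v = np.full(8, 0.05)
        y = rng.normal(0.2, 0.01, 8)  # far less spread than sampling error
        dl, fe = pool(y, v, "DL"), pool(y, v, "FE")
        assert dl.Q < dl.df
        assert dl.tau2 == 0.0
        assert dl.estimate == pytest.approx(fe.estimate, abs=1e-14)

    def test_order_invariance(self, tiny_dataset):
        res = RandomEffectsMeta.from_dataset(tiny_dataset).fit("DL")
        rev = MetaDataset(list(reversed(tiny_dataset.records)), "rev")
        res_rev = RandomEffectsMeta.from_dataset(rev).fit("DL")
        assert res.estimate == pytest.approx(res_rev.estimate, abs=1e-15)
        assert res.tau2 == pytest.approx(res_rev.tau2, abs=1e-15)

    def test_i2_matches_q_formula_under_dl(self, tiny_dataset):
        res = RandomEffectsMeta.from_dataset(tiny_dataset).fit("DL")
        assert res.I2 == pytest.approx(max(0, (res.Q - res.df) / res.Q) * 100,
                                       abs=1e-9)

    def test_k_equals_one_flagged(self):
        res = pool([0.4], [0.01], "DL")
        assert res.k == 1 and np.isnan(res.Q) and np.isnan(res.I2)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            pool([0.1, 0.2], [0.0, 0.1], "DL")


class TestREML:
    def test_grid_oracle_small_k(self, tiny_dataset):
        """REML tau2 agrees with a brute-force grid search of the restricted
        likelihood for k <= 12."""
        y, v = tiny_dataset.effects("z")

        def neg_rll(tau2):
            w = 1 / (v + tau2)
            mu = np.sum(w * y) / np.sum(w)
            return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                          + np.sum(w * (y - mu) ** 2))

        grid = np.linspace(0, 0.5, 200_001)
        brute = grid[np.argmin([neg_rll(t) for t in grid])]
        assert reml_tau2(y, v) == pytest.approx(brute, abs=1e-4)

    def test_truncates_at_zero(self):
        rng = np.random.default_rng(2)
        v = np.full(10, 0.05)
        y = rng.normal(0.0, 0.02, 10)
        assert reml_tau2(y, v) == 0.0

    def test_against_metafor(self, tiny_dataset):
        """Independent oracle: r-metafor on the same ten studies."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        y, v = tiny_dataset.effects("z")
        script = textwrap.dedent(f"""
            suppressMessages(library(metafor))
            y <- c({','.join(f'{x:.17g}' for x in y)})
            v <- c({','.join(f'{x:.17g}' for x in v)})
            for (m in c("DL","REML","FE")) {{
              f <- rma(yi=y, vi=v, method=m)
              cat(sprintf("%s %.10f %.10f %.10f\\n", m, f$b, f$se, f$tau2))
            }}
        """)
        out = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, timeout=120)
        assert out.returncode == 0, out.stderr
        oracle = {line.split()[0]: [float(x) for x in line.split()[1:]]
                  for line in out.stdout.strip().splitlines()}
        for method, vals in oracle.items():
            # REML solutions differ by the optimizers' convergence criteria
            tol = 1e-5 if method == "REML" else 1e-10
            res = pool(y, v, method)
            assert res.estimate == pytest.approx(vals[0], abs=tol)
            assert res.se == pytest.approx(vals[1], abs=tol)
            assert res.tau2 == pytest.approx(vals[2], abs=max(tol, 1e-6))


class TestUnweighted:
    def test_mean_and_se(self):
        y = np.array([0.1, 0.2, 0.6])
        res = pool(y, [0.01, 0.02, 0.03], "UNWEIGHTED")
        assert res.estimate == pytest.approx(y.mean(), abs=1e-14)
        assert res.se == pytest.approx(y.std(ddof=1) / np.sqrt(3), abs=1e-14)


class TestParameterRecovery:
    def test_dl_reml_recover_truth(self):
        """On synthetic data (rho = -0.15, tau2 = 0.02, k = 100) both
        estimators recover rho within 0.02 and tau2 within 50% on average."""
        reps = 120
        est = {"DL": [], "REML": []}
        tau = {"DL": [], "REML": []}
        for i in range(reps):
            ds = simulate_dataset(SimConfig(k=100, rho=-0.15, tau2=0.02,
                                            n_min=50, n_max=2000, seed=10_000 + i))
            model = RandomEffectsMeta.from_dataset(ds)
            for m in ("DL", "REML"):
                fit = model.fit(m)
                est[m].append(fit.estimate_r)
                tau[m].append(fit.tau2)
        for m in ("DL", "REML"):
            assert np.mean(est[m]) == pytest.approx(-0.15, abs=0.02)
            assert np.mean(tau[m]) == pytest.approx(0.02, rel=0.5)


class TestSubgroups:
    def test_identical_groups_give_zero_q(self):
        recs = [make_record(i, r, n, religiosity_type=t)
                for i, (r, n, t) in enumerate([
                    (-0.2, 100, "beliefs"), (-0.1, 200, "beliefs"),
                    (-0.2, 100, "behavior"), (-0.1, 200, "behavior")])]
        comp = subgroup_test(MetaDataset(recs), "religiosity_type",
                             ["beliefs", "behavior"])
        assert comp.Q_between == pytest.approx(0.0, abs=1e-12)
        assert comp.df_between == 1

    def test_small_level_rejected_by_name(self, tiny_dataset):
        with pytest.raises(ValueError, match="behavior"):
            subgroup_test(tiny_dataset, "religiosity_type",
                          ["beliefs", "behavior"])

    def test_p_from_chisquare(self, table1):
        comp = subgroup_test(table1, "publication_status",
                             ["published", "unpublished"])
        assert comp.p_between == pytest.approx(
            float(stats.chi2.sf(comp.Q_between, 1)), abs=1e-12)


class TestMetaRegression:
    def test_saturated_two_point_fit(self):
        recs = [make_record(0, -0.1, 100, pct_men=0.2),
                make_record(1, -0.3, 100, pct_men=0.8),
                make_record(2, -0.2, 100, pct_men=0.5)]
        fit = MetaRegression(MetaDataset(recs), ["pct_men"]).fit("DL")
        # three collinear-in-moderator studies: slope interpolates the trend
        assert fit.params["pct_men"] < 0

    def test_constant_moderator_rejected(self):
        recs = [make_record(i, -0.1 * i, 100, pct_men=0.5) for i in range(5)]
        with pytest.raises(np.linalg.LinAlgError):
            MetaRegression(MetaDataset(recs), ["pct_men"])

    def test_missing_moderator_rows_dropped(self, table1):
        fit = MetaRegression(table1, ["pct_men"]).fit()
        assert fit.k == 76
        assert fit.n_dropped == 29

    def test_null_moderator_type_i_rate(self):
        """Slope test keeps its nominal size when the moderator is noise."""
        reps, hits = 400, 0
        rng = np.random.default_rng(77)
        for i in range(reps):
            ds = simulate_dataset(SimConfig(k=40, rho=-0.1, tau2=0.01,
                                            n_min=50, n_max=1000, seed=40_000 + i))
            recs = [make_record(j, rec.r, rec.n, pct_men=float(rng.uniform()))
                    for j, rec in enumerate(ds.records)]
            fit = MetaRegression(MetaDataset(recs), ["pct_men"]).fit("DL")
            hits += fit.p["pct_men"] < 0.05
        rate = hits / reps
        assert 0.02 < rate < 0.09
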