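"""Dissemination-bias methods: enumerable cases, constructed truths, and
small-scale simulation checks (full-size calibration lives in the acceptance
suite)."""

import itertools

import numpy as np
import pytest
from scipy import stats

from specmeta import (
    MetaDataset,
    SimConfig,
    begg_test,
    egger_test,
    excess_significance,
    p_curve,
    p_uniform,
    p_uniform_star,
    pool,
    simulate_dataset,
    trim_and_fill,
)
from specmeta.bias import _significant_subset

from conftest import make_record


def dataset_from_z(zs, ns, **kw):
    return MetaDataset([make_record(i, float(np.tanh(z)), n, **kw)
                        for i, (z, n) in enumerate(zip(zs, ns))])


class TestBegg:
    def test_k3_tau_is_enumerable(self):
        """With three studies Kendall tau can only take values +-1, +-1/3."""
        ds = dataset_from_z([0.5, 0.1, -0.2], [20, 80, 300])
        rep = begg_test(ds)
        assert any(np.isclose(rep.statistic, t, atol=1e-12)
                   for t in (-1.0, -1 / 3, 1 / 3, 1.0))

    def test_exhaustive_pair_count_matches(self):
        ds = dataset_from_z([0.4, 0.2, 0.05, -0.1], [30, 90, 250, 800])
        rep = begg_test(ds)
        # recompute tau by brute-force pair counting on the same deviates
        y, v = ds.effects("z")
        sign = -1 if np.sum(y / v) / np.sum(1 / v) < 0 else 1
        y = sign * y
        w = 1 / v
        dev = (y - np.sum(w * y) / np.sum(w)) / np.sqrt(v - 1 / np.sum(w))
        conc = disc = 0
        for i, j in itertools.combinations(range(4), 2):
            s = np.sign((dev[i] - dev[j]) * (v[i] - v[j]))
            conc += s > 0
            disc += s < 0
        tau_brute = (conc - disc) / 6
        assert rep.statistic * sign == pytest.approx(tau_brute, abs=1e-12)

    def test_too_few_studies(self):
        with pytest.raises(ValueError):
            begg_test(dataset_from_z([0.1, 0.2], [50, 60]))


class TestEgger:
    def test_symmetric_funnel_zero_intercept(self):
        # mirror construction: every deviate appears with both signs
        zs = [0.3, -0.3, 0.15, -0.15, 0.05, -0.05]
        ns = [25, 25, 100, 100, 900, 900]
        rep = egger_test(dataset_from_z(zs, ns))
        assert rep.details["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_detects_selection_bias(self):
        """Published-only samples from a selection process (publish iff
        significant w.p. 1, else 0.2) show funnel asymmetry at k ~ 100."""
        hits = 0
        reps = 60
        for i in range(reps):
            sim = simulate_dataset(SimConfig(
                k=260, rho=0.15, tau2=0.0, n_min=20, n_max=400,
                select_prob_sig=1.0, select_prob_nonsig=0.2, seed=60_000 + i))
            pub = sim.where(publication_status="published")
            hits += egger_test(pub).p < 0.05
        assert hits / reps > 0.5

    def test_identical_precision_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            egger_test(dataset_from_z([0.1, 0.2, 0.3], [50, 50, 50]))


class TestTrimAndFill:
    def test_symmetric_funnel_no_imputation(self):
        zs = [0.3, -0.3, 0.15, -0.15, 0.05, -0.05, 0.0]
        ns = [25, 25, 100, 100, 900, 900, 400]
        rep = trim_and_fill(dataset_from_z(zs, ns))
        assert rep.details["k0"] == 0
        assert rep.details["converged"]

    def test_recovers_deleted_studies(self):
        """Delete the 5 largest effects from a funnel whose center is pinned
        by very large studies; the rank estimators recover a missing count
        near 5 and the adjusted estimate moves back toward the truth."""
        z_big = 0.2 + np.linspace(-0.005, 0.005, 20)
        n_big = np.full(20, 20_000)
        z_small = 0.2 + np.concatenate([np.arange(1, 16), -np.arange(1, 16)]) * 0.03
        n_small = np.full(30, 60)
        z = np.concatenate([z_big, z_small])
        n = np.concatenate([n_big, n_small])
        keep = np.argsort(z)[:-5]  # drop the 5 largest -> missing on the right
        ds = dataset_from_z(z[keep], n[keep])
        for estimator in ("L0", "R0"):
            out = trim_and_fill(ds, side="right", estimator=estimator)
            assert abs(out.details["k0"] - 5) <= 2
            assert out.adjusted_estimate_r == pytest.approx(np.tanh(0.2), abs=0.01)
            assert out.adjusted_estimate_r >= pool(*ds.effects("z"), "DL").estimate_r - 1e-12

    def test_k0_matches_metafor(self):
        """Oracle equivalence: the iterated L0 count equals r-metafor's on
        noisy deleted-study data."""
        import shutil
        import subprocess
        import textwrap
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        blocks, ours = [], []
        for i in range(3):
            n = rng.integers(30, 500, 60)
            z = rng.normal(0.2, 1 / np.sqrt(n - 3))
            keep = np.argsort(z)[:-5]
            ds = dataset_from_z(z[keep], n[keep])
            ours.append(trim_and_fill(ds, side="right").details["k0"])
            y, v = ds.effects("z")
            blocks.append("y <- c(%s); v <- c(%s); "
                          "cat(trimfill(rma(yi=y, vi=v, method='DL'), "
                          "side='right', estimator='L0')$k0, '\\n')"
                          % (",".join(f"{x:.17g}" for x in y),
                             ",".join(f"{x:.17g}" for x in v)))
        script = "suppressMessages(library(metafor))\n" + "\n".join(blocks)
        out = subprocess.run(["Rscript", "-"], input=script, text=True,
                             capture_output=True, timeout=120)
        assert out.returncode == 0, out.stderr
        theirs = [int(s) for s in out.stdout.split()]
        assert ours == theirs

    def test_matches_metafor_on_fixture(self, table1):
        """metafor reports zero imputed studies on the published funnel."""
        from specmeta import filter_records
        rep = trim_and_fill(filter_records(table1, published_only=True))
        assert rep.details["k0"] == 0
        assert rep.adjusted_estimate_r == pytest.approx(-0.1428, abs=5e-4)


class TestExcessSignificance:
    def test_all_powered_all_significant(self):
        # every study huge: power ~ 1 and every study significant
        ds = dataset_from_z([0.4] * 6, [5000] * 6)
        pooled = pool(*ds.effects("z"), "DL")
        rep = excess_significance(ds, pooled)
        assert rep.details["expected"] == pytest.approx(6, abs=1e-6)
        assert rep.details["observed"] == 6
        assert rep.p == pytest.approx(1.0, abs=1e-4)

    def test_counts_conforming_tail_only(self):
        # a significant effect in the wrong direction must not count
        ds = dataset_from_z([0.4, 0.5, -0.5], [200, 200, 200])
        pooled = pool(*ds.effects("z"), "DL")
        rep = excess_significance(ds, pooled)
        assert rep.details["observed"] == 2


class TestPCurve:
    def test_null_uniform_pvalues_estimate_zero(self):
        """Studies constructed with pp-values exactly uniform under theta = 0
        yield a near-zero estimate."""
        k = 40
        n = np.full(k, 200)
        se = 1 / np.sqrt(n - 3)
        crit = stats.norm.isf(0.025) * se
        targets = (np.arange(k) + 0.5) / k  # exact uniform grid of pp's
        z = se * stats.norm.isf(targets * stats.norm.sf(crit / se))
        ds = dataset_from_z(z, n)
        rep = p_curve(ds)
        assert abs(rep.adjusted_estimate_r) < 0.02

    def test_recovers_homogeneous_truth(self):
        sim = simulate_dataset(SimConfig(k=600, rho=-0.20, tau2=0.0,
                                         n_min=50, n_max=500, seed=123))
        rep = p_curve(sim)
        assert rep.adjusted_estimate_r == pytest.approx(-0.20, abs=0.02)

    def test_right_skew_detected_for_real_effect(self):
        sim = simulate_dataset(SimConfig(k=120, rho=-0.25, tau2=0.0,
                                         n_min=100, n_max=500, seed=9))
        rep = p_curve(sim)
        assert rep.details["p_right_skew"] < 1e-4

    def test_insufficient_studies(self):
        ds = dataset_from_z([0.9, 0.8], [100, 100])
        with pytest.raises(ValueError):
            p_curve(ds)


class TestPUniform:
    def test_single_study_at_boundary_degenerates(self):
        """A lone study with p exactly at alpha has conditional p = 1 for
        every candidate effect: the moment condition has no root in any
        finite bracket and the failure is signalled."""
        n = 103
        se = 1 / np.sqrt(n - 3)
        z_at_alpha = stats.norm.isf(0.025) * se * (1 + 1e-9)
        ds = dataset_from_z([z_at_alpha, 0.05], [n, 50])  # second study ns
        y, s, _ = _significant_subset(ds)
        assert y.size == 1
        with pytest.raises(RuntimeError, match="bracket"):
            p_uniform(ds)

    def test_single_clearly_significant_study_estimable(self):
        n = 103
        se = 1 / np.sqrt(n - 3)
        ds = dataset_from_z([3.5 * se, 0.05], [n, 50])
        rep = p_uniform(ds)
        assert np.isfinite(rep.statistic) and rep.k_used == 1

    def test_recovers_homogeneous_truth(self):
        sim = simulate_dataset(SimConfig(k=600, rho=-0.20, tau2=0.0,
                                         n_min=50, n_max=500, seed=321))
        rep = p_uniform(sim)
        assert rep.adjusted_estimate_r == pytest.approx(-0.20, abs=0.02)

    def test_ci_brackets_estimate(self, table1):
        from specmeta import filter_records
        rep = p_uniform(filter_records(table1, published_only=True))
        assert rep.details["ci_low_r"] < rep.adjusted_estimate_r < rep.details["ci_high_r"]

    def test_lnp_variant_runs(self, table1):
        from specmeta import filter_records
        rep = p_uniform(filter_records(table1, published_only=True), method="LNP")
        assert rep.details["moment_method"] == "LNP"
        # LNP overweights small pp's and lands further from zero here
        assert rep.adjusted_estimate_r < -0.2


class TestPUniformStar:
    def test_no_selection_matches_pooled(self):
        """Without selection and with tau2 > 0 the conditional ML estimate
        tracks the ordinary random-effects estimate."""
        sim = simulate_dataset(SimConfig(k=300, rho=-0.15, tau2=0.02,
                                         n_min=50, n_max=1000, seed=777))
        rep = p_uniform_star(sim)
        fe = pool(*sim.effects("z"), "REML")
        assert rep.adjusted_estimate_r == pytest.approx(fe.estimate_r, abs=0.015)

    def test_null_truth_estimates_zero(self):
        sim = simulate_dataset(SimConfig(k=300, rho=0.0, tau2=0.0,
                                         n_min=50, n_max=500, seed=555))
        rep = p_uniform_star(sim)
        assert abs(rep.adjusted_estimate_r) < 0.02

    def test_needs_both_strata(self):
        ds = dataset_from_z([0.9, 0.95, 0.85], [400, 400, 400])  # all significant
        with pytest.raises(ValueError):
            p_uniform_star(ds)
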