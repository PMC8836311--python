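"""Dissemination-bias detection and correction for correlational meta-analysis.

Seven methods, all operating by default on the published subset and on a
direction-normalized scale (effects are flipped so the summary effect is
positive; reported estimates are flipped back):

* Begg-Mazumdar rank correlation between variance-stabilized deviates and
  sampling variances;
* Sterne-Egger regression of standard normal deviates on precision;
* Duval-Tweedie trim-and-fill (L0/R0 estimators of the missing-study count);
* test of excess significance (observed vs power-expected significant counts);
* p-curve (skew tests plus KS-distance effect estimation from significant p's);
* p-uniform (conditional-p moment estimation; Irwin-Hall "P" condition
  ``sum(pp) = k/2`` by default, Fisher-type "LNP" ``sum(-ln pp) = k`` optional);
* p-uniform* (joint conditional ML of effect and tau^2 from significant and
  non-significant studies).

Conditional p-values (pp-values) use the normal approximation on the Fisher-z
scale with se = 1/sqrt(n-3); study significance is recomputed from (r, n) via
the two-sided z-test at alpha = .05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .dataset import MetaDataset
from .pooling import MetaResult, RandomEffectsMeta

__all__ = [
    "BiasReport",
    "begg_test",
    "egger_test",
    "trim_and_fill",
    "excess_significance",
    "p_curve",
    "p_uniform",
    "p_uniform_star",
    "run_all_bias_methods",
    "funnel_plot_data",
]

ALPHA = 0.05
Z_CRIT = stats.norm.isf(ALPHA / 2)


@dataclass(frozen=True)
class BiasReport:
    method: str
    statistic: float
    p: float | None
    adjusted_estimate_r: float | None
    k_used: int
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p,
            "adjusted_estimate_r": self.adjusted_estimate_r,
            "k_used": self.k_used,
            "details": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in self.details.items()},
        }


def _direction(ds: MetaDataset) -> int:
    """Sign of the fixed-effect summary; +1 when zero. Effects are flipped by
    this sign so every method can assume a positive summary effect."""
    y, v = ds.effects("z")
    w = 1.0 / v
    s = np.sign(np.sum(w * y) / np.sum(w))
    return int(s) if s != 0 else 1


def _flipped(ds: MetaDataset) -> tuple[np.ndarray, np.ndarray, int]:
    sign = _direction(ds)
    y, v = ds.effects("z")
    return sign * y, v, sign


def begg_test(ds: MetaDataset) -> BiasReport:
    """Rank correlation (Kendall tau) between standardized deviates from the
    fixed-effect summary and the sampling variances."""
    if ds.k < 3:
        raise ValueError("Begg-Mazumdar test needs k >= 3")
    y, v, sign = _flipped(ds)
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    vstar = v - 1.0 / np.sum(w)
    deviates = (y - mu) / np.sqrt(vstar)
    tau, p = stats.kendalltau(deviates, v)  # normal approximation, tie-corrected
    return BiasReport("BEGG", sign * float(tau), float(p), None, ds.k,
                      {"alpha_convention": 0.10, "direction_sign": sign})


def egger_test(ds: MetaDataset) -> BiasReport:
    """Regression of standard normal deviates (z_i/se_i) on precision (1/se_i);
    the intercept's z-statistic indicates small-study asymmetry."""
    if ds.k < 3:
        raise ValueError("Egger regression needs k >= 3")
    y, v, sign = _flipped(ds)
    se = np.sqrt(v)
    if np.ptp(se) == 0:
        raise np.linalg.LinAlgError("identical precisions: design is singular")
    X = sm.add_constant(1.0 / se)
    fit = sm.OLS(y / se, X).fit()
    z_int = float(fit.tvalues[0])
    return BiasReport("EGGER", sign * z_int, float(fit.pvalues[0]), None, ds.k,
                      {"intercept": sign * float(fit.params[0]),
                       "slope": float(fit.params[1]), "direction_sign": sign})


def _tf_k0(y: np.ndarray, mu: float, estimator: str) -> int:
    """Duval-Tweedie missing-study estimators from the signed ranks of |y - mu|."""
    n = y.size
    dev = y - mu
    ranks = stats.rankdata(np.abs(dev))
    t_pos = np.sum(ranks[dev > 0])
    if estimator == "R0":
        # rightmost run of positive deviations
        order = np.argsort(np.abs(dev))
        signs = np.sign(dev)[order]
        gamma = 0
        for s in signs[::-1]:
            if s > 0:
                gamma += 1
            else:
                break
        k0 = gamma - 1
    else:  # L0
        k0 = (4 * t_pos - n * (n + 1)) / (2 * n - 1)
    return int(max(0, round(k0)))


def trim_and_fill(ds: MetaDataset, side: str = "right", estimator: str = "L0",
                  pool_estimator: str = "DL", max_iter: int = 50) -> BiasReport:
    """Estimate and impute studies missing from one side of the funnel plot.

    Iterates (estimate k0 from the ranks of deviations on the chosen side; trim
    the k0 most extreme studies; re-pool) until k0 stabilizes, then mirrors the
    trimmed studies about the trimmed summary and re-pools the augmented set.
    ``side`` is the side presumed deficient; by convention the side opposite
    the observed summary effect. On the direction-normalized scale (summary
    positive), missing "right"-side studies are the high-end ones, i.e. a
    deficit of large effects; operationally the funnel side is handled on the
    flipped scale and results flipped back.
    """
    if ds.k < 3:
        raise ValueError("trim-and-fill needs k >= 3")
    y, v = ds.effects("z")
    # the rank estimators are formulated for studies missing on the LEFT
    # (an excess of large effects); a missing-right problem is its mirror image
    flip = -1.0 if side == "right" else 1.0
    yy = flip * y
    k0, converged = 0, False
    for _ in range(max_iter):
        keep = np.argsort(yy)[: yy.size - k0] if k0 else np.arange(yy.size)
        w = 1.0 / v[keep]
        mu = np.sum(w * yy[keep]) / np.sum(w)
        k0_new = min(_tf_k0(yy, mu, estimator), yy.size - 2)
        if k0_new == k0:
            converged = True
            break
        k0 = k0_new
    # impute mirror images of the k0 largest studies about the trimmed summary
    if k0:
        order = np.argsort(yy)
        trimmed = order[: yy.size - k0]
        w = 1.0 / v[trimmed]
        mu = np.sum(w * yy[trimmed]) / np.sum(w)
        extremes = order[yy.size - k0:]
        y_aug = np.concatenate([yy, 2 * mu - yy[extremes]])
        v_aug = np.concatenate([v, v[extremes]])
    else:
        y_aug, v_aug = yy, v
    res = RandomEffectsMeta(y_aug, v_aug, "z").fit(pool_estimator)
    adj = float(np.tanh(flip * res.estimate))
    return BiasReport("TRIMFILL", float(k0), None, adj, ds.k,
                      {"k0": k0, "converged": converged, "side": side,
                       "estimator": estimator, "adjusted_se": res.se})


def _study_power(ds: MetaDataset, pooled_z: float, alpha: float = ALPHA) -> np.ndarray:
    """Power of each study's two-sided z-test to detect the summary effect,
    counting only the hypothesis-conforming tail."""
    n = np.array([rec.n for rec in ds.records])
    ncp = abs(pooled_z) * np.sqrt(n - 3)
    return stats.norm.sf(stats.norm.isf(alpha / 2) - ncp)


def excess_significance(ds: MetaDataset, pooled: MetaResult | None = None,
                        alpha: float = ALPHA) -> BiasReport:
    """Test of excess significance: compare the observed number of significant,
    direction-conforming studies with the number expected from per-study power
    against the pooled summary effect (chi-squared test)."""
    if ds.k < 2:
        raise ValueError("excess significance test needs k >= 2")
    if pooled is None:
        pooled = RandomEffectsMeta.from_dataset(ds).fit("DL")
    sign = np.sign(pooled.estimate_z) or 1
    power = _study_power(ds, pooled.estimate_z, alpha)
    expected = float(np.sum(power))
    y, v = ds.effects("z")
    p_exact = 2 * stats.norm.sf(np.abs(y) / np.sqrt(v))
    observed = int(np.sum((p_exact < alpha) & (np.sign(y) == sign)))
    k = ds.k
    # chi-squared comparison of observed vs expected counts; each term is
    # guarded against a degenerate margin (all or none expected significant)
    a = 0.0
    if expected > 1e-12:
        a += (observed - expected) ** 2 / expected
    if k - expected > 1e-12:
        a += (observed - expected) ** 2 / (k - expected)
    p = float(stats.chi2.sf(a, 1))
    return BiasReport("TES", float(a), p, None, k,
                      {"observed": observed, "expected": expected,
                       "mean_power": float(np.mean(power)),
                       "excess": observed > expected})


def _significant_subset(ds: MetaDataset, alpha: float = ALPHA):
    """Direction-conforming significant studies on the flipped (positive) scale."""
    y, v, sign = _flipped(ds)
    se = np.sqrt(v)
    sig = (2 * stats.norm.sf(np.abs(y) / se) < alpha) & (y > 0)
    return y[sig], se[sig], sign


def _log_pp(theta: float, y: np.ndarray, se: np.ndarray, crit: np.ndarray) -> np.ndarray:
    """log conditional p-values given candidate effect theta on the z scale."""
    return stats.norm.logsf((y - theta) / se) - stats.norm.logsf((crit - theta) / se)


def p_curve(ds: MetaDataset, alpha: float = ALPHA) -> BiasReport:
    """p-curve analysis of the significant, direction-conforming studies.

    Right-skew (evidential value) and left-skew/33%-power (p-hacking) tests by
    Stouffer aggregation of pp-values; effect estimated as the theta whose
    conditional-p distribution is closest to Uniform(0,1) in KS distance.
    """
    y, se, sign = _significant_subset(ds, alpha)
    k = y.size
    if k < 5:
        raise ValueError(f"p-curve needs >= 5 significant studies (got {k})")
    crit = stats.norm.isf(alpha / 2) * se

    # skew tests under theta = 0 and under 33% power
    pp_null = np.exp(np.clip(_log_pp(0.0, y, se, crit), -700, 0))
    z_right = float(np.sum(stats.norm.isf(pp_null)) / np.sqrt(k))
    p_right = float(stats.norm.sf(z_right))
    theta33 = np.array([optimize.brentq(
        lambda t, s=s_i, c=c_i: stats.norm.sf((c - t) / s) - 1.0 / 3.0, 0, 10)
        for s_i, c_i in zip(se, crit)])
    pp33 = 1.0 - np.exp(np.clip(_log_pp(theta33, y, se, crit), -700, 0))
    z_flat = float(np.sum(stats.norm.isf(np.clip(pp33, 1e-300, 1))) / np.sqrt(k))
    p_flat = float(stats.norm.sf(z_flat))

    def ks_distance(theta: float) -> float:
        pp = np.exp(np.clip(_log_pp(theta, y, se, crit), -700, 0))
        return stats.kstest(pp, "uniform").statistic

    res = optimize.minimize_scalar(ks_distance, bounds=(-1.0, 2.0),
                                   method="bounded", options={"xatol": 1e-6})
    est = float(np.tanh(res.x)) * sign
    return BiasReport("PCURVE", res.x * sign, p_right, est, k,
                      {"z_right_skew": z_right, "p_right_skew": p_right,
                       "z_flatness": z_flat, "p_flatness": p_flat,
                       "ks_distance": float(res.fun), "direction_sign": sign})


def _irwin_hall_root(fun: Callable[[float], float], lo: float = -2.0, hi: float = 2.0):
    """Bisection bracket with doubling expansion (up to 4 times)."""
    for _ in range(5):
        try:
            if fun(lo) * fun(hi) <= 0:
                return optimize.brentq(fun, lo, hi, xtol=1e-10)
        except ValueError:
            pass
        lo, hi = lo * 2, hi * 2
    raise RuntimeError("p-uniform: no root in the expanded bracket")


def p_uniform(ds: MetaDataset, alpha: float = ALPHA, method: str = "P") -> BiasReport:
    """p-uniform effect estimate from the significant, direction-conforming
    studies via a moment condition on conditional p-values.

    method "P" (default): at the true effect the pp-values are Uniform(0,1),
    so their sum follows an Irwin-Hall distribution with mean k/2; the estimate
    solves ``sum(pp(theta)) = k/2`` and the CI inverts the same statistic at
    its normal-approximation 2.5/97.5% quantiles. method "LNP": Fisher-type
    condition ``sum(-ln pp(theta)) = k`` inverted against Gamma(k, 1).
    The publication-bias test compares the pp-distribution at the fixed-effect
    estimate of the full set against uniformity.
    """
    y, se, sign = _significant_subset(ds, alpha)
    k = y.size
    if k < 1:
        raise ValueError("p-uniform needs at least one significant study")
    crit = stats.norm.isf(alpha / 2) * se

    if method.upper() == "P":
        def stat(theta):
            return float(np.sum(np.exp(np.clip(_log_pp(theta, y, se, crit), -700, 0))))
        target, spread = k / 2.0, math.sqrt(k / 12.0)
        # normal-approximation quantiles of the Irwin-Hall sum, clipped into
        # the statistic's attainable range (0, k) for very small k
        q_lo = max(target - stats.norm.isf(0.025) * spread, 1e-6)
        q_hi = min(target + stats.norm.isf(0.025) * spread, k - 1e-6)
        est = _irwin_hall_root(lambda t: stat(t) - target)
        ci = sorted([_irwin_hall_root(lambda t: stat(t) - q_lo),
                     _irwin_hall_root(lambda t: stat(t) - q_hi)])
    elif method.upper() == "LNP":
        def stat(theta):
            return float(-np.sum(_log_pp(theta, y, se, crit)))
        est = _irwin_hall_root(lambda t: stat(t) - k)
        ci = sorted([_irwin_hall_root(lambda t: stat(t) - stats.gamma.ppf(0.975, k)),
                     _irwin_hall_root(lambda t: stat(t) - stats.gamma.ppf(0.025, k))])
    else:
        raise ValueError("method must be 'P' or 'LNP'")

    # z-test of the estimate against zero via the same moment statistic at 0
    stat0 = stat(0.0)
    if method.upper() == "P":
        z0 = (k / 2.0 - stat0) / math.sqrt(k / 12.0)
    else:
        z0 = (stat0 - k) / math.sqrt(k)
    p_est = float(stats.norm.sf(z0))

    # publication-bias test: pp's at the FE estimate of the full input set
    y_all, v_all = ds.effects("z")
    w = 1.0 / v_all
    fe = abs(np.sum(w * y_all) / np.sum(w))
    stat_fe = stat(fe)
    if method.upper() == "P":
        z_bias = (stat_fe - k / 2.0) / math.sqrt(k / 12.0)
    else:
        z_bias = (k - stat_fe) / math.sqrt(k)
    p_bias = float(stats.norm.sf(z_bias))  # one-sided toward left-skew / bias

    ci_r = sorted([float(np.tanh(c)) * sign for c in ci])
    return BiasReport("PUNIFORM", est * sign, p_est, float(np.tanh(est)) * sign, k,
                      {"ci_low_r": ci_r[0], "ci_high_r": ci_r[1],
                       "p_bias_test": p_bias, "moment_method": method.upper(),
                       "direction_sign": sign})


def p_uniform_star(ds: MetaDataset, alpha: float = ALPHA) -> BiasReport:
    """p-uniform*: joint conditional maximum likelihood of (theta, tau^2) using
    significant and non-significant studies, each study's normal density being
    truncated to its own (two-sided) significance stratum."""
    y, v, sign = _flipped(ds)
    se = np.sqrt(v)
    k = y.size
    crit = stats.norm.isf(alpha / 2) * se
    issig = np.abs(y) > crit
    if k < 3 or issig.all() or (~issig).all():
        raise ValueError("p-uniform* needs both significant and non-significant studies, k >= 3")

    def negll(params: np.ndarray) -> float:
        theta, sq_tau = params
        tau2 = sq_tau**2
        sd = np.sqrt(v + tau2)
        dens = stats.norm.logpdf(y, theta, sd)
        p_sig = stats.norm.sf((crit - theta) / sd) + stats.norm.cdf((-crit - theta) / sd)
        strata = np.where(issig, p_sig, 1.0 - p_sig)
        return -float(np.sum(dens - np.log(np.clip(strata, 1e-300, None))))

    best = None
    for start in [(0.1, 0.1), (0.0, 0.15), (0.25, 0.05), (0.15, 0.2)]:
        res = optimize.minimize(negll, start, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"p-uniform* optimization failed at {best.x}")
    theta, tau2 = float(best.x[0]), float(best.x[1] ** 2)
    return BiasReport("PUNIFORM_STAR", theta * sign, None,
                      float(np.tanh(theta)) * sign, k,
                      {"tau2": tau2, "negll": float(best.fun),
                       "converged": bool(best.success), "direction_sign": sign})


def run_all_bias_methods(ds: MetaDataset, published_only: bool = True,
                         alpha: float = ALPHA) -> dict[str, BiasReport]:
    """All seven methods on the (by default) published subset; methods whose
    preconditions fail are reported as absent with the reason in the key order."""
    from .dataset import filter_records

    target = filter_records(ds, published_only=True) if published_only else ds
    pooled = RandomEffectsMeta.from_dataset(ds).fit("DL")
    out: dict[str, BiasReport] = {}
    runners: list[tuple[str, Callable[[], BiasReport]]] = [
        ("BEGG", lambda: begg_test(target)),
        ("EGGER", lambda: egger_test(target)),
        ("TRIMFILL", lambda: trim_and_fill(target)),
        ("TES", lambda: excess_significance(target, pooled, alpha)),
        ("TES_ALL", lambda: excess_significance(ds, pooled, alpha)),
        ("PCURVE", lambda: p_curve(target, alpha)),
        ("PUNIFORM", lambda: p_uniform(target, alpha)),
        ("PUNIFORM_STAR", lambda: p_uniform_star(target, alpha)),
    ]
    for name, runner in runners:
        try:
            out[name] = runner()
        except (ValueError, RuntimeError) as exc:
            out[name] = BiasReport(name, float("nan"), None, None, 0,
                                   {"error": str(exc)})
    return out


def funnel_plot_data(ds: MetaDataset) -> "pd.DataFrame":
    """Tidy per-study funnel-plot table: effect, SE, and contour significance
    band (the smallest conventional alpha at which the study is significant)."""
    import pandas as pd

    y, v = ds.effects("z")
    se = np.sqrt(v)
    p = 2 * stats.norm.sf(np.abs(y) / se)
    band = np.select([p < 0.01, p < 0.05, p < 0.10], ["<.01", "<.05", "<.10"], ">=.10")
    return pd.DataFrame({
        "study_id": [rec.study_id for rec in ds.records],
        "z": y, "se": se, "r": [rec.r for rec in ds.records],
        "p_exact": p, "contour_band": band,
    })
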