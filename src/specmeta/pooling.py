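"""Pooling estimators, heterogeneity, subgroup comparisons and meta-regression.

The central object is :class:`RandomEffectsMeta`, a model built from per-study
effects and sampling variances (usually Fisher-z correlations with variance
1/(n-3)). ``fit(method=...)`` supports four estimators:

``FE``
    fixed-effect inverse-variance pooling;
``DL``
    DerSimonian-Laird moment estimator of the between-study variance tau^2;
``REML``
    restricted maximum likelihood for tau^2 (bounded 1-D optimization);
``UNWEIGHTED``
    arithmetic mean of effects with SE = sd/sqrt(k).

Fitting returns a :class:`MetaResult` carrying the pooled estimate on both the
analysis scale and the correlation scale, Wald 95% confidence limits, Cochran's
Q (always computed under fixed-effect weights), I^2 and tau^2.

I^2 is reported as ``100 * tau2 / (tau2 + s2)`` where ``s2`` is the typical
within-study variance ``(k-1) * sum(w) / (sum(w)^2 - sum(w^2))`` under FE
weights; with the DL tau^2 this reduces exactly to ``max(0, (Q - df) / Q)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .dataset import MetaDataset

__all__ = [
    "RandomEffectsMeta",
    "MetaResult",
    "SubgroupComparison",
    "MetaRegression",
    "MetaRegressionResult",
    "pool",
    "subgroup_test",
    "meta_regress",
]

Z975 = stats.norm.ppf(0.975)
ESTIMATORS = ("FE", "DL", "REML", "UNWEIGHTED")


def _check_inputs(effects, variances):
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.ndim != 1 or y.shape != v.shape or y.size == 0:
        raise ValueError("effects and variances must be matching non-empty 1-D arrays")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be positive")
    return y, v


def _fe_heterogeneity(y: np.ndarray, v: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q, its df, and the moment denominator C under FE weights."""
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return q, y.size - 1, c


def reml_tau2(y: np.ndarray, v: np.ndarray, tol: float = 1e-10) -> float:
    """Restricted maximum-likelihood estimate of tau^2, clipped at zero."""

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    if y.size < 2:
        return 0.0
    hi = max(np.var(y) * 10, np.max(v) * 10, 1e-3)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, hi), method="bounded",
        options={"xatol": tol},
    )
    # the bounded minimizer can stall a hair away from the 0 boundary
    if neg_restricted_ll(0.0) <= res.fun:
        return 0.0
    return float(res.x)


@dataclass(frozen=True)
class MetaResult:
    """Pooled meta-analytic estimate with heterogeneity statistics.

    ``estimate`` is on the analysis scale (Fisher z when ``metric == "z"``);
    ``estimate_r`` and the CI bounds are on the correlation scale.
    """

    estimate: float
    se: float
    k: int
    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float
    estimator: str
    metric: str

    @property
    def estimate_z(self) -> float:
        return self.estimate if self.metric == "z" else float(np.arctanh(np.clip(self.estimate, -0.999999, 0.999999)))

    @property
    def estimate_r(self) -> float:
        return float(np.tanh(self.estimate)) if self.metric == "z" else self.estimate

    @property
    def ci_low(self) -> float:
        return self.estimate - Z975 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z975 * self.se

    @property
    def ci_low_r(self) -> float:
        return float(np.tanh(self.ci_low)) if self.metric == "z" else self.ci_low

    @property
    def ci_high_r(self) -> float:
        return float(np.tanh(self.ci_high)) if self.metric == "z" else self.ci_high

    @property
    def z_value(self) -> float:
        return self.estimate / self.se

    @property
    def p_value(self) -> float:
        return float(2 * stats.norm.sf(abs(self.z_value)))

    @property
    def heterogeneity_label(self) -> str:
        """Conventional verbal band for I^2: trivial/small/moderate/large."""
        if not np.isfinite(self.I2):
            return "undefined"
        for bound, label in [(25, "trivial"), (50, "small"), (75, "moderate")]:
            if self.I2 <= bound:
                return label
        return "large"

    def to_dict(self) -> dict:
        d = {
            "estimate": self.estimate,
            "estimate_r": self.estimate_r,
            "se": self.se,
            "ci_low_r": self.ci_low_r,
            "ci_high_r": self.ci_high_r,
            "p": self.p_value,
            "k": self.k,
            "Q": self.Q,
            "df": self.df,
            "p_Q": self.p_Q,
            "I2": self.I2,
            "tau2": self.tau2,
            "estimator": self.estimator,
            "metric": self.metric,
        }
        return d

    def summary(self) -> str:
        lines = [
            f"Random-effects meta-analysis ({self.estimator}, metric={self.metric}, k={self.k})",
            f"  estimate (r) {self.estimate_r: .4f}   95% CI [{self.ci_low_r: .4f}, {self.ci_high_r: .4f}]",
            f"  SE {self.se:.4f}   z {self.z_value:.3f}   p {self.p_value:.3g}",
            f"  Q {self.Q:.3f} (df={self.df}, p={self.p_Q:.3g})   "
            f"I2 {self.I2:.2f}% ({self.heterogeneity_label})   tau2 {self.tau2:.4f}",
        ]
        return "\n".join(lines)


class RandomEffectsMeta:
    """Meta-analytic pooling model over per-study effects and variances.

    Parameters
    ----------
    effects, variances
        Matching 1-D arrays on the analysis scale.
    metric
        "z" (Fisher z; results are back-transformed to r for reporting),
        "r", or "r_unit" (raw correlations with unit sampling variance).
    """

    def __init__(self, effects: Sequence[float], variances: Sequence[float], metric: str = "z"):
        self.effects, self.variances = _check_inputs(effects, variances)
        self.metric = metric

    @classmethod
    def from_dataset(cls, ds: MetaDataset, metric: str = "z") -> "RandomEffectsMeta":
        y, v = ds.effects(metric)
        return cls(y, v, metric)

    def fit(self, method: str = "REML") -> MetaResult:
        method = method.upper()
        if method not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        y, v = self.effects, self.variances
        k = y.size

        if k == 1:
            est, se = float(y[0]), float(np.sqrt(v[0]))
            return MetaResult(est, se, 1, np.nan, 0, np.nan, np.nan,
                              0.0, method, self.metric)

        q, df, c = _fe_heterogeneity(y, v)
        p_q = float(stats.chi2.sf(q, df))

        if method == "FE":
            tau2 = 0.0
        elif method == "DL":
            tau2 = max(0.0, (q - df) / c)
        elif method == "REML":
            tau2 = reml_tau2(y, v)
        else:  # UNWEIGHTED
            tau2 = max(0.0, float(np.var(y, ddof=1) - np.mean(v)))

        if method == "UNWEIGHTED":
            est = float(np.mean(y))
            se = float(np.std(y, ddof=1) / np.sqrt(k))
        else:
            w = 1.0 / (v + (tau2 if method != "FE" else 0.0))
            est = float(np.sum(w * y) / np.sum(w))
            se = float(np.sqrt(1.0 / np.sum(w)))

        # typical within-study variance under FE weights (the s^2 of Higgins-
        # Thompson); with the DL tau2, I2 reduces to max(0, (Q-df)/Q)*100
        wfe = 1.0 / v
        s2 = df * np.sum(wfe) / (np.sum(wfe) ** 2 - np.sum(wfe**2))
        i2 = float(100.0 * tau2 / (tau2 + s2)) if method != "FE" else float(
            max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
        )
        return MetaResult(est, se, k, q, df, p_q, i2, tau2, method, self.metric)


def pool(effects: Sequence[float], variances: Sequence[float],
         estimator: str = "DL", metric: str = "z") -> MetaResult:
    """Functional shorthand for ``RandomEffectsMeta(effects, variances, metric).fit(estimator)``."""
    return RandomEffectsMeta(effects, variances, metric).fit(estimator)


@dataclass(frozen=True)
class SubgroupComparison:
    """Mixed-effects moderator test: random-effects pooling within subgroups,
    fixed-effect comparison of the subgroup estimates between groups."""

    group_results: Mapping[str, MetaResult]
    Q_between: float
    df_between: int
    p_between: float

    def summary(self) -> str:
        lines = [f"Subgroup comparison (Q_between = {self.Q_between:.3f}, "
                 f"df = {self.df_between}, p = {self.p_between:.4g})"]
        for label, res in self.group_results.items():
            lines.append(f"  {label:>14s}: k={res.k:3d}  r={res.estimate_r: .3f} "
                         f"[{res.ci_low_r: .3f}, {res.ci_high_r: .3f}]  I2={res.I2:.1f}%")
        return "\n".join(lines)


def subgroup_test(ds: MetaDataset, grouping: str,
                  levels: Sequence[str] | None = None,
                  estimator: str = "REML", metric: str = "z") -> SubgroupComparison:
    """Compare pooled effects between moderator levels.

    Each level is pooled by a random-effects model with its own tau^2; the
    between-group statistic is ``Q_b = sum_g w_g (theta_g - theta_bar)^2`` with
    ``w_g = 1/se_g^2``, referred to a chi-square with (#groups - 1) df.
    """
    if levels is None:
        levels = sorted({getattr(rec, grouping) for rec in ds.records})
    results: dict[str, MetaResult] = {}
    for level in levels:
        sub = ds.where(**{grouping: level})
        if sub.k < 2:
            raise ValueError(f"level {level!r} has k = {sub.k} < 2")
        results[level] = RandomEffectsMeta.from_dataset(sub, metric).fit(estimator)
    theta = np.array([res.estimate for res in results.values()])
    w = np.array([1.0 / res.se**2 for res in results.values()])
    theta_bar = np.sum(w * theta) / np.sum(w)
    q_b = float(np.sum(w * (theta - theta_bar) ** 2))
    df_b = len(levels) - 1
    return SubgroupComparison(results, q_b, df_b, float(stats.chi2.sf(q_b, df_b)))


@dataclass(frozen=True)
class MetaRegressionResult:
    """Precision-weighted mixed-effects meta-regression fit."""

    params: Mapping[str, float]
    se: Mapping[str, float]
    p: Mapping[str, float]
    QM: float
    df_M: int
    p_QM: float
    QE: float
    R2: float
    tau2_residual: float
    tau2_null: float
    k: int
    n_dropped: int  # records without the moderator(s), silently excluded

    def summary(self) -> str:
        lines = [f"Meta-regression (k = {self.k}, {self.n_dropped} dropped; "
                 f"QM = {self.QM:.3f}, p = {self.p_QM:.4g}; R2 = {self.R2:.3f}; "
                 f"residual tau2 = {self.tau2_residual:.4f})"]
        for name in self.params:
            lines.append(f"  {name:>12s}  b = {self.params[name]: .4f}  "
                         f"se = {self.se[name]:.4f}  p = {self.p[name]:.4g}")
        return "\n".join(lines)


class MetaRegression:
    """Mixed-effects meta-regression of effects on numeric moderators.

    Weighted least squares on the analysis scale with weights 1/(v_i + tau^2);
    residual tau^2 estimated by REML (default) or a DL-type moment estimator on
    the WLS residuals, both clipped at zero.
    """

    def __init__(self, ds: MetaDataset, moderators: Sequence[str], metric: str = "z"):
        self.moderator_names = list(moderators)
        keep, dropped = [], 0
        for rec in ds.records:
            vals = [getattr(rec, m) for m in self.moderator_names]
            if any(val is None for val in vals):
                dropped += 1
            else:
                keep.append((rec, vals))
        if len(keep) <= len(self.moderator_names) + 1:
            raise ValueError("k must exceed the number of coefficients")
        sub = MetaDataset([rec for rec, _ in keep], ds.provenance + "[metareg]")
        self.y, self.v = sub.effects(metric)
        self.X = np.column_stack(
            [np.ones(len(keep))] + [np.array([float(vals[j]) for _, vals in keep])
                                    for j in range(len(self.moderator_names))]
        )
        for j, name in enumerate(self.moderator_names, start=1):
            if np.ptp(self.X[:, j]) == 0:
                raise np.linalg.LinAlgError(f"moderator {name!r} is constant")
        self.n_dropped = dropped

    def _tau2_moment(self) -> float:
        """DL-type moment estimator on the fixed-effect WLS residuals."""
        w = 1.0 / self.v
        wls = sm.WLS(self.y, self.X, weights=w).fit()
        q_e = float(np.sum(w * wls.resid**2))
        p = self.X.shape[1]
        wx = self.X * w[:, None]
        trace_correction = np.trace(np.linalg.solve(self.X.T @ wx, wx.T @ (wx * self.v[:, None])))
        c = np.sum(w) - trace_correction
        return max(0.0, (q_e - (len(self.y) - p)) / c)

    def _tau2_reml(self) -> float:
        y, v, X = self.y, self.v, self.X

        def neg_rll(tau2):
            w = 1.0 / (v + tau2)
            xtwx = X.T @ (X * w[:, None])
            beta = np.linalg.solve(xtwx, X.T @ (w * y))
            resid = y - X @ beta
            sign, logdet = np.linalg.slogdet(xtwx)
            return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2))

        hi = max(np.var(y) * 10, np.max(v) * 10, 1e-3)
        res = optimize.minimize_scalar(neg_rll, bounds=(0.0, hi), method="bounded",
                                       options={"xatol": 1e-10})
        return 0.0 if neg_rll(0.0) <= res.fun else float(res.x)

    def fit(self, tau2_method: str = "REML") -> MetaRegressionResult:
        tau2 = self._tau2_reml() if tau2_method.upper() == "REML" else self._tau2_moment()
        w = 1.0 / (self.v + tau2)
        wls = sm.WLS(self.y, self.X, weights=w).fit()
        # classical Wald inference with known heteroscedastic variances:
        # cov(beta) = (X' W X)^-1, not scaled by the WLS mean square
        cov = np.linalg.inv(self.X.T @ (self.X * w[:, None]))
        se = np.sqrt(np.diag(cov))
        beta = wls.params
        names = ["intercept"] + self.moderator_names
        zval = beta / se
        pvals = 2 * stats.norm.sf(np.abs(zval))
        # omnibus moderator test (all slopes zero)
        slope_cov = cov[1:, 1:]
        qm = float(beta[1:] @ np.linalg.solve(slope_cov, beta[1:])) if len(beta) > 1 else 0.0
        df_m = len(beta) - 1
        qe = float(np.sum((1.0 / self.v) * (self.y - self.X @ np.linalg.solve(
            self.X.T @ (self.X / self.v[:, None]), self.X.T @ (self.y / self.v))) ** 2))
        # heterogeneity accounted for, vs the intercept-only model
        null_model = RandomEffectsMeta(self.y, self.v)
        tau2_null = (null_model.fit("REML" if tau2_method.upper() == "REML" else "DL")).tau2
        r2 = 0.0 if tau2_null <= 0 else max(0.0, 1.0 - tau2 / tau2_null)
        return MetaRegressionResult(
            params=dict(zip(names, beta)), se=dict(zip(names, se)),
            p=dict(zip(names, pvals)), QM=qm, df_M=df_m,
            p_QM=float(stats.chi2.sf(qm, df_m)) if df_m else np.nan,
            QE=qe, R2=float(r2), tau2_residual=float(tau2),
            tau2_null=float(tau2_null), k=len(self.y), n_dropped=self.n_dropped,
        )


def meta_regress(ds: MetaDataset, moderators: Sequence[str],
                 weighted: bool = True, tau2_method: str = "REML") -> MetaRegressionResult:
    """Regress effects (Fisher z) on numeric moderators with precision weights.

    ``weighted=False`` fits ordinary least squares (used for the simple,
    non-precision-weighted quality regression)."""
    model = MetaRegression(ds, moderators)
    if weighted:
        return model.fit(tau2_method)
    # unweighted OLS path, reported in the same container
    ols = sm.OLS(model.y, model.X).fit()
    names = ["intercept"] + model.moderator_names
    return MetaRegressionResult(
        params=dict(zip(names, ols.params)), se=dict(zip(names, ols.bse)),
        p=dict(zip(names, ols.pvalues)), QM=float("nan"), df_M=len(names) - 1,
        p_QM=float("nan"), QE=float("nan"),
        R2=float(ols.rsquared), tau2_residual=float("nan"), tau2_null=float("nan"),
        k=len(model.y), n_dropped=model.n_dropped,
    )
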