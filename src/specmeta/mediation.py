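"""Two-stage meta-analytic mediation over pooled correlation matrices.

Stage 1 pools, cell by cell, the per-study 3 x 3 correlation matrices among a
predictor (intelligence), a mediator (e.g. education or analytic cognitive
style) and an outcome (religiosity), using DL random-effects pooling on the
Fisher-z scale. Stage 2 solves the standardized path model from the pooled
matrix: with predictor X, mediator M and outcome Y,

    a  = r_xm
    b  = (r_my - r_xm * r_xy) / (1 - r_xm^2)
    c' = (r_xy - r_xm * r_my) / (1 - r_xm^2)

so that total = r_xy = c' + a*b holds exactly. Confidence intervals for the
indirect effect a*b are obtained by Monte-Carlo resampling of the stage-1 cell
estimates from their asymptotic normal distributions (seeded), with a
delta-method variant exposed as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pooling import RandomEffectsMeta

__all__ = [
    "StudyCorrelationMatrix",
    "PooledCorrelationMatrix",
    "MediationResult",
    "pool_matrices",
    "partial_correlation",
    "TwoStageMediation",
    "fit_mediation",
    "load_correlation_csv",
]

CELLS = ("r_ir", "r_im", "r_mr")  # intelligence-religiosity, intelligence-mediator, mediator-religiosity


@dataclass(frozen=True)
class StudyCorrelationMatrix:
    """One study's correlations among intelligence (i), the mediator (m) and
    religiosity (r); missing cells are None and contribute nothing to pooling."""

    study_id: str
    n: int
    r_ir: float | None
    r_im: float | None
    r_mr: float | None

    def matrix(self) -> np.ndarray:
        def val(x):
            return np.nan if x is None else x
        return np.array([
            [1.0, val(self.r_im), val(self.r_ir)],
            [val(self.r_im), 1.0, val(self.r_mr)],
            [val(self.r_ir), val(self.r_mr), 1.0],
        ])

    def is_psd(self, tol: float = 1e-10) -> bool | None:
        m = self.matrix()
        if np.isnan(m).any():
            return None
        return bool(np.linalg.eigvalsh(m).min() >= -tol)


@dataclass(frozen=True)
class PooledCorrelationMatrix:
    """Random-effects pooled correlation matrix (order: intelligence, mediator,
    religiosity) with harmonic-mean sample size."""

    matrix: np.ndarray
    se_z: Mapping[str, float]   # stage-1 SEs of the pooled Fisher-z cells
    k_cells: Mapping[str, int]
    n_harmonic: float
    k: int
    psd_projected: bool = False

    @property
    def r_ir(self) -> float:
        return float(self.matrix[0, 2])

    @property
    def r_im(self) -> float:
        return float(self.matrix[0, 1])

    @property
    def r_mr(self) -> float:
        return float(self.matrix[1, 2])


def partial_correlation(rxy: float, rxz: float, ryz: float) -> float:
    """Correlation of x and y with z partialled out."""
    if max(abs(rxz), abs(ryz)) >= 1:
        raise ValueError("control correlations must be strictly inside (-1, 1)")
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


def pool_matrices(mats: Sequence[StudyCorrelationMatrix],
                  estimator: str = "DL") -> PooledCorrelationMatrix:
    """Stage-1 cellwise pooling of per-study correlation matrices.

    Each cell is pooled independently over the studies reporting it (DL on
    Fisher z, variance 1/(n-3)); the pooled matrix is projected to the nearest
    positive semi-definite matrix (eigenvalue clip at 1e-6, unit diagonal
    restored) if needed, with a flag.
    """
    if len(mats) < 2:
        raise ValueError("pooling needs k >= 2 matrices")
    pooled: dict[str, float] = {}
    ses: dict[str, float] = {}
    ks: dict[str, int] = {}
    contributing: set[str] = set()
    for cell in CELLS:
        vals = [(m.n, getattr(m, cell)) for m in mats if getattr(m, cell) is not None]
        if not vals:
            raise ValueError(f"cell {cell} has no contributing studies")
        n = np.array([n_ for n_, _ in vals])
        r = np.array([r_ for _, r_ in vals])
        res = RandomEffectsMeta(np.arctanh(r), 1.0 / (n - 3), "z").fit(estimator)
        pooled[cell] = res.estimate_r
        ses[cell] = res.se
        ks[cell] = len(vals)
        contributing |= {m.study_id for m in mats if getattr(m, cell) is not None}
    n_list = [m.n for m in mats]
    n_harm = len(n_list) / np.sum(1.0 / np.asarray(n_list, dtype=float))
    mat = np.array([
        [1.0, pooled["r_im"], pooled["r_ir"]],
        [pooled["r_im"], 1.0, pooled["r_mr"]],
        [pooled["r_ir"], pooled["r_mr"], 1.0],
    ])
    projected = False
    evals, evecs = np.linalg.eigh(mat)
    if evals.min() < 1e-6:
        projected = True
        evals = np.clip(evals, 1e-6, None)
        mat = evecs @ np.diag(evals) @ evecs.T
        d = np.sqrt(np.diag(mat))
        mat = mat / np.outer(d, d)
    return PooledCorrelationMatrix(mat, ses, ks, float(n_harm), len(mats), projected)


@dataclass(frozen=True)
class MediationResult:
    """Standardized direct, indirect and total paths with Monte-Carlo CIs."""

    pooled: PooledCorrelationMatrix
    a: float           # predictor -> mediator
    b: float           # mediator -> outcome (predictor controlled)
    direct: float      # predictor -> outcome controlling the mediator (c')
    indirect: float    # a * b
    total: float       # zero-order predictor-outcome correlation
    indirect_ci: tuple[float, float]
    direct_ci: tuple[float, float]
    mediation_type: str  # none | partial | full

    def summary(self) -> str:
        return "\n".join([
            f"Two-stage mediation (k = {self.pooled.k}, harmonic n = {self.pooled.n_harmonic:.1f})",
            f"  total    c  = {self.total: .4f}",
            f"  direct   c' = {self.direct: .4f}  95% CI [{self.direct_ci[0]: .4f}, {self.direct_ci[1]: .4f}]",
            f"  indirect ab = {self.indirect: .4f}  95% CI [{self.indirect_ci[0]: .4f}, {self.indirect_ci[1]: .4f}]",
            f"  a = {self.a: .4f}, b = {self.b: .4f}; mediation: {self.mediation_type}",
        ])


def _paths(r_xm: float, r_xy: float, r_my: float) -> tuple[float, float, float]:
    denom = 1.0 - r_xm**2
    if denom <= 0:
        raise np.linalg.LinAlgError("singular path system (|r_xm| = 1)")
    b = (r_my - r_xm * r_xy) / denom
    c_prime = (r_xy - r_xm * r_my) / denom
    return r_xm, b, c_prime


class TwoStageMediation:
    """Model object: pooled matrix plus role assignment; ``fit`` solves the
    path system and simulates CIs.

    ``roles`` maps {"predictor", "mediator", "outcome"} onto the matrix axes
    ("intelligence", "mediator", "religiosity"); the default treats
    intelligence as predictor and religiosity as outcome. Swapping predictor
    and mediator reproduces the reverse-direction model.
    """

    AXES = {"intelligence": 0, "mediator": 1, "religiosity": 2}

    def __init__(self, pooled: PooledCorrelationMatrix,
                 roles: Mapping[str, str] | None = None):
        self.pooled = pooled
        roles = roles or {"predictor": "intelligence", "mediator": "mediator",
                          "outcome": "religiosity"}
        self.idx = {role: self.AXES[axis] for role, axis in roles.items()}

    def _extract(self, mat: np.ndarray) -> tuple[float, float, float]:
        i, j, k = self.idx["predictor"], self.idx["mediator"], self.idx["outcome"]
        return mat[i, j], mat[i, k], mat[j, k]  # r_xm, r_xy, r_my

    def fit(self, n_draws: int = 10_000, seed: int = 0,
            alpha: float = 0.05) -> MediationResult:
        r_xm, r_xy, r_my = self._extract(self.pooled.matrix)
        a, b, c_prime = _paths(r_xm, r_xy, r_my)
        indirect = a * b

        # Monte-Carlo propagation of stage-1 uncertainty: resample each pooled
        # cell on the Fisher-z scale from its asymptotic normal distribution
        rng = np.random.default_rng(seed)
        se = self.pooled.se_z
        cells = {"r_im": self.pooled.r_im, "r_ir": self.pooled.r_ir,
                 "r_mr": self.pooled.r_mr}
        draws = {c: np.tanh(rng.normal(np.arctanh(cells[c]), se[c], n_draws))
                 for c in cells}
        full = np.empty((n_draws, 3, 3))
        full[:, 0, 0] = full[:, 1, 1] = full[:, 2, 2] = 1.0
        full[:, 0, 1] = full[:, 1, 0] = draws["r_im"]
        full[:, 0, 2] = full[:, 2, 0] = draws["r_ir"]
        full[:, 1, 2] = full[:, 2, 1] = draws["r_mr"]
        xm = full[:, self.idx["predictor"], self.idx["mediator"]]
        xy = full[:, self.idx["predictor"], self.idx["outcome"]]
        my = full[:, self.idx["mediator"], self.idx["outcome"]]
        denom = 1.0 - xm**2
        b_s = (my - xm * xy) / denom
        c_s = (xy - xm * my) / denom
        ind_s = xm * b_s
        lo, hi = alpha / 2, 1 - alpha / 2
        ind_ci = (float(np.quantile(ind_s, lo)), float(np.quantile(ind_s, hi)))
        dir_ci = (float(np.quantile(c_s, lo)), float(np.quantile(c_s, hi)))

        ind_sig = not (ind_ci[0] <= 0 <= ind_ci[1])
        dir_sig = not (dir_ci[0] <= 0 <= dir_ci[1])
        mtype = "none" if not ind_sig else ("full" if not dir_sig else "partial")
        return MediationResult(self.pooled, a, b, c_prime, indirect,
                               r_xy, ind_ci, dir_ci, mtype)


def fit_mediation(pooled: PooledCorrelationMatrix,
                  roles: Mapping[str, str] | None = None,
                  n_draws: int = 10_000, seed: int = 0) -> MediationResult:
    """Functional form of :class:`TwoStageMediation`."""
    return TwoStageMediation(pooled, roles).fit(n_draws=n_draws, seed=seed)


def load_correlation_csv(path) -> list[StudyCorrelationMatrix]:
    """Read per-study correlation triplets (columns: study_id, n, r_ir, r_im,
    r_mr; blank cells for unreported correlations)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        def cell(c):
            return None if pd.isna(row[c]) else float(row[c])
        out.append(StudyCorrelationMatrix(str(row["study_id"]), int(row["n"]),
                                          cell("r_ir"), cell("r_im"), cell("r_mr")))
    return out
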