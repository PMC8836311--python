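"""Synthetic meta-analytic datasets with the structure the analyses assume.

The generator emulates the study-level data-generating process of a
correlational meta-analysis: a true correlation rho on the Fisher-z scale,
between-study heterogeneity tau^2, study sizes spanning the range seen in the
literature (log-uniform, ~20-40,000), categorical moderators with
subgroup-specific effect shifts, and a publication-selection mechanism driven
by each study's own significance and sign (not by effect magnitude). A
companion generator draws per-study 3 x 3 correlation matrices from a known
population matrix for the mediation stage.

Reproducibility: one seed sequence is split into per-study substreams, so the
first k studies of a larger simulation are identical to a smaller one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dataset import MetaDataset, PValue, StudyRecord
from .mediation import StudyCorrelationMatrix

__all__ = ["SimConfig", "simulate_dataset", "simulate_correlation_matrices"]

# moderator composition mirroring the packaged dataset: level -> (probability, z shift)
DEFAULT_MODERATORS: dict[str, dict[str, tuple[float, float]]] = {
    "religiosity_type": {"beliefs": (0.65, 0.0), "behavior": (0.10, 0.0),
                         "mixed": (0.25, 0.0)},
    "sample_type": {"precollege": (0.12, 0.0), "college": (0.46, 0.0),
                    "noncollege": (0.38, 0.0), "mixed": (0.04, 0.0)},
    "intelligence_type": {"iq": (0.89, 0.0), "gpa": (0.07, 0.0), "mixed": (0.04, 0.0)},
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study-level generator.

    Defaults reproduce the observed scale of the packaged dataset: a true
    correlation of -0.14, between-study variance 0.018 on the z^2 scale, and
    study sizes log-uniform between 20 and 40,000.
    """

    k: int = 105
    rho: float = -0.14
    tau2: float = 0.018
    n_min: int = 20
    n_max: int = 40_000
    moderator_spec: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_MODERATORS)
    # selection: probability of being labelled "published" given
    # (significant two-sided at alpha, sign-conforming) vs otherwise
    select_prob_sig: float = 1.0
    select_prob_nonsig: float = 1.0
    select_alpha: float = 0.05
    mediation_truth: np.ndarray | None = None
    mediation_n: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not (4 <= self.n_min <= self.n_max):
            raise ValueError("need 4 <= n_min <= n_max")
        for p in (self.select_prob_sig, self.select_prob_nonsig):
            if not 0 <= p <= 1:
                raise ValueError("selection probabilities must be in [0, 1]")


def _draw_level(rng: np.random.Generator, spec: Mapping[str, tuple[float, float]]):
    levels = list(spec)
    probs = np.array([spec[l][0] for l in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(levels, p=probs)


def simulate_dataset(cfg: SimConfig) -> MetaDataset:
    """Draw a synthetic :class:`MetaDataset` under ``cfg``.

    Per study: n ~ log-uniform; theta_i = atanh(rho) + moderator shifts +
    Normal(0, tau^2); observed z ~ Normal(theta_i, 1/(n-3)); r = tanh(z); the
    two-sided p comes from the z-test, and the publication label is drawn from
    the significance-driven selection probabilities.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.k)
    mu = np.arctanh(cfg.rho)
    sign_conform = np.sign(mu) if mu != 0 else 1.0
    records = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        n = int(round(np.exp(rng.uniform(np.log(cfg.n_min), np.log(cfg.n_max)))))
        levels = {col: _draw_level(rng, spec)
                  for col, spec in cfg.moderator_spec.items()}
        shift = sum(cfg.moderator_spec[col][lev][1] for col, lev in levels.items())
        theta = mu + shift + rng.normal(0.0, np.sqrt(cfg.tau2))
        z = rng.normal(theta, 1.0 / np.sqrt(n - 3))
        r = float(np.tanh(z))
        p = float(2 * stats.norm.sf(abs(z) * np.sqrt(n - 3)))
        conforming = np.sign(z) == sign_conform
        sig = p < cfg.select_alpha and conforming
        prob_pub = cfg.select_prob_sig if sig else cfg.select_prob_nonsig
        published = rng.uniform() < prob_pub
        records.append(StudyRecord(
            study_id=f"sim{i:05d}", author=f"sim{i:05d}", year=2000, n=n, r=r,
            p_value=PValue(p), sample_type=levels.get("sample_type", "college"),
            pct_men=None, religiosity_type=levels.get("religiosity_type", "beliefs"),
            intelligence_type=levels.get("intelligence_type", "iq"),
            publication_status="published" if published else "unpublished",
        ))
    return MetaDataset(records, provenance=f"simulated(seed={cfg.seed})")


def simulate_correlation_matrices(cfg: SimConfig) -> list[StudyCorrelationMatrix]:
    """Per-study sample correlation matrices: draw a size-n multivariate-normal
    sample from the population matrix ``cfg.mediation_truth`` (order:
    intelligence, mediator, religiosity) and return its sample correlations."""
    if cfg.mediation_truth is None:
        raise ValueError("mediation_truth must be provided")
    truth = np.asarray(cfg.mediation_truth, dtype=float)
    if truth.shape != (3, 3) or np.linalg.eigvalsh(truth).min() < -1e-10:
        raise ValueError("mediation_truth must be a PSD 3x3 correlation matrix")
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.k)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        sample = rng.multivariate_normal(np.zeros(3), truth, size=cfg.mediation_n,
                                         method="cholesky")
        c = np.corrcoef(sample, rowvar=False)
        out.append(StudyCorrelationMatrix(
            study_id=f"sim{i:05d}", n=cfg.mediation_n,
            r_ir=float(c[0, 2]), r_im=float(c[0, 1]), r_mr=float(c[1, 2])))
    return out
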