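"""GOSH-style combinatorial meta-analysis.

Summary effects are computed over a large random sample of study subsets
(sizes uniform on [2, K], membership uniform given size, duplicates rejected by
bitmask hashing), optionally with stratified oversampling of subsets that
contain at least one of the most extreme effects, to expose the influence of
leverage studies on the pooled estimate and on heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import MetaDataset
from .pooling import RandomEffectsMeta

__all__ = ["GoshResult", "gosh", "leverage_studies", "leave_one_out"]


def leave_one_out(ds: MetaDataset, estimator: str = "DL") -> pd.DataFrame:
    """Pooled estimate with each study removed in turn, with the shift it causes."""
    full = RandomEffectsMeta.from_dataset(ds).fit(estimator)
    rows = []
    for i, rec in enumerate(ds.records):
        mask = np.ones(ds.k, dtype=bool)
        mask[i] = False
        res = RandomEffectsMeta.from_dataset(ds.subset(mask)).fit(estimator)
        rows.append({"study_id": rec.study_id, "estimate_r": res.estimate_r,
                     "delta_r": full.estimate_r - res.estimate_r,
                     "I2": res.I2, "Q": res.Q})
    return pd.DataFrame(rows)


def leverage_studies(ds: MetaDataset, m: int = 2, estimator: str = "DL") -> list[str]:
    """The m studies whose removal shifts the pooled estimate the most."""
    loo = leave_one_out(ds, estimator)
    return list(loo.reindex(loo.delta_r.abs().sort_values(ascending=False).index)
                .study_id.head(m))


@dataclass
class GoshResult:
    """Per-subset pooled estimates from combinatorial sampling."""

    table: pd.DataFrame  # columns: k, estimate_r, se, I2, ci_excludes_zero, contains_leverage
    masks: np.ndarray    # (n_subsets, K) boolean inclusion matrix
    leverage_ids: list[str]
    exhaustive: bool

    @property
    def share_negative(self) -> float:
        return float((self.table.estimate_r < 0).mean())

    @property
    def share_ci_excludes_zero(self) -> float:
        return float(self.table.ci_excludes_zero.mean())

    def density_quantiles(self, qs: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975)) -> dict:
        return {str(q): float(np.quantile(self.table.estimate_r, q)) for q in qs}

    def summary(self) -> str:
        return (f"GOSH: {len(self.table)} subsets"
                f"{' (exhaustive)' if self.exhaustive else ''}; "
                f"{100 * self.share_negative:.1f}% of estimates negative, "
                f"{100 * self.share_ci_excludes_zero:.1f}% of CIs exclude zero; "
                f"median r = {self.table.estimate_r.median():.3f}")


def _dl_pool_masks(y: np.ndarray, v: np.ndarray, masks: np.ndarray):
    """Vectorized DL pooling of many subsets (rows of the boolean mask matrix)."""
    w = 1.0 / v
    m = masks.astype(float)
    k = m.sum(axis=1)
    sw = m @ w
    sw2 = m @ (w**2)
    swy = m @ (w * y)
    swy2 = m @ (w * y**2)
    mu_fe = swy / sw
    q = swy2 - swy**2 / sw
    df = k - 1
    c = sw - sw2 / sw
    tau2 = np.maximum(0.0, (q - df) / c)
    # random-effects pass with subset-specific tau2
    wr = 1.0 / (v[None, :] + tau2[:, None])
    wr = wr * m
    swr = wr.sum(axis=1)
    mu = (wr * y[None, :]).sum(axis=1) / swr
    se = np.sqrt(1.0 / swr)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(q > 0, np.maximum(0.0, (q - df) / q) * 100.0, 0.0)
    return mu, se, q, i2, tau2, k


def gosh(ds: MetaDataset, n_subsets: int = 100_000, estimator: str = "DL",
         seed: int | None = None, oversample_extremes: bool = True,
         batch: int = 5_000) -> GoshResult:
    """Random-subset combinatorial meta-analysis.

    Subset sizes are uniform on [2, K] and membership uniform given size;
    duplicates are rejected via canonical bitmask hashing. When
    ``oversample_extremes`` is set, half of the draws force inclusion of at
    least one of the two most extreme observed effects (smallest and largest
    r). If the number of feasible subsets (2^K - 1 - K singletons) is below
    ``n_subsets``, the enumeration is exhaustive instead.
    """
    if ds.k < 2:
        raise ValueError("GOSH needs k >= 2")
    if n_subsets < 1:
        raise ValueError("n_subsets must be positive")
    if seed is None:
        raise ValueError("a seed is required")
    if estimator != "DL":
        raise NotImplementedError("vectorized GOSH supports the DL estimator")
    K = ds.k
    y, v = ds.effects("z")
    r = np.tanh(y)
    extremes = [int(np.argmin(r)), int(np.argmax(r))]
    feasible = (1 << K) - 1 - K if K < 63 else None  # subsets of size >= 2

    masks_list: list[np.ndarray] = []
    if feasible is not None and feasible <= n_subsets:
        exhaustive = True
        for code in range(1, 1 << K):
            if code.bit_count() >= 2:
                masks_list.append(np.array([(code >> i) & 1 for i in range(K)], bool))
        masks = np.array(masks_list)
    else:
        exhaustive = False
        rng = np.random.default_rng(seed)
        seen: set[bytes] = set()
        masks_acc = np.zeros((n_subsets, K), dtype=bool)
        filled = 0
        attempts = 0
        while filled < n_subsets and attempts < 200:
            attempts += 1
            want = n_subsets - filled
            sizes = rng.integers(2, K + 1, size=want)
            for sz in sizes:
                members = rng.choice(K, size=sz, replace=False)
                mask = np.zeros(K, dtype=bool)
                mask[members] = True
                if oversample_extremes and (filled % 2 == 1) and not mask[extremes].any():
                    # stratified half: force one of the extreme-effect studies in
                    drop = members[rng.integers(sz)]
                    mask[drop] = False
                    mask[extremes[int(rng.integers(2))]] = True
                key = np.packbits(mask).tobytes()
                if key in seen:
                    continue
                seen.add(key)
                masks_acc[filled] = mask
                filled += 1
                if filled == n_subsets:
                    break
        masks = masks_acc[:filled]

    # pool in batches to bound memory
    parts = []
    for start in range(0, len(masks), batch):
        chunk = masks[start:start + batch]
        mu, se, q, i2, tau2, k = _dl_pool_masks(y, v, chunk)
        parts.append(pd.DataFrame({
            "k": k.astype(int), "estimate_r": np.tanh(mu), "se": se,
            "Q": q, "I2": i2, "tau2": tau2,
            "ci_excludes_zero": np.abs(mu) > 1.959963984540054 * se,
        }))
    table = pd.concat(parts, ignore_index=True)
    lev_ids = leverage_studies(ds, 2, estimator)
    lev_idx = [i for i, rec in enumerate(ds.records) if rec.study_id in lev_ids]
    table["contains_leverage"] = masks[:, lev_idx].any(axis=1)
    return GoshResult(table, masks, lev_ids, exhaustive)
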