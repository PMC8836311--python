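"""Study-level records for correlational meta-analysis, and the effect-size algebra.

A :class:`MetaDataset` is an ordered collection of :class:`StudyRecord` objects, one
per independent sample: the Pearson correlation between intelligence and religiosity,
the sample size, the reported p-value, and the categorical moderators used throughout
the analysis (sample type, religiosity-assessment type, intelligence-assessment type,
publication status).

The packaged fixture (``data/table1.csv``) is the 105-sample dataset of the
intelligence-religiosity literature, 1928-2020, transcribed from the printed study
table of the source meta-analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyRecord",
    "MetaDataset",
    "PValue",
    "load_dataset",
    "load_table1",
    "fisher_z",
    "back_transform",
    "sampling_variance",
    "average_within_study",
    "correct_range_restriction",
    "filter_records",
    "SchemaError",
    "ValidationError",
]

SAMPLE_TYPES = frozenset({"precollege", "college", "noncollege", "mixed"})
RELIGIOSITY_TYPES = frozenset({"beliefs", "behavior", "mixed"})
INTELLIGENCE_TYPES = frozenset({"iq", "gpa", "mixed"})
PUBLICATION_STATUSES = frozenset({"published", "unpublished"})


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates the domain constraints (|r| >= 1, n < 4, unknown level...)."""


@dataclass(frozen=True)
class PValue:
    """A reported two-sided p-value, possibly only as an upper bound ("< .01").

    Printed study tables frequently report bounds instead of exact values; the bound
    is preserved so that significance against a level alpha can be decided without
    inventing an exact number (a bound ``< x`` is significant iff ``x <= alpha``).
    """

    value: float
    is_bound: bool = False

    def significant(self, alpha: float) -> bool:
        if self.is_bound:
            return self.value <= alpha
        return self.value <= alpha

    def __str__(self) -> str:  # round-trips the CSV representation
        return f"<{self.value:g}" if self.is_bound else f"{self.value:g}"

    @classmethod
    def parse(cls, text: str | float) -> "PValue":
        if isinstance(text, (int, float)) and not isinstance(text, bool):
            return cls(float(text))
        s = str(text).strip().replace(" ", "")
        if s.startswith("<"):
            return cls(float(s[1:]), True)
        return cls(float(s))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing transform z = atanh(r); domain |r| < 1."""
    r = np.asarray(r, dtype=float) if np.ndim(r) else float(r)
    if np.any(np.abs(r) >= 1):
        raise ValidationError("fisher_z requires |r| < 1")
    return np.arctanh(r)


def back_transform(z: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`fisher_z`: r = tanh(z)."""
    return np.tanh(z)


def sampling_variance(n: int | np.ndarray, metric: str = "z", r: float | np.ndarray = 0.0):
    """Large-sample variance of a correlation: 1/(n-3) on the z scale,
    (1-r^2)^2/(n-1) on the raw-r scale."""
    n = np.asarray(n)
    if np.any(n < 4):
        raise ValidationError("sampling variance requires n >= 4")
    if metric == "z":
        return 1.0 / (n - 3)
    if metric == "r":
        r = np.asarray(r, dtype=float)
        return (1.0 - r**2) ** 2 / (n - 1)
    raise ValueError(f"unknown metric {metric!r}")


def average_within_study(rs: Sequence[float], n: int | None = None) -> float:
    """Average several correlations from one sample on the Fisher-z scale.

    Used when a primary study reports more than one eligible correlation: the
    r's are z-transformed, averaged, and back-transformed.
    """
    if len(rs) == 0:
        raise ValidationError("cannot average an empty list of correlations")
    return float(np.tanh(np.mean(np.arctanh(np.asarray(rs, dtype=float)))))


def correct_range_restriction(r: float, ratio: float) -> float:
    """Thorndike Case 2 correction for direct range restriction.

    ``ratio`` is the unrestricted/restricted SD ratio of the selection variable
    (intelligence). With R = ratio the corrected correlation is
    ``r*R / sqrt(1 - r^2 + r^2 R^2)``; R = 1 is the identity and the sign of r
    is preserved.
    """
    if abs(r) >= 1:
        raise ValidationError("correct_range_restriction requires |r| < 1")
    if ratio <= 0:
        raise ValidationError("SD ratio must be positive")
    return r * ratio / math.sqrt(1.0 - r**2 + r**2 * ratio**2)


@dataclass(frozen=True)
class StudyRecord:
    """One independent sample: effect size, precision, and moderator codes."""

    study_id: str
    author: str
    year: int
    n: int
    r: float
    p_value: PValue
    sample_type: str
    pct_men: float | None  # stored as a proportion in [0, 1]; None when unavailable
    religiosity_type: str
    intelligence_type: str
    publication_status: str
    quality: int | None = None

    def __post_init__(self):
        if self.n < 4:
            raise ValidationError(f"{self.study_id}: n = {self.n} < 4")
        if not -1 < self.r < 1:
            raise ValidationError(f"{self.study_id}: r = {self.r} outside (-1, 1)")
        for name, value, levels in [
            ("sample_type", self.sample_type, SAMPLE_TYPES),
            ("religiosity_type", self.religiosity_type, RELIGIOSITY_TYPES),
            ("intelligence_type", self.intelligence_type, INTELLIGENCE_TYPES),
            ("publication_status", self.publication_status, PUBLICATION_STATUSES),
        ]:
            if value not in levels:
                raise ValidationError(f"{self.study_id}: {name} = {value!r} not in {sorted(levels)}")
        if self.pct_men is not None and not 0 <= self.pct_men <= 1:
            raise ValidationError(f"{self.study_id}: pct_men out of [0, 1]")
        if self.quality is not None and not 0 <= self.quality <= 5:
            raise ValidationError(f"{self.study_id}: quality out of 0-5")

    @property
    def z(self) -> float:
        """Fisher-z effect size."""
        return math.atanh(self.r)

    @property
    def variance_z(self) -> float:
        return 1.0 / (self.n - 3)

    def exact_p(self) -> float:
        """Two-sided p recomputed from (r, n) via the z-test on the Fisher scale.

        Printed p-values are rounded or bounded; the conditional-p methods
        (p-curve, p-uniform) need exact values, so they are always recomputed.
        """
        return 2 * stats.norm.sf(abs(self.z) * math.sqrt(self.n - 3))


@dataclass
class MetaDataset:
    """Ordered collection of study records with a provenance label."""

    records: list[StudyRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [rec.study_id for rec in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate study_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.records)

    @property
    def k(self) -> int:
        return len(self.records)

    @property
    def total_n(self) -> int:
        return sum(rec.n for rec in self.records)

    def effects(self, metric: str = "z") -> tuple[np.ndarray, np.ndarray]:
        """Per-study effects and sampling variances on the requested scale.

        metric "z": Fisher z with variance 1/(n-3); "r": raw correlation with
        variance (1-r^2)^2/(n-1); "r_unit": raw correlation with unit variance
        (an unweighted-synthesis convention used as a third effect-size choice
        in the multiverse grid).
        """
        r = np.array([rec.r for rec in self.records])
        n = np.array([rec.n for rec in self.records])
        if metric == "z":
            return np.arctanh(r), 1.0 / (n - 3)
        if metric == "r":
            return r, (1.0 - r**2) ** 2 / (n - 1)
        if metric == "r_unit":
            return r, np.ones_like(r)
        raise ValueError(f"unknown metric {metric!r}")

    def subset(self, mask: Iterable[bool], provenance: str | None = None) -> "MetaDataset":
        recs = [rec for rec, keep in zip(self.records, mask) if keep]
        return MetaDataset(recs, provenance or self.provenance)

    def where(self, **criteria: str) -> "MetaDataset":
        """Filter by moderator equality, e.g. ``ds.where(sample_type="college")``."""
        recs = self.records
        for name, level in criteria.items():
            recs = [rec for rec in recs if getattr(rec, name) == level]
        label = ",".join(f"{k}={v}" for k, v in criteria.items())
        return MetaDataset(list(recs), f"{self.provenance}[{label}]")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "study_id": rec.study_id,
                    "author": rec.author,
                    "year": rec.year,
                    "n": rec.n,
                    "r": rec.r,
                    "p_value": str(rec.p_value),
                    "sample_type": rec.sample_type,
                    "pct_men": np.nan if rec.pct_men is None else rec.pct_men * 100,
                    "religiosity_type": rec.religiosity_type,
                    "intelligence_type": rec.intelligence_type,
                    "publication_status": rec.publication_status,
                    "quality": np.nan if rec.quality is None else rec.quality,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


DEFAULT_SCHEMA = {
    "study_id": "study_id",
    "author": "author",
    "year": "year",
    "n": "n",
    "r": "r",
    "p_value": "p_value",
    "sample_type": "sample_type",
    "pct_men": "pct_men",
    "religiosity_type": "religiosity_type",
    "intelligence_type": "intelligence_type",
    "publication_status": "publication_status",
    "quality": "quality",
}

_ALIASES = {
    "non-college": "noncollege",
    "non college": "noncollege",
    "pre-college": "precollege",
    "pre college": "precollege",
    "behaviour": "behavior",
}


def _norm_level(value: str) -> str:
    v = str(value).strip().lower()
    return _ALIASES.get(v, v)


def load_dataset(path: str | Path, schema: dict[str, str] | None = None,
                 provenance: str | None = None) -> MetaDataset:
    """Read a study table from CSV into a validated :class:`MetaDataset`.

    ``schema`` maps canonical field names to the file's column names; enum levels
    are normalized case-insensitively, p-value bounds ("< .01") are preserved as
    bounds, and percentages of men are converted to proportions internally.
    Raises :class:`SchemaError` for missing columns and :class:`ValidationError`
    naming the offending row for out-of-domain values.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [f for f in DEFAULT_SCHEMA if f not in ("quality", "pct_men", "author")]
    missing = [schema[f] for f in required if schema[f] not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: no records")

    records = []
    for idx, row in df.iterrows():
        def cell(fieldname, default=""):
            col = schema.get(fieldname)
            return row[col].strip() if col in df.columns else default

        sid = cell("study_id") or f"row{idx}"
        try:
            pct = cell("pct_men")
            qual = cell("quality")
            records.append(
                StudyRecord(
                    study_id=sid,
                    author=cell("author") or sid,
                    year=int(cell("year")),
                    n=int(cell("n")),
                    r=float(cell("r")),
                    p_value=PValue.parse(cell("p_value")),
                    sample_type=_norm_level(cell("sample_type")),
                    pct_men=None if pct in ("", "n/a", "na", "NA") else float(pct) / 100.0,
                    religiosity_type=_norm_level(cell("religiosity_type")),
                    intelligence_type=_norm_level(cell("intelligence_type")),
                    publication_status=_norm_level(cell("publication_status")),
                    quality=None if qual == "" else int(qual),
                )
            )
        except ValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"row {idx} ({sid}): {exc}") from exc
    return MetaDataset(records, provenance or str(path))


def load_table1() -> MetaDataset:
    """The packaged 105-sample intelligence-religiosity dataset (1928-2020)."""
    with resources.as_file(resources.files("specmeta").joinpath("data/table1.csv")) as p:
        return load_dataset(p, provenance="table1")


def filter_records(ds: MetaDataset, published_only: bool = False,
                   significant_only: bool = False, alpha: float = 0.05,
                   direction: int | None = None,
                   use_exact_p: bool = True) -> MetaDataset:
    """Filter to published and/or significant and/or direction-consistent records.

    Significance is decided from the exact two-sided p recomputed from (r, n) by
    default (``use_exact_p``), or from the reported p (bounds "< x" count as
    significant when x <= alpha). ``direction`` (+1/-1) keeps effects whose sign
    matches; an empty result is returned as an empty dataset, not an error.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    recs = ds.records
    if published_only:
        recs = [rec for rec in recs if rec.publication_status == "published"]
    if significant_only:
        if use_exact_p:
            recs = [rec for rec in recs if rec.exact_p() < alpha]
        else:
            recs = [rec for rec in recs if rec.p_value.significant(alpha)]
    if direction is not None:
        recs = [rec for rec in recs if np.sign(rec.r) == np.sign(direction)]
    return MetaDataset(list(recs), ds.provenance + "[filtered]")
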