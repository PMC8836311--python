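"""Pipeline orchestration and tidy plot-data export.

``run_pipeline`` executes the enabled stages in dependency order (dataset ->
core pooling -> bias / multiverse / GOSH / mediation), writes one CSV/JSON per
stage plus a single ``summary.json``, and logs per-stage record counts so the
funnel of k's (e.g. 105 -> 88 published -> 55 significant) is auditable.
Stochastic stages require seeds; identical configuration and seeds reproduce
every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bias as bias_mod
from .dataset import MetaDataset, filter_records, load_dataset, load_table1
from .gosh import gosh
from .mediation import fit_mediation, load_correlation_csv, pool_matrices
from .multiverse import SpecCurveAnalysis, SpecificationGrid
from .pooling import MetaRegression, RandomEffectsMeta, subgroup_test

log = logging.getLogger("specmeta")

__all__ = ["PipelineConfig", "run_pipeline", "export_plot_data"]


@dataclass
class PipelineConfig:
    """Which stages to run, with their sizes and seeds."""

    input_path: str | None = None          # None -> packaged dataset
    output_dir: str = "specmeta_out"
    stages: tuple[str, ...] = ("overall", "subgroups", "metaregression",
                               "bias", "multiverse")
    estimator: str = "REML"                # headline pooling estimator
    grid: SpecificationGrid = field(default_factory=SpecificationGrid)
    bootstrap_B: int = 0                   # 0 -> descriptive curve only
    gosh_subsets: int = 100_000
    mediation_input: str | None = None
    seed: int | None = None

    def __post_init__(self):
        stochastic = ("gosh" in self.stages or self.bootstrap_B > 0
                      or "mediation" in self.stages)
        if stochastic and self.seed is None:
            raise ValueError("a seed is required when stochastic stages are enabled")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the summary bundle."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}
    t_all = time.time()

    ds = load_dataset(cfg.input_path) if cfg.input_path else load_table1()
    log.info("dataset: k=%d, N=%d (%s)", ds.k, ds.total_n, ds.provenance)
    ds.to_csv(out / "dataset_validated.csv")
    summary["dataset"] = {"k": ds.k, "total_n": ds.total_n,
                          "provenance": ds.provenance}

    def stage(name):
        enabled = name in cfg.stages
        if enabled:
            log.info("stage %s: start", name)
        return enabled

    if stage("overall"):
        t = time.time()
        res = RandomEffectsMeta.from_dataset(ds).fit(cfg.estimator)
        summary["stages"]["overall"] = res.to_dict()
        log.info("stage overall: r=%.3f k=%d (%.2fs)", res.estimate_r, res.k,
                 time.time() - t)

    if stage("subgroups"):
        t = time.time()
        groups = {}
        for moderator, levels in [
            ("intelligence_type", ("iq", "gpa", "mixed")),
            ("religiosity_type", ("beliefs", "behavior", "mixed")),
            ("sample_type", ("precollege", "college", "noncollege")),
            ("publication_status", ("published", "unpublished")),
        ]:
            present = [lev for lev in levels if ds.where(**{moderator: lev}).k >= 2]
            if len(present) < 2:
                log.info("subgroups: %s skipped (<2 populated levels)", moderator)
                continue
            if len(present) < len(levels):
                log.info("subgroups: %s reduced to levels %s", moderator, present)
            comp = subgroup_test(ds, moderator, present, cfg.estimator)
            groups[moderator] = {
                "Q_between": comp.Q_between, "df": comp.df_between,
                "p": comp.p_between,
                "levels": {lev: r.to_dict() for lev, r in comp.group_results.items()},
            }
        summary["stages"]["subgroups"] = groups
        rows = [{"moderator": mod, "level": lev, **res}
                for mod, g in groups.items() for lev, res in g["levels"].items()]
        pd.DataFrame(rows).to_csv(out / "subgroups.csv", index=False,
                                  float_format="%.6f")
        log.info("stage subgroups: %d moderators (%.2fs)", len(groups), time.time() - t)

    if stage("metaregression"):
        t = time.time()
        mr = {}
        for name, mods in [("pct_men", ["pct_men"]), ("year", ["year"])]:
            try:
                fit = MetaRegression(ds, mods).fit()
            except (ValueError, np.linalg.LinAlgError) as exc:
                log.info("meta-regression on %s skipped: %s", name, exc)
                continue
            mr[name] = {"b": fit.params[mods[0]], "se": fit.se[mods[0]],
                        "p": fit.p[mods[0]], "R2": fit.R2, "k": fit.k,
                        "dropped": fit.n_dropped}
            log.info("meta-regression on %s: k=%d (dropped %d), b=%.4f",
                     name, fit.k, fit.n_dropped, fit.params[mods[0]])
        summary["stages"]["metaregression"] = mr
        log.info("stage metaregression done (%.2fs)", time.time() - t)

    if stage("bias"):
        t = time.time()
        published = filter_records(ds, published_only=True)
        log.info("bias: %d published of %d", published.k, ds.k)
        sig = filter_records(ds, published_only=True, significant_only=True,
                             direction=-1 if RandomEffectsMeta.from_dataset(ds)
                             .fit("DL").estimate < 0 else 1)
        log.info("bias: %d published significant direction-consistent", sig.k)
        reports = bias_mod.run_all_bias_methods(ds)
        summary["stages"]["bias"] = {k: v.to_dict() for k, v in reports.items()}
        with open(out / "bias.json", "w") as fh:
            json.dump(summary["stages"]["bias"], fh, indent=2, default=_json_default)
        bias_mod.funnel_plot_data(published).to_csv(out / "funnel_published.csv",
                                                    index=False)
        log.info("stage bias: %d methods (%.2fs)", len(reports), time.time() - t)

    if stage("multiverse"):
        t = time.time()
        analysis = SpecCurveAnalysis(ds, cfg.grid)
        curve = (analysis.fit(B=cfg.bootstrap_B, seed=cfg.seed)
                 if cfg.bootstrap_B else analysis.fit())
        curve.to_frame().to_csv(out / "spec_curve.csv", index=False,
                                float_format="%.6f")
        curve.p_value_histogram().to_csv(out / "spec_p_histogram.csv", index=False)
        summary["stages"]["multiverse"] = {
            "n_total": curve.n_total, "n_admissible": curve.n_admissible,
            "n_sig_negative": curve.n_sig_negative,
            "n_sig_positive": curve.n_sig_positive,
            "decision": curve.decision, "B": curve.n_boot,
        }
        log.info("stage multiverse: %d/%d admissible (%.2fs)",
                 curve.n_admissible, curve.n_total, time.time() - t)

    if stage("gosh"):
        t = time.time()
        g = gosh(ds, n_subsets=cfg.gosh_subsets, seed=cfg.seed)
        g.table.to_csv(out / "gosh.csv", index=False, float_format="%.6f")
        summary["stages"]["gosh"] = {
            "n_subsets": len(g.table), "exhaustive": g.exhaustive,
            "share_negative": g.share_negative,
            "share_ci_excludes_zero": g.share_ci_excludes_zero,
            "density_quantiles": g.density_quantiles(),
            "leverage_ids": g.leverage_ids,
        }
        log.info("stage gosh: %d subsets (%.2fs)", len(g.table), time.time() - t)

    if stage("mediation"):
        t = time.time()
        if cfg.mediation_input is None:
            raise ValueError("mediation stage needs --mediation-input "
                             "(per-study correlation triplets)")
        mats = load_correlation_csv(cfg.mediation_input)
        pooled = pool_matrices(mats)
        res = fit_mediation(pooled, seed=cfg.seed)
        summary["stages"]["mediation"] = {
            "k": pooled.k, "n_harmonic": pooled.n_harmonic,
            "total": res.total, "direct": res.direct, "indirect": res.indirect,
            "indirect_ci": list(res.indirect_ci), "direct_ci": list(res.direct_ci),
            "mediation_type": res.mediation_type,
            "pooled_matrix": pooled.matrix,
        }
        with open(out / "mediation.json", "w") as fh:
            json.dump(summary["stages"]["mediation"], fh, indent=2,
                      default=_json_default)
        log.info("stage mediation: k=%d (%.2fs)", pooled.k, time.time() - t)

    summary["elapsed_s"] = time.time() - t_all
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    log.info("pipeline done in %.2fs -> %s", summary["elapsed_s"], out)
    return summary


def export_plot_data(stage: str, results, out_path: str | Path) -> pd.DataFrame:
    """One tidy CSV per figure-equivalent: study rows for forest/funnel, rank
    rows for the specification curve, subset rows for GOSH, bin rows for
    p-value histograms."""
    if stage == "forest":
        df = results.to_frame() if isinstance(results, MetaDataset) else results
    elif stage == "funnel":
        df = bias_mod.funnel_plot_data(results)
    elif stage == "spec_curve":
        df = results.to_frame()
    elif stage == "spec_p_histogram":
        df = results.p_value_histogram()
    elif stage == "gosh":
        df = results.table
    else:
        raise ValueError(f"unknown stage {stage!r}")
    df.to_csv(out_path, index=False)
    return df
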