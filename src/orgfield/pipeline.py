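"""End-to-end pipeline: simulate → harmonize → refine → metrics → fit → report.

Every stage writes plain-text artifacts (CSV/GeoJSON/ASC/JSON) into the run
directory; a single global seed is fanned out to per-stage child seeds so a
rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from orgfield import harmonization, hurdle, io, metrics, refinement, synthetic
from orgfield.config import PipelineConfig

logger = logging.getLogger(__name__)

KEY = ["permit", "site", "year"]


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (< 2**31)."""
    ss = np.random.SeedSequence([seed, zlib.crc32(stage.encode()) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def summarize_table1(table: pd.DataFrame, crops: tuple[str, ...] = ()) -> pd.DataFrame:
    """Per-management-class summary: n, mean ± sd/sqrt(n) of field size, soil
    grade and use rates, overall and per selected crop.

    Single-observation groups report a missing SE; empty groups are omitted
    (with a warning in the log).
    """
    rows = []
    subsets = [("all", table)] + [(c, table[table.crop == c]) for c in crops]
    for label, sub in subsets:
        for organic, grp in sub.groupby("organic"):
            if len(grp) == 0:
                logger.warning("empty summary group %s/%s omitted", label, organic)
                continue
            row = {"subset": label, "management": "organic" if organic else "conventional",
                   "n": len(grp)}
            for col, name in [("area_adj_ha", "field_size_ha"), ("storie", "storie"),
                              ("rate_ai", "ai_rate"), ("rate_product", "product_rate")]:
                vals = grp[col].dropna()
                row[f"mean_{name}"] = float(vals.mean()) if len(vals) else np.nan
                row[f"se_{name}"] = (float(vals.std(ddof=1) / np.sqrt(len(vals)))
                                     if len(vals) > 1 else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def _confusion(labels: pd.DataFrame, truth: synthetic.TruthBundle) -> dict:
    t = truth.field_truth[KEY + ["organic_true"]].drop_duplicates(KEY)
    m = labels.merge(t, on=KEY, how="inner")
    tp = int((m.organic & m.organic_true).sum())
    fp = int((m.organic & ~m.organic_true).sum())
    fn = int((~m.organic & m.organic_true).sum())
    tn = int((~m.organic & ~m.organic_true).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": precision, "recall": recall}


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the report dict (also written to report.json).

    Any stage failure raises with the stage name; artifacts of completed
    stages stay on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    stage = "simulate"
    try:
        t0 = time.time()
        sim = dataclasses.replace(config.sim, seed=child_seed(config.seed, "simulate"))
        bundle = synthetic.simulate_all(sim, config.params)
        synthetic.write_bundle(bundle, outdir)
        logger.info("stage simulate done in %.1fs", time.time() - t0)

        stage = "harmonize"
        t0 = time.time()
        candidates, match_report = harmonization.harmonize(
            bundle["registry"], bundle["parcels"], bundle["sections"],
            bundle["fields"], buffer_m=config.buffer_m)
        candidates.to_csv(outdir / "candidates.csv", index=False)
        (outdir / "match_report.json").write_text(json.dumps(match_report.to_dict(), default=str))
        report["registry_match_rate"] = (
            match_report.n_matched / match_report.n_records if match_report.n_records else float("nan"))
        logger.info("stage harmonize done in %.1fs", time.time() - t0)

        stage = "refine"
        t0 = time.time()
        labels, history = refinement.refine_organic(
            candidates, bundle["applications"], bundle["products"],
            bundle["fields"], top_n=config.top_n)
        labels.to_csv(outdir / "organic_labels.csv", index=False)
        audit = [dataclasses.asdict(h) for h in history]
        (outdir / "refinement_audit.json").write_text(json.dumps(audit))
        report["identification"] = _confusion(labels, bundle["truth"])
        report["n_organic_fields"] = int(labels.organic.sum())
        logger.info("stage refine done in %.1fs (%d iterations)", time.time() - t0, len(history))

        stage = "metrics"
        t0 = time.time()
        table = metrics.build_analysis_table(
            bundle["fields"], bundle["applications"], bundle["products"], labels,
            surface=bundle["surface"], tox_table=bundle["tox"],
            idw_power=config.idw_power, pti_threshold=config.pti_threshold,
            seed=child_seed(config.seed, "metrics"))
        table.drop(columns=["geometry"], errors="ignore").to_csv(
            outdir / "analysis_table.csv", index=False)
        summary = summarize_table1(table, crops=tuple(
            c for c in config.focal_crops if c in set(table.crop)))
        summary.to_csv(outdir / "table1.csv", index=False)
        report["dropped_rows"] = {
            "missing_family": int(table.missing_family.sum()),
            "imputed_soil": int(table.get("storie_imputed", pd.Series(False, index=table.index)).sum()),
            "total_rows": len(table),
        }
        logger.info("stage metrics done in %.1fs", time.time() - t0)

        stage = "fit"
        t0 = time.time()
        effects_rows, fits_payload = [], {}
        for outcome in config.outcomes:
            spec = hurdle.HurdleSpec(outcome=outcome, n_nodes=20)
            try:
                fit = hurdle.fit_double_hurdle(table, spec)
            except (ValueError, hurdle.SeparationError) as exc:
                logger.warning("outcome %s skipped: %s", outcome, exc)
                continue
            effects_rows.append(_effect_row(outcome, fit))
            fits_payload[outcome] = _fit_payload(fit)
        effects = pd.DataFrame(effects_rows)
        effects.to_csv(outdir / "effects.csv", index=False)
        (outdir / "fits.json").write_text(json.dumps(fits_payload))
        report["effects"] = effects_rows

        if config.fit_crop_specific:
            crop_rows = []
            for crop in config.focal_crops:
                try:
                    cf = hurdle.fit_crop_specific(table, crop, hurdle.HurdleSpec(outcome="ai"))
                    crop_rows.append({**_effect_row("ai", cf), "crop": crop})
                except (ValueError, hurdle.SeparationError) as exc:
                    logger.warning("crop %s skipped: %s", crop, exc)
            pd.DataFrame(crop_rows).to_csv(outdir / "crop_effects.csv", index=False)
            report["crop_effects"] = crop_rows

        if config.apply_yield_gap:
            adjusted = hurdle.apply_yield_gap(table, config.params.yield_gap_table)
            gap_rows = []
            for outcome in config.outcomes:
                spec = hurdle.HurdleSpec(outcome=outcome, n_nodes=20)
                try:
                    fit = hurdle.fit_double_hurdle(adjusted, spec)
                except (ValueError, hurdle.SeparationError) as exc:
                    logger.warning("yield-gap outcome %s skipped: %s", outcome, exc)
                    continue
                gap_rows.append(_effect_row(outcome, fit))
            pd.DataFrame(gap_rows).to_csv(outdir / "effects_yield_gap.csv", index=False)
            report["effects_yield_gap"] = gap_rows
        logger.info("stage fit done in %.1fs", time.time() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(json.dumps(report, default=float))
    return report


def _effect_row(outcome: str, fit: hurdle.HurdleFit) -> dict:
    lo1, hi1 = fit.ame.ci95
    lo2, hi2 = fit.semi.ci95
    return {
        "outcome": outcome,
        "ame": fit.ame.estimate, "ame_se": fit.ame.se,
        "ame_ci_lo": lo1, "ame_ci_hi": hi1,
        "semi_elasticity": fit.semi.estimate, "semi_se": fit.semi.se,
        "semi_ci_lo": lo2, "semi_ci_hi": hi2,
        "n_h1": fit.h1.n_obs, "n_h2": fit.h2.n_obs,
    }


def _fit_payload(fit: hurdle.HurdleFit) -> dict:
    return {
        "h1": {"names": fit.h1.names, "params": fit.h1.params.tolist(),
               "se": fit.h1.se.tolist(), "tau2": fit.h1.tau2,
               "loglik": fit.h1.loglik, "aic": fit.h1.aic, "bic": fit.h1.bic,
               "n": fit.h1.n_obs, "n_groups": fit.h1.n_groups},
        "h2": {"names": fit.h2.names, "params": fit.h2.params.tolist(),
               "se": fit.h2.se.tolist(), "sigma2": fit.h2.sigma2,
               "tau2": fit.h2.tau2, "loglik": fit.h2.loglik,
               "aic": fit.h2.aic, "bic": fit.h2.bic,
               "n": fit.h2.n_obs, "n_groups": fit.h2.n_groups},
    }
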