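"""End-to-end pipeline: generate cohort -> simulate tasks -> fit models ->
correct ratings -> select models -> group statistics -> recovery report.

One mandatory global seed fans out into per-stage, per-participant
substreams, so the pipeline is idempotent for a fixed (config, seed) and a
partial rerun with some stages disabled reproduces the surviving stages
bit-for-bit.  The latent-truth table written by the generate stage is read
by the recovery report only — no inference stage ever sees it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cohort import GeneratorConfig, generate_cohort, generate_am_eft_scores, cohort_frame, truth_frame
from .discounting import MCMCConfig, fit_hierarchical, combine_and_refit, summarize_log_k
from .ratings import (RatingMCMCConfig, fit_rating_model, correct_time_ratings,
                      model_selection_table, MODELS)
from .stats import (welch_t, pearson_r, compare_independent_correlations,
                    addiction_severity, regress_log_k)
from .tasks import (StaircaseConfig, TimeSessionConfig, run_adaptive_task,
                    run_fixed_item_task, simulate_time_session,
                    simulate_circle_session, STANDARD_CIRCLE_TARGETS)

log = logging.getLogger("chronodisc")

__all__ = ["PipelineConfig", "StageToggles", "StageError", "run_pipeline", "recovery_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class StageToggles:
    generate: bool = True
    simulate: bool = True
    fit_discounting: bool = True
    fit_time: bool = True
    correct: bool = True
    select_model: bool = True
    stats: bool = True
    recovery: bool = True


@dataclass
class PipelineConfig:
    seed: int
    n_hc: int = 20
    n_pg: int = 20
    out_dir: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    time_session: TimeSessionConfig = field(default_factory=TimeSessionConfig)
    hier_mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    rating_mcmc: RatingMCMCConfig = field(default_factory=RatingMCMCConfig)
    stages: StageToggles = field(default_factory=StageToggles)
    include_eft_predictor: bool = True

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_hc < 2 or self.n_pg < 2:
            raise ValueError("need at least 2 participants per group for group comparisons")
        self.generator.validate()
        self.staircase.validate()

    def digest(self) -> str:
        blob = repr(sorted(repr(asdict(self)))).encode()
        return hashlib.sha256(repr(asdict(self)).encode()).hexdigest()[:16] or blob


def _write(df: pd.DataFrame, out: Path | None, name: str) -> None:
    if out is not None:
        df.to_csv(out / name, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages in order; returns the artifact bundle.

    Artifacts are returned in memory and, if ``out_dir`` is set, written as
    CSV (tables), text (the model-selection report), and JSON (manifest).
    """
    config.validate()
    out = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)

    seed = config.seed
    art: dict = {}
    stage_log: list[dict] = []

    def run_stage(name: str, enabled: bool, fn) -> None:
        if not enabled:
            log.info("stage %s: disabled, skipping", name)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # tag and re-raise; partial outputs stay in art
            art["incomplete"] = name
            raise StageError(f"[{name}] {exc}") from exc
        dt = time.perf_counter() - t0
        stage_log.append({"stage": name, "seconds": round(dt, 3)})
        log.info("stage %s finished in %.1fs", name, dt)

    # ---- generate -------------------------------------------------------
    def _generate():
        cohort = generate_cohort(config.n_hc, config.n_pg, config.generator, seed=seed)
        art["cohort"] = cohort
        art["participants"] = cohort_frame(cohort)
        art["truth"] = truth_frame(cohort)
        ami_rows = []
        for p, prof in cohort:
            am, eft = generate_am_eft_scores(
                prof, config.generator.am_eft_rho, seed,
                sd_am=config.generator.details_sd, sd_eft=config.generator.details_sd,
                participant=p.id)
            ami_rows.append({"participant": p.id, "group": p.group,
                             "am_sum": am, "eft_sum": eft})
        art["ami"] = pd.DataFrame(ami_rows)
        _write(art["participants"], out, "cohort.csv")
        _write(art["truth"], out, "latent_truth.csv")
        _write(art["ami"], out, "ami_scores.csv")

    run_stage("generate", config.stages.generate, _generate)
    if "cohort" not in art:
        raise StageError("[generate] downstream stages need the generate stage enabled")
    cohort = art["cohort"]
    groups = {p.id: p.group for p, _ in cohort}

    # ---- simulate -------------------------------------------------------
    def _simulate():
        adaptive, fixed, times, circles, indiff_rows = {}, {}, {}, {}, []
        for p, prof in cohort:
            ds, ip = run_adaptive_task(prof, config.staircase, seed=seed, participant=p.id)
            adaptive[p.id] = ds
            indiff_rows += [{"participant": p.id, "delay": d, "indifference": v}
                            for d, v in ip.items()]
            fixed[p.id] = run_fixed_item_task(prof, seed=seed, participant=p.id)
            tsess = simulate_time_session(prof, config=config.time_session,
                                          seed=seed, participant=p.id)
            times[p.id] = tsess
            targets = list(STANDARD_CIRCLE_TARGETS) + [
                min(100.0, t.diameter * 100.0) for t in tsess.trials]
            circles[p.id] = simulate_circle_session(prof, targets, seed=seed, participant=p.id)
        art.update(adaptive=adaptive, fixed=fixed, time_sessions=times,
                   circle_sessions=circles)
        art["indifference"] = pd.DataFrame(indiff_rows)
        _write(pd.concat([d.to_frame() for d in adaptive.values()]), out, "choices_adaptive.csv")
        _write(pd.concat([d.to_frame() for d in fixed.values()]), out, "choices_fixed.csv")
        _write(pd.concat([s.to_frame() for s in list(times.values()) + list(circles.values())]),
               out, "ratings.csv")
        _write(art["indifference"], out, "indifference_points.csv")

    run_stage("simulate", config.stages.simulate, _simulate)

    # ---- fit_discounting ------------------------------------------------
    def _fit_discounting():
        adaptive, fixed = art["adaptive"], art["fixed"]
        art["fit_adaptive"] = fit_hierarchical(adaptive, groups, config.hier_mcmc, seed=seed)
        art["fit_fixed"] = fit_hierarchical(fixed, groups, config.hier_mcmc, seed=seed + 1)
        art["fit_combined"] = combine_and_refit(adaptive, fixed, groups,
                                                config.hier_mcmc, seed=seed + 2)
        _write(art["fit_combined"].summary, out, "discounting_posterior.csv")

    run_stage("fit_discounting", config.stages.fit_discounting and "adaptive" in art,
              _fit_discounting)

    # ---- fit_time -------------------------------------------------------
    def _fit_time():
        dic_rows, circle_power = [], {}
        for p, _ in cohort:
            for analysis, sess in (("delay", art["time_sessions"][p.id]),
                                   ("circle", art["circle_sessions"][p.id])):
                for model in MODELS:
                    fit = fit_rating_model(sess, model, config.rating_mcmc, seed=seed)
                    dic_rows.append({"participant": p.id, "group": p.group,
                                     "analysis": analysis, "model": model, "dic": fit.dic})
                    if analysis == "circle" and model == "power":
                        circle_power[p.id] = fit
        art["dic_rows"] = dic_rows
        art["circle_power_fits"] = circle_power

    run_stage("fit_time", config.stages.fit_time and "time_sessions" in art, _fit_time)

    # ---- correct --------------------------------------------------------
    def _correct():
        corrected, power_fits = {}, {}
        for p, _ in cohort:
            corr = correct_time_ratings(art["time_sessions"][p.id],
                                        art["circle_power_fits"][p.id])
            corrected[p.id] = corr
            for model in MODELS:
                fit = fit_rating_model(corr, model, config.rating_mcmc, seed=seed)
                art["dic_rows"].append({"participant": p.id, "group": p.group,
                                        "analysis": "corrected delay",
                                        "model": model, "dic": fit.dic})
                if model == "power":
                    power_fits[p.id] = fit
        art["corrected"] = corrected
        art["corrected_power_fits"] = power_fits
        _write(pd.concat([c.to_frame() for c in corrected.values()]), out,
               "corrected_ratings.csv")

    run_stage("correct", config.stages.correct and "circle_power_fits" in art, _correct)

    # ---- select_model ---------------------------------------------------
    def _select():
        table = model_selection_table(pd.DataFrame(art["dic_rows"]))
        art["dic_table"] = table
        _write(table, out, "dic_table.csv")
        if out is not None:
            lines = ["Model selection (summed DIC; smaller is better; * = winner)", ""]
            for row in table.itertuples(index=False):
                star = " *" if row.winner else ""
                lines.append(f"{row.analysis:>16} {row.group:>4} {row.model:>10} "
                             f"{row.summed_dic:10.2f}{star}")
            (out / "model_selection.txt").write_text("\n".join(lines) + "\n")

    run_stage("select_model", config.stages.select_model and "dic_rows" in art, _select)

    # ---- stats ----------------------------------------------------------
    def _stats():
        parts = art["participants"]
        hc = parts[parts.group == "HC"]
        pg = parts[parts.group == "PG"]
        rows = []
        for covar in ("bdi", "ftnd", "audit", "kfg", "sogs", "age"):
            t, df_, p_, d = welch_t(hc[covar], pg[covar])
            rows.append({"analysis": f"welch_{covar}", "statistic": "t",
                         "value": t, "df": df_, "p": p_, "extra": d})
        sev = addiction_severity(parts["kfg"], parts["sogs"])
        parts = parts.assign(severity=sev)
        ami = art.get("ami")
        if ami is not None:
            for g, sub in ami.groupby("group"):
                r, p_ = pearson_r(sub["am_sum"], sub["eft_sum"])
                rows.append({"analysis": f"am_eft_r_{g}", "statistic": "r",
                             "value": r, "df": len(sub) - 2, "p": p_, "extra": np.nan})
            r_hc, _ = pearson_r(ami[ami.group == "HC"]["am_sum"], ami[ami.group == "HC"]["eft_sum"])
            r_pg, _ = pearson_r(ami[ami.group == "PG"]["am_sum"], ami[ami.group == "PG"]["eft_sum"])
            z, p_ = compare_independent_correlations(
                r_hc, (ami.group == "HC").sum(), r_pg, (ami.group == "PG").sum())
            rows.append({"analysis": "am_eft_r_compare", "statistic": "z",
                         "value": z, "df": np.nan, "p": p_, "extra": np.nan})
        if "fit_combined" in art:
            logk = summarize_log_k(art["fit_combined"]).set_index("participant")["log_k"]
            t, df_, p_, d = welch_t(logk[hc.id], logk[pg.id])
            rows.append({"analysis": "welch_log_k", "statistic": "t",
                         "value": t, "df": df_, "p": p_, "extra": d})
            predictors = {
                "audit": parts.set_index("id").loc[logk.index, "audit"].to_numpy(),
                "ftnd": parts.set_index("id").loc[logk.index, "ftnd"].to_numpy(),
                "bdi": parts.set_index("id").loc[logk.index, "bdi"].to_numpy(),
                "group": parts.set_index("id").loc[logk.index, "group"].to_numpy(),
            }
            if "corrected_power_fits" in art:
                predictors["b_exponent"] = np.array(
                    [art["corrected_power_fits"][pid].medians["b"] for pid in logk.index])
            if ami is not None:
                predictors["eft_sum"] = ami.set_index("participant").loc[logk.index, "eft_sum"].to_numpy()
            if len(logk) > len(predictors) + 2:
                reg = regress_log_k(logk.to_numpy(), predictors,
                                    include_eft=config.include_eft_predictor)
                art["regression"] = reg
                _write(reg.to_frame().assign(adj_r2=reg.adj_r2, n=reg.n), out, "regression.csv")
            else:
                log.warning("stats: cohort too small for the multiple regression; skipped")
        art["stats"] = pd.DataFrame(rows)
        _write(art["stats"], out, "stats.csv")

    run_stage("stats", config.stages.stats, _stats)

    # ---- recovery -------------------------------------------------------
    def _recovery():
        b_time = None
        if "corrected_power_fits" in art:
            b_time = {pid: f.medians["b"] for pid, f in art["corrected_power_fits"].items()}
        art["recovery"] = recovery_report(art["truth"], art.get("fit_combined"), b_time)
        _write(art["recovery"], out, "recovery.csv")

    run_stage("recovery", config.stages.recovery and "fit_combined" in art, _recovery)

    # ---- manifest -------------------------------------------------------
    manifest = {
        "config_digest": config.digest(),
        "seed": seed,
        "version": _version,
        "stages": stage_log,
        "complete": "incomplete" not in art,
    }
    art["manifest"] = manifest
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return art


def recovery_report(truth: pd.DataFrame | None, fit, b_time_estimates: dict | None = None
                    ) -> pd.DataFrame:
    """Join inferred parameters to latent truth; one row per parameter with
    the recovery correlation, bias, and RMSE.

    ``truth`` is the latent-truth table from the generate stage; running in
    real-data mode (no truth table) is refused since recovery is only
    defined for synthetic cohorts.
    """
    if truth is None:
        raise ValueError("no latent-truth table: recovery reports require a synthetic "
                         "cohort; for real data, inspect the posterior summaries instead")
    rows = []
    t = truth.set_index("id")
    if fit is not None:
        s = fit.summary.set_index("participant")
        for name, true_col, est_col in (("log_k", "log_k", "log_k"),
                                        ("log_beta", "beta", "log_beta")):
            true = t[true_col].reindex(s.index).to_numpy(float)
            if true_col == "beta":
                true = np.log(true)
            est = s[est_col].to_numpy(float)
            r, _ = pearson_r(true, est)
            rows.append({"parameter": name, "r": r,
                         "bias": float(np.mean(est - true)),
                         "rmse": float(np.sqrt(np.mean((est - true) ** 2))),
                         "n": len(est)})
    if b_time_estimates:
        pids = list(b_time_estimates)
        true = t["b_time"].reindex(pids).to_numpy(float)
        est = np.array([b_time_estimates[p] for p in pids])
        r, _ = pearson_r(true, est)
        rows.append({"parameter": "b_time", "r": r,
                     "bias": float(np.mean(est - true)),
                     "rmse": float(np.sqrt(np.mean((est - true) ** 2))),
                     "n": len(est)})
    if not rows:
        raise ValueError("nothing to report: no fits supplied")
    return pd.DataFrame(rows)
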