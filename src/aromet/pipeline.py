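"""End-to-end orchestration: cohort -> screening -> split -> model -> validation.

``run_pipeline`` sequences the whole prognostic workflow and writes a
reproducible report bundle: the serialized one-class models (8 analytes and
7 analytes without p-HPhLA), the six-group assignment, four ROC curves
(both multivariate models, the univariate p-HPhLA marker and the clinical
APACHE II score), distance plots and a markdown report.  Every random choice
derives from the single configured seed, so a rerun reproduces the JSON
artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import simca, validation
from .duplex import split_modeled_class
from .cohort import Cohort, CohortTable, read_cohort, write_cohort
from .preprocess import (
    SplitAssignment,
    assign_groups,
    autoscale,
    impute_half_min,
    imputed_concentration_matrix,
    screen_outliers,
)
from .synthetic import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "plot_distances", "plot_roc"]

logger = logging.getLogger("aromet")

APACHE_CUTOFF = 19  # fixed clinical decision rule: negative prognosis from 20 points


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one reproducible run.

    Either ``cohort_csv`` (an existing cohort table) or ``cohort`` (generator
    settings) supplies the data.  The default generator settings emulate the
    study population, including an outlier rate that yields roughly 15
    atypically high survivor samples.
    """

    cohort_csv: str | None = None
    cohort: CohortConfig = field(
        default_factory=lambda: CohortConfig(outlier_rate=0.19, outlier_multiplier=20.0)
    )
    alpha: float = 0.01
    gamma: float = 0.01
    n_components: int = 3
    ratio: tuple[float, float] = (2, 1)
    excluded_variable: str = "p_hphla"
    seed: int = 0
    outdir: str = "aromet_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.gamma < 1:
            raise ValueError("alpha and gamma must lie in (0, 1)")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def _roc_to_csv(curve: validation.RocCurve, path: Path) -> None:
    lines = ["threshold,fpr,tpr"]
    for t, x, y in zip(curve.thresholds, curve.fpr, curve.tpr):
        lines.append(f"{t!r},{x!r},{y!r}")
    path.write_text("\n".join(lines) + "\n")


@_stage("synth")
def _load_or_generate(config: PipelineConfig) -> CohortTable:
    if config.cohort_csv is not None:
        logger.info("stage=synth action=load path=%s", config.cohort_csv)
        return read_cohort(config.cohort_csv)
    cohort_cfg = replace(config.cohort, seed=config.seed)
    logger.info("stage=synth action=generate seed=%d", config.seed)
    return generate_cohort(cohort_cfg)


@_stage("preprocess")
def _screen_and_assign(table: CohortTable, config: PipelineConfig):
    survivor_rows = table.indices(cohort=Cohort.SURVIVOR)
    flags_arr = screen_outliers(table, survivor_rows, gamma=config.gamma,
                                n_components=config.n_components)
    flags = dict(zip(survivor_rows, map(bool, flags_arr)))
    pre = assign_groups(table, flags)
    logger.info(
        "stage=preprocess n_flagged=%d n_modeled=%d n_outlier_group=%d",
        sum(flags.values()), len(pre.modeled), len(pre.survivors_outliers),
    )
    return flags, pre


@_stage("split")
def _split(table: CohortTable, flags, pre: SplitAssignment, config: PipelineConfig):
    modeled = list(pre.modeled)
    X = table.area_matrix(modeled)
    keep = np.flatnonzero(X.std(axis=0, ddof=1) > 0)
    X_scaled, _ = autoscale(X[:, keep])
    labels = [table.samples[i].cohort.value for i in modeled]
    result = split_modeled_class(X_scaled, labels, config.ratio)
    cal = [modeled[i] for i in result.calibration]
    test = [modeled[i] for i in result.test]
    assignment = assign_groups(table, flags, split=(cal, test))
    logger.info("stage=split n_cal=%d n_test=%d", len(cal), len(test))
    return assignment


@_stage("fit")
def _fit_models(table: CohortTable, assignment: SplitAssignment, config: PipelineConfig):
    cal = list(assignment.calibration)
    X_cal = table.area_matrix(cal)
    model8 = simca.fit_simca(
        X_cal, n_components=config.n_components, alpha=config.alpha,
        variables=table.panel.analytes, drop_constant=True,
    )
    vars7 = [a for a in table.panel.analytes if a != config.excluded_variable]
    model7 = simca.fit_simca(
        table.area_matrix(cal, vars7), n_components=config.n_components,
        alpha=config.alpha, variables=vars7, drop_constant=True,
    )
    logger.info(
        "stage=fit Nh=%d Nv=%d f_crit=%.3f n_vars8=%d n_vars7=%d",
        model8.dist.Nh, model8.dist.Nv, model8.dist.f_crit,
        len(model8.variables), len(model7.variables),
    )
    return model8, model7


@_stage("validate")
def _validate(table: CohortTable, assignment: SplitAssignment,
              model8: simca.SimcaModel, model7: simca.SimcaModel,
              config: PipelineConfig):
    cal = list(assignment.calibration)
    test = list(assignment.test)
    pool = cal + test
    nonsurv = list(assignment.non_survivors)
    if not nonsurv:
        raise ValueError("one class empty: no non-survivor admission samples for ROC")

    def fn_rates(model):
        acc_cal, _ = simca.classify(model, table.area_matrix(cal, model.variables))
        X_cal_scaled, _ = autoscale(
            table.area_matrix(cal, model.variables), model.pca.scaling
        )
        pv = validation.procrustes_cv(X_cal_scaled, config.n_components)
        acc_pv, _ = simca.classify(model, pv.matrix, scaled=True)
        rates = {
            "calibration": round(simca.false_negative_rate(acc_cal), 3),
            "pcv": round(simca.false_negative_rate(acc_pv), 3),
        }
        if test:
            acc_test, _ = simca.classify(model, table.area_matrix(test, model.variables))
            rates["test"] = round(simca.false_negative_rate(acc_test), 3)
        return rates

    def roc_for(scores_pool, scores_nonsurv):
        scores = np.concatenate([scores_pool, scores_nonsurv])
        labels = np.r_[np.zeros(len(scores_pool), bool), np.ones(len(scores_nonsurv), bool)]
        return validation.roc(scores, labels)

    _, f8_pool = simca.classify(model8, table.area_matrix(pool, model8.variables))
    _, f8_ns = simca.classify(model8, table.area_matrix(nonsurv, model8.variables))
    _, f7_pool = simca.classify(model7, table.area_matrix(pool, model7.variables))
    _, f7_ns = simca.classify(model7, table.area_matrix(nonsurv, model7.variables))

    conc = imputed_concentration_matrix(table, variables=["p_hphla"])
    phphla_pool = conc[pool, 0]
    phphla_ns = conc[nonsurv, 0]

    def apache_scores(rows):
        out = []
        for i in rows:
            s = table.samples[i]
            out.append(0.0 if s.cohort is Cohort.HEALTHY else float(s.apache2 or 0))
        return np.array(out)

    curves = {
        "simca_8": roc_for(f8_pool, f8_ns),
        "simca_7": roc_for(f7_pool, f7_ns),
        "p_hphla": roc_for(phphla_pool, phphla_ns),
        "apache2": roc_for(apache_scores(pool), apache_scores(nonsurv)),
    }
    cutoff = simca.univariate_cutoff(phphla_pool, alpha=config.alpha)
    logger.info(
        "stage=validate auc8=%.3f auc7=%.3f auc_phphla=%.3f auc_apache=%.3f cutoff=%.2f",
        curves["simca_8"].auc, curves["simca_7"].auc, curves["p_hphla"].auc,
        curves["apache2"].auc, cutoff,
    )
    return fn_rates(model8), fn_rates(model7), curves, cutoff


def _group_statistics(table: CohortTable) -> list[dict]:
    """Per-analyte Kruskal-Wallis across the three admission-day groups, Holm-adjusted."""
    groups = {
        "healthy": table.indices(cohort=Cohort.HEALTHY),
        "survivor": [i for i in table.indices(cohort=Cohort.SURVIVOR)
                     if table.samples[i].day == 0],
        "non_survivor": table.indices(cohort=Cohort.NON_SURVIVOR, day=0),
    }
    rows = []
    raw_p = []
    for a in table.panel.analytes:
        try:
            column = impute_half_min(table.measurement_column(a))
        except ValueError:  # analyte never quantified in this cohort
            continue
        vals = {g: column[idx] for g, idx in groups.items() if idx}
        if len(vals) < 2:
            continue
        H, p = validation.kruskal_wallis(list(vals.values()))
        med = {g: float(np.median(v)) for g, v in vals.items()}
        rows.append({"analyte": a, "H": round(H, 2), "p_raw": p, "medians": med})
        raw_p.append(p)
    if rows:
        adj = validation.holm_adjust(raw_p)
        for row, pa in zip(rows, adj):
            row["p_holm"] = float(pa)
            row["p_raw"] = float(row["p_raw"])
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table = _load_or_generate(config)
    if config.cohort_csv is None:
        write_cohort(table, outdir / "cohort.csv")
    flags, pre = _screen_and_assign(table, config)
    assignment = _split(table, flags, pre, config)
    model8, model7 = _fit_models(table, assignment, config)
    fn8, fn7, curves, cutoff = _validate(table, assignment, model8, model7, config)
    stats_rows = _group_statistics(table)

    # ---- serialize ---------------------------------------------------------
    _json_dump(assignment.to_dict(), outdir / "groups.json")
    (outdir / "model_8.json").write_text(simca.model_to_json(model8) + "\n")
    (outdir / "model_7.json").write_text(simca.model_to_json(model7) + "\n")
    for name, curve in curves.items():
        _roc_to_csv(curve, outdir / f"roc_{name}.csv")

    summary = {
        "seed": config.seed,
        "alpha": config.alpha,
        "gamma": config.gamma,
        "n_components": config.n_components,
        "counts": {k: len(v) for k, v in assignment.to_dict().items()},
        "n_samples": len(table),
        "n_subjects": table.n_subjects(),
        "false_negative_rates": {"simca_8": fn8, "simca_7": fn7},
        "auc": {name: round(curve.auc, 3) for name, curve in curves.items()},
        "univariate_cutoff_p_hphla": round(cutoff, 2),
        "apache2_cutoff": APACHE_CUTOFF,
        "model_8": {"Nh": model8.dist.Nh, "Nv": model8.dist.Nv,
                    "h0": model8.dist.h0, "v0": model8.dist.v0,
                    "f_crit": model8.dist.f_crit,
                    "variables": list(model8.variables)},
        "model_7": {"Nh": model7.dist.Nh, "Nv": model7.dist.Nv,
                    "h0": model7.dist.h0, "v0": model7.dist.v0,
                    "f_crit": model7.dist.f_crit,
                    "variables": list(model7.variables)},
        "group_statistics": stats_rows,
    }
    _json_dump(summary, outdir / "summary.json")

    # ---- figures & report --------------------------------------------------
    try:
        plot_distances(model8, table, assignment, outdir / "distances_8_2d.png", mode="2d")
        plot_distances(model8, table, assignment, outdir / "distances_8_1d.png",
                       mode="1d", seed=config.seed)
        plot_distances(model7, table, assignment, outdir / "distances_7_1d.png",
                       mode="1d", seed=config.seed)
        plot_roc(curves, outdir / "roc.png")
    except Exception as exc:  # plotting must never invalidate the numbers
        logger.warning("figure generation failed: %s", exc)

    (outdir / "report.md").write_text(_render_report(summary))
    return summary


def _render_report(summary: dict) -> str:
    lines = [
        "# Prognostic-model run report",
        "",
        f"Seed {summary['seed']}, alpha {summary['alpha']}, gamma {summary['gamma']}, "
        f"{summary['n_components']} principal components.",
        "",
        f"Cohort: {summary['n_samples']} samples from {summary['n_subjects']} subjects.",
        "",
        "## Sample groups",
        "",
        "| group | n |",
        "|---|---|",
    ]
    for k, v in summary["counts"].items():
        lines.append(f"| {k} | {v} |")
    lines += [
        "",
        "## One-class models",
        "",
        "| model | Nh | Nv | f_crit | FN cal | FN PCV | FN test |",
        "|---|---|---|---|---|---|---|",
    ]
    for key in ("model_8", "model_7"):
        m = summary[key]
        fn = summary["false_negative_rates"]["simca_8" if key == "model_8" else "simca_7"]
        lines.append(
            f"| {key} ({len(m['variables'])} vars) | {m['Nh']} | {m['Nv']} | "
            f"{m['f_crit']:.3f} | {fn['calibration']} | {fn['pcv']} | {fn.get('test', '-')} |"
        )
    lines += [
        "",
        "## Prognostic performance (AUC)",
        "",
        "| score | AUC |",
        "|---|---|",
    ]
    for name, auc in summary["auc"].items():
        lines.append(f"| {name} | {auc} |")
    lines += [
        "",
        f"Univariate p-HPhLA cutoff (data-driven, alpha={summary['alpha']}): "
        f"{summary['univariate_cutoff_p_hphla']} µmol/L; "
        f"APACHE II clinical cutoff: {summary['apache2_cutoff']} points.",
        "",
        "## Group comparison (Kruskal-Wallis, Holm-adjusted)",
        "",
        "| analyte | H | p (Holm) | medians (healthy / survivor / non-survivor) |",
        "|---|---|---|---|",
    ]
    for row in summary["group_statistics"]:
        med = row["medians"]
        meds = " / ".join(
            f"{med.get(g, float('nan')):.2f}" for g in ("healthy", "survivor", "non_survivor")
        )
        lines.append(f"| {row['analyte']} | {row['H']} | {row['p_holm']:.2g} | {meds} |")
    lines.append("")
    return "\n".join(lines)


# ---- plotting --------------------------------------------------------------

_GROUP_STYLE = {
    "calibration": ("tab:blue", "o"),
    "test": ("tab:cyan", "s"),
    "survivors_outliers": ("tab:orange", "^"),
    "survivors_others": ("tab:green", "v"),
    "non_survivors": ("tab:red", "x"),
    "non_survivors_others": ("tab:purple", "+"),
}


def plot_distances(model: simca.SimcaModel, table: CohortTable,
                   assignment: SplitAssignment, path, mode: str = "2d",
                   seed: int = 0) -> None:
    """Distance plot of all six groups with the acceptance boundary.

    ``2d``: log(1 + h/h0) vs log(1 + v/v0) with the decision curve; ``1d``:
    full distance on a log axis with vertical jitter and the decision rule as
    a vertical line.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = model.dist
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(7, 5))
    for name, rows in assignment.to_dict().items():
        if not rows:
            logger.warning("plot: empty group %s omitted from legend", name)
            continue
        X = table.area_matrix(rows, model.variables)
        h, v = simca.distances(model.pca, X)
        color, marker = _GROUP_STYLE[name]
        if mode == "2d":
            ax.scatter(np.log1p(h / d.h0), np.log1p(v / d.v0), s=22,
                       c=color, marker=marker, label=name)
        else:
            f = simca.full_distance(h, v, d)
            ax.scatter(1.0 + f, rng.uniform(0, 1, size=len(rows)), s=22,
                       c=color, marker=marker, label=name)
    if mode == "2d":
        u = np.linspace(0, d.f_crit / d.Nh, 200)
        w = (d.f_crit - d.Nh * u) / d.Nv
        ax.plot(np.log1p(u), np.log1p(w), "k-", lw=1.5)
        ax.set_xlabel("log(1 + h/h0)")
        ax.set_ylabel("log(1 + v/v0)")
    else:
        ax.axvline(1.0 + d.f_crit, color="k", lw=1.5)
        ax.set_xscale("log")
        ax.set_xlabel("1 + full distance")
        ax.set_yticks([])
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_roc(curves: dict, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5))
    for name, curve in curves.items():
        ax.plot(curve.fpr, curve.tpr, label=f"{name} (AUC {curve.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
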