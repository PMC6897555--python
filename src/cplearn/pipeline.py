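"""End-to-end orchestration: generate → simulate → analyze → report.

``run_pipeline`` wires the stages together for a synthetic cohort: stimulus
and schedule generation, per-subject trial logs and ratings, learning-curve
classification, CP statistics, the ERP measurement chain keyed to each
subject's learning point, cohort-level correlations, and the neural-net sweep.
Outputs are plain CSV/JSON files plus a manifest recording every seed and
analysis constant, so a report is exactly reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    block_summaries,
    classify_learner,
    cp_stats,
    spearman_fisher,
    split_trials,
    window_accuracy,
)
from .erp import (
    LPC_DEFAULT,
    N1_DEFAULT,
    ComponentWindow,
    SubjectExcluded,
    baseline_correct,
    component_mean,
    reject_extreme,
    reject_probability,
    split_and_average,
)
from .netmodel import NetConfig, sweep_k
from .stimuli import build_schedule, make_scheme, make_set, sample_rating_pairs
from .synthdata import gen_cohort

log = logging.getLogger("cplearn")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Every analysis constant of the pipeline, with its study default."""

    out_dir: str = "cplearn-run"
    seed: int = 0
    k: int = 4                      # covariant feature pairs (difficulty)
    n_stimuli: int = 180
    n_trials: int = 400
    n_subjects: int = 12
    mix: dict = field(
        default_factory=lambda: {"Learner": 0.65, "NonLearner": 0.25, "Borderline": 0.10}
    )
    criterion: float = 0.80         # learning criterion (proportion correct)
    window_width: int = 20          # learning-curve window (trials)
    min_remaining_trials: int = 60  # sustained run must span at least this
    extreme_limit_uv: float = 100.0
    single_sd: float = 2.0
    global_sd: float = 6.0
    n1_window_ms: tuple = (150.0, 220.0)
    lpc_window_ms: tuple = (600.0, 800.0)
    n1_cluster: tuple = N1_DEFAULT.cluster
    lpc_cluster: tuple = LPC_DEFAULT.cluster
    success_threshold: float = 1e-3  # net learner criterion (regularized MSE)
    net_k_values: tuple = (3, 4, 5, 6)
    net_seeds: tuple = tuple(range(10))
    include_epochs: bool = True


def _analyze_subject_erp(cfg: RunConfig, cohort, i, assessment, n1_cw, lpc_cw):
    """ERP chain for one subject; returns measure rows and rejection counts."""
    lp = assessment.learning_point
    epochs = cohort.epochs_for(i, learning_point=lp)
    epochs = baseline_correct(epochs)
    epochs, rej_ext = reject_extreme(epochs, limit=cfg.extreme_limit_uv)
    epochs, rej_prob = reject_probability(
        epochs, single_sd=cfg.single_sd, global_sd=cfg.global_sd
    )
    before_idx, after_idx = split_trials(assessment, cfg.n_trials)
    erp_before, erp_after = split_and_average(
        epochs, before_idx, after_idx,
        n_scheduled=(len(before_idx), len(after_idx)),
    )
    rows = []
    sid = cohort.logs[i].subject_id
    for cw in (n1_cw, lpc_cw):
        for cond, erp_ in (("before", erp_before), ("after", erp_after)):
            m = component_mean(erp_, cw, subject_id=sid, condition=cond)
            rows.append(
                {
                    "subject_id": sid,
                    "component": cw.name,
                    "condition": cond,
                    "mean_voltage": m.mean_voltage,
                }
            )
    return rows, len(rej_ext) + len(rej_prob)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic study and write cohort-level reports.

    Returns the report tables as DataFrames keyed by name; the same tables are
    written as CSV under ``cfg.out_dir`` together with ``manifest.json``.
    Per-subject failures are logged and skipped; the run continues.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stimuli -----------------------------------------------------------
    scheme = make_scheme(cfg.k, seed=cfg.seed)
    stim_set = make_set(scheme, n=cfg.n_stimuli, seed=cfg.seed)
    schedule = build_schedule(stim_set, n_trials=cfg.n_trials, seed=cfg.seed)
    pairs = sample_rating_pairs(stim_set, seed=cfg.seed)
    stim_set.manifest().to_csv(out / "stimuli.csv", index=False)
    (out / "scheme.json").write_text(scheme.to_json())
    (out / "schedule.json").write_text(schedule.to_json())

    # --- synthetic cohort --------------------------------------------------
    cohort = gen_cohort(
        cfg.n_subjects, mix=cfg.mix, seed=cfg.seed, pairs=pairs,
        n_trials=cfg.n_trials,
    )

    n1_cw = ComponentWindow("N1", cfg.n1_window_ms, cfg.n1_cluster)
    lpc_cw = ComponentWindow("LPC", cfg.lpc_window_ms, cfg.lpc_cluster)

    assess_rows, cp_rows, erp_rows, block_rows = [], [], [], []
    rejected_counts = {}
    for i, trial_log in enumerate(cohort.logs):
        sid = trial_log.subject_id
        try:
            acc = window_accuracy(trial_log, width=cfg.window_width)
            assessment = classify_learner(
                acc, subject_id=sid, width=cfg.window_width,
                criterion=cfg.criterion,
                min_remaining_trials=cfg.min_remaining_trials,
            )
            assess_rows.append(
                {
                    "subject_id": sid,
                    "archetype": cohort.profiles[i].archetype,
                    "status": assessment.status,
                    "learning_point": assessment.learning_point,
                    "last_block_accuracy": float(
                        block_summaries(trial_log)["accuracy"].iloc[-1]
                    ),
                }
            )
            for _, row in block_summaries(trial_log).iterrows():
                block_rows.append({"subject_id": sid, **row.to_dict()})
            if cohort.ratings:
                s = cp_stats(cohort.ratings[i])
                cp_rows.append(
                    {
                        "subject_id": sid,
                        "status": assessment.status,
                        "w_pre": s.w_pre, "w_post": s.w_post,
                        "b_pre": s.b_pre, "b_post": s.b_post,
                        "diff_w": s.diff_w, "diff_b": s.diff_b,
                        "global_cp": s.global_cp,
                    }
                )
            if cfg.include_epochs and assessment.status != "Immediate":
                rows, n_rej = _analyze_subject_erp(
                    cfg, cohort, i, assessment, n1_cw, lpc_cw
                )
                erp_rows.extend(rows)
                rejected_counts[sid] = n_rej
        except SubjectExcluded as e:
            log.warning("subject %s excluded from ERP analysis: %s", sid, e)
        except Exception:
            log.exception("subject %s failed; skipping", sid)

    report = {
        "assessments": pd.DataFrame(assess_rows),
        "blocks": pd.DataFrame(block_rows),
        "cp_stats": pd.DataFrame(cp_rows),
        "cluster_measures": pd.DataFrame(erp_rows),
    }

    # --- correlations: ERP change vs last-block accuracy -------------------
    corr_rows = []
    if erp_rows:
        cm = report["cluster_measures"].pivot_table(
            index=["subject_id", "component"], columns="condition",
            values="mean_voltage",
        ).reset_index()
        cm["change"] = cm["after"] - cm["before"]
        acc_by_sid = report["assessments"].set_index("subject_id")[
            "last_block_accuracy"
        ]
        for comp in ("N1", "LPC"):
            sub = cm[cm["component"] == comp]
            x = sub["change"].to_numpy()
            y = acc_by_sid.reindex(sub["subject_id"]).to_numpy()
            if len(x) >= 4 and np.ptp(x) > 0 and np.ptp(y) > 0:
                r = spearman_fisher(x, y)
                corr_rows.append(
                    {
                        "component": comp,
                        "rho": r.rho, "n": r.n, "fisher_z": r.fisher_z,
                        "ci_low": r.ci95[0], "ci_high": r.ci95[1], "p": r.p,
                    }
                )
    report["correlations"] = pd.DataFrame(corr_rows)

    # --- neural-net sweep --------------------------------------------------
    base_net = NetConfig(success_threshold=cfg.success_threshold)
    report["net_sweep"] = sweep_k(cfg.net_k_values, cfg.net_seeds, base_net)

    for name, df in report.items():
        df.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "cplearn_version": __version__,
        "python": sys.version.split()[0],
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "rejected_trials": rejected_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
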