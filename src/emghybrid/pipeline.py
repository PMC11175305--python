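"""In-silico motor-learning experiment: pre-evaluation, alternating
training/sequential evaluation, post-evaluation and retention, with
group statistics.

Two simulated arms mirror the experimental design: a *hybrid* group whose
training is passive guidance along the instructed minimum-jerk
trajectory (its skill decays faster toward the instructed movement,
including the movement duration converging to T_instruct) and a
*visual_feedback* group that improves quickly at first but plateaus at
a higher residual error and keeps its own movement tempo. Both arms are
phenomenological learning profiles on the trial generator — no claim
about human cognition is made; the pipeline's purpose is to exercise
every computational stage end to end with known ground truth.

Evaluation trials never use instruction or feedback: they always come
from the subject's own skill-driven generator at the current session's
skill. Improvement ratios are normalized to pre-training and are
sign-aware: 100*(pre-post)/pre for indices where lower is better
(e, e_perp_max, s, jc) and 100*(post-pre)/pre for indices where higher
is better (r_orbit, v_norm), so a positive ratio always means
improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DIRECTIONS, ExperimentConfig
from .metrics import endpoint_sd, evaluate_trial, orbit_correlation
from .synth import SubjectSkill, generate_trial, skill_at_session

#: indices where a larger value indicates better performance
HIGHER_IS_BETTER = ("r_orbit", "v_norm")
METRIC_COLUMNS = ("e", "e_perp_max", "jc", "v_norm", "reaching_time")
SET_METRICS = ("s", "r_orbit")
ALL_INDICES = ("e", "e_perp_max", "s", "r_orbit", "jc", "v_norm")

#: group learning profiles applied to the baseline subject skill
GROUP_PROFILES = {
    "hybrid": dict(decay=0.85, floor_frac=0.08, duration_decay=0.82),
    "visual_feedback": dict(decay=0.75, floor_frac=0.30, duration_decay=1.0),
}


@dataclass
class ExperimentReport:
    """Tables produced by :func:`run_experiment`.

    ``trials``: one row per evaluation trial (subject, group, stage,
    session, direction and the single-trial indices). ``set_metrics``:
    per subject/stage/direction stability indices computed across the
    stage's repeated trials. ``improvement``: per subject and index, the
    pre-to-post improvement ratio in percent.
    """

    trials: pd.DataFrame
    set_metrics: pd.DataFrame
    improvement: pd.DataFrame
    config: ExperimentConfig = None
    seeds: dict = field(default_factory=dict)


def _baseline_skill(rng: np.random.Generator, group: str,
                    cfg: ExperimentConfig, profiles: dict) -> SubjectSkill:
    """Draw a subject's pre-training skill; apply the group profile."""
    profile = profiles[group]
    bias_dir = rng.uniform(0.0, 2.0 * np.pi)
    bias_mag = rng.uniform(1.5, 3.5)
    return SubjectSkill(
        endpoint_bias=bias_mag * np.array([np.cos(bias_dir), np.sin(bias_dir)]),
        endpoint_noise_sd=rng.uniform(1.5, 2.5),
        curvature=rng.uniform(2.0, 5.0),
        tremor_amp=rng.uniform(0.3, 0.8),
        tremor_freq=rng.uniform(6.0, 10.0),
        duration=rng.uniform(2.2, 2.8),
        duration_target=cfg.schedule.t_instruct,
        **profile,
    )


def _eval_trials(
    skill: SubjectSkill,
    cfg: ExperimentConfig,
    n_trials: int,
    rng: np.random.Generator,
) -> dict:
    """``n_trials`` evaluation pointings in each of the four directions."""
    out = {}
    for direction in DIRECTIONS:
        target = cfg.schedule.target_map[direction]
        out[direction] = [
            generate_trial(skill, start=np.zeros(2), target=target,
                           fs=cfg.fs_traj, rng=rng)
            for _ in range(n_trials)
        ]
    return out


def run_experiment(
    cfg: ExperimentConfig,
    group_profiles: dict | None = None,
    baseline_skill: SubjectSkill | None = None,
) -> ExperimentReport:
    """Simulate every subject through the full experimental flow.

    Per subject: ``n_pre`` pre-evaluations, then ``n_sessions`` training
    sessions each followed by one sequential evaluation per direction,
    then ``n_post`` post-evaluations and (optionally) retention
    evaluations at the final skill. Deterministic given ``cfg.seed``.

    ``group_profiles`` overrides the built-in learning profiles;
    ``baseline_skill`` fixes every subject's pre-training skill instead
    of drawing it (the group profile is still applied on top).
    """
    profiles = GROUP_PROFILES if group_profiles is None else group_profiles
    trial_rows = []
    set_rows = []
    seeds = {}
    subj_idx = 0
    for group in cfg.groups:
        if group not in profiles:
            raise ValueError(f"unknown group {group!r}")
        for s in range(cfg.n_subjects_per_group):
            subject = f"{group[0].upper()}{s + 1:02d}"
            ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(subj_idx,))
            rng = np.random.default_rng(ss)
            seeds[subject] = int(ss.generate_state(1)[0])
            if baseline_skill is None:
                skill0 = _baseline_skill(rng, group, cfg, profiles)
            else:
                skill0 = replace(baseline_skill, **profiles[group])

            stages = [("pre", 0, cfg.n_pre)]
            stages += [("sequential", sess + 1, 1) for sess in range(cfg.n_sessions)]
            stages += [("post", cfg.n_sessions, cfg.n_post)]
            if cfg.retention:
                stages += [("retention", cfg.n_sessions, cfg.n_retention)]
            for stage, session, n_trials in stages:
                skill = skill_at_session(skill0, session)
                per_dir = _eval_trials(skill, cfg, n_trials, rng)
                for direction, trials in per_dir.items():
                    for k, trial in enumerate(trials):
                        row = {
                            "subject": subject, "group": group, "stage": stage,
                            "session": session, "direction": direction,
                            "trial": k,
                        }
                        row.update(evaluate_trial(trial))
                        trial_rows.append(row)
                    if len(trials) >= 2:
                        set_rows.append({
                            "subject": subject, "group": group, "stage": stage,
                            "session": session, "direction": direction,
                            "s": endpoint_sd(trials),
                            "r_orbit": orbit_correlation(trials),
                        })
            subj_idx += 1

    trials_df = pd.DataFrame(trial_rows)
    set_df = pd.DataFrame(set_rows)
    improvement = improvement_ratios(trials_df, set_df)
    return ExperimentReport(
        trials=trials_df, set_metrics=set_df, improvement=improvement,
        config=cfg, seeds=seeds,
    )


def improvement_ratios(
    trials: pd.DataFrame, set_metrics: pd.DataFrame
) -> pd.DataFrame:
    """Pre-to-post improvement in percent, per subject and index.

    Normalized to the pre-training value; sign-aware so positive always
    means improvement.
    """
    rows = []
    if trials.empty:
        return pd.DataFrame(columns=["subject", "group", "index", "improvement_pct"])
    for subject, sub in trials.groupby("subject"):
        group = sub["group"].iloc[0]
        for index in ALL_INDICES:
            if index in SET_METRICS:
                src = set_metrics[set_metrics["subject"] == subject]
            else:
                src = sub
            if src.empty or index not in src:
                continue
            pre = src.loc[src["stage"] == "pre", index].mean()
            post = src.loc[src["stage"] == "post", index].mean()
            if not np.isfinite(pre) or pre == 0:
                continue
            if index in HIGHER_IS_BETTER:
                ratio = 100.0 * (post - pre) / abs(pre)
            else:
                ratio = 100.0 * (pre - post) / abs(pre)
            rows.append({
                "subject": subject, "group": group, "index": index,
                "improvement_pct": float(ratio),
            })
    return pd.DataFrame(rows)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, len(p) * p)


def group_stats(report: ExperimentReport) -> pd.DataFrame:
    """Stage and group comparisons for every index.

    Intra-group: Wilcoxon signed-rank tests between the per-subject
    stage means (pre vs post, pre vs retention, post vs retention),
    Bonferroni-adjusted across the three stage pairs per index and
    group. Inter-group: Mann-Whitney U on the per-subject improvement
    ratios (exact null distribution when both samples are small and
    untied, scipy's default policy).
    """
    rows = []
    trials, sets = report.trials, report.set_metrics
    stages = [st for st in ("pre", "post", "retention")
              if st in set(trials["stage"])]
    groups = sorted(trials["group"].unique())

    def stage_means(index, group):
        src = sets if index in SET_METRICS else trials
        sub = src[src["group"] == group]
        return {
            st: sub[sub["stage"] == st].groupby("subject")[index].mean()
            for st in stages
        }

    for group in groups:
        n_subj = trials.loc[trials["group"] == group, "subject"].nunique()
        if n_subj < 2:
            raise ValueError(f"group {group!r} needs >= 2 subjects for statistics")
        for index in ALL_INDICES:
            means = stage_means(index, group)
            pairs = list(combinations(stages, 2))
            raw = []
            for a, b in pairs:
                x = means[a]
                y = means[b].reindex(x.index)
                diff = (x - y).dropna()
                if len(diff) < 2 or np.allclose(diff, 0.0):
                    raw.append(1.0)
                    continue
                raw.append(float(sps.wilcoxon(diff).pvalue))
            adj = bonferroni(raw)
            for (a, b), p, q in zip(pairs, raw, adj):
                rows.append({
                    "comparison": "intra", "group": group, "index": index,
                    "stage_a": a, "stage_b": b,
                    "p_raw": p, "p_adjusted": float(q),
                })

    if len(groups) == 2 and not report.improvement.empty:
        ga, gb = groups
        for index in ALL_INDICES:
            imp = report.improvement[report.improvement["index"] == index]
            xa = imp.loc[imp["group"] == ga, "improvement_pct"]
            xb = imp.loc[imp["group"] == gb, "improvement_pct"]
            if len(xa) == 0 and len(xb) == 0:
                continue  # index undefined for every subject (e.g. zero pre)
            if len(xa) < 2 or len(xb) < 2:
                raise ValueError("inter-group test needs >= 2 subjects per group")
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append({
                "comparison": "inter", "group": f"{ga} vs {gb}", "index": index,
                "stage_a": "improvement", "stage_b": "improvement",
                "p_raw": float(res.pvalue), "p_adjusted": float(res.pvalue),
                "U": float(res.statistic),
            })
    return pd.DataFrame(rows)


def report_render(report: ExperimentReport, out_dir: str | Path) -> list[Path]:
    """Write the report tables as CSV and the summary figures as PNG.

    Produces ``trials.csv``, ``set_metrics.csv``, ``improvement.csv``,
    ``group_stats.csv`` plus three figures: reaching time per stage,
    sequential endpoint error over sessions, and a six-panel grid of
    the evaluation indices per stage.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    header = ""
    if report.config is not None:
        header = f"# seed={report.config.seed}\n"
    tables = {
        "trials.csv": report.trials,
        "set_metrics.csv": report.set_metrics,
        "improvement.csv": report.improvement,
    }
    if not report.trials.empty:
        tables["group_stats.csv"] = group_stats(report)
    for name, df in tables.items():
        path = out_dir / name
        with open(path, "w") as fh:
            if header:
                fh.write(header)
            df.to_csv(fh, index=False)
        written.append(path)

    if report.trials.empty:
        return written

    trials = report.trials
    stages = [st for st in ("pre", "post", "retention")
              if st in set(trials["stage"])]
    groups = sorted(trials["group"].unique())

    # reaching time per stage and group
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.35
    for gi, group in enumerate(groups):
        vals = [
            trials[(trials["group"] == group) & (trials["stage"] == st)]
            .groupby("subject")["reaching_time"].mean()
            for st in stages
        ]
        pos = np.arange(len(stages)) + (gi - 0.5 * (len(groups) - 1)) * width
        ax.boxplot(vals, positions=pos, widths=0.3 * width * 2,
                   label=group, patch_artist=True)
    ax.set_xticks(np.arange(len(stages)), stages)
    ax.set_ylabel("reaching time [s]")
    fig.tight_layout()
    path = out_dir / "reaching_time.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # sequential endpoint error over sessions
    fig, ax = plt.subplots(figsize=(6, 4))
    seq = trials[trials["stage"] == "sequential"]
    for group in groups:
        sub = seq[seq["group"] == group].groupby("session")["e"].mean()
        ax.plot(sub.index, sub.values, marker="o", label=group)
    ax.set_xlabel("training session")
    ax.set_ylabel("endpoint error e [deg]")
    ax.legend()
    fig.tight_layout()
    path = out_dir / "sequential_error.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # six-panel indices figure
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, index in zip(axes.ravel(), ALL_INDICES):
        src = report.set_metrics if index in SET_METRICS else trials
        for group in groups:
            sub = src[src["group"] == group]
            vals = [sub[sub["stage"] == st].groupby("subject")[index].mean()
                    .mean() for st in stages]
            ax.plot(range(len(stages)), vals, marker="o", label=group)
        ax.set_xticks(range(len(stages)), stages)
        ax.set_title(index)
    axes[0, 0].legend()
    fig.tight_layout()
    path = out_dir / "indices_panel.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
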