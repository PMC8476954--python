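"""End-to-end study analysis: features, prediction, attribution, statistics.

For every participant-day the pipeline assembles a feature row — sex,
sitting hours, occurrence rate of the common motif (/30 sitting min), and
the morning sleepiness and fullness scores — and the day's low-back-pain
change label: ``morning LBP minus evening LBP``, negative = exacerbated,
zero = no change, positive = improved.

Stages: load or simulate recordings -> COP at 1 Hz -> TICC segmentation
(fixed K or a BIC sweep) -> MASA motif discovery -> feature table ->
repeated nested-CV training of the SSA-tuned weighted PNN (with a
label-permuted surrogate for chance level) -> exact Shapley feature
attribution -> Kruskal-Wallis and Dunn comparison of motif rates across the
three LBP-change groups.

Shapley values are computed by exact coalition enumeration (2^5 subsets for
the five features) with interventional expectations over a background
sample, so the efficiency and null-player axioms hold to numerical
tolerance on every row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cop_io, masa, ssa_pnn, synthetic_data, ticc
from .exceptions import ConfigError, FormatError

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["sex", "sitting_hours", "motif_rate_30min", "sleepiness", "fullness"]
LABELS = synthetic_data.CATEGORIES  # exacerbated / no_change / improved


# ---------------------------------------------------------------------------
# labels and features


def lbp_change_label(morning, evening):
    """Sign of morning minus evening LBP: negative = exacerbated, zero =
    no change, positive = improved; None when either score is missing."""
    if morning is None or evening is None or \
            (isinstance(morning, float) and np.isnan(morning)) or \
            (isinstance(evening, float) and np.isnan(evening)):
        return None
    if not (0 <= morning <= 10 and 0 <= evening <= 10):
        raise FormatError("LBP scores must lie in [0, 10]")
    d = morning - evening
    return "exacerbated" if d < 0 else "improved" if d > 0 else "no_change"


def build_feature_table(day_features: pd.DataFrame, questionnaire: pd.DataFrame,
                        metadata: pd.DataFrame) -> pd.DataFrame:
    """Join per-day measurements with questionnaires and participant metadata.

    ``day_features`` needs columns participant_id, date, sitting_hours,
    motif_rate_30min.  Morning (first answered slot) scores provide the
    sleepiness/fullness features and the morning LBP; the last answered slot
    provides the evening LBP.  Days without a label or with zero sitting
    time are dropped (logged).  Column order is fixed for the classifier.
    """
    q = questionnaire.sort_values(["participant_id", "date", "time_slot"])
    rows = []
    dropped = 0
    meta = metadata.set_index("participant_id")
    missing = set(day_features["participant_id"]) - set(meta.index)
    if missing:
        raise ConfigError(f"metadata missing for participant(s) {sorted(missing)}")
    for _, day in day_features.iterrows():
        key = (day["participant_id"], day["date"])
        slots = q[(q["participant_id"] == key[0]) & (q["date"] == key[1])]
        slots = slots[slots["lbp"].notna()]
        if len(slots) == 0:
            raise ConfigError(f"no questionnaire rows for participant-day {key}")
        first, last = slots.iloc[0], slots.iloc[-1]
        label = lbp_change_label(first["lbp"], last["lbp"]) if len(slots) >= 2 else None
        if label is None or day["sitting_hours"] <= 0:
            dropped += 1
            continue
        rows.append({
            "participant_id": key[0], "date": key[1],
            "sex": int(meta.loc[key[0], "sex"]),
            "sitting_hours": float(day["sitting_hours"]),
            "motif_rate_30min": float(day["motif_rate_30min"]),
            "sleepiness": float(first["sleepiness"]),
            "fullness": float(first["fullness"]),
            "label": label,
        })
    if dropped:
        logger.info("build_feature_table: dropped %d unlabelable/zero-sitting days",
                    dropped)
    table = pd.DataFrame(rows, columns=["participant_id", "date", *FEATURE_COLUMNS,
                                        "label"])
    return table


# ---------------------------------------------------------------------------
# exact Shapley attribution


def exact_shapley(predict_fn, row, background, n_outputs: int | None = None):
    """Exact Shapley values by full coalition enumeration.

    ``predict_fn(X)`` maps an (N, n_features) array to (N, n_outputs) model
    outputs.  ``f_S`` is the interventional expectation: features outside S
    are replaced by background rows and the prediction averaged.  Returns
    ``(phi, base)`` with ``phi`` of shape (n_features, n_outputs) and
    ``base = E[f]`` over the background; ``sum_j phi_j = f(x) - base``
    exactly (up to float round-off).
    """
    row = np.asarray(row, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if len(background) == 0:
        raise ConfigError("background must be non-empty")
    n = row.size
    if n > 12:
        raise ConfigError("exact enumeration is limited to 12 features")
    features = list(range(n))

    def f_S(subset) -> np.ndarray:
        Xb = background.copy()
        for j in subset:
            Xb[:, j] = row[j]
        return np.asarray(predict_fn(Xb), dtype=float).mean(axis=0)

    cache = {}
    for r in range(n + 1):
        for S in combinations(features, r):
            cache[S] = f_S(S)
    n_outputs = len(cache[()]) if n_outputs is None else n_outputs
    phi = np.zeros((n, n_outputs))
    fact = factorial
    for j in features:
        others = [k for k in features if k != j]
        for r in range(n):
            weight = fact(r) * fact(n - r - 1) / fact(n)
            for S in combinations(others, r):
                Sj = tuple(sorted((*S, j)))
                phi[j] += weight * (cache[Sj] - cache[S])
    return phi, cache[()]


def shapley_summary(predict_fn, X, background, feature_names=FEATURE_COLUMNS):
    """Mean absolute Shapley value per feature and output over rows of X.

    Returns a DataFrame indexed by feature, one column per model output plus
    ``overall`` (summed across outputs), sorted by overall importance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    phis = []
    for row in X:
        phi, _ = exact_shapley(predict_fn, row, background)
        phis.append(np.abs(phi))
    mean_abs = np.mean(phis, axis=0)
    table = pd.DataFrame(mean_abs, index=feature_names)
    table["overall"] = table.sum(axis=1)
    return table.sort_values("overall", ascending=False)


# ---------------------------------------------------------------------------
# group statistics


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-squared.

    ``groups`` is a sequence of >= 2 non-empty 1-D samples.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ConfigError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(tie_counts ** 3 - tie_counts) / (N ** 3 - N)
    if tie_term <= 0:
        return 0.0, 1.0  # all pooled values identical
    H /= tie_term
    df = len(groups) - 1
    return float(H), float(sps.chi2.sf(H, df))


def dunn_posthoc(groups, labels=None, adjust: str | None = None) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    z statistics use pooled mean ranks with tie correction; p-values are
    two-sided and unadjusted by default (``adjust='holm'`` applies Holm's
    step-down).  Returns a row per pair with z and p.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ConfigError("need >= 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = np.sum(tie_counts ** 3 - tie_counts)
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": float(z), "p": float(min(p, 1.0))})
    table = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        table["p_adjusted"] = adj
    elif adjust is not None:
        raise ConfigError(f"unknown adjustment {adjust!r}")
    return table


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """One self-contained run: simulate (or read) a cohort and analyse it.

    ``k_states`` fixes the cluster count; ``k_sweep`` (e.g. ``range(2, 7)``)
    selects it by BIC instead.  ``max_fit_windows`` caps the number of
    windows used for the TICC EM (contiguous per-day slices); decoding
    always uses every window.
    """

    cohort: synthetic_data.CohortSpec = field(
        default_factory=synthetic_data.CohortSpec)
    k_states: int = 3
    k_sweep: tuple | None = None
    w: int = 5
    beta: float = 50.0
    lam: float = 0.001
    gamma: float = 0.9
    min_count: int = 5
    max_motif_len: int = 6
    cv_reps: int = 10
    n_permutations: int = 20
    ssa_pop: int = 20
    ssa_iters: int = 10
    max_fit_windows: int = 150_000
    shap_background: int = 30
    seed: int = 0
    out_dir: str | None = None


def extract_day_windows(cohort: synthetic_data.CohortData, w: int):
    """Per-day COP windows and sitting hours from raw load-cell frames."""
    days = []
    for (pid, date), frame in sorted(cohort.loadcells.items()):
        calibrated, _ = cop_io.calibrate(frame)
        series = cop_io.cop_series_from_frames(calibrated, pid, date)
        X, _ = ticc.stack_windows(series, w)
        days.append({"participant_id": pid, "date": date, "windows": X,
                     "sitting_hours": cop_io.sitting_time(series)})
    return days


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and optionally writes) a report."""
    report: dict = {"config_seed": config.seed, "stages": []}

    def stage(name):
        report["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        cohort = synthetic_data.simulate_cohort(config.cohort)

        stage("preprocess")
        days = extract_day_windows(cohort, config.w)
        days = [d for d in days if len(d["windows"]) > 0]

        stage("ticc")
        rng = np.random.default_rng(config.seed)
        fit_slices = _fit_subsample(days, config.max_fit_windows)
        ticc_cfg = ticc.TICCConfig(K=config.k_states, w=config.w, beta=config.beta,
                                   lam=config.lam, seed=config.seed)
        if config.k_sweep is not None:
            model, best_k, bic_table = ticc.select_k(fit_slices, config.k_sweep,
                                                     ticc_cfg)
            report["bic_table"] = bic_table.to_dict(orient="records")
            report["selected_k"] = best_k
        else:
            model = ticc.fit_ticc(fit_slices, ticc_cfg)
            report["selected_k"] = config.k_states
        report["ticc_objective_trace"] = [float(v) for v in model.objective_trace]

        stage("masa")
        masa_cfg = masa.MASAConfig(gamma=config.gamma, L=config.min_count,
                                   beta=config.beta, max_len=config.max_motif_len,
                                   seed=config.seed)
        masa_model = masa.fit_masa([d["windows"] for d in days], model, masa_cfg)
        common = masa_model.common_motif
        report["common_motif"] = list(common.states) if common else None
        report["motif_scores"] = [
            {"motif": list(rec["motif"].states), "score": rec["score"],
             "count": rec["count"]} for rec in masa_model.motifs[:5]]

        stage("features")
        day_rows = []
        for i, day in enumerate(days):
            inst = masa_model.motifs[0]["instances"][i] if masa_model.motifs else []
            rate = masa.motif_occurrence_rate(inst, day["sitting_hours"]) \
                if day["sitting_hours"] > 0 else np.nan
            day_rows.append({"participant_id": day["participant_id"],
                             "date": day["date"],
                             "sitting_hours": day["sitting_hours"],
                             "motif_rate_30min": rate})
        features = build_feature_table(pd.DataFrame(day_rows),
                                       cohort.questionnaire, cohort.metadata)
        report["n_days"] = int(len(features))
        report["motif_prevalence_pct"] = 100.0 * float(
            np.mean(features["motif_rate_30min"] > 0)) if len(features) else np.nan
        X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
        y = features["label"].to_numpy()

        stage("classify")
        plan = ssa_pnn.CVPlan(reps=config.cv_reps, seed=config.seed)
        ssa_cfg = ssa_pnn.SSAConfig(pop_size=config.ssa_pop, max_iter=config.ssa_iters,
                                    bounds=ssa_pnn.default_search_bounds(X.shape[1]),
                                    seed=config.seed)
        summary, rep_table = ssa_pnn.repeat_cv(X, y, plan, ssa_cfg)
        report["cv_metrics"] = {k: {"mean": v[0], "sd": v[1]}
                                for k, v in summary.items()}
        fold_records, fold_metrics = ssa_pnn.nested_cv_train(X, y, plan, ssa_cfg)
        report["confusion"] = fold_metrics["confusion"].tolist()
        report["confusion_normalized"] = np.round(
            fold_metrics["confusion_normalized"], 4).tolist()
        if config.n_permutations > 0:
            chance = ssa_pnn.permutation_chance(X, y, plan, ssa_cfg,
                                                n_perm=config.n_permutations,
                                                seed=config.seed + 1)
            report["surrogate_accuracy"] = {"mean": float(chance.mean()),
                                            "sd": float(chance.std(ddof=1))}

        stage("shapley")
        # explain a model with the fold-median tuned parameters: hyper-
        # parameters that only exploit a fold-specific accident are unstable
        # across outer folds, the median damps them
        sigma_med = float(np.median([r["sigma"] for r in fold_records]))
        omega_med = np.median(np.vstack([r["omega"] for r in fold_records]), axis=0)
        final_model = ssa_pnn.fit_pnn(X, y, sigma_med, omega_med)
        report["final_params"] = {"sigma": sigma_med, "omega": omega_med.tolist()}
        bg_idx = rng.choice(len(X), size=min(config.shap_background, len(X)),
                            replace=False)
        shap_table = shapley_summary(
            lambda rows: ssa_pnn.predict_proba(rows, final_model), X, X[bg_idx])
        report["shap_ranking"] = list(shap_table.index)
        report["shap_overall"] = {f: float(v)
                                  for f, v in shap_table["overall"].items()}

        stage("stats")
        groups = [features.loc[features["label"] == lab, "motif_rate_30min"].to_numpy()
                  for lab in LABELS]
        have = [lab for lab, g in zip(LABELS, groups) if len(g) > 0]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) >= 2:
            H, p = kruskal_wallis(groups)
            report["kruskal_wallis"] = {"H": H, "p": p}
            dunn = dunn_posthoc(groups, labels=have)
            report["dunn"] = dunn.to_dict(orient="records")
            if p >= 0.05:
                report["dunn_note"] = "omnibus test not significant at 0.05"
        report["group_motif_rates"] = {
            lab: {"mean": float(g.mean()), "sd": float(g.std(ddof=1))
                  if len(g) > 1 else 0.0, "n": int(len(g))}
            for lab, g in zip(have, groups)}
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {report['stages'][-1]!r}: {exc}") from exc

    if config.out_dir is not None:
        _write_report(report, features, shap_table, config.out_dir)
    return report


def _fit_subsample(days, cap: int) -> np.ndarray:
    """Contiguous per-day window slices, capped at ``cap`` rows in total.

    Slices stay contiguous so the switching penalty in the EM remains
    meaningful; decoding later uses every window of every day.
    """
    total = sum(len(d["windows"]) for d in days)
    if total <= cap:
        return np.vstack([d["windows"] for d in days])
    frac = cap / total
    parts = []
    for d in days:
        k = max(int(len(d["windows"]) * frac), 1)
        start = (len(d["windows"]) - k) // 2
        parts.append(d["windows"][start:start + k])
    return np.vstack(parts)


def _write_report(report, features, shap_table, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": 1, **report}
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=str))
    features.to_csv(out / "features.csv", index=False)
    shap_table.to_csv(out / "shap_summary.csv")
    try:
        _plots(report, features, shap_table, out)
    except Exception as exc:  # plotting must never sink a finished analysis
        logger.warning("plotting failed: %s", exc)


def _plots(report, features, shap_table, out) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    shap_table["overall"].iloc[::-1].plot.barh(ax=ax)
    ax.set_xlabel("mean |Shapley value| (summed over classes)")
    fig.tight_layout()
    fig.savefig(out / "shap_ranking.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    data = [features.loc[features["label"] == lab, "motif_rate_30min"]
            for lab in LABELS]
    ax.violinplot([d for d in data if len(d)], showmeans=True)
    ax.set_xticks(range(1, 1 + sum(1 for d in data if len(d))),
                  [lab for lab, d in zip(LABELS, data) if len(d)])
    ax.set_ylabel("motif rate / 30 min")
    fig.tight_layout()
    fig.savefig(out / "motif_rate_by_group.svg")
    plt.close(fig)

    cm = np.asarray(report["confusion"], dtype=float)
    fig, ax = plt.subplots(figsize=(3.6, 3.2))
    ax.imshow(cm, cmap="Blues")
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            ax.text(j, i, f"{cm[i, j]:.0f}", ha="center", va="center")
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    fig.tight_layout()
    fig.savefig(out / "confusion_matrix.svg")
    plt.close(fig)
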