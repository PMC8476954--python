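"""Weighted probabilistic neural network tuned by the social spider algorithm.

The classifier is a Parzen-window density estimator per class: for a query
``x`` with ``n`` features, class ``g`` with exemplars ``x_i^(g)`` scores

    p_g(x) = 1 / ((2 pi)^{n/2} sigma^n) * (1/l_g)
             * sum_i exp( - sum_j (w_j x_j - w_j x_ij^(g))^2 / (2 sigma^2) )

so the per-feature weights ``w_j`` turn the spherical kernel elliptical: a
larger weight shrinks the kernel radius along that feature, making it more
influential.  With all weights 1 this is the ordinary Parzen estimate.
Densities are evaluated in log space with log-sum-exp.

``sigma`` and ``w`` are chosen by the social spider algorithm (SSA), a
population metaheuristic in which candidate solutions ("spiders") broadcast
fitness "vibrations" across the search space; each spider follows the
strongest vibration it perceives, with attenuation by distance and a random
dimension mask for exploration.  The tuning objective is the mean validation
cross-entropy over five inner folds of the training split, with a soft
penalty when ``sigma`` drops below 0.1 (small kernels overfit).  The outer
6-fold split is evaluated once with the tuned parameters, and the whole
procedure can be repeated with re-randomised folds to get metric
distributions; a label-permuted ("surrogate") run estimates chance level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics import accuracy_score, precision_recall_fscore_support, \
    confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigError, StratificationError

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))

#: sigma below this triggers the overfitting penalty
SIGMA_FLOOR = 0.1
#: penalty slope: 10 per 0.1 of shortfall
SIGMA_PENALTY_SLOPE = 10.0 / 0.1

PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# the PNN


@dataclass
class PNNModel:
    """Class exemplar sets with smoothing ``sigma``, feature weights
    ``omega`` and the training-set standardisation parameters."""

    classes: np.ndarray
    exemplars: list          # standardized, one (l_g, n) array per class
    sigma: float
    omega: np.ndarray
    scale_mean: np.ndarray
    scale_std: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigError("sigma must be > 0")
        self.omega = np.asarray(self.omega, dtype=float)
        if np.any(self.omega < 0):
            raise ConfigError("feature weights must be >= 0")
        if any(len(e) < 1 for e in self.exemplars):
            raise ConfigError("every class needs at least one exemplar")

    @property
    def n_features(self) -> int:
        return self.exemplars[0].shape[1]


def fit_pnn(X, y, sigma: float, omega, standardize: bool = True) -> PNNModel:
    """Store the (standardised) training set as per-class exemplars."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    Xs = (X - mean) / std
    classes = np.unique(y)
    exemplars = [Xs[y == c] for c in classes]
    return PNNModel(classes=classes, exemplars=exemplars, sigma=float(sigma),
                    omega=np.asarray(omega, dtype=float), scale_mean=mean,
                    scale_std=std)


def _log_density_matrix(X, model: PNNModel) -> np.ndarray:
    """(N, M) log p_g(x) for standardised queries drawn from raw X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xs = (X - model.scale_mean) / model.scale_std
    n = model.n_features
    w2 = model.omega ** 2
    const = -0.5 * n * LOG_2PI - n * np.log(model.sigma)
    out = np.empty((len(Xs), len(model.classes)))
    for g, ex in enumerate(model.exemplars):
        d2 = ((Xs[:, None, :] - ex[None, :, :]) ** 2 * w2).sum(axis=2)
        out[:, g] = const - np.log(len(ex)) + logsumexp(-d2 / (2.0 * model.sigma ** 2),
                                                        axis=1)
    return out


def pnn_density(x, g: int, model: PNNModel) -> float:
    """Class-``g`` Parzen density at ``x`` (``g`` indexes ``model.classes``)."""
    return float(np.exp(_log_density_matrix(x, model)[0, g]))


def pnn_classify(x, model: PNNModel, priors=None):
    """Argmax of prior-weighted class densities; ties take the lowest class
    index (logged).  Returns ``(class_label, normalised scores)``."""
    logp = _log_density_matrix(x, model)[0]
    if priors is not None:
        logp = logp + np.log(np.asarray(priors, dtype=float))
    best = logp.max()
    winners = np.flatnonzero(logp == best)
    if len(winners) > 1:
        logger.info("pnn_classify: tie between classes %s, taking the first",
                    model.classes[winners])
    scores = np.exp(logp - logsumexp(logp))
    return model.classes[winners[0]], scores


def predict_proba(X, model: PNNModel, priors=None) -> np.ndarray:
    """Row-normalised posterior scores (N, M)."""
    logp = _log_density_matrix(X, model)
    if priors is not None:
        logp = logp + np.log(np.asarray(priors, dtype=float))
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def predict(X, model: PNNModel, priors=None) -> np.ndarray:
    proba = predict_proba(X, model, priors)
    return model.classes[np.argmax(proba, axis=1)]


def cross_entropy(labels, proba, classes=None) -> float:
    """Mean categorical cross-entropy with probabilities floored at 1e-12.

    ``proba`` rows are re-normalised before flooring, so unnormalised class
    scores are accepted.
    """
    labels = np.asarray(labels)
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    proba = proba / proba.sum(axis=1, keepdims=True)
    if classes is None:
        classes = np.unique(labels)
    col = {c: i for i, c in enumerate(classes)}
    idx = np.array([col[l] for l in labels])
    p_true = np.clip(proba[np.arange(len(labels)), idx], PROB_FLOOR, None)
    return float(np.mean(-np.log(p_true)))


# ---------------------------------------------------------------------------
# the tuning objective


def sigma_penalty(sigma: float) -> float:
    """Soft barrier below the 0.1 smoothing floor: 10 per 0.1 shortfall."""
    return SIGMA_PENALTY_SLOPE * max(0.0, SIGMA_FLOOR - sigma)


def make_inner_objective(X, y, inner_folds: list, classes) -> callable:
    """Mean validation cross-entropy over fixed inner folds.

    ``inner_folds`` is a list of (train_idx, val_idx) pairs fixed *before*
    optimisation; the same (sigma, omega) is applied to all inner models
    simultaneously.  The argument vector is ``[sigma, omega_1..omega_n]``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)

    def objective(params: np.ndarray) -> float:
        sigma = float(params[0])
        omega = np.asarray(params[1:], dtype=float)
        if sigma <= 0:
            return np.inf
        losses = []
        for tr, va in inner_folds:
            model = fit_pnn(X[tr], y[tr], sigma, omega)
            proba = predict_proba(X[va], model)
            # align model classes with the full class list
            full = np.full((len(va), len(classes)), PROB_FLOOR)
            for j, c in enumerate(model.classes):
                full[:, list(classes).index(c)] = proba[:, j]
            losses.append(cross_entropy(y[va], full, classes))
        return float(np.mean(losses)) + sigma_penalty(sigma)

    return objective


# ---------------------------------------------------------------------------
# social spider algorithm


@dataclass
class SSAConfig:
    """Population metaheuristic settings.

    ``r_a`` controls vibration attenuation over distance, ``p_c`` the mask
    persistence and ``p_m`` the per-dimension mask probability; the defaults
    follow the algorithm's standard form with 10 iterations (epochs).
    """

    pop_size: int = 20
    max_iter: int = 10
    r_a: float = 1.0
    p_c: float = 0.7
    p_m: float = 0.1
    bounds: tuple = ((0.01, 10.0),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ConfigError("pop_size must be >= 2")
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or not np.all(np.isfinite(b)):
            raise ConfigError("bounds must be a finite sequence of (lo, hi) pairs")
        if np.any(b[:, 0] >= b[:, 1]):
            raise ConfigError("each lower bound must be below its upper bound")


def ssa_optimize(objective, config: SSAConfig):
    """Minimise ``objective`` over the bounded box with social spiders.

    Each iteration: evaluate fitness, convert to vibration intensity,
    propagate vibrations with distance attenuation (``r_a``), let every
    spider follow the strongest vibration it perceives with a random masked
    walk (``p_c``, ``p_m``), and clamp to the bounds.  Non-finite objective
    values trigger a resample of that spider (logged).  Returns
    ``(best position, best value, best-so-far trace)``; the trace is
    monotone non-increasing (elitist bookkeeping).
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(config.bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    dim = len(bounds)
    pop = config.pop_size

    pos = lo + rng.random((pop, dim)) * (hi - lo)
    prev_move = np.zeros((pop, dim))
    fit = np.empty(pop)
    for s in range(pop):
        fit[s] = _safe_eval(objective, pos[s], lo, hi, rng)
    C = fit.min() - 1.0
    target_pos = pos.copy()
    target_intensity = np.full(pop, -np.inf)
    inactive = np.zeros(pop, dtype=int)
    mask = np.zeros((pop, dim), dtype=bool)

    best_idx = int(np.argmin(fit))
    best_pos = pos[best_idx].copy()
    best_val = float(fit[best_idx])
    trace = [best_val]

    for _ in range(config.max_iter):
        if fit.min() <= C:
            C = fit.min() - 1.0
        intensity = np.log(1.0 / (fit - C) + 1.0)
        sigma_bar = float(np.mean(pos.std(axis=0)))
        if sigma_bar <= 0:
            sigma_bar = 1e-12
        dist = np.abs(pos[:, None, :] - pos[None, :, :]).sum(axis=2)  # 1-norm
        received = intensity[None, :] * np.exp(-dist / (sigma_bar * config.r_a))
        for s in range(pop):
            b = int(np.argmax(received[s]))
            if received[s, b] > target_intensity[s]:
                target_intensity[s] = received[s, b]
                target_pos[s] = pos[b].copy()
                inactive[s] = 0
            else:
                inactive[s] += 1
            if rng.random() > config.p_c ** inactive[s]:
                mask[s] = rng.random(dim) < config.p_m
        rand_rows = rng.integers(0, pop, size=(pop, dim))
        follow = np.where(mask, pos[rand_rows, np.arange(dim)[None, :]], target_pos)
        step = prev_move * rng.random((pop, dim)) + \
            (follow - pos) * rng.random((pop, dim))
        new_pos = np.clip(pos + step, lo, hi)
        prev_move = new_pos - pos
        pos = new_pos
        for s in range(pop):
            fit[s] = _safe_eval(objective, pos[s], lo, hi, rng)
        i = int(np.argmin(fit))
        if fit[i] < best_val:
            best_val = float(fit[i])
            best_pos = pos[i].copy()
        trace.append(best_val)
    return best_pos, best_val, np.asarray(trace)


def _safe_eval(objective, x, lo, hi, rng, max_tries: int = 10) -> float:
    val = objective(x)
    tries = 0
    while not np.isfinite(val) and tries < max_tries:
        logger.info("ssa_optimize: non-finite objective, resampling position")
        x[:] = lo + rng.random(len(lo)) * (hi - lo)
        val = objective(x)
        tries += 1
    return float(val) if np.isfinite(val) else 1e30


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class CVPlan:
    """Stratified nested cross-validation: 6 outer folds, 5 inner folds,
    repeatable with re-randomised splits."""

    outer: int = 6
    inner: int = 5
    reps: int = 200
    seed: int = 0


def default_search_bounds(n_features: int) -> tuple:
    """Search box: sigma in [0.01, 10], each weight in [0, 5]."""
    return ((0.01, 10.0),) + ((0.0, 5.0),) * n_features


def nested_cv_train(X, y, cv_plan: CVPlan, ssa_config: SSAConfig | None = None):
    """Tune (sigma, omega) per outer fold on inner folds only, test once.

    The outer test fold never enters the SSA objective.  Returns
    ``(per-fold records, metrics dict)`` where metrics are accuracy and
    support-weighted precision/recall/F1 over the pooled outer predictions,
    plus raw and row-normalised confusion matrices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    counts = np.array([np.sum(y == c) for c in classes])
    if counts.min() < 2:
        raise StratificationError(
            f"class {classes[counts.argmin()]} has {counts.min()} sample(s); "
            "need >= 2 per class")
    n_outer = min(cv_plan.outer, int(counts.min()))
    if n_outer < cv_plan.outer:
        logger.warning("nested_cv_train: rarest class has %d samples; using "
                       "%d outer folds instead of %d", counts.min(), n_outer,
                       cv_plan.outer)
    if ssa_config is None:
        ssa_config = SSAConfig(bounds=default_search_bounds(X.shape[1]),
                               seed=cv_plan.seed)
    outer = StratifiedKFold(n_splits=n_outer, shuffle=True,
                            random_state=cv_plan.seed)
    records = []
    y_true_all, y_pred_all = [], []
    for fold_i, (tr, te) in enumerate(outer.split(X, y)):
        inner_counts = np.array([np.sum(y[tr] == c) for c in classes])
        n_inner = min(cv_plan.inner, int(inner_counts.min()))
        if n_inner < 2:
            raise StratificationError(
                "outer-training split lost a class; re-seed the plan")
        inner = StratifiedKFold(n_splits=n_inner, shuffle=True,
                                random_state=cv_plan.seed + 1 + fold_i)
        inner_folds = list(inner.split(X[tr], y[tr]))
        objective = make_inner_objective(X[tr], y[tr], inner_folds, classes)
        cfg = SSAConfig(pop_size=ssa_config.pop_size, max_iter=ssa_config.max_iter,
                        r_a=ssa_config.r_a, p_c=ssa_config.p_c, p_m=ssa_config.p_m,
                        bounds=ssa_config.bounds,
                        seed=ssa_config.seed * 1000 + fold_i)
        params, val_loss, trace = ssa_optimize(objective, cfg)
        model = fit_pnn(X[tr], y[tr], params[0], params[1:])
        pred = predict(X[te], model)
        records.append({"fold": fold_i, "sigma": float(params[0]),
                        "omega": np.asarray(params[1:]), "val_loss": val_loss,
                        "trace": trace, "model": model,
                        "test_idx": te, "pred": pred})
        y_true_all.append(y[te])
        y_pred_all.append(pred)
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="weighted", zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    with np.errstate(invalid="ignore"):
        cm_norm = cm / cm.sum(axis=1, keepdims=True)
    metrics = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision_weighted": float(prec),
        "recall_weighted": float(rec),
        "f1_weighted": float(f1),
        "confusion": cm,
        "confusion_normalized": cm_norm,
        "classes": classes,
    }
    return records, metrics


METRIC_KEYS = ("accuracy", "precision_weighted", "recall_weighted", "f1_weighted")


def repeat_cv(X, y, plan: CVPlan, ssa_config: SSAConfig | None = None):
    """Repeat the nested CV with re-randomised folds; mean and sd per metric.

    Returns ``(summary dict {metric: (mean, sd)}, per-repeat table)``.
    """
    if plan.reps < 1:
        raise ConfigError("reps must be >= 1")
    rows = []
    for rep in range(plan.reps):
        rep_plan = CVPlan(outer=plan.outer, inner=plan.inner, reps=1,
                          seed=plan.seed + 7919 * rep)
        _, metrics = nested_cv_train(X, y, rep_plan, ssa_config)
        rows.append({k: metrics[k] for k in METRIC_KEYS})
    import pandas as pd

    table = pd.DataFrame(rows)
    summary = {k: (float(table[k].mean()), float(table[k].std(ddof=1))
                   if plan.reps > 1 else 0.0) for k in METRIC_KEYS}
    return summary, table


def permutation_chance(X, y, plan: CVPlan, ssa_config: SSAConfig | None = None,
                       n_perm: int = 20, seed: int = 0) -> np.ndarray:
    """Chance-level accuracies from label-permuted (surrogate) datasets."""
    rng = np.random.default_rng(seed)
    out = []
    for p in range(n_perm):
        y_perm = rng.permutation(np.asarray(y))
        rep_plan = CVPlan(outer=plan.outer, inner=plan.inner, reps=1,
                          seed=plan.seed + 104729 * p)
        _, metrics = nested_cv_train(X, y_perm, rep_plan, ssa_config)
        out.append(metrics["accuracy"])
    return np.asarray(out)
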