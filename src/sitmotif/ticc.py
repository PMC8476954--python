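"""Toeplitz inverse-covariance-based clustering (TICC) of COP windows.

Each sitting "state" is modelled as a Gaussian Markov random field over a
short window of ``w`` consecutive 2-D COP samples, i.e. an ``nw x nw``
precision matrix constrained to be block Toeplitz: its (i, j) sub-block
depends only on ``j - i``, so within-window dependencies are time-invariant.
The sub-block ``A(0)`` carries the intra-time partial correlations between
the two COP axes, ``A(k)`` the lag-k cross-time ones.

Fitting alternates, EM-style, between

* an exact dynamic-programming assignment of windows to clusters under a
  switching penalty ``beta`` that rewards temporally contiguous segments, and
* per-cluster sparse precision estimation: a block-Toeplitz-constrained
  graphical lasso with an l1 penalty ``lam`` on the off-diagonal entries,
  solved by ADMM where the l1 proximal step averages each Toeplitz parameter
  group before soft-thresholding (the exact prox on the constraint subspace).

Model order is chosen by BIC, counting as free parameters the unique
non-negligible entries of the A blocks plus the per-cluster window means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._dp import viterbi_switch
from .cop_io import COPSeries
from .exceptions import ConfigError

logger = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))

#: entries with magnitude at or below this count as structural zeros in BIC
ZERO_TOL = 1e-5


# ---------------------------------------------------------------------------
# window stacking


def stack_windows(series, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack a COP series into overlapping ``nw``-dimensional windows.

    A window ending at sample ``t`` concatenates the ``w`` samples
    ``t-w+1 .. t`` (oldest first, two coordinates per sample).  Windows are
    built only inside contiguous runs of present samples; runs shorter than
    ``w`` contribute none.

    Returns ``(X, idx)`` where ``X`` is (n_windows, 2*w) and ``idx`` the
    sample index each window ends at.
    """
    if w < 1:
        raise ConfigError("window w must be >= 1")
    if isinstance(series, COPSeries):
        xy = series.xy
        present = series.present
    else:
        xy = np.asarray(series, dtype=float)
        present = ~np.isnan(xy).any(axis=1)
    T = len(xy)
    n = xy.shape[1] if T else 2
    out, idx = [], []
    start = None
    for t in range(T + 1):
        if t < T and present[t]:
            if start is None:
                start = t
            continue
        if start is not None:
            run = xy[start:t]
            if len(run) >= w:
                windows = np.lib.stride_tricks.sliding_window_view(run, (w, n))
                out.append(windows.reshape(len(run) - w + 1, w * n))
                idx.append(np.arange(start + w - 1, t))
            start = None
    if not out:
        return np.empty((0, w * n)), np.empty(0, dtype=np.int64)
    return np.ascontiguousarray(np.vstack(out)), np.concatenate(idx)


# ---------------------------------------------------------------------------
# block-Toeplitz precision


def assemble_theta(blocks: list[np.ndarray]) -> np.ndarray:
    """Assemble the nw x nw block-Toeplitz matrix from blocks A(0)..A(w-1).

    Sub-block (r, c) equals ``A(r-c)`` below the diagonal and ``A(c-r)^T``
    above it.
    """
    w = len(blocks)
    n = blocks[0].shape[0]
    theta = np.zeros((w * n, w * n))
    for r in range(w):
        for c in range(w):
            k = r - c
            blk = blocks[k] if k >= 0 else blocks[-k].T
            theta[r * n:(r + 1) * n, c * n:(c + 1) * n] = blk
    return theta


@dataclass
class ToeplitzPrecision:
    """One cluster's block-Toeplitz precision with its window mean."""

    blocks: list
    mean: np.ndarray
    _theta: np.ndarray = field(default=None, repr=False)
    _logdet: float = field(default=None, repr=False)

    @property
    def w(self) -> int:
        return len(self.blocks)

    @property
    def n(self) -> int:
        return self.blocks[0].shape[0]

    @property
    def theta(self) -> np.ndarray:
        if self._theta is None:
            self._theta = assemble_theta(self.blocks)
        return self._theta

    @property
    def logdet(self) -> float:
        if self._logdet is None:
            sign, val = np.linalg.slogdet(self.theta)
            if sign <= 0:
                raise np.linalg.LinAlgError("precision matrix is not positive definite")
            self._logdet = float(val)
        return self._logdet


def log_likelihood(X: np.ndarray, theta: ToeplitzPrecision) -> np.ndarray:
    """Gaussian log density of stacked windows under one cluster.

    ``-1/2 (X-mu)' Theta (X-mu) + 1/2 log det Theta - (nw/2) log 2 pi``,
    vectorised over rows of ``X``.
    """
    arr = np.asarray(X, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    d = arr - theta.mean
    quad = np.einsum("ij,jk,ik->i", d, theta.theta, d)
    ll = -0.5 * quad + 0.5 * theta.logdet - 0.5 * arr.shape[1] * LOG_2PI
    return float(ll[0]) if single else ll


def emission_matrix(windows: np.ndarray, thetas: list[ToeplitzPrecision]) -> np.ndarray:
    """(T, K) matrix of per-cluster log likelihoods."""
    T = len(windows)
    out = np.empty((T, len(thetas)))
    for k, th in enumerate(thetas):
        d = windows - th.mean
        quad = np.einsum("ij,jk,ik->i", d, th.theta, d)
        out[:, k] = -0.5 * quad + 0.5 * th.logdet - 0.5 * windows.shape[1] * LOG_2PI
    return out


def assign_states(windows, thetas, beta: float) -> np.ndarray:
    """Exact minimiser of ``sum_t -ll(X_t, Theta_{s_t}) + beta 1{s_t != s_{t-1}}``.

    Dynamic programming over the K states; ties stay with the previous state,
    then break toward the lower state id.  ``windows`` may be the stacked
    array or a precomputed (T, K) log-likelihood matrix when ``thetas`` is
    None.
    """
    if thetas is None:
        emis = np.asarray(windows, dtype=float)
    else:
        emis = emission_matrix(np.asarray(windows, dtype=float), thetas)
    if emis.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    return viterbi_switch(np.ascontiguousarray(-emis), float(beta))


# ---------------------------------------------------------------------------
# block-Toeplitz graphical lasso (ADMM)

_GROUP_CACHE: dict = {}


def _toeplitz_groups(w: int, n: int):
    """Group index per entry of Theta; entries in a group share one A value.

    Returns (group_ids (nw, nw) int array, n_groups, is_diagonal_group,
    block_of_group, cell_of_group).
    """
    key = (w, n)
    if key in _GROUP_CACHE:
        return _GROUP_CACHE[key]
    nw = w * n
    gid = np.empty((nw, nw), dtype=np.int64)
    groups = {}

    def group_key(r, c, i, j):
        k = r - c
        if k > 0:
            return (k, i, j)
        if k < 0:
            return (-k, j, i)
        return (0, min(i, j), max(i, j))  # A(0) symmetric

    for r in range(w):
        for c in range(w):
            for i in range(n):
                for j in range(n):
                    gk = group_key(r, c, i, j)
                    gid[r * n + i, c * n + j] = groups.setdefault(gk, len(groups))
    n_groups = len(groups)
    keys = sorted(groups, key=groups.get)
    is_diag = np.array([k[0] == 0 and k[1] == k[2] for k in keys])
    block = np.array([k[0] for k in keys])
    cell = np.array([(k[1], k[2]) for k in keys])
    _GROUP_CACHE[key] = (gid, n_groups, is_diag, block, cell)
    return _GROUP_CACHE[key]


def _project_groups(M: np.ndarray, gid: np.ndarray, n_groups: int) -> np.ndarray:
    """Group means of M, one value per Toeplitz parameter group."""
    counts = np.bincount(gid.ravel(), minlength=n_groups)
    sums = np.bincount(gid.ravel(), weights=M.ravel(), minlength=n_groups)
    return sums / counts


def _blocks_from_groups(values: np.ndarray, w: int, n: int) -> list[np.ndarray]:
    gid, n_groups, is_diag, block, cell = _toeplitz_groups(w, n)
    blocks = [np.zeros((n, n)) for _ in range(w)]
    for g in range(n_groups):
        k = block[g]
        i, j = cell[g]
        blocks[k][i, j] = values[g]
        if k == 0:
            blocks[0][j, i] = values[g]
    return blocks


def fit_toeplitz_precision(
    member_windows: np.ndarray,
    lam: float,
    w: int,
    n: int = 2,
    rho: float = 1.0,
    max_iter: int = 1000,
    abstol: float = 1e-5,
    reltol: float = 1e-4,
) -> ToeplitzPrecision:
    """Block-Toeplitz-constrained sparse precision fit for one cluster.

    Minimises ``-sum_t ll(X_t, Theta) + lam * ||offdiag(Theta)||_1`` over
    symmetric block-Toeplitz positive-definite matrices by ADMM.  The
    constraint-plus-l1 proximal step is exact: each Toeplitz parameter group
    is averaged, then soft-thresholded (diagonal unpenalised).

    With fewer than ``nw`` member windows the sample covariance is
    ridge-regularised (logged) so the problem stays well posed.
    """
    X = np.atleast_2d(np.asarray(member_windows, dtype=float))
    nw = w * n
    if X.shape[1] != nw:
        raise ConfigError(f"windows have dim {X.shape[1]}, expected w*n = {nw}")
    N = X.shape[0]
    mean = X.mean(axis=0)
    d = X - mean
    S = d.T @ d / max(N, 1)
    if N < nw:
        ridge = 1e-3 * (np.trace(S) / nw + 1.0)
        S = S + ridge * np.eye(nw)
        logger.info("fit_toeplitz_precision: %d < %d windows, ridge %.2e added", N, nw, ridge)
    if lam == 0.0 and w == 1:
        theta = np.linalg.inv(S)
        theta = 0.5 * (theta + theta.T)
        return ToeplitzPrecision(blocks=[theta], mean=mean)

    gid, n_groups, is_diag, _, _ = _toeplitz_groups(w, n)
    counts = np.bincount(gid.ravel(), minlength=n_groups).astype(float)
    # scale so the ADMM objective is -logdet + tr(S Theta) + lam' ||.||_1
    lam_eff = 2.0 * lam / max(N, 1)

    Z = np.linalg.inv(S + 0.1 * np.eye(nw))
    Z = _project_groups(Z, gid, n_groups)[gid]
    U = np.zeros((nw, nw))
    Theta = Z.copy()
    for it in range(max_iter):
        # Theta update: closed form via eigen-decomposition
        G = rho * (Z - U) - S
        vals, vecs = np.linalg.eigh(0.5 * (G + G.T))
        theta_vals = (vals + np.sqrt(vals ** 2 + 4.0 * rho)) / (2.0 * rho)
        Theta = (vecs * theta_vals) @ vecs.T
        # Z update: project onto the Toeplitz subspace, soft-threshold
        Z_old = Z
        V = _project_groups(Theta + U, gid, n_groups)
        thresh = np.where(is_diag, 0.0, lam_eff / rho)
        Vs = np.sign(V) * np.maximum(np.abs(V) - thresh, 0.0)
        Z = Vs[gid]
        U = U + Theta - Z
        r_norm = np.linalg.norm(Theta - Z)
        s_norm = rho * np.linalg.norm(Z - Z_old)
        eps_pri = abstol * nw + reltol * max(np.linalg.norm(Theta), np.linalg.norm(Z))
        eps_dual = abstol * nw + reltol * rho * np.linalg.norm(U)
        if r_norm < eps_pri and s_norm < eps_dual:
            break
        # adaptive penalty keeps the two residuals balanced
        if r_norm > 10.0 * s_norm:
            rho *= 2.0
            U /= 2.0
        elif s_norm > 10.0 * r_norm:
            rho /= 2.0
            U *= 2.0
    else:
        logger.warning("fit_toeplitz_precision: ADMM stopped at max_iter=%d "
                       "(residual %.2e); returning best iterate", max_iter, r_norm)
    group_vals = _project_groups(Z, gid, n_groups)
    blocks = _blocks_from_groups(group_vals, w, n)
    theta = assemble_theta(blocks)
    min_eig = float(np.linalg.eigvalsh(theta).min())
    if min_eig < 1e-8:
        bump = 1e-8 - min_eig
        blocks[0] = blocks[0] + bump * np.eye(n)
        logger.info("fit_toeplitz_precision: PD bump %.2e added to A(0) diagonal", bump)
    return ToeplitzPrecision(blocks=blocks, mean=mean)


# ---------------------------------------------------------------------------
# EM fit


@dataclass
class TICCConfig:
    """Hyperparameters of the segmentation.

    ``w`` (window, samples), ``beta`` (switching penalty) and ``lam``
    (l1 sparsity) default to the study settings: 5, 50 and 0.001.
    """

    K: int = 4
    w: int = 5
    beta: float = 50.0
    lam: float = 0.001
    max_iter: int = 100
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.w < 1 or self.beta < 0 or self.lam < 0:
            raise ConfigError("require K >= 1, w >= 1, beta >= 0, lam >= 0")


@dataclass
class TICCModel:
    thetas: list
    assignments: np.ndarray
    objective_trace: list
    config: TICCConfig
    converged: bool = True

    @property
    def K(self) -> int:
        return len(self.thetas)


def _cluster_objective(windows: np.ndarray, theta: ToeplitzPrecision, lam: float) -> float:
    """-sum ll + lam * ||offdiag(Theta)||_1 for one cluster's members."""
    ll = log_likelihood(windows, theta)
    pen = lam * (np.abs(theta.theta).sum() - np.abs(np.diag(theta.theta)).sum())
    return float(-np.sum(ll) + pen)


def ticc_objective(windows: np.ndarray, thetas, assignments, beta: float, lam: float) -> float:
    """The full switching-penalised, l1-regularised negative objective."""
    emis = emission_matrix(windows, thetas)
    ll = emis[np.arange(len(windows)), assignments].sum()
    switches = int(np.count_nonzero(np.diff(assignments)))
    pen = sum(
        lam * (np.abs(th.theta).sum() - np.abs(np.diag(th.theta)).sum()) for th in thetas
    )
    return float(-ll + beta * switches + pen)


def _init_features(X: np.ndarray, w: int, n: int) -> np.ndarray:
    """Per-window mean, log standard deviation and pairwise correlation."""
    V = X.reshape(len(X), w, n)
    mean = V.mean(axis=1)
    sd = V.std(axis=1) + 1e-9
    cols = [mean, np.log(sd)]
    if w > 1:
        centred = V - mean[:, None, :]
        for i in range(n):
            for j in range(i + 1, n):
                corr = (centred[:, :, i] * centred[:, :, j]).mean(axis=1) / (sd[:, i] * sd[:, j])
                cols.append(corr[:, None])
    return np.column_stack(cols)


def fit_ticc(windows: np.ndarray, config: TICCConfig) -> TICCModel:
    """Alternating minimisation from a seeded GMM initialisation.

    The objective trace is non-increasing: each precision refit is kept only
    if it improves its cluster's penalised likelihood over the previous
    iterate, and the assignment step is an exact DP minimiser.
    """
    X = np.atleast_2d(np.asarray(windows, dtype=float))
    K, w = config.K, config.w
    n = X.shape[1] // w
    if X.shape[1] != w * n:
        raise ConfigError("window dimension is not a multiple of w")
    if len(X) < K * X.shape[1]:
        raise ConfigError(f"need at least K*nw = {K * X.shape[1]} windows, got {len(X)}")

    if K == 1:
        labels = np.zeros(len(X), dtype=np.int64)
    else:
        # initialise on per-window summary features (location, log scale,
        # cross-correlation): states that differ mainly in covariance scale
        # are poorly separated by a GMM on the raw stacked windows
        feats = _init_features(X, w, n)
        rows = feats
        if len(feats) > 50000:  # deterministic thinning for the init only
            rows = feats[:: len(feats) // 50000 + 1]
        gmm = GaussianMixture(n_components=K, covariance_type="full",
                              reg_covar=1e-6, random_state=config.seed, n_init=10)
        gmm.fit(rows)
        labels = gmm.predict(feats).astype(np.int64)

    thetas = [None] * K
    trace = []
    converged = False
    for it in range(config.max_iter):
        new_thetas = []
        for k in range(K):
            members = X[labels == k]
            if len(members) == 0:
                # re-seed an empty cluster from the worst-fit windows
                logger.info("fit_ticc: cluster %d empty at iter %d, re-seeding", k, it)
                emis = emission_matrix(X, [t for t in thetas if t is not None])
                worst = np.argsort(emis.max(axis=1))[: X.shape[1]]
                members = X[worst]
            prev = thetas[k]
            fitted = fit_toeplitz_precision(members, config.lam, w, n)
            if prev is not None and _cluster_objective(members, prev, config.lam) < \
                    _cluster_objective(members, fitted, config.lam):
                fitted = prev  # safeguard: never accept a worse solve
            new_thetas.append(fitted)
        thetas = new_thetas
        new_labels = assign_states(X, thetas, config.beta)
        trace.append(ticc_objective(X, thetas, new_labels, config.beta, config.lam))
        changed = np.mean(new_labels != labels)
        labels = new_labels
        if changed < config.tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_ticc: EM stopped at max_iter=%d", config.max_iter)
    return TICCModel(thetas=thetas, assignments=labels, objective_trace=trace,
                     config=config, converged=converged)


# ---------------------------------------------------------------------------
# model selection


def count_parameters(model: TICCModel) -> int:
    """Free parameters: unique non-zero A-block entries plus means, per cluster."""
    k_params = 0
    for th in model.thetas:
        n = th.n
        a0 = th.blocks[0]
        iu = np.triu_indices(n)
        k_params += int(np.count_nonzero(np.abs(a0[iu]) > ZERO_TOL))
        for blk in th.blocks[1:]:
            k_params += int(np.count_nonzero(np.abs(blk) > ZERO_TOL))
        k_params += th.mean.size
    return k_params


def bic(model: TICCModel, windows: np.ndarray) -> float:
    """``-2 ln L + k ln n`` with L the maximised assigned-window likelihood."""
    X = np.atleast_2d(np.asarray(windows, dtype=float))
    emis = emission_matrix(X, model.thetas)
    lnL = float(emis[np.arange(len(X)), model.assignments].sum())
    k = count_parameters(model)
    return -2.0 * lnL + k * float(np.log(len(X)))


def select_k(windows: np.ndarray, k_range, config: TICCConfig):
    """Fit every K in ``k_range`` and return (best model, BIC table).

    The table records one row per K (BIC, convergence, any error); the best
    K is the argmin of BIC among successful fits.
    """
    rows = []
    models = {}
    for K in k_range:
        cfg = TICCConfig(K=K, w=config.w, beta=config.beta, lam=config.lam,
                         max_iter=config.max_iter, tol=config.tol, seed=config.seed)
        try:
            model = fit_ticc(windows, cfg)
            score = bic(model, windows)
            models[K] = model
            rows.append({"K": K, "bic": score, "converged": model.converged, "error": ""})
        except Exception as exc:  # recorded, not fatal for the sweep
            rows.append({"K": K, "bic": np.nan, "converged": False, "error": str(exc)})
    table = pd.DataFrame(rows)
    if table["bic"].isna().all():
        raise ConfigError("select_k: every K failed to fit")
    best_k = int(table.loc[table["bic"].idxmin(), "K"])
    return models[best_k], best_k, table
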