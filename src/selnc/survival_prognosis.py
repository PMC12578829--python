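"""Prognostic cascade: univariate Cox screen, L1-penalized Cox feature
selection with cross-validation, random-survival-forest risk scoring,
Kaplan-Meier / log-rank analysis by risk group, IPCW time-dependent AUC
and permutation feature importance.

Kaplan-Meier, log-rank and the Newton-Raphson Cox fit (Breslow tie
handling throughout) are implemented here directly so that they can be
checked against hand-computed and grid-search oracles; the penalized
path and the forest are backed by scikit-survival's coordinate-descent
Coxnet and log-rank-splitting RandomSurvivalForest behind the module's
own contracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # risk-set size just before each event time
    n_events: np.ndarray

    def __post_init__(self) -> None:
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival curve must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function starting at 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def survival_before(self, t: float) -> float:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Product-limit survival estimate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = len(time)
    out_t, out_s, out_r, out_d = [], [], [], []
    s = 1.0
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
        out_r.append(at_risk)
        out_d.append(d)
    return KMCurve(np.array(out_t), np.array(out_s),
                   np.array(out_r), np.array(out_d))


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) from chi-square(1)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    g1 = group == labels[1]
    if g1.all() or (~g1).all():
        raise ValueError("one group is empty")
    observed_minus_expected = 0.0
    variance = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_total = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d_total = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & g1).sum())
        expected = d_total * n1 / n_total
        observed_minus_expected += d1 - expected
        if n_total > 1:
            variance += (d_total * (n1 / n_total) * (1 - n1 / n_total)
                         * (n_total - d_total) / (n_total - 1))
    if variance == 0:
        return 0.0, 1.0
    chi2 = observed_minus_expected ** 2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson, Breslow ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))


def cox_partial_loglik(beta, X, time, event) -> float:
    """Breslow log partial likelihood at ``beta``."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # descending: prefix = risk set
    eta_d, time_d, event_d = eta[order], time[order], event[order]
    cum = np.cumsum(np.exp(eta_d))
    ll = 0.0
    i = 0
    n = len(time_d)
    while i < n:
        j = i
        while j < n and time_d[j] == time_d[i]:
            j += 1
        d = int(event_d[i:j].sum())
        if d > 0:
            ll += float(eta_d[i:j][event_d[i:j] == 1].sum())
            ll -= d * np.log(cum[j - 1])
        i = j
    return float(ll)


def _cox_derivatives(beta, X, time, event):
    """(loglik, gradient, negative Hessian) under Breslow ties."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")
    X_d, eta_d, time_d, event_d = X[order], eta[order], time[order], event[order]
    w = np.exp(eta_d)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * X_d, axis=0)
    s2 = np.cumsum(w[:, None, None] * (X_d[:, :, None] * X_d[:, None, :]), axis=0)
    p = X.shape[1]
    ll, grad, info = 0.0, np.zeros(p), np.zeros((p, p))
    i, n = 0, len(time_d)
    while i < n:
        j = i
        while j < n and time_d[j] == time_d[i]:
            j += 1
        ev = event_d[i:j] == 1
        d = int(ev.sum())
        if d > 0:
            xe = X_d[i:j][ev]
            ll += float(eta_d[i:j][ev].sum()) - d * np.log(s0[j - 1])
            mean_x = s1[j - 1] / s0[j - 1]
            grad += xe.sum(axis=0) - d * mean_x
            info += d * (s2[j - 1] / s0[j - 1] - np.outer(mean_x, mean_x))
        i = j
    return ll, grad, info


def cox_fit(X, time, event, l2_eps: float = 1e-9,
            tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Newton-Raphson maximum partial likelihood with a tiny ridge.

    Raises on constant columns; non-convergence is flagged, never silent.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(time)) > 1:
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant column in X")
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _cox_derivatives(beta, X, time, event)
    ll -= 0.5 * l2_eps * beta @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad_pen = grad - l2_eps * beta
        info_pen = info + l2_eps * np.eye(p)
        try:
            step = np.linalg.solve(info_pen, grad_pen)
        except np.linalg.LinAlgError:
            break
        if not np.isfinite(step).all():
            break
        # step-halving line search on the penalized log likelihood
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new = (cox_partial_loglik(beta_new, X, time, event)
                      - 0.5 * l2_eps * beta_new @ beta_new)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            break
        beta = beta_new
        ll_raw, grad, info = _cox_derivatives(beta, X, time, event)
        ll = ll_raw - 0.5 * l2_eps * beta @ beta
        if np.abs(grad - l2_eps * beta).max() < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(info + l2_eps * np.eye(p))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
        converged = False
    if not converged:
        logger.warning("Cox fit did not converge after %d iterations", it)
    if not np.isfinite(se).all() or (se <= 0).any():
        converged = False
        se = np.where(np.isfinite(se) & (se > 0), se, np.inf)
    if p > 1 and np.linalg.cond(info + l2_eps * np.eye(p)) > 1e10:
        converged = False  # collinear design: flag instability, never silent
    return CoxFit(beta=beta, se=se,
                  loglik=cox_partial_loglik(beta, X, time, event),
                  converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    feature_ids: list[str]
    beta: np.ndarray
    p: np.ndarray
    q: np.ndarray
    logrank_p: np.ndarray
    significant: list[str]
    skipped: list[str]


def univariate_screen(X, time, event, feature_ids=None,
                      alpha: float = 0.05) -> ScreenResult:
    """One Cox fit per feature, BH across features; a median-split
    log-rank p is reported as a secondary column.  Constant features are
    skipped with a warning and listed in ``skipped``."""
    from selnc.expression_analytics import bh_fdr

    X = np.asarray(X, dtype=float)
    n, p = X.shape
    feature_ids = list(feature_ids) if feature_ids is not None \
        else [f"f{i}" for i in range(p)]
    betas, pvals, lr_pvals, kept, skipped = [], [], [], [], []
    for j in range(p):
        col = X[:, j]
        if col.std() == 0:
            logger.warning("feature %s is constant; skipped", feature_ids[j])
            skipped.append(feature_ids[j])
            continue
        fit = cox_fit(col[:, None], time, event)
        betas.append(fit.beta[0])
        pvals.append(fit.p[0] if fit.converged else 1.0)
        median = np.median(col)
        grp = col > median
        if grp.any() and (~grp).any():
            _, lr_p = logrank_test(time, event, grp.astype(int))
        else:
            lr_p = 1.0
        lr_pvals.append(lr_p)
        kept.append(feature_ids[j])
    if not kept:
        raise ValueError("no usable (non-constant) features")
    q = bh_fdr(np.array(pvals))
    significant = [f for f, qv in zip(kept, q) if qv < alpha]
    return ScreenResult(kept, np.array(betas), np.array(pvals), q,
                        np.array(lr_pvals), significant, skipped)


# ---------------------------------------------------------------------------
# LASSO Cox path with cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LassoPath:
    lambdas: np.ndarray          # descending
    beta: np.ndarray             # feature x lambda, original scale
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    selected_lambda: float
    selected_features: list[str]
    feature_ids: list[str]


def lasso_cox_path(X, time, event, feature_ids=None, n_lambda: int = 50,
                   cv_folds: int = 5, rule: str = "1se",
                   seed: int = 0, lambdas=None) -> LassoPath:
    """L1-penalized Cox path (coordinate descent) with k-fold CV selection.

    Columns are z-scaled internally; coefficients are reported on the
    original scale.  Held-out deviance uses the Verweij-van Houwelingen
    form -2*[l(beta; all) - l(beta; train)].
    """
    if rule not in {"min", "1se"}:
        raise ValueError("rule must be 'min' or '1se'")
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    feature_ids = list(feature_ids) if feature_ids is not None \
        else [f"f{i}" for i in range(p)]
    if cv_folds > int(event.sum()):
        raise ValueError("cv_folds exceeds the number of events")

    mu, sd = X.mean(axis=0), X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant column in X")
    Xs = (X - mu) / sd
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if lambdas is not None:
        base = CoxnetSurvivalAnalysis(l1_ratio=1.0, tol=1e-9,
                                      alphas=np.sort(np.asarray(lambdas))[::-1])
    else:
        base = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_lambda,
                                      alpha_min_ratio=1e-3, tol=1e-7)
    base.fit(Xs, y)
    explicit_grid = lambdas is not None
    lambdas = np.asarray(base.alphas_)
    beta_std = np.asarray(base.coef_)  # feature x lambda
    if not explicit_grid and np.abs(beta_std[:, 0]).max() > 0:
        # prepend an all-zero lambda so the path starts at the null model
        lam0 = lambdas[0] * 1.5
        refit = CoxnetSurvivalAnalysis(l1_ratio=1.0, tol=1e-7,
                                       alphas=np.r_[lam0, lambdas])
        refit.fit(Xs, y)
        lambdas = np.asarray(refit.alphas_)
        beta_std = np.asarray(refit.coef_)

    rng = np.random.default_rng(seed)
    # event-stratified fold assignment keeps events in every training set
    folds = np.empty(n, dtype=int)
    for mask in (event == 1, event == 0):
        idx = np.nonzero(mask)[0]
        idx = idx[rng.permutation(len(idx))]
        folds[idx] = np.arange(len(idx)) % cv_folds

    deviance = np.zeros((cv_folds, len(lambdas)))
    for k in range(cv_folds):
        train = folds != k
        model_k = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=lambdas, tol=1e-7)
        model_k.fit(Xs[train], Surv.from_arrays(event=event[train].astype(bool),
                                                time=time[train]))
        beta_k = np.asarray(model_k.coef_)
        alphas_k = np.asarray(model_k.alphas_)
        for m in range(len(lambdas)):
            # coxnet may truncate the path; use the nearest fitted lambda
            mk = int(np.argmin(np.abs(alphas_k - lambdas[m])))
            ll_all = cox_partial_loglik(beta_k[:, mk], Xs, time, event)
            ll_train = cox_partial_loglik(beta_k[:, mk], Xs[train],
                                          time[train], event[train])
            deviance[k, m] = -2.0 * (ll_all - ll_train)
    cv_mean = deviance.mean(axis=0)
    cv_se = deviance.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[i_min])
    within = np.nonzero(cv_mean <= cv_mean[i_min] + cv_se[i_min])[0]
    i_1se = int(within[0])  # largest lambda within one SE (grid is descending)
    lambda_1se = float(lambdas[i_1se])
    i_sel = i_min if rule == "min" else i_1se
    beta_orig = beta_std / sd[:, None]
    selected = [feature_ids[j] for j in np.nonzero(beta_std[:, i_sel])[0]]
    return LassoPath(lambdas, beta_orig, cv_mean, cv_se, lambda_min,
                     lambda_1se, float(lambdas[i_sel]), selected, feature_ids)


# ---------------------------------------------------------------------------
# Random survival forest risk model
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    feature_ids: list[str]
    estimator: RandomSurvivalForest
    n_trees: int
    mtry: int
    min_node_events: int
    seed: int

    @property
    def trees(self) -> list[dict]:
        """Split structure of each fitted tree (for introspection)."""
        out = []
        for est in self.estimator.estimators_:
            t = est.tree_
            out.append({
                "feature": t.feature.copy(),
                "threshold": t.threshold.copy(),
                "children_left": t.children_left.copy(),
                "children_right": t.children_right.copy(),
            })
        return out


def rsf_fit(X_selected, time, event, feature_ids=None, n_trees: int = 200,
            mtry: int | None = None, min_node_events: int = 3,
            seed: int = 0) -> RiskModel:
    """Random survival forest (log-rank splitting, Nelson-Aalen leaves).

    The risk score of :func:`risk_score` is the ensemble cumulative
    hazard summed over the event-time grid; higher means worse expected
    survival.  Deterministic given ``seed``.
    """
    X = np.asarray(X_selected, dtype=float)
    n, p = X.shape
    if n_trees < 10:
        raise ValueError("n_trees must be >= 10")
    feature_ids = list(feature_ids) if feature_ids is not None \
        else [f"f{i}" for i in range(p)]
    mtry = mtry or max(1, int(np.sqrt(p)))
    est = RandomSurvivalForest(
        n_estimators=n_trees,
        max_features=min(mtry, p),
        min_samples_leaf=max(min_node_events, 1),
        n_jobs=1,
        random_state=seed,
    )
    est.fit(X, Surv.from_arrays(event=np.asarray(event, dtype=bool),
                                time=np.asarray(time, dtype=float)))
    return RiskModel(feature_ids, est, n_trees, mtry, min_node_events, seed)


def risk_score(model: RiskModel, X) -> np.ndarray:
    return np.asarray(model.estimator.predict(np.asarray(X, dtype=float)))


def feature_importance(model: RiskModel, X, time, event, n_perm: int = 10,
                       seed: int = 0) -> list[tuple[str, float]]:
    """Permutation importance: drop in Harrell C-index when one feature's
    column is permuted, averaged over ``n_perm`` permutations.  Sorted
    descending, ties broken by feature name."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    event_b = np.asarray(event, dtype=bool)
    time = np.asarray(time, dtype=float)
    base = concordance_index_censored(event_b, time, risk_score(model, X))[0]
    rng = np.random.default_rng(seed)
    importances = []
    for j, name in enumerate(model.feature_ids):
        drops = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(X)), j]
            c = concordance_index_censored(event_b, time, risk_score(model, Xp))[0]
            drops.append(base - c)
        importances.append((name, float(np.mean(drops))))
    importances.sort(key=lambda kv: (-kv[1], kv[0]))
    return importances


# ---------------------------------------------------------------------------
# Time-dependent AUC and risk-group analysis
# ---------------------------------------------------------------------------

def time_dependent_auc(scores, time, event, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with IPCW case weights.

    Cases are samples with an event at or before the horizon, controls
    those still under observation beyond it.  Case i is weighted by
    1/G(T_i-) where G is the Kaplan-Meier estimate of the censoring
    survival; score ties contribute 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if not cases.any():
        raise ValueError(f"no cases (events at or before t={horizon})")
    if not controls.any():
        raise ValueError(f"no controls (followed beyond t={horizon})")

    cens_event = 1 - event
    if cens_event.sum() > 0:
        G = km_estimate(time, cens_event)
        w = np.array([1.0 / max(G.survival_before(t), 1e-12)
                      for t in time[cases]])
    else:
        w = np.ones(int(cases.sum()))

    s_case, s_ctrl = scores[cases], scores[controls]
    conc = (s_case[:, None] > s_ctrl[None, :]).sum(axis=1) \
        + 0.5 * (s_case[:, None] == s_ctrl[None, :]).sum(axis=1)
    return float((w * conc).sum() / (w.sum() * len(s_ctrl)))


@dataclass
class RiskGroupResult:
    km_high: KMCurve
    km_low: KMCurve
    chi2: float
    logrank_p: float
    score_time_rho: float  # Spearman rho among events
    threshold: float


def risk_group_analysis(scores, time, event) -> RiskGroupResult:
    """Median split into high/low risk, KM per group, log-rank test and
    the sign of the score-vs-survival-time association among events."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(scores) < 4:
        raise ValueError("need >= 4 samples")
    if np.ptp(scores) == 0:
        raise ValueError("all risk scores identical; no split possible")
    threshold = float(np.median(scores))
    high = scores > threshold
    if not high.any() or high.all():
        # fall back: split at the mean when the median ties everything high/low
        threshold = float(scores.mean())
        high = scores > threshold
    if not high.any() or high.all():
        raise ValueError("degenerate score distribution; no split possible")
    chi2, p = logrank_test(time, event, high.astype(int))
    ev = event == 1
    if ev.sum() >= 3 and np.ptp(scores[ev]) > 0:
        rho = float(stats.spearmanr(scores[ev], time[ev])[0])
    else:
        rho = float("nan")
    return RiskGroupResult(
        km_high=km_estimate(time[high], event[high]),
        km_low=km_estimate(time[~high], event[~high]),
        chi2=chi2, logrank_p=p, score_time_rho=rho, threshold=threshold,
    )
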