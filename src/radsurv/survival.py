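"""Right-censored survival statistics: Cox proportional hazards, concordance,
Kaplan-Meier / Nelson-Aalen estimators, logrank tests and maximally selected
cut-offs.

All estimators take a pair of aligned arrays ``time`` (strictly positive
follow-up times) and ``event`` (1 = event observed, 0 = right-censored).
Tied event times are handled with the Breslow convention throughout: every
event at a tied time uses the full risk set at that time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "CoxFit",
    "HazardCurve",
    "SurvivalCurve",
    "CutoffResult",
    "ConvergenceError",
    "cox_partial_loglik",
    "cox_partial_loglik_grad",
    "fit_cox",
    "stepwise_select",
    "concordance_index",
    "kaplan_meier",
    "nelson_aalen",
    "logrank_test",
    "optimal_cutoff",
]


class ConvergenceError(RuntimeError):
    """Raised when the Newton solver fails (non-convergence or separation)."""


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _check_time_event(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValueError("time and event must be aligned 1-D arrays")
    if np.any(time <= 0):
        raise ValueError("follow-up times must be strictly positive")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicators must be 0 (censored) or 1 (event)")
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def cox_partial_loglik(risks, time, event):
    """Log partial likelihood of linear predictors under the Cox model.

    ``sum_{i: event} [eta_i - log sum_{j: T_j >= T_i} exp(eta_j)]`` with the
    Breslow convention for ties (each tied event sees the full risk set at
    its time).  Raises ``ValueError`` when no event is observed, because the
    partial likelihood is then an empty product.
    """
    eta = np.asarray(risks, dtype=float)
    time, event = _check_time_event(time, event)
    if eta.shape != time.shape:
        raise ValueError("risks must align with records")
    if event.sum() == 0:
        raise ValueError("partial likelihood undefined without events")

    order = np.argsort(time, kind="stable")
    t, d, e = time[order], event[order], eta[order]
    n = len(t)
    # log of the risk-set sum for each position: subjects with T >= t_i.
    # Walk from the latest time backwards, accumulating a stable logsumexp.
    log_denom = np.empty(n)
    running = -np.inf
    i = n - 1
    while i >= 0:
        j = i
        while j >= 0 and t[j] == t[i]:
            j -= 1
        running = np.logaddexp(running, logsumexp(e[j + 1 : i + 1]))
        log_denom[j + 1 : i + 1] = running
        i = j
    return float(np.sum((e - log_denom)[d == 1]))


def cox_partial_loglik_grad(risks, time, event):
    """Gradient of :func:`cox_partial_loglik` with respect to the risks.

    d ll / d eta_j = event_j - exp(eta_j) * sum_{i: t_i <= t_j, event_i}
    d_i-weighted 1/S(t_i), with S(t) the risk-set sum of exp(eta).
    """
    eta = np.asarray(risks, dtype=float)
    time, event = _check_time_event(time, event)
    if event.sum() == 0:
        raise ValueError("partial likelihood undefined without events")

    order = np.argsort(time, kind="stable")
    t, d, e = time[order], event[order], eta[order]
    n = len(t)
    shift = e.max()  # stabilize exp
    w = np.exp(e - shift)
    # S(t_i) over tie groups, from latest backwards
    S = np.empty(n)
    running = 0.0
    i = n - 1
    while i >= 0:
        j = i
        while j >= 0 and t[j] == t[i]:
            j -= 1
        running += w[j + 1 : i + 1].sum()
        S[j + 1 : i + 1] = running
        i = j
    # cumulative sum of d_i / S(t_i) over event times <= t_j
    inv = np.where(d == 1, 1.0 / S, 0.0)
    cum = np.cumsum(inv)
    # subjects in the same tie group share the same cumulative value: take the
    # group's last index so every member sees all events at its own time
    grp_last = np.empty(n, dtype=int)
    i = n - 1
    while i >= 0:
        j = i
        while j >= 0 and t[j] == t[i]:
            j -= 1
        grp_last[j + 1 : i + 1] = i
        i = j
    grad_sorted = d - w * cum[grp_last]
    grad = np.empty(n)
    grad[order] = grad_sorted
    return grad


# ---------------------------------------------------------------------------
# Cox PH fitting (Newton with step-halving) and stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``p_values`` are nested-model likelihood-ratio tests: for each covariate
    the model is refit without it and twice the log-likelihood difference is
    referred to a 1-df chi-square.
    """

    coefficients: dict[str, float]
    hazard_ratios: dict[str, float]
    p_values: dict[str, float]
    selected: list[str]
    log_partial_likelihood: float
    standard_errors: dict[str, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return len(self.selected) == 0


def _cox_nll_grad_hess(beta, X, time, event):
    """Negative log partial likelihood with gradient and Hessian in beta."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")[::-1]  # descending time
    Xs, ts, ds = X[order], time[order], event[order]
    eta = Xs @ beta
    shift = eta.max()
    w = np.exp(eta - shift)

    nll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        blk = slice(i, j)
        wb = w[blk]
        Xb = Xs[blk]
        S0 += wb.sum()
        S1 += wb @ Xb
        S2 += (Xb * wb[:, None]).T @ Xb
        ev = ds[blk] == 1
        d_l = int(ev.sum())
        if d_l:
            # S0 can underflow to 0 for extreme trial coefficients during
            # line search; clamp so the step is rejected by a huge loss
            # instead of propagating NaNs
            S0c = S0 if S0 > 0 else np.finfo(float).tiny
            xbar = S1 / S0c
            nll -= eta[blk][ev].sum() - d_l * (np.log(S0c) + shift)
            grad -= Xb[ev].sum(axis=0) - d_l * xbar
            hess += d_l * (S2 / S0c - np.outer(xbar, xbar))
        i = j
    return nll, grad, hess


def fit_cox(X, time, event, names=None, tol=1e-8, max_iter=100,
            compute_p_values=True):
    """Fit a Cox PH model by Newton-Raphson on the partial likelihood.

    Parameters
    ----------
    X : (n, p) array or DataFrame of covariates. Constant columns are
        rejected. Columns are centered internally (the partial likelihood is
        invariant; coefficients are unchanged).
    names : covariate names; taken from DataFrame columns when omitted.

    Returns a :class:`CoxFit` whose ``selected`` lists every covariate (no
    selection is performed here) and whose p-values are 1-df likelihood-ratio
    tests against the model with that covariate removed.
    """
    if hasattr(X, "columns"):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    time, event = _check_time_event(time, event)
    n, p = X.shape
    if names is None:
        names = [f"x{k}" for k in range(p)]
    if len(names) != p:
        raise ValueError("names length must match covariate count")
    if n <= p:
        raise ValueError("need more subjects than covariates")
    if event.sum() == 0:
        raise ValueError("cannot fit a Cox model with zero events")
    col_sd = X.std(axis=0)
    if np.any(col_sd == 0):
        bad = [names[k] for k in np.where(col_sd == 0)[0]]
        raise ValueError(f"constant covariate(s): {bad}")

    Xc = X - X.mean(axis=0)
    beta = np.zeros(p)
    nll, grad, hess = _cox_nll_grad_hess(beta, Xc, time, event)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        # step-halving line search on the negative log-likelihood
        lam = 1.0
        for _ in range(30):
            cand = beta - lam * step
            nll_new, grad_new, hess_new = _cox_nll_grad_hess(cand, Xc, time, event)
            if nll_new <= nll + 1e-12:
                break
            lam *= 0.5
        else:
            raise ConvergenceError("step-halving failed to reduce the loss")
        beta, nll, grad, hess = cand, nll_new, grad_new, hess_new
        if np.any(np.abs(beta) > 50):
            raise ConvergenceError("diverging coefficients (likely separation)")
    else:
        if np.linalg.norm(grad) >= tol:
            raise ConvergenceError("Newton solver did not converge")
    if not converged and np.linalg.norm(grad) >= tol:
        raise ConvergenceError("Newton solver did not converge")

    if np.any(np.abs(beta) > 20):
        # a log-hazard ratio beyond +-20 with a converged gradient means the
        # likelihood is monotone in that coefficient (complete separation)
        raise ConvergenceError("implausibly large coefficient (likely separation)")
    ll_full = -nll
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    p_values = {}
    if compute_p_values:
        for k, nm in enumerate(names):
            if p == 1:
                ll_restricted = cox_partial_loglik(np.zeros(n), time, event)
            else:
                sub = np.delete(Xc, k, axis=1)
                sub_fit = fit_cox(sub, time, event,
                                  names=[m for m in names if m != nm],
                                  tol=tol, max_iter=max_iter,
                                  compute_p_values=False)
                ll_restricted = sub_fit.log_partial_likelihood
            lr = max(0.0, 2.0 * (ll_full - ll_restricted))
            p_values[nm] = float(stats.chi2.sf(lr, df=1))

    coeffs = {nm: float(b) for nm, b in zip(names, beta)}
    return CoxFit(
        coefficients=coeffs,
        hazard_ratios={nm: float(np.exp(b)) for nm, b in coeffs.items()},
        p_values=p_values,
        selected=list(names),
        log_partial_likelihood=float(ll_full),
        standard_errors={nm: float(s) for nm, s in zip(names, se)},
    )


def stepwise_select(X, time, event, names=None, alpha=0.05):
    """Backward elimination over a Cox model at significance level ``alpha``.

    Starting from the full model, repeatedly refit and drop the covariate
    whose nested-model likelihood-ratio p-value is largest and >= alpha;
    stop when every remaining covariate is significant. If nothing survives,
    an empty :class:`CoxFit` is returned (its concordance is then reported
    as not calculable by callers).
    """
    if hasattr(X, "columns"):
        if names is None:
            names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{k}" for k in range(X.shape[1])]
    names = list(names)
    if X.shape[1] < 1:
        raise ValueError("need at least one covariate")

    current = list(range(X.shape[1]))
    while current:
        try:
            fit = fit_cox(X[:, current], time, event,
                          names=[names[k] for k in current])
        except ConvergenceError:
            if len(current) == 1:
                break
            # non-convergence (typically separation in a small sample):
            # back off by removing the covariate whose removal leaves the
            # best-converging restricted model
            best_ll, best_drop = -np.inf, None
            for pos in range(len(current)):
                sub = [c for k, c in enumerate(current) if k != pos]
                try:
                    sub_fit = fit_cox(X[:, sub], time, event,
                                      names=[names[k] for k in sub],
                                      compute_p_values=False)
                except ConvergenceError:
                    continue
                if sub_fit.log_partial_likelihood > best_ll:
                    best_ll, best_drop = sub_fit.log_partial_likelihood, pos
            if best_drop is None:
                break
            del current[best_drop]
            continue
        pvals = np.array([fit.p_values[names[k]] for k in current])
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            return fit
        del current[worst]
    ll0 = (cox_partial_loglik(np.zeros(X.shape[0]), time, event)
           if np.asarray(event).sum() > 0 else float("nan"))
    return CoxFit(coefficients={}, hazard_ratios={}, p_values={},
                  selected=[], log_partial_likelihood=ll0)


# ---------------------------------------------------------------------------
# Concordance index
# ---------------------------------------------------------------------------

def concordance_index(predictions, time, event, tie_policy="half", kind="risk"):
    """Fraction of permissible ordered pairs ranked correctly.

    A pair (i, j) is permissible when subject i has an observed event and
    T_j > T_i. With ``kind='time'`` the predictions are predicted event
    times and the pair counts when f(x_i) < f(x_j); with ``kind='risk'``
    (default) higher prediction means earlier expected event, so the
    comparison is sign-flipped. ``tie_policy='half'`` (Harrell) credits tied
    predictions 1/2 so a constant predictor scores 0.5; ``'strict'`` awards
    ties 0 (the literal indicator definition).
    """
    pred = np.asarray(predictions, dtype=float)
    time, event = _check_time_event(time, event)
    if pred.shape != time.shape:
        raise ValueError("predictions must align with records")
    if kind not in ("risk", "time"):
        raise ValueError("kind must be 'risk' or 'time'")
    if tie_policy not in ("half", "strict"):
        raise ValueError("tie_policy must be 'half' or 'strict'")
    f = -pred if kind == "risk" else pred  # work on the predicted-time scale

    permissible = (event[:, None] == 1) & (time[None, :] > time[:, None])
    n_pairs = int(permissible.sum())
    if n_pairs == 0:
        raise ValueError("no permissible pairs (need an event before another time)")
    conc = (f[:, None] < f[None, :]) & permissible
    score = float(conc.sum())
    if tie_policy == "half":
        ties = (f[:, None] == f[None, :]) & permissible
        score += 0.5 * float(ties.sum())
    return score / n_pairs


# ---------------------------------------------------------------------------
# Nonparametric estimators
# ---------------------------------------------------------------------------

@dataclass
class HazardCurve:
    """Nelson-Aalen cumulative hazard: increments d_l / Y_l at event times."""

    times: np.ndarray  # distinct event times, increasing
    chf: np.ndarray    # cumulative hazard at those times
    at_risk: np.ndarray
    deaths: np.ndarray

    def evaluate(self, grid):
        """Step-function value of the CHF at each grid point (0 before the
        first event time)."""
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right")
        padded = np.concatenate([[0.0], self.chf])
        return padded[idx]


@dataclass
class SurvivalCurve:
    """Kaplan-Meier product-limit estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray

    def evaluate(self, grid):
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


def _event_table(time, event):
    """Distinct event times with death counts and numbers at risk."""
    etimes = np.unique(time[event == 1])
    deaths = np.array([(time[event == 1] == t).sum() for t in etimes], dtype=int)
    at_risk = np.array([(time >= t).sum() for t in etimes], dtype=int)
    return etimes, deaths, at_risk


def nelson_aalen(time, event):
    time, event = _check_time_event(time, event)
    etimes, deaths, at_risk = _event_table(time, event)
    if len(etimes) == 0:
        return HazardCurve(times=np.empty(0), chf=np.empty(0),
                           at_risk=np.empty(0, int), deaths=np.empty(0, int))
    return HazardCurve(times=etimes, chf=np.cumsum(deaths / at_risk),
                       at_risk=at_risk, deaths=deaths)


def kaplan_meier(time, event):
    time, event = _check_time_event(time, event)
    etimes, deaths, at_risk = _event_table(time, event)
    if len(etimes) == 0:
        return SurvivalCurve(times=np.empty(0), survival=np.empty(0),
                             at_risk=np.empty(0, int), deaths=np.empty(0, int))
    return SurvivalCurve(times=etimes, survival=np.cumprod(1.0 - deaths / at_risk),
                         at_risk=at_risk, deaths=deaths)


# ---------------------------------------------------------------------------
# Logrank test and maximally selected cut-off
# ---------------------------------------------------------------------------

def logrank_test(time1, event1, time2, event2):
    """Two-group logrank chi-square (1 df) and its p-value."""
    time1, event1 = _check_time_event(time1, event1)
    time2, event2 = _check_time_event(time2, event2)
    if len(time1) == 0 or len(time2) == 0:
        raise ValueError("both groups must be nonempty")
    if event1.sum() + event2.sum() == 0:
        raise ValueError("need at least one event across the two groups")

    time = np.concatenate([time1, time2])
    event = np.concatenate([event1, event2])
    group = np.concatenate([np.zeros(len(time1), int), np.ones(len(time2), int)])
    etimes = np.unique(time[event == 1])
    observed1 = 0.0
    expected1 = 0.0
    variance = 0.0
    for t in etimes:
        at = time >= t
        n_t = at.sum()
        n1 = (at & (group == 0)).sum()
        dying = (time == t) & (event == 1)
        d_t = dying.sum()
        d1 = (dying & (group == 0)).sum()
        observed1 += d1
        expected1 += d_t * n1 / n_t
        if n_t > 1:
            variance += d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
    if variance == 0:
        return 0.0, 1.0
    statistic = (observed1 - expected1) ** 2 / variance
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


@dataclass
class CutoffResult:
    threshold: float
    logrank_statistic: float
    p_value: float
    n_low: int
    n_high: int


def optimal_cutoff(values, time, event, min_group_fraction=0.1):
    """Maximally selected logrank cut-off for a continuous covariate.

    Scans midpoints between consecutive sorted unique values; a candidate is
    admissible when both induced groups hold at least ``min_group_fraction``
    of the subjects. Returns the threshold maximizing the logrank statistic.
    The reported p-value is the uncorrected p of the maximal statistic: it
    ignores the multiplicity of the scan and is anti-conservative.
    """
    values = np.asarray(values, dtype=float)
    time, event = _check_time_event(time, event)
    if values.shape != time.shape:
        raise ValueError("values must align with records")
    uniq = np.unique(values)
    if len(uniq) < 2:
        raise ValueError("covariate is constant; no cut-off exists")
    n = len(values)
    min_n = max(1, int(np.ceil(min_group_fraction * n)))

    thresholds = 0.5 * (uniq[:-1] + uniq[1:])
    low = values[:, None] <= thresholds[None, :]          # (n, K)
    n_low = low.sum(axis=0)
    ok = (n_low >= min_n) & ((n - n_low) >= min_n)
    if not ok.any():
        raise ValueError("no admissible threshold under the group-size constraint")
    low = low[:, ok].astype(float)
    thresholds = thresholds[ok]

    # vectorized logrank statistic over all candidate splits at once
    etimes = np.unique(time[event == 1])
    at_risk = (time[None, :] >= etimes[:, None]).astype(float)   # (E, n)
    dying = ((time[None, :] == etimes[:, None])
             & (event[None, :] == 1)).astype(float)
    n_t = at_risk.sum(axis=1)
    d_t = dying.sum(axis=1)
    n1 = at_risk @ low                                            # (E, K)
    d1 = dying @ low
    frac = n1 / n_t[:, None]
    observed = d1.sum(axis=0)
    expected = (d_t[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = np.where(n_t[:, None] > 1,
                         d_t[:, None] * frac * (1 - frac)
                         * (n_t[:, None] - d_t[:, None]) / (n_t[:, None] - 1),
                         0.0)
    variance = vterm.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(variance > 0,
                        (observed - expected) ** 2 / variance, 0.0)
    best = int(np.argmax(stat))
    n_low_best = int(low[:, best].sum())
    return CutoffResult(threshold=float(thresholds[best]),
                        logrank_statistic=float(stat[best]),
                        p_value=float(stats.chi2.sf(stat[best], df=1)),
                        n_low=n_low_best, n_high=n - n_low_best)
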