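"""Right-censored survival statistics: Kaplan-Meier, log-rank, Cox PH.

The estimators here follow the conventions used throughout the package:
Breslow handling of tied event times (Efron available behind a flag),
events-before-censorings at tied times for the product-limit estimator,
and Wald inference on the log-hazard-ratio scale.  The unpenalized
Newton-Raphson Cox fit doubles as the reference solution that the
elastic-net path must approach as the penalty vanishes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalData",
    "KaplanMeierCurve",
    "CoxFitResult",
    "truncate_followup",
    "kaplan_meier",
    "logrank_test",
    "logrank_statistic",
    "cox_fit",
    "cox_loglik",
    "cox_gradient",
    "cox_score_test",
    "make_endpoints",
    "km_report",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SurvivalData:
    """Right-censored times (years), binary event flags, optional covariates."""

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be strictly positive")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event flags must be 0/1")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class KaplanMeierCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFitResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str = "breslow"

    @property
    def hazard_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> np.ndarray:
        return np.exp(self.coef - 1.959963984540054 * self.se)

    @property
    def ci_upper(self) -> np.ndarray:
        return np.exp(self.coef + 1.959963984540054 * self.se)

    @property
    def wald_z(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def wald_p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "hr": self.hazard_ratio,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "se": self.se,
                "wald_p": self.wald_p,
            },
            index=pd.Index(self.names, name="covariate"),
        )

    def to_json(self) -> str:
        d = {
            "n": self.n,
            "n_events": self.n_events,
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "ties": self.ties,
            "covariates": {
                name: {
                    "coef": float(c),
                    "hr": float(np.exp(c)),
                    "ci_lower": float(lo),
                    "ci_upper": float(hi),
                    "wald_p": float(p),
                }
                for name, c, lo, hi, p in zip(
                    self.names, self.coef, self.ci_lower, self.ci_upper, self.wald_p
                )
            },
        }
        return json.dumps(d, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# endpoint construction
# ---------------------------------------------------------------------------

def truncate_followup(data: SurvivalData, horizon: float = 5.0) -> SurvivalData:
    """Administratively censor follow-up beyond ``horizon`` years.

    Times strictly greater than the horizon become (horizon, censored);
    a time exactly at the horizon keeps its observed event status.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    beyond = data.time > horizon
    time = np.where(beyond, horizon, data.time)
    event = np.where(beyond, 0, data.event)
    return SurvivalData(time=time, event=event, covariates=data.covariates)


def make_endpoints(clinical: pd.DataFrame) -> dict[str, SurvivalData]:
    """Build OS and DFS endpoints from a clinical record table.

    Expected columns: ``followup_years`` (time to death or last follow-up),
    ``death`` (0/1), ``relapse`` (0/1) and ``relapse_years`` (time to relapse,
    ignored when ``relapse`` is 0).  OS events are deaths; DFS events are the
    first of relapse or death.
    """
    fu = clinical["followup_years"].to_numpy(dtype=float)
    death = clinical["death"].to_numpy(dtype=int)
    if np.any(fu <= 0):
        raise ValueError("negative or zero follow-up durations")
    covars = clinical.drop(
        columns=[c for c in ("followup_years", "death", "relapse", "relapse_years")
                 if c in clinical.columns]
    )
    os_data = SurvivalData(time=fu, event=death, covariates=covars)

    relapse = clinical.get("relapse")
    if relapse is None:
        dfs_data = SurvivalData(time=fu.copy(), event=death.copy(), covariates=covars)
    else:
        relapse = relapse.to_numpy(dtype=int)
        rel_t = clinical["relapse_years"].to_numpy(dtype=float)
        if np.any(relapse.astype(bool) & (rel_t <= 0)):
            raise ValueError("negative or zero relapse durations")
        dfs_t = np.where(relapse.astype(bool), np.minimum(rel_t, fu), fu)
        dfs_e = np.where(relapse.astype(bool) | death.astype(bool), 1, 0)
        dfs_data = SurvivalData(time=dfs_t, event=dfs_e, covariates=covars)
    return {"os": os_data, "dfs": dfs_data}


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Product-limit estimator.

    At tied times events are processed before censorings, i.e. a censored
    subject at an event time is still at risk for that event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, first_idx = np.unique(t, return_index=True)
    n = len(t)
    # number at risk just before each unique time; events per unique time
    at_risk = n - first_idx
    d = np.add.reduceat(e, first_idx)
    has_event = d > 0
    et, ar, dd = uniq[has_event], at_risk[has_event], d[has_event]
    surv = np.cumprod(1.0 - dd / ar)
    return KaplanMeierCurve(event_times=et, survival=surv, at_risk=ar, n_events=dd)


def km_report(times, events, groups) -> pd.DataFrame:
    """Tidy long-format KM curves per group, for export/plotting."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        km = kaplan_meier(times[mask], events[mask])
        for t, s, r, d in zip(km.event_times, km.survival, km.at_risk, km.n_events):
            rows.append({"group": g, "time": t, "survival": s,
                         "at_risk": int(r), "events": int(d)})
    return pd.DataFrame(rows, columns=["group", "time", "survival", "at_risk", "events"])


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_statistic(times, events, groups) -> float:
    """Two-group log-rank chi-square (observed minus expected form).

    Uses the hypergeometric variance at each distinct event time.  For k
    groups use :func:`logrank_test`, which generalizes via the quadratic
    form; this fast two-group path is also the permutation-test kernel.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError("logrank_statistic requires exactly two groups")
    x = (g == labels[1]).astype(float)

    order = np.argsort(times, kind="stable")
    t, e, x = times[order], events[order], x[order]
    uniq, first_idx = np.unique(t, return_index=True)
    n_at_risk = len(t) - first_idx
    d_tot = np.add.reduceat(e, first_idx).astype(float)
    # at-risk and events in group 1 per unique time
    cum_x = np.concatenate(([0.0], np.cumsum(x)))
    n1_at_risk = cum_x[-1] - cum_x[first_idx]
    d1 = np.add.reduceat(e * x, first_idx)

    mask = (d_tot > 0) & (n_at_risk > 1)
    n_r, n1_r, d_r, d1_r = n_at_risk[mask], n1_at_risk[mask], d_tot[mask], d1[mask]
    expected = d_r * n1_r / n_r
    var = d_r * (n1_r / n_r) * (1 - n1_r / n_r) * (n_r - d_r) / (n_r - 1)
    v = var.sum()
    if v <= 0:
        return 0.0
    return float((d1_r.sum() - expected.sum()) ** 2 / v)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank test across k >= 2 groups; returns (chi2, p) with k-1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = pd.unique(g)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if not np.any(g == lab):  # pragma: no cover - pd.unique precludes
            raise ValueError(f"empty group {lab!r}")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    if k == 2:
        chi2 = logrank_statistic(times, events, g)
        return chi2, float(stats.chi2.sf(chi2, df=1))

    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    ind = np.stack([(g[order] == lab).astype(float) for lab in labels], axis=1)
    uniq, first_idx = np.unique(t, return_index=True)
    n_at_risk = len(t) - first_idx
    d_tot = np.add.reduceat(e, first_idx).astype(float)
    cum = np.vstack([np.zeros((1, k)), np.cumsum(ind, axis=0)])
    nj = cum[-1] - cum[first_idx]            # at risk per group per time
    dj = np.add.reduceat(e[:, None] * ind, first_idx, axis=0)

    mask = (d_tot > 0) & (n_at_risk > 1)
    nj, dj = nj[mask], dj[mask]
    n_r, d_r = n_at_risk[mask].astype(float), d_tot[mask]
    exp_j = d_r[:, None] * nj / n_r[:, None]
    u = (dj - exp_j).sum(axis=0)[:-1]
    # covariance of the first k-1 components
    frac = nj / n_r[:, None]
    scale = d_r * (n_r - d_r) / (n_r - 1)
    cov = np.einsum("t,ti,tj->ij", scale, frac[:, :-1], frac[:, :-1]) * -1
    cov[np.diag_indices(k - 1)] = np.einsum(
        "t,ti->i", scale, frac[:, :-1] * (1 - frac[:, :-1])
    )
    chi2 = float(u @ np.linalg.solve(cov, u))
    return chi2, float(stats.chi2.sf(chi2, df=k - 1))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton-Raphson, Breslow/Efron ties)
# ---------------------------------------------------------------------------

def cox_loglik(beta, X, time, event, ties: str = "breslow") -> float:
    """Cox log partial likelihood at ``beta``."""
    eta = X @ beta
    return _loglik_eta(eta, time, event, ties)


def _loglik_eta(eta, time, event, ties: str = "breslow") -> float:
    order = np.argsort(time, kind="stable")
    eta_s, e_s, t_s = eta[order], event[order], time[order]
    w = np.exp(eta_s)
    # risk-set sums via reversed cumulative sum
    rev_cum = np.cumsum(w[::-1])[::-1]
    uniq, first_idx = np.unique(t_s, return_index=True)
    stops = np.append(first_idx[1:], len(t_s))
    ll = 0.0
    for start, stop in zip(first_idx, stops):
        ev = e_s[start:stop].astype(bool)
        d = int(ev.sum())
        if d == 0:
            continue
        s0 = rev_cum[start]
        ll += float(eta_s[start:stop][ev].sum())
        if ties == "breslow" or d == 1:
            ll -= d * np.log(s0)
        else:  # efron
            tied_sum = float(w[start:stop][ev].sum())
            for m in range(d):
                ll -= np.log(s0 - (m / d) * tied_sum)
    return float(ll)


def _grad_hess(beta, X, time, event, ties: str = "breslow"):
    """Gradient and (negative) Hessian of the log partial likelihood."""
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs, es, ts = X[order], event[order], time[order]
    eta = Xs @ beta
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = np.einsum("i,ij,ik->ijk", w, Xs, Xs)

    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    uniq, first_idx = np.unique(ts, return_index=True)
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    stops = np.append(first_idx[1:], len(ts))
    for start, stop in zip(first_idx, stops):
        ev = es[start:stop].astype(bool)
        d = int(ev.sum())
        if d == 0:
            continue
        xe = Xs[start:stop][ev]
        grad += xe.sum(axis=0)
        if ties == "breslow" or d == 1:
            mu = s1[start] / s0[start]
            grad -= d * mu
            hess += d * (s2[start] / s0[start] - np.outer(mu, mu))
        else:  # efron
            tw = w[start:stop][ev]
            tsum0 = tw.sum()
            tsum1 = (tw[:, None] * xe).sum(axis=0)
            tsum2 = np.einsum("i,ij,ik->jk", tw, xe, xe)
            for m in range(d):
                f = m / d
                den = s0[start] - f * tsum0
                num1 = s1[start] - f * tsum1
                num2 = s2[start] - f * tsum2
                mu = num1 / den
                grad -= mu
                hess += num2 / den - np.outer(mu, mu)
    return grad, hess


def cox_gradient(beta, X, time, event, ties: str = "breslow") -> np.ndarray:
    return _grad_hess(np.asarray(beta, float), X, time, event, ties)[0]


def cox_score_test(x, time, event) -> float:
    """Score (Rao) chi-square at beta = 0 for a single covariate.

    For a binary covariate this equals the two-group log-rank chi-square.
    """
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    grad, hess = _grad_hess(np.zeros(1), X, np.asarray(time, float),
                            np.asarray(event, int), "breslow")
    return float(grad[0] ** 2 / hess[0, 0])


def cox_fit(
    data: SurvivalData,
    covariate_names: list[str] | None = None,
    X: np.ndarray | None = None,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFitResult:
    """Maximum partial-likelihood Cox fit with Wald inference.

    Covariates come either from ``data.covariates[covariate_names]`` (must be
    numeric) or from an explicit design matrix ``X``.  Collinear covariates
    and monotone likelihood (perfect separation) are detected and reported.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    if X is None:
        if covariate_names is None or data.covariates is None:
            raise ValueError("supply covariate_names with data.covariates, or X")
        X = data.covariates[covariate_names].to_numpy(dtype=float)
        names = list(covariate_names)
    else:
        X = np.asarray(X, dtype=float)
        names = covariate_names or [f"x{j}" for j in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values")
    n, p = X.shape
    n_events = int(data.event.sum())
    if n_events < p + 1:
        raise ValueError(f"need at least {p + 1} events for {p} covariates, got {n_events}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < p:
        raise ValueError("collinear covariates detected")

    beta = np.zeros(p)
    ll_null = cox_loglik(beta, X, data.time, data.event, ties)
    ll = ll_null
    for it in range(max_iter):
        grad, hess = _grad_hess(beta, X, data.time, data.event, ties)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError("singular information matrix (possible separation)") from err
        # step-halving to guarantee ascent
        new_beta = beta + step
        new_ll = cox_loglik(new_beta, X, data.time, data.event, ties)
        halves = 0
        while new_ll < ll and halves < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = cox_loglik(new_beta, X, data.time, data.event, ties)
            halves += 1
        beta, delta_ll, ll = new_beta, new_ll - ll, new_ll
        if np.max(np.abs(step)) < tol or abs(delta_ll) < tol:
            break
    else:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")
    if np.max(np.abs(beta)) > 15:
        warnings.warn(
            "extreme coefficient magnitude: monotone likelihood / perfect "
            "separation is likely", RuntimeWarning, stacklevel=2,
        )
    _, hess = _grad_hess(beta, X, data.time, data.event, ties)
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return CoxFitResult(
        names=names, coef=beta, se=se, loglik=ll, loglik_null=ll_null,
        n=n, n_events=n_events, ties=ties,
    )
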