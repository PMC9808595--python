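"""Survival-signature modelling: Kaplan–Meier, log-rank, Cox, risk groups.

Implements the disease-free-survival arm: product-limit curves on median
expression splits, the two-group log-rank test, a multivariate Cox
proportional-hazards fit (Newton–Raphson on the Efron-corrected partial
likelihood), the linear risk score with median dichotomization, AIC,
time-dependent cumulative/dynamic ROC with inverse-probability-of-censoring
weights, and the five-group stratification by per-gene median expression.

Times are in years; ties at year resolution are expected, which is why the
Efron correction (not Breslow) is the default and only tie handling — users
comparing against Breslow-based software will see small differences at tied
event times.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pbscreen.errors import ConvergenceError, ValidationError

FIVE_GROUP_LABELS = {
    4: "Four_genes_high",
    3: "Three_genes_high",
    2: "Two_genes_high",
    1: "One_genes_high",
    0: "Low_group",
}


def _check_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValidationError("need at least one record")
    if t.size != e.size:
        raise ValidationError("time and event lengths differ")
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValidationError("times must be finite and non-negative")
    if not np.all((e == 0) | (e == 1)):
        raise ValidationError("event indicators must be 0 or 1")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


@dataclass
class KmCurve:
    """Product-limit estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""

    times: np.ndarray  # distinct event times, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S at each event time

    @property
    def median(self) -> float | None:
        """Earliest event time with S <= 0.5, or None if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else None

    def at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(time, event) -> KmCurve:
    """Kaplan–Meier curve over the distinct event times of the sample."""
    t, e = _check_time_event(time, event)
    event_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= u).sum() for u in event_times])
    n_events = np.array([((t == u) & (e == 1)).sum() for u in event_times])
    factors = 1.0 - n_events / n_at_risk if event_times.size else np.array([])
    surv = np.cumprod(factors) if event_times.size else np.array([])
    return KmCurve(event_times, n_at_risk, n_events, surv)


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test: ((sum O - E)^2 / sum V, chi-square df=1 p).

    The variance at each event time is hypergeometric. With no events at
    all, the statistic is 0 and p is 1.
    """
    ta, ea = _check_time_event(time_a, event_a)
    tb, eb = _check_time_event(time_b, event_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros_like(ta), np.ones_like(tb)])
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return 0.0, 1.0
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        at_risk = t >= u
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & (grp == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def dichotomize_median(expression_row) -> pd.Series:
    """Per-sample high/low by the row median; ties go to "high".

    A constant row cannot be split; everyone is labelled high and a warning
    is raised.
    """
    x = pd.Series(expression_row, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two samples to dichotomize")
    med = float(x.median())
    labels = pd.Series(np.where(x >= med, "high", "low"), index=x.index)
    if (labels == labels.iloc[0]).all():
        warnings.warn("degenerate median split: all samples on one side", stacklevel=2)
    return labels


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxModel:
    """A fitted Cox model: beta, SE, hazard ratios, logPL and AIC."""

    gene_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    log_partial_likelihood: float
    n: int
    n_events: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        """exp(beta -/+ 1.96 se), shape (p, 2)."""
        return np.exp(
            np.column_stack(
                [self.beta - 1.959963984540054 * self.se,
                 self.beta + 1.959963984540054 * self.se]
            )
        )

    @property
    def aic(self) -> float:
        return -2.0 * self.log_partial_likelihood + 2.0 * len(self.beta)

    def to_dict(self) -> dict:
        lo, hi = self.ci95[:, 0], self.ci95[:, 1]
        return {
            "genes": {
                g: {
                    "beta": float(b),
                    "se": float(s),
                    "hr": float(np.exp(b)),
                    "ci95": [float(a), float(c)],
                }
                for g, b, s, a, c in zip(self.gene_ids, self.beta, self.se, lo, hi)
            },
            "log_partial_likelihood": float(self.log_partial_likelihood),
            "aic": float(self.aic),
            "n": self.n,
            "n_events": self.n_events,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _efron_loglik(beta, t, e, x):
    """(logPL, gradient, Hessian) under the Efron tie correction.

    Risk-set sums are suffix cumulative sums over time-sorted samples, so
    one evaluation is O(n p^2) regardless of the number of event times.
    """
    order = np.argsort(t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]
    eta = xs @ beta
    w = np.exp(eta)
    n, p = xs.shape
    # suffix sums: index i -> sum over samples with time >= ts[i]
    cw = np.cumsum(w[::-1])[::-1]
    cwx = np.cumsum((w[:, None] * xs)[::-1], axis=0)[::-1]
    cwxx = np.cumsum((w[:, None, None] * xs[:, :, None] * xs[:, None, :])[::-1],
                     axis=0)[::-1]
    logpl = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for u in np.unique(ts[es == 1]):
        i0 = int(np.searchsorted(ts, u, side="left"))
        dead = (ts == u) & (es == 1)
        d = int(dead.sum())
        s_w, s_wx, s_wxx = cw[i0], cwx[i0], cwxx[i0]
        d_w = w[dead].sum()
        d_wx = w[dead] @ xs[dead]
        d_wxx = (w[dead, None] * xs[dead]).T @ xs[dead]
        logpl += eta[dead].sum()
        grad += xs[dead].sum(axis=0)
        for l in range(d):
            f = l / d
            phi = s_w - f * d_w
            a = s_wx - f * d_wx
            b = s_wxx - f * d_wxx
            logpl -= np.log(phi)
            grad -= a / phi
            hess -= b / phi - np.outer(a, a) / phi**2
    return logpl, grad, hess


def fit_cox(
    time,
    event,
    covariates: pd.DataFrame,
    *,
    ridge: float = 0.0,
    tol: float = 1e-7,
    max_iter: int = 50,
) -> CoxModel:
    """Maximize the Efron partial likelihood by Newton–Raphson.

    ``covariates`` is samples x predictors. Convergence when the largest
    score component falls below ``tol`` (or ``max_iter`` Newton steps with
    step-halving). Standard errors come from the inverse observed
    information. ``ridge`` adds an optional L2 penalty
    -ridge/2 * ||beta||^2 to the log partial likelihood (penalized mode);
    the reported logPL and AIC are always the unpenalized values.
    """
    t, e = _check_time_event(time, event)
    if e.sum() == 0:
        raise ValidationError("no events: Cox model cannot be fitted")
    x = np.asarray(covariates, dtype=float)
    names = list(covariates.columns)
    if x.shape[0] != t.size:
        raise ValidationError("covariate rows must match the number of samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("covariates must be finite")
    const = [names[j] for j in range(x.shape[1]) if np.ptp(x[:, j]) == 0]
    if const:
        raise ValidationError(f"constant covariates cannot be fitted: {const}")

    p = x.shape[1]
    beta = np.zeros(p)
    logpl, grad, hess = _efron_loglik(beta, t, e, x)
    for _ in range(max_iter):
        g = grad - ridge * beta
        h = hess - ridge * np.eye(p)
        if np.max(np.abs(g)) < tol:
            break
        try:
            step = np.linalg.solve(h, -g)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_logpl, new_grad, new_hess = _efron_loglik(new_beta, t, e, x)
        halvings = 0
        while (new_logpl - 0.5 * ridge * new_beta @ new_beta) < (
            logpl - 0.5 * ridge * beta @ beta
        ) and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_logpl, new_grad, new_hess = _efron_loglik(new_beta, t, e, x)
            halvings += 1
        if halvings == 20 and new_logpl <= logpl:
            break  # at a likelihood plateau: converged to machine precision
        beta, logpl, grad, hess = new_beta, new_logpl, new_grad, new_hess
        if np.max(np.abs(beta)) > 100:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone partial likelihood (perfect separation) for "
                f"covariate {worst!r}"
            )
    else:
        if np.max(np.abs(grad - ridge * beta)) >= 1e-6:
            raise ConvergenceError("Newton–Raphson did not converge")
    if ridge == 0.0 and np.max(np.abs(beta)) > 15:
        # score -> 0 as beta -> inf under a monotone likelihood, so Newton
        # "converges" at an absurd coefficient; call it out instead
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"monotone partial likelihood (perfect separation) for "
            f"covariate {worst!r}"
        )
    info = -(hess - ridge * np.eye(p))
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return CoxModel(
        gene_ids=names,
        beta=beta,
        se=se,
        log_partial_likelihood=float(logpl),
        n=int(t.size),
        n_events=int(e.sum()),
    )


def risk_score(
    model: CoxModel, expression: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Linear predictor sum_g beta_g * x_g per sample, plus high/low split.

    ``expression`` is genes x samples; every model gene must be a row.
    Groups split at the median score, ties high.
    """
    missing = [g for g in model.gene_ids if g not in expression.index]
    if missing:
        raise ValidationError(f"genes missing from expression matrix: {missing}")
    x = expression.loc[model.gene_ids]
    scores = pd.Series(model.beta @ x.to_numpy(), index=expression.columns)
    med = float(scores.median())
    groups = pd.Series(np.where(scores >= med, "high", "low"), index=scores.index)
    return scores, groups


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------


def censoring_km(time, event) -> KmCurve:
    """KM estimate of the censoring distribution (event flag flipped)."""
    t, e = _check_time_event(time, event)
    return km_estimate(t, 1 - e)


def td_roc_auc(time, event, scores, horizon_years: float) -> float | None:
    """Cumulative-case / dynamic-control AUC at the horizon, IPCW-weighted.

    Cases are samples with an observed event by the horizon; controls are
    samples still at risk past it. Case pairs are weighted by the inverse
    censoring-survival 1/G(T_i-); with no censoring this reduces to the
    plain concordance fraction over all case/control pairs. Returns None
    when there are no cases or no controls at the horizon.
    """
    t, e = _check_time_event(time, event)
    s = np.asarray(scores, dtype=float)
    if s.size != t.size:
        raise ValidationError("scores length must match records")
    cases = (t <= horizon_years) & (e == 1)
    controls = t > horizon_years
    if not cases.any() or not controls.any():
        return None
    g = censoring_km(t, e)
    eps = 1e-12
    w = np.array([1.0 / max(g.at(ti - 1e-9), eps) for ti in t[cases]])
    sc = s[cases]
    sk = s[controls]
    num = 0.0
    for wi, si in zip(w, sc):
        num += wi * ((si > sk).sum() + 0.5 * (si == sk).sum())
    den = w.sum() * sk.size
    return float(num / den)


# ---------------------------------------------------------------------------
# five-group stratification
# ---------------------------------------------------------------------------


def five_group_assign(expression: pd.DataFrame, gene_ids: list[str]) -> pd.Series:
    """Label each sample by how many signature genes sit at/above their
    cohort median expression: 4 -> Four_genes_high ... 0 -> Low_group."""
    if len(gene_ids) != 4:
        raise ValidationError("five-group stratification needs exactly four genes")
    missing = [g for g in gene_ids if g not in expression.index]
    if missing:
        raise ValidationError(f"genes missing from expression matrix: {missing}")
    x = expression.loc[gene_ids]
    high = x.ge(x.median(axis=1), axis=0)
    counts = high.sum(axis=0)
    return counts.map(FIVE_GROUP_LABELS).rename("five_group")
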