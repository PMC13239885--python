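"""Survival layer: Kaplan–Meier, log-rank, maximally selected cutpoints,
and Cox proportional-hazards regression on scaled continuous covariates.

The Cox model maximises the Efron-corrected partial likelihood by Newton
iterations (gradient sup-norm < 1e-8, 50-iteration cap) and distinguishes
plain non-convergence from monotone likelihood (perfect separation, a
diverging coefficient).  Continuous covariates are standardised to mean 0
and SD 1 by default so hazard ratios read "per 1 SD"; 0/1 covariates are
left on their natural scale so their HRs stay per-category.

The optimal cutpoint evaluates the standardized log-rank statistic at
every admissible threshold (midpoints of consecutive distinct scores
whose split leaves at least ``minprop`` of the samples on each side) and
returns the maximiser of its absolute value — the maximally selected
rank statistic used for survival dichotomisation.  The p value of the
induced split is flagged as selection-biased; a seeded permutation
correction is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import NichesigError, ValidationError
from .signatures import bh_adjust

__all__ = [
    "KMCurve", "CoxFit", "CutpointResult",
    "km_estimate", "logrank_test", "optimal_cutpoint",
    "cox_fit", "univariate_cox_screen",
    "ConvergenceError", "MonotoneLikelihoodError",
]


class ConvergenceError(NichesigError):
    """Newton iterations did not reach the gradient tolerance."""


class MonotoneLikelihoodError(NichesigError):
    """Perfect separation: the partial likelihood is monotone in a coefficient."""


def _check_surv(time, event):
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if t.size == 0:
        raise ValidationError("no observations")
    if t.size != e.size:
        raise ValidationError("time and event must be paired")
    if np.any(t <= 0):
        raise ValidationError("survival times must be positive")
    if not set(np.unique(e)) <= {0.0, 1.0}:
        raise ValidationError("event indicator must be 0/1")
    return t, e.astype(int)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate: one row per distinct observed time.

    ``survival[i]`` is S(t) just after ``times[i]``; subjects censored at
    an event time remain at risk for that time.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "survival": self.survival,
            "n_at_risk": self.n_at_risk, "n_events": self.n_events,
            "n_censored": self.n_censored,
        })


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimator."""
    t, e = _check_surv(time, event)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    utimes = np.unique(t)
    n = t.size
    surv, rows = 1.0, []
    survs, risks, deaths, cens = [], [], [], []
    for u in utimes:
        at_risk = int(np.sum(t >= u))
        d = int(np.sum((t == u) & (e == 1)))
        c = int(np.sum((t == u) & (e == 0)))
        if d > 0:
            surv *= 1.0 - d / at_risk
        survs.append(surv)
        risks.append(at_risk)
        deaths.append(d)
        cens.append(c)
    return KMCurve(times=utimes, survival=np.array(survs),
                   n_at_risk=np.array(risks), n_events=np.array(deaths),
                   n_censored=np.array(cens))


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def _logrank_oe(t: np.ndarray, e: np.ndarray, in_g1: np.ndarray) -> tuple[float, float]:
    """(O - E, hypergeometric variance) for group 1 over all event times."""
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        at_risk = t >= u
        nj = int(at_risk.sum())
        n1j = int((at_risk & in_g1).sum())
        dead = (t == u) & (e == 1)
        dj = int(dead.sum())
        d1j = int((dead & in_g1).sum())
        o_minus_e += d1j - dj * n1j / nj
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    return o_minus_e, var


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    t, e = _check_surv(time, event)
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValidationError(f"log-rank needs exactly two non-empty groups, got {labels.size}")
    in_g1 = g == labels[0]
    oe, var = _logrank_oe(t, e, in_g1)
    if var == 0:
        return 0.0, 1.0
    chi2 = oe * oe / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# maximally selected cutpoint
# ---------------------------------------------------------------------------


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float           # standardized log-rank statistic at the cutpoint
    n_low: int
    n_high: int
    p: float                   # log-rank p of the induced split
    selection_biased: bool = True
    permutation_p: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("cutpoint", "statistic", "n_low", "n_high", "p",
                 "selection_biased", "permutation_p")}


def _candidate_cutpoints(scores: np.ndarray, minprop: float) -> np.ndarray:
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValidationError("constant scores admit no cutpoint")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = scores.size
    n_low = np.array([(scores <= c).sum() for c in mids])
    ok = (n_low >= minprop * n) & ((n - n_low) >= minprop * n)
    mids = mids[ok]
    if mids.size == 0:
        raise ValidationError(f"no admissible split at minprop={minprop}")
    return mids


def optimal_cutpoint(scores, time, event, minprop: float = 0.1,
                     n_permutations: int = 0, seed: int = 0) -> CutpointResult:
    """Score threshold maximising the absolute standardized log-rank statistic.

    All midpoints between consecutive distinct score values whose induced
    low/high split keeps at least ``minprop`` of the samples in each group
    are evaluated; ties in |statistic| resolve toward the smaller
    threshold.  The reported split p value is selection-biased by
    construction; with ``n_permutations > 0`` a permutation-corrected p
    (scores permuted against the survival data, seeded) is also returned.
    """
    s = np.asarray(scores, dtype=float)
    t, e = _check_surv(time, event)
    if s.size != t.size:
        raise ValidationError("scores must be paired with time/event")
    mids = _candidate_cutpoints(s, minprop)

    def max_abs_stat(sc: np.ndarray) -> tuple[float, float]:
        best_c, best_z = None, 0.0
        for c in mids:
            high = sc > c
            oe, var = _logrank_oe(t, e, high)
            z = 0.0 if var == 0 else oe / np.sqrt(var)
            if best_c is None or abs(z) > abs(best_z):
                best_c, best_z = c, z
        return best_c, best_z

    cut, z = max_abs_stat(s)
    high = s > cut
    chi2, p = logrank_test(t, e, high.astype(int))

    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            _, zp = max_abs_stat(rng.permutation(s))
            if abs(zp) >= abs(z):
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)

    return CutpointResult(cutpoint=float(cut), statistic=float(z),
                          n_low=int((~high).sum()), n_high=int(high.sum()),
                          p=float(p), permutation_p=perm_p)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, Newton)
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Per-covariate estimates of one proportional-hazards fit."""

    names: list
    coef: np.ndarray             # log-hazard units
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    n_iter: int
    scaled: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hr": self.hr,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p,
        }, index=pd.Index(self.names, name="term"))


def _is_binary(col: np.ndarray) -> bool:
    return set(np.unique(col)) <= {0.0, 1.0}


def _efron_ll(beta, X, t, e):
    """Efron partial log-likelihood with gradient and Hessian.

    Rows must be sorted by ascending time.  O(n p^2) via suffix sums.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)
    wX = X * theta[:, None]
    # suffix (risk-set) accumulators: index i covers subjects with time >= t[i]
    s0 = np.cumsum(theta[::-1])[::-1]
    s1 = np.cumsum(wX[::-1], axis=0)[::-1]
    s2_full = np.einsum("ij,ik->ijk", X, wX)
    s2 = np.cumsum(s2_full[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    event_times = np.unique(t[e == 1])
    for u in event_times:
        start = np.searchsorted(t, u, side="left")
        dead = np.flatnonzero((t == u) & (e == 1))
        d = dead.size
        S0, S1, S2 = s0[start], s1[start], s2[start]
        S0d = theta[dead].sum()
        S1d = wX[dead].sum(axis=0)
        S2d = s2_full[dead].sum(axis=0)
        ll += eta[dead].sum()
        grad += X[dead].sum(axis=0)
        for l in range(d):
            f = l / d
            Z0 = S0 - f * S0d
            Z1 = S1 - f * S1d
            Z2 = S2 - f * S2d
            ll -= np.log(Z0)
            grad -= Z1 / Z0
            hess -= Z2 / Z0 - np.outer(Z1, Z1) / Z0 ** 2
    return ll, grad, hess


def cox_fit(covariates, time, event, scale_covariates: bool = True,
            max_iter: int = 50, tol: float = 1e-8) -> CoxFit:
    """Cox proportional-hazards fit with Efron tie correction.

    ``covariates`` is a DataFrame or 2-D array (samples x covariates).
    With ``scale_covariates`` continuous columns are standardised (0/1
    columns are left alone).  Raises :class:`MonotoneLikelihoodError` on
    perfect separation and :class:`ConvergenceError` if the gradient
    tolerance is not met within ``max_iter`` Newton steps.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] == 1 and X.size > 1 and np.asarray(time).size != 1:
            X = X.T
        names = [f"x{i}" for i in range(X.shape[1])]
    t, e = _check_surv(time, event)
    if X.shape[0] != t.size:
        raise ValidationError("covariates and survival data must be paired")
    n, p = X.shape
    n_events = int(e.sum())
    if n_events < p + 1:
        raise ValidationError(f"{n_events} events cannot support {p} covariates")
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = [names[i] for i in np.flatnonzero(sds == 0)]
        raise ValidationError(f"constant covariates: {bad}")
    if scale_covariates:
        X = X.copy()
        for j in range(p):
            if not _is_binary(X[:, j]):
                X[:, j] = (X[:, j] - X[:, j].mean()) / X[:, j].std(ddof=0)

    order = np.argsort(t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]

    beta = np.zeros(p)
    ll0, _, _ = _efron_ll(beta, Xs, ts, es)
    ll = ll0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, hess = _efron_ll(beta, Xs, ts, es)
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {n_iter}") from exc
        new_beta = beta - step
        # step-halving keeps the likelihood non-decreasing
        for _ in range(30):
            new_ll, _, _ = _efron_ll(new_beta, Xs, ts, es)
            if new_ll >= ll - 1e-12:
                break
            new_beta = (beta + new_beta) / 2.0
        beta = new_beta
        if np.max(np.abs(beta)) > 50:
            raise MonotoneLikelihoodError(
                "diverging coefficient (|beta| > 50): the partial likelihood is "
                "monotone — perfect separation of events by a covariate")
    else:
        raise ConvergenceError(
            f"gradient norm {np.max(np.abs(grad)):.3g} after {max_iter} Newton iterations")

    ll, grad, hess = _efron_ll(beta, Xs, ts, es)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    zq = stats.norm.ppf(0.975)
    zstat = beta / se
    return CoxFit(
        names=names, coef=beta, se=se, hr=np.exp(beta),
        ci_low=np.exp(beta - zq * se), ci_high=np.exp(beta + zq * se),
        p=2 * stats.norm.sf(np.abs(zstat)),
        loglik=float(ll), loglik_null=float(ll0),
        n=n, n_events=n_events, n_iter=n_iter, scaled=scale_covariates,
    )


def univariate_cox_screen(cohort, genes=None, scale_covariates: bool = True) -> pd.DataFrame:
    """One single-covariate Cox fit per gene, BH-adjusted across genes.

    ``cohort`` is a :class:`~nichesig.datasets.BulkCohort`.  Genes whose
    fit fails are reported with the failure reason, never dropped
    silently.  Each converged gene is flagged ``risk`` (HR > 1) or
    ``protective`` (HR < 1).
    """
    if genes is None:
        genes = list(cohort.expression.columns)
    t = cohort.clinical["time"].to_numpy(dtype=float)
    e = cohort.clinical["event"].to_numpy(dtype=float)
    rows = []
    for g in genes:
        x = cohort.expression[g].to_numpy(dtype=float)[:, None]
        try:
            fit = cox_fit(x, t, e, scale_covariates=scale_covariates)
            rows.append({"gene": g, "coef": fit.coef[0], "hr": fit.hr[0],
                         "ci_low": fit.ci_low[0], "ci_high": fit.ci_high[0],
                         "se": fit.se[0], "p": fit.p[0],
                         "direction": "risk" if fit.hr[0] > 1 else "protective",
                         "error": ""})
        except NichesigError as exc:
            rows.append({"gene": g, "coef": np.nan, "hr": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "se": np.nan,
                         "p": np.nan, "direction": "failed", "error": str(exc)})
    out = pd.DataFrame(rows).set_index("gene")
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
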