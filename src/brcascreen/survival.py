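"""Time-to-event layer: Kaplan-Meier, Cox proportional hazards, log-rank.

Age is the time scale (time zero at birth, censoring at current age, no left
truncation), matching "% of women with a diagnosis by age" curves. Ages
recorded in whole years produce heavy ties, so the Cox partial likelihood
uses the Efron tie correction and is maximized by damped Newton iterations.

The API follows the fitted-model convention: a model object is built from
data and ``fit()`` returns a results object carrying estimates, standard
errors and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959964  # two-sided 95% normal quantile


def _as_arrays(durations, events):
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("durations and events must be 1-D and aligned")
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t <= 0) or not np.all(np.isfinite(t)):
        raise ValueError("durations must be positive and finite")
    return t, e


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class KaplanMeier:
    """Product-limit survival model for one stratum.

    Parameters
    ----------
    durations : array-like
        Age at first breast-cancer code (events) or at censoring.
    events : array-like of bool
        True where the duration is an event.
    """

    def __init__(self, durations, events):
        self.durations, self.events = _as_arrays(durations, events)

    def fit(self) -> "KaplanMeierResults":
        t, e = self.durations, self.events
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        utimes, first, inv = np.unique(t, return_index=True, return_inverse=True)
        n = t.size
        # at-risk count just before each unique time
        at_risk = n - first
        d = np.bincount(inv, weights=e.astype(float), minlength=utimes.size)
        keep = d > 0
        if not keep.any():
            warnings.warn("no events: survival curve is identically 1", stacklevel=2)
        times = utimes[keep]
        nrisk = at_risk[keep].astype(float)
        deaths = d[keep]
        frac = 1.0 - deaths / nrisk
        surv = np.cumprod(frac)
        # Greenwood variance of log S, delta-method plain CI on S
        with np.errstate(divide="ignore", invalid="ignore"):
            gw = np.cumsum(deaths / (nrisk * (nrisk - deaths)))
        se = surv * np.sqrt(np.where(np.isfinite(gw), gw, 0.0))
        lo = np.clip(surv - Z95 * se, 0.0, 1.0)
        hi = np.clip(surv + Z95 * se, 0.0, 1.0)
        return KaplanMeierResults(
            times=times, survival=surv, at_risk=nrisk, n_events=deaths,
            ci_lower=lo, ci_upper=hi, n=n,
        )


@dataclass
class KaplanMeierResults:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int

    def survival_at(self, age) -> np.ndarray | float:
        """S(age) with the right-continuous step convention."""
        age_arr = np.atleast_1d(np.asarray(age, dtype=float))
        if np.any(age_arr < 0):
            raise ValueError("age must be non-negative")
        idx = np.searchsorted(self.times, age_arr, side="right") - 1
        out = np.where(idx >= 0, np.concatenate([[1.0], self.survival])[idx + 1], 1.0)
        return float(out[0]) if np.isscalar(age) or np.ndim(age) == 0 else out

    def cumulative_incidence_at(self, age):
        """1 - S(age): probability of a diagnosis by the given age."""
        s = self.survival_at(age)
        return 1.0 - s

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            }
        )

    def plot(self, ax=None, label=None, ci=True, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.concatenate([[0.0], self.times])
        y = 1.0 - np.concatenate([[1.0], self.survival])
        ax.step(x, 100 * y, where="post", label=label, **kwargs)
        if ci and len(self.times):
            ax.fill_between(
                x, 100 * (1 - np.concatenate([[1.0], self.ci_upper])),
                100 * (1 - np.concatenate([[1.0], self.ci_lower])),
                step="post", alpha=0.2,
            )
        ax.set_xlabel("age (years)")
        ax.set_ylabel("% with breast-cancer diagnosis")
        return ax


def km_fit(durations, events) -> KaplanMeierResults:
    """Functional wrapper around :class:`KaplanMeier`."""
    return KaplanMeier(durations, events).fit()


def km_risk_at(results: KaplanMeierResults, age) -> float:
    """Cumulative incidence read-out at a target age."""
    return float(results.cumulative_incidence_at(age))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties, damped Newton)
# ---------------------------------------------------------------------------

class ConvergenceError(RuntimeError):
    pass


class CoxPH:
    """Cox proportional-hazards model.

    Parameters
    ----------
    durations, events : array-like
        Follow-up ages and event indicators.
    covariates : DataFrame or 2-D array
        One column per covariate; constant columns are rejected.
    """

    def __init__(self, durations, events, covariates, names=None):
        self.durations, self.events = _as_arrays(durations, events)
        if isinstance(covariates, pd.DataFrame):
            names = list(covariates.columns)
            X = covariates.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(covariates, dtype=float))
            if X.shape[0] != self.durations.size:
                X = X.T
            names = names or [f"x{i}" for i in range(X.shape[1])]
        if X.shape[0] != self.durations.size:
            raise ValueError("covariates not aligned with durations")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite")
        if np.any(X.std(axis=0) == 0):
            raise ValueError("constant covariate column")
        if self.events.sum() < 2:
            raise ValueError("need at least 2 events to fit a Cox model")
        self.X = X
        self.names = names

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, duration_col: str, event_col: str,
                       covariate_cols: list[str]) -> "CoxPH":
        return cls(df[duration_col], df[event_col], df[covariate_cols])

    # Efron log partial likelihood, gradient and hessian at beta.
    # Risk-set sums come from cumulative sums over times sorted descending;
    # untied event times are handled fully vectorized (Efron == Breslow when
    # d = 1) and only tied death groups take the explicit Efron inner loop.
    def _loglik(self, beta: np.ndarray):
        if not hasattr(self, "_sorted"):
            order = np.argsort(-self.durations, kind="stable")
            t = self.durations[order]
            e = self.events[order]
            X = self.X[order]
            # last index (inclusive) of each equal-time block, per row
            n = t.size
            is_last = np.empty(n, dtype=bool)
            is_last[:-1] = t[:-1] != t[1:]
            is_last[-1] = True
            block_end = np.where(is_last, np.arange(n), n)
            last = np.minimum.accumulate(block_end[::-1])[::-1]
            self._sorted = (t, e, X, last)
        t, e, X, last = self._sorted
        n, p = X.shape
        eta = X @ beta
        eta -= eta.max()  # overflow guard; partial likelihood is invariant
        w = np.exp(eta)
        wX = X * w[:, None]
        wXX = wX[:, :, None] * X[:, None, :]
        C0 = np.cumsum(w)
        C1 = np.cumsum(wX, axis=0)
        C2 = np.cumsum(wXX, axis=0)

        ev = np.nonzero(e)[0]
        ev_last = last[ev]
        # split events into untied (single death at their time) and tied groups
        d_at = np.bincount(ev_last, minlength=n)[ev_last]
        single = d_at == 1
        ll = float(eta[ev].sum())
        grad = X[ev].sum(axis=0).astype(float)
        hess = np.zeros((p, p))

        if single.any():
            idx = ev_last[single]
            s0 = C0[idx]
            r1 = C1[idx] / s0[:, None]
            ll -= float(np.log(s0).sum())
            grad -= r1.sum(axis=0)
            hess += np.einsum("ijk,i->jk", C2[idx], 1.0 / s0)
            hess -= np.einsum("ij,ik->jk", r1, r1)

        if not single.all():
            tied_ev = ev[~single]
            for end in np.unique(ev_last[~single]):
                members = tied_ev[ev_last[~single] == end]
                d = members.size
                s0, s1, s2 = C0[end], C1[end], C2[end]
                s0d = w[members].sum()
                s1d = wX[members].sum(axis=0)
                s2d = wXX[members].sum(axis=0)
                for l in range(d):
                    f = l / d
                    phi0 = s0 - f * s0d
                    phi1 = s1 - f * s1d
                    phi2 = s2 - f * s2d
                    ll -= np.log(phi0)
                    r1 = phi1 / phi0
                    grad -= r1
                    hess += phi2 / phi0 - np.outer(r1, r1)
        return ll, grad, hess

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "CoxPHResults":
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll, grad, hess = self._loglik(beta)
        ll0 = ll
        converged = False
        for _ in range(maxiter):
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            # damped Newton: halve until the partial likelihood improves
            alpha = 1.0
            for _ in range(30):
                cand = beta + alpha * step
                ll_new, grad_new, hess_new = self._loglik(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                alpha *= 0.5
            delta = np.max(np.abs(cand - beta))
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
            if delta < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"Newton iterations did not converge (max |dbeta| = {delta:.3g})"
            )
        separation = bool(np.any(np.abs(beta) > 15))
        if separation:
            warnings.warn("very large coefficient: possible complete separation",
                          stacklevel=2)
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
        zstat = beta / se
        pvals = 2.0 * stats.norm.sf(np.abs(zstat))
        return CoxPHResults(
            names=list(self.names),
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(se, index=self.names),
            loglik=float(ll),
            loglik_null=float(ll0),
            pvalues=pd.Series(pvals, index=self.names),
            covariance=cov,
            n=self.durations.size,
            n_events=int(self.events.sum()),
            separation_flag=separation,
        )


@dataclass
class CoxPHResults:
    names: list[str]
    params: pd.Series
    bse: pd.Series
    loglik: float
    loglik_null: float
    pvalues: pd.Series
    covariance: np.ndarray
    n: int
    n_events: int
    separation_flag: bool

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2) if alpha != 0.05 else Z95
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame({"hr_lower": lo, "hr_upper": hi})

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "hr": self.hazard_ratios,
                "hr_lower": ci["hr_lower"],
                "hr_upper": ci["hr_upper"],
                "p": self.pvalues,
            }
        )


def cox_fit(df: pd.DataFrame, duration_col: str = "time", event_col: str = "event",
            covariate_cols: list[str] | None = None) -> CoxPHResults:
    """Functional wrapper: fit a Cox model on a tidy survival frame."""
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (duration_col, event_col)]
    return CoxPH.from_dataframe(df, duration_col, event_col, covariate_cols).fit()


# ---------------------------------------------------------------------------
# two-sample log-rank test
# ---------------------------------------------------------------------------

def logrank(durations_a, events_a, durations_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank chi-square (1 df) and its p-value."""
    ta, ea = _as_arrays(durations_a, events_a)
    tb, eb = _as_arrays(durations_b, events_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either arm")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, dtype=bool), np.ones(tb.size, dtype=bool)])
    utimes = np.unique(t[e])
    obs_a = exp_a = var = 0.0
    for u in utimes:
        at_risk = t >= u
        n_all = at_risk.sum()
        n_a = (at_risk & ~g).sum()
        dying = e & (t == u)
        d_all = dying.sum()
        d_a = (dying & ~g).sum()
        obs_a += d_a
        exp_a += d_all * n_a / n_all
        if n_all > 1:
            var += (
                d_all * (n_a / n_all) * (1 - n_a / n_all) * (n_all - d_all) / (n_all - 1)
            )
    if var == 0:
        return 0.0, 1.0
    chi2 = (obs_a - exp_a) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
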