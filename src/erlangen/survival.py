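"""Survival stack for progression-to-dementia analyses.

Implements, from first principles:

* Kaplan-Meier product-limit and Nelson-Aalen cumulative-hazard estimators
  with Fig.-style risk tables;
* the weighted log-rank family (log-rank, Gehan-Breslow-Wilcoxon, and the
  ordinal trend test);
* counting-process episode splitting with a Heaviside split of follow-up
  time (default 3 years), producing ``(start, stop]`` rows whose
  ``possible_early`` / ``possible_late`` covariates carry the time-varying
  effect of the "neurochemically possible AD" category;
* Cox partial-likelihood fitting on counting-process data (Newton-Raphson
  with step-halving; Breslow or Efron ties) — the proportional-hazards model
  and, through the split covariates, the Extended Cox Model;
* the Grambsch-Therneau scaled-Schoenfeld-residual test of hazard
  proportionality.

Risk-set convention: a row ``(start, stop]`` is at risk at time ``t`` iff
``start < t <= stop``.  Times are years as floating point.

The model API follows the statsmodels idiom: :class:`CoxModel` is built from
an episode table and ``fit()`` returns a :class:`CoxResults` carrying the
coefficients, their covariance, and diagnostic methods (``summary()``,
``schoenfeld_test()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "km_estimator",
    "na_estimator",
    "LogRankResult",
    "weighted_logrank",
    "episode_split",
    "CoxModel",
    "CoxResults",
    "PHTestResult",
    "ConvergenceError",
    "SingularInformationError",
    "SeparationError",
]

EPISODE_COLUMNS = ["id", "start", "stop", "event"]


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class SingularInformationError(np.linalg.LinAlgError):
    """Observed information is singular (collinear covariates)."""


class SeparationError(RuntimeError):
    """Monotone partial likelihood (complete separation on a covariate)."""


# ---------------------------------------------------------------------------
# Nonparametric estimators
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Step-function output of the Kaplan-Meier or Nelson-Aalen estimator.

    ``event_times`` holds the distinct event times in ascending order, with
    ``estimate[i]`` the value of S(t) (KM) or H(t) (NA) at and after
    ``event_times[i]``; before the first event time S = 1 and H = 0.
    """

    kind: str                      # "km" or "na"
    event_times: np.ndarray
    estimate: np.ndarray
    at_risk: np.ndarray            # n at risk just before each event time
    events: np.ndarray             # deaths at each event time
    censor_times: np.ndarray
    n_subjects: int

    def __call__(self, t):
        """Evaluate the step function at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        base = 1.0 if self.kind == "km" else 0.0
        padded = np.concatenate([[base], self.estimate])
        return padded[idx]

    def to_frame(self) -> pd.DataFrame:
        """Curve as a table: time, estimate, n_at_risk, n_events, n_censored."""
        cens = np.array(
            [((self.censor_times == t).sum()) for t in self.event_times], dtype=int
        )
        return pd.DataFrame(
            {
                "time": self.event_times,
                "estimate": self.estimate,
                "n_at_risk": self.at_risk,
                "n_events": self.events,
                "n_censored": cens,
            }
        )

    def risk_table(self, interval: float = 2.0, max_time: float | None = None) -> pd.DataFrame:
        """Numbers at risk / progressing / censored per time interval.

        Mirrors the tabulated part of a KM figure: for each interval
        ``[k*interval, (k+1)*interval)`` report the number at risk at the
        interval start and the events and censorings within the interval.
        """
        all_t = np.concatenate([self.event_times, self.censor_times])
        if max_time is None:
            max_time = float(all_t.max()) if all_t.size else 0.0
        edges = np.arange(0.0, max_time + interval, interval)
        rows = []
        for lo in edges[:-1]:
            hi = lo + interval
            ev = int(
                self.events[(self.event_times >= lo) & (self.event_times < hi)].sum()
            )
            cens = int(((self.censor_times >= lo) & (self.censor_times < hi)).sum())
            later_ev = int(self.events[self.event_times >= lo].sum())
            later_cens = int((self.censor_times >= lo).sum())
            rows.append(
                {
                    "interval_start": lo,
                    "n_at_risk": later_ev + later_cens,
                    "n_events": ev,
                    "n_censored": cens,
                }
            )
        return pd.DataFrame(rows)


def _check_surv_input(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValueError("follow-up times must be strictly positive and finite")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event flags must be 0/1")
    return time, event


def _curve_ingredients(time, event):
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    ev_times = np.unique(time[event == 1])
    n = time.size
    # at risk just before t: subjects with time >= t
    at_risk = n - np.searchsorted(time, ev_times, side="left")
    deaths = np.array([(time[event == 1] == t).sum() for t in ev_times], dtype=int)
    censor_times = time[event == 0]
    return ev_times, at_risk, deaths, censor_times, n


def km_estimator(time, event) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod (1 - d_i/n_i)."""
    time, event = _check_surv_input(time, event)
    ev_times, at_risk, deaths, cens, n = _curve_ingredients(time, event)
    est = np.cumprod(1.0 - deaths / at_risk) if ev_times.size else np.array([])
    return SurvivalCurve("km", ev_times, est, at_risk, deaths, cens, n)


def na_estimator(time, event) -> SurvivalCurve:
    """Nelson-Aalen cumulative hazard H(t) = sum d_i/n_i."""
    time, event = _check_surv_input(time, event)
    ev_times, at_risk, deaths, cens, n = _curve_ingredients(time, event)
    est = np.cumsum(deaths / at_risk) if ev_times.size else np.array([])
    return SurvivalCurve("na", ev_times, est, at_risk, deaths, cens, n)


# ---------------------------------------------------------------------------
# Weighted log-rank family
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    weight: str


def weighted_logrank(time, event, group, weight: str = "logrank",
                     scores=None) -> LogRankResult:
    """k-sample weighted log-rank test.

    Parameters
    ----------
    weight
        ``"logrank"`` (w = 1), ``"wilcoxon"`` (Gehan-Breslow, w = n at risk)
        or ``"trend"`` (df = 1 test of ordered alternatives with per-group
        ``scores``, default 0, 1, ..., k-1, applied with log-rank weights).
    """
    time, event = _check_surv_input(time, event)
    group = np.asarray(group)
    labels, gidx = np.unique(group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    for g, lab in enumerate(labels):
        if (gidx == g).sum() == 0:  # pragma: no cover - unique() precludes this
            raise ValueError(f"group {lab!r} has zero subjects")
    if weight not in ("logrank", "wilcoxon", "trend"):
        raise ValueError(f"unknown weight {weight!r}")

    ev_times = np.unique(time[event == 1])
    O_minus_E = np.zeros(k)
    V = np.zeros((k, k))
    for t in ev_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = int(((time == t) & (event == 1)).sum())
        n_gt = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_gt = np.bincount(gidx[(time == t) & (event == 1)], minlength=k).astype(float)
        w = float(n_t) if weight == "wilcoxon" else 1.0
        frac = n_gt / n_t
        O_minus_E += w * (d_gt - frac * d_t)
        if n_t > 1:
            hyper = d_t * (n_t - d_t) / (n_t - 1)
            V += w * w * hyper * (np.diag(frac) - np.outer(frac, frac))

    if weight == "trend":
        c = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
        if c.size != k:
            raise ValueError("scores must match the number of groups")
        num = float(c @ O_minus_E)
        den = float(c @ V @ c)
        chi2 = 0.0 if den == 0 else num * num / den
        df = 1
    else:
        # drop one group; V restricted to k-1 groups is invertible
        sub = slice(0, k - 1)
        z = O_minus_E[sub]
        Vs = V[sub, sub]
        try:
            chi2 = float(z @ np.linalg.solve(Vs, z)) if np.any(z) else 0.0
        except np.linalg.LinAlgError:
            chi2 = float(z @ np.linalg.pinv(Vs) @ z)
        df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LogRankResult(float(chi2), df, p, weight)


# ---------------------------------------------------------------------------
# Episode splitting (Heaviside on follow-up time)
# ---------------------------------------------------------------------------

def episode_split(records: pd.DataFrame, split_time: float = 3.0,
                  category_col: str = "es_category3",
                  extra_covariates: tuple = ("age", "female", "apoe4", "mmse"),
                  ) -> pd.DataFrame:
    """Expand subject rows into counting-process episodes.

    Every subject followed beyond ``split_time`` contributes two rows,
    ``(0, split_time]`` and ``(split_time, followup]``; the event flag sits
    on the last row.  The "possible" category indicator is split into
    ``possible_early`` (active while t <= split_time) and ``possible_late``;
    ``probable`` stays time-constant.  Total exposure and total events are
    conserved exactly.
    """
    if split_time <= 0:
        raise ValueError("split_time must be positive")
    required = {"id", "followup_years", "event", category_col}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records lack columns: {sorted(missing)}")
    rows = []
    for rec in records.itertuples(index=False):
        f = float(getattr(rec, "followup_years"))
        if not (f > 0 and np.isfinite(f)):
            raise ValueError(f"invalid follow-up time {f} for subject {rec.id}")
        ev = int(getattr(rec, "event"))
        cat = getattr(rec, category_col)
        possible = int(cat == "possible")
        probable = int(cat == "probable")
        extras = {c: getattr(rec, c) for c in extra_covariates if hasattr(rec, c)}
        if f <= split_time:
            rows.append(dict(id=rec.id, start=0.0, stop=f, event=ev,
                             possible_early=possible, possible_late=0,
                             probable=probable, **extras))
        else:
            rows.append(dict(id=rec.id, start=0.0, stop=split_time, event=0,
                             possible_early=possible, possible_late=0,
                             probable=probable, **extras))
            rows.append(dict(id=rec.id, start=split_time, stop=f, event=ev,
                             possible_early=0, possible_late=possible,
                             probable=probable, **extras))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cox model on counting-process episodes
# ---------------------------------------------------------------------------

class CoxModel:
    """Cox regression on ``(start, stop]`` episode data.

    Parameters
    ----------
    episodes
        Episode table with columns ``start``, ``stop``, ``event`` plus the
        covariates.  Single-row subjects (``start = 0``) give the ordinary
        proportional-hazards model; rows produced by :func:`episode_split`
        give the Extended Cox Model with the Heaviside-split "possible"
        effect.
    covariates
        Names of the covariate columns to include.
    ties
        ``"breslow"`` (default) or ``"efron"``.
    """

    def __init__(self, episodes: pd.DataFrame, covariates: list[str],
                 ties: str = "breslow"):
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie method {ties!r}")
        for c in ("start", "stop", "event", *covariates):
            if c not in episodes.columns:
                raise ValueError(f"episode table lacks column {c!r}")
        sub = episodes[["start", "stop", "event", *covariates]]
        if sub[covariates].isna().any().any():
            raise ValueError("missing covariate values in episode table")
        self.covariates = list(covariates)
        self.ties = ties
        self.start = sub["start"].to_numpy(dtype=float)
        self.stop = sub["stop"].to_numpy(dtype=float)
        self.event = sub["event"].to_numpy(dtype=int)
        self.X = sub[covariates].to_numpy(dtype=float)
        if np.any(self.start < 0) or np.any(self.stop <= self.start):
            raise ValueError("episodes must satisfy 0 <= start < stop")
        if self.event.sum() < 1:
            raise ValueError("need at least one event")
        self._prepare()

    @classmethod
    def from_cohort(cls, records: pd.DataFrame, covariates: list[str] | None = None,
                    split_time: float = 3.0, ties: str = "breslow") -> "CoxModel":
        """Episode-split a scored cohort and set up the Extended Cox Model."""
        episodes = episode_split(records, split_time=split_time)
        if covariates is None:
            covariates = ["possible_early", "possible_late", "probable"]
        return cls(episodes, covariates, ties=ties)

    # -- risk-set machinery: suffix sums over stop- and start-sorted rows ----
    def _prepare(self):
        m = self.stop.size
        self._m = m
        self._stop_order = np.argsort(self.stop, kind="stable")
        self._stop_sorted = self.stop[self._stop_order]
        self._start_order = np.argsort(self.start, kind="stable")
        self._start_sorted = self.start[self._start_order]
        ev_times = np.unique(self.stop[self.event == 1])
        self._ev_times = ev_times
        # death sets per distinct event time
        self._death_groups = [
            np.flatnonzero((self.stop == t) & (self.event == 1)) for t in ev_times
        ]
        self._d = np.array([g.size for g in self._death_groups], dtype=int)
        self._i_stop = np.searchsorted(self._stop_sorted, ev_times, side="left")
        self._i_start = np.searchsorted(self._start_sorted, ev_times, side="left")
        p = self.X.shape[1]
        iu, ju = np.triu_indices(p)
        self._triu = (iu, ju)
        self._XX = self.X[:, iu] * self.X[:, ju]   # packed x_i x_j products
        self._sum_x_deaths = np.array(
            [self.X[g].sum(axis=0) for g in self._death_groups]
        )

    def _risk_sums(self, w):
        """s0, s1, s2 over the risk set at each distinct event time.

        Risk set at t = {rows: start < t <= stop}; its sums equal
        (suffix sum over stop >= t) - (suffix sum over start >= t), because
        start >= t implies stop > t.
        """
        M = np.concatenate([w[:, None], w[:, None] * self.X, w[:, None] * self._XX],
                           axis=1)
        def suffix(order, idx):
            Ms = M[order]
            S = np.vstack([np.cumsum(Ms[::-1], axis=0)[::-1], np.zeros(M.shape[1])])
            return S[idx]
        R = suffix(self._stop_order, self._i_stop) - suffix(self._start_order, self._i_start)
        p = self.X.shape[1]
        s0 = R[:, 0]
        s1 = R[:, 1:1 + p]
        s2 = np.zeros((R.shape[0], p, p))
        iu, ju = self._triu
        s2[:, iu, ju] = R[:, 1 + p:]
        s2[:, ju, iu] = R[:, 1 + p:]
        return s0, s1, s2

    def _loglik_score_info(self, beta):
        eta = self.X @ beta
        eta = np.clip(eta, -200.0, 200.0)
        w = np.exp(eta)
        s0, s1, s2 = self._risk_sums(w)
        p = beta.size
        d = self._d.astype(float)
        sum_eta_d = np.array([eta[g].sum() for g in self._death_groups])

        if self.ties == "breslow" or np.all(self._d == 1):
            ll = float(np.sum(sum_eta_d - d * np.log(s0)))
            xbar = s1 / s0[:, None]
            U = (self._sum_x_deaths - d[:, None] * xbar).sum(axis=0)
            I = np.einsum("k,kij->ij", d, s2 / s0[:, None, None]) \
                - np.einsum("k,ki,kj->ij", d, xbar, xbar)
        else:
            ll, U, I = 0.0, np.zeros(p), np.zeros((p, p))
            for k, g in enumerate(self._death_groups):
                dk = g.size
                s0D = w[g].sum()
                s1D = (w[g, None] * self.X[g]).sum(axis=0)
                s2D = np.einsum("i,ij,ik->jk", w[g], self.X[g], self.X[g])
                ll += eta[g].sum()
                for j in range(dk):
                    f = j / dk
                    den = s0[k] - f * s0D
                    num = s1[k] - f * s1D
                    ll -= np.log(den)
                    U += -num / den
                    I += (s2[k] - f * s2D) / den - np.outer(num, num) / den**2
                U += self.X[g].sum(axis=0)
        return ll, U, I

    def fit(self, tol: float = 1e-9, maxiter: int = 100) -> "CoxResults":
        """Maximise the partial likelihood by Newton-Raphson with step-halving."""
        p = self.X.shape[1]
        beta = np.zeros(p)
        ll, U, I = self._loglik_score_info(beta)
        ll0 = ll
        trace = [(0, ll)]
        converged = False
        niter = 0
        for it in range(1, maxiter + 1):
            niter = it
            try:
                step = np.linalg.solve(I, U)
            except np.linalg.LinAlgError as exc:
                raise SingularInformationError(
                    f"singular information matrix (collinear covariates?): {exc}"
                ) from exc
            new_beta = beta + step
            new_ll, new_U, new_I = self._loglik_score_info(new_beta)
            halvings = 0
            while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 30:
                step *= 0.5
                halvings += 1
                new_beta = beta + step
                new_ll, new_U, new_I = self._loglik_score_info(new_beta)
            trace.append((it, new_ll))
            delta_ll = abs(new_ll - ll)
            beta, ll, U, I = new_beta, new_ll, new_U, new_I
            if np.max(np.abs(beta)) > 30:
                raise SeparationError(
                    "monotone partial likelihood: a coefficient diverged "
                    f"(max |beta| = {np.max(np.abs(beta)):.1f}); data are separated"
                )
            if delta_ll < tol or np.linalg.norm(U) < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {maxiter} iterations", trace
            )
        if np.max(np.abs(beta)) > 15:
            # the likelihood plateaued while a coefficient kept drifting:
            # an infinite maximum-likelihood estimate in disguise
            raise SeparationError(
                "monotone partial likelihood: coefficient "
                f"{self.covariates[int(np.argmax(np.abs(beta)))]!r} has no finite "
                "maximum (complete separation)"
            )
        try:
            cov = np.linalg.inv(I)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(str(exc)) from exc
        return CoxResults(self, beta, cov, float(ll), float(ll0), niter)


@dataclass
class CoxResults:
    """Fitted Cox model: coefficients, covariance and diagnostics."""

    model: CoxModel
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    llnull: float
    niter: int
    _alpha: float = field(default=0.05, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def hazard_ratios(self) -> pd.Series:
        return pd.Series(np.exp(self.params), index=self.model.covariates)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.model.covariates)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.model.covariates)

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        with np.errstate(over="ignore"):   # an unbounded CI prints as inf
            return pd.DataFrame(
                {
                    "coef": self.params,
                    "se": self.bse,
                    "hr": np.exp(self.params),
                    "hr_lower": np.exp(ci["lower"]),
                    "hr_upper": np.exp(ci["upper"]),
                    "p": self.pvalues,
                },
                index=self.model.covariates,
            )

    def summary(self) -> str:
        frame = self.to_frame()
        lines = [
            "Cox regression (counting-process episodes)",
            f"ties = {self.model.ties}, n episodes = {self.model._m}, "
            f"events = {int(self.model.event.sum())}",
            f"log-likelihood = {self.llf:.4f} (null {self.llnull:.4f}), "
            f"iterations = {self.niter}",
            "",
            frame.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    # -- proportional-hazards diagnostics -----------------------------------
    def schoenfeld_residuals(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-event Schoenfeld residuals and their event times."""
        m = self.model
        eta = np.clip(m.X @ self.params, -200, 200)
        w = np.exp(eta)
        s0, s1, _ = m._risk_sums(w)
        xbar = s1 / s0[:, None]
        times, resids = [], []
        for k, g in enumerate(m._death_groups):
            for i in g:
                times.append(m._ev_times[k])
                resids.append(m.X[i] - xbar[k])
        return np.array(times), np.array(resids)

    def schoenfeld_test(self, transform: str = "identity") -> "PHTestResult":
        """Grambsch-Therneau test that hazard ratios are time-constant.

        Correlates the scaled Schoenfeld residuals with (a transform of)
        event time; the identity transform is the default, the ``"km"``
        option uses 1 - KM(t) estimated from the episode data.
        """
        times, resid = self.schoenfeld_residuals()
        d = times.size
        if d < 3:
            raise ValueError("need at least 3 events for the proportionality test")
        if transform == "identity":
            g = times.astype(float)
        elif transform == "km":
            km = km_estimator(self.model.stop[self.model.start == 0],
                              self.model.event[self.model.start == 0]) \
                if np.any(self.model.start == 0) else None
            if km is None:
                raise ValueError("km transform requires rows starting at 0")
            g = 1.0 - km(times)
        else:
            raise ValueError(f"unknown transform {transform!r}")
        gc = g - g.mean()
        ssg = float(gc @ gc)
        if ssg == 0.0:
            raise ValueError("no variation in (transformed) event times")
        z = resid.T @ gc                       # p-vector
        _, _, I = self.model._loglik_score_info(self.params)
        try:
            Iinv = np.linalg.inv(I)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError(str(exc)) from exc
        Iz = Iinv @ z
        per_cov_chi2 = d * Iz**2 / (np.diag(Iinv) * ssg)
        global_chi2 = float(d * (z @ Iz) / ssg)
        p = len(self.params)
        return PHTestResult(
            covariates=list(self.model.covariates),
            chi2=per_cov_chi2,
            p_values=stats.chi2.sf(per_cov_chi2, 1),
            global_chi2=global_chi2,
            global_df=p,
            global_p=float(stats.chi2.sf(global_chi2, p)),
            transform=transform,
        )


@dataclass
class PHTestResult:
    """Schoenfeld proportionality test: per-covariate df=1 and global chi-square."""

    covariates: list[str]
    chi2: np.ndarray
    p_values: np.ndarray
    global_chi2: float
    global_df: int
    global_p: float
    transform: str

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"chi2": self.chi2, "df": 1, "p": self.p_values}, index=self.covariates
        )
        frame.loc["GLOBAL"] = [self.global_chi2, self.global_df, self.global_p]
        return frame
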