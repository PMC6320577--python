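"""Group-level statistics for scored cohorts.

Covers the cross-sectional and landmark parts of the analysis: ordinal
contingency tables of Erlangen Score categories by diagnostic group, the
tie-corrected Kruskal-Wallis test with Dunn-Bonferroni pairwise contrasts,
the single-operating-point diagnostic accuracy of the score, two-sample t
tests, landmark logistic regression of progression within a fixed horizon,
and covariate-adjusted fast/slow-progressor biomarker contrasts with
population-averaged (marginal) predictions.

The ordinal tests operate directly on the contingency counts via mid-ranks,
which is algebraically identical to ranking the expanded per-subject vector;
the expansion route (scipy) serves as the cross-check in the test suite.
Logistic and linear model fits delegate to statsmodels (IRLS / OLS) behind
this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survival import SeparationError

__all__ = [
    "ContingencyTable",
    "es_contingency",
    "KWResult",
    "kruskal_wallis",
    "DunnResult",
    "dunn_pairwise",
    "DiagnosticAccuracy",
    "diagnostic_accuracy",
    "two_sample_ttest",
    "LandmarkLogit",
    "LandmarkLogitResults",
    "adjusted_biomarker_contrast",
    "MarginalMeans",
]

CATEGORY3 = ["improbable", "possible", "probable"]


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """Diagnostic groups (rows) by ordinal score categories (columns)."""

    counts: pd.DataFrame   # integer counts, ordinal column order

    def __post_init__(self):
        c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("negative count")

    @classmethod
    def from_counts(cls, counts: dict[str, list[int]],
                    categories: list[str] | None = None) -> "ContingencyTable":
        frame = pd.DataFrame.from_dict(counts, orient="index")
        frame.columns = categories if categories is not None else list(frame.columns)
        return cls(frame.astype(int))

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_percentages(self, decimals: int = 1) -> pd.DataFrame:
        pct = self.counts.div(self.counts.sum(axis=1), axis=0) * 100.0
        return pct.round(decimals)

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject (ordinal value, group index) vectors; the rank oracle."""
        vals, grps = [], []
        for gi, (_, row) in enumerate(self.counts.iterrows()):
            for ci, count in enumerate(row):
                vals.extend([ci] * int(count))
                grps.extend([gi] * int(count))
        return np.array(vals), np.array(grps)

    def mid_ranks(self) -> np.ndarray:
        """Mid-rank of each ordinal category over the pooled sample."""
        col_tot = self.counts.sum(axis=0).to_numpy(dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(col_tot)])
        return cum[:-1] + (col_tot + 1.0) / 2.0


def es_contingency(records: pd.DataFrame, levels: int = 3,
                   group_col: str = "group") -> ContingencyTable:
    """Contingency table of ES categories by diagnostic group.

    ``levels=3`` uses the improbable/possible/probable categorisation,
    ``levels=5`` the raw 0-4 score.
    """
    col = {3: "es_category3", 5: "es_category5"}.get(levels)
    if col is None:
        raise ValueError("levels must be 3 or 5")
    if col not in records.columns:
        raise ValueError(f"records are not scored (missing {col!r})")
    bad = records[records[col].isna()]
    if len(bad):
        ids = bad.get("id", bad.index).tolist()
        raise ValueError(f"unscored records: {ids}")
    cats = CATEGORY3 if levels == 3 else [0, 1, 2, 3, 4]
    counts = pd.crosstab(records[group_col], records[col])
    counts = counts.reindex(columns=cats, fill_value=0)
    order = [g for g in ("Control", "MCI-Stable", "MCI-AD", "ADD")
             if g in counts.index] + [g for g in counts.index
                                      if g not in ("Control", "MCI-Stable", "MCI-AD", "ADD")]
    counts = counts.loc[order]
    counts.index.name = "group"
    counts.columns.name = "category"
    return ContingencyTable(counts.astype(int))


# ---------------------------------------------------------------------------
# Rank tests on ordinal contingency data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KWResult:
    h: float
    df: int
    p_value: float


def _kw_ingredients(table: ContingencyTable):
    C = table.counts.to_numpy(dtype=float)
    n_i = C.sum(axis=1)
    if (n_i == 0).any():
        empty = [g for g, n in zip(table.groups, n_i) if n == 0]
        raise ValueError(f"groups with zero subjects: {empty}")
    N = C.sum()
    ranks = table.mid_ranks()
    R_i = C @ ranks                      # rank sums per group
    t = C.sum(axis=0)                    # tie sizes = column totals
    tie_term = float(np.sum(t**3 - t))
    return C, n_i, N, ranks, R_i, tie_term


def kruskal_wallis(table: ContingencyTable) -> KWResult:
    """Tie-corrected Kruskal-Wallis H on an ordinal contingency table.

    H_uncorrected = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), computed on
    mid-ranks, divided by the tie correction C = 1 - sum(t^3-t)/(N^3-N).
    Identical to ranking the expanded per-subject vector.
    """
    C, n_i, N, _, R_i, tie_term = _kw_ingredients(table)
    if len(n_i) < 2:
        raise ValueError("need at least two groups")
    if C.shape[1] < 2 or (C.sum(axis=0) > 0).sum() < 2:
        return KWResult(0.0, len(n_i) - 1, 1.0)
    h_unc = 12.0 / (N * (N + 1)) * float(np.sum(R_i**2 / n_i)) - 3.0 * (N + 1)
    corr = 1.0 - tie_term / (N**3 - N)
    if corr <= 0:
        return KWResult(0.0, len(n_i) - 1, 1.0)
    h = h_unc / corr
    df = len(n_i) - 1
    return KWResult(float(h), df, float(stats.chi2.sf(h, df)))


@dataclass(frozen=True)
class DunnResult:
    pairs: pd.DataFrame   # columns: group1, group2, z, p_raw, p_adjusted


def dunn_pairwise(table: ContingencyTable) -> DunnResult:
    """Dunn's pairwise rank comparison with Bonferroni correction.

    z_ij = (mean rank_i - mean rank_j) /
           sqrt( [N(N+1)/12 - sum(t^3-t)/(12(N-1))] (1/n_i + 1/n_j) );
    two-sided normal p, Bonferroni over all k(k-1)/2 pairs.
    """
    _, n_i, N, _, R_i, tie_term = _kw_ingredients(table)
    mean_ranks = R_i / n_i
    k = len(n_i)
    m = k * (k - 1) // 2
    var_core = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_core * (1.0 / n_i[i] + 1.0 / n_i[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2 * stats.norm.sf(abs(z)))
        rows.append({
            "group1": table.groups[i], "group2": table.groups[j],
            "z": float(z), "p_raw": p_raw, "p_adjusted": min(1.0, m * p_raw),
        })
    return DunnResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Diagnostic accuracy at the published operating point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticAccuracy:
    sensitivity: float
    specificity: float
    tp: int
    disease_n: int
    tn: int
    control_n: int


def diagnostic_accuracy(table: ContingencyTable,
                        disease_groups=("MCI-AD", "ADD"),
                        control_group: str = "Control") -> DiagnosticAccuracy:
    """Sensitivity/specificity of the three-level categorisation.

    The two proportions use deliberately asymmetric thresholds, as the score
    is reported clinically: sensitivity counts diseased subjects *not*
    called improbable (score >= 2), while specificity counts controls *not*
    called probable (only score 4 misclassifies a control).
    """
    if list(table.categories) != CATEGORY3:
        raise ValueError("diagnostic accuracy requires the 3-level table")
    counts = table.counts
    present = [g for g in disease_groups if g in counts.index]
    if not present or control_group not in counts.index:
        raise ValueError("table lacks the disease pool or control group")
    pool = counts.loc[present].sum(axis=0)
    disease_n = int(pool.sum())
    tp = int(pool["possible"] + pool["probable"])
    ctrl = counts.loc[control_group]
    control_n = int(ctrl.sum())
    tn = int(ctrl["improbable"] + ctrl["possible"])
    if disease_n == 0 or control_n == 0:
        raise ValueError("empty disease pool or control group")
    return DiagnosticAccuracy(tp / disease_n, tn / control_n,
                              tp, disease_n, tn, control_n)


# ---------------------------------------------------------------------------
# t test
# ---------------------------------------------------------------------------

def two_sample_ttest(x, y, welch: bool = False) -> tuple[float, float, float]:
    """Two-tailed two-sample t test; pooled variance by default.

    Returns ``(t, df, p)``.  Two zero-variance samples with equal means give
    t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            df = x.size + y.size - 2
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------------
# Landmark logistic regression
# ---------------------------------------------------------------------------

class LandmarkLogit:
    """Logistic model of progression within a fixed horizon.

    The outcome is "event within ``horizon`` years".  Subjects censored
    before the horizon without an event carry no landmark information and
    are excluded (configurable via ``include_censored``, which would instead
    count them as non-progressors).  The three-level ES category enters as
    two indicators against the improbable reference; additional covariates
    are used as given.  Rows with missing model covariates are dropped
    listwise.
    """

    def __init__(self, records: pd.DataFrame, horizon: float,
                 covariates: tuple = ("age", "female", "mmse"),
                 category_col: str = "es_category3",
                 include_censored: bool = False):
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        df = records.copy()
        needed = ["followup_years", "event", category_col, *covariates]
        for c in needed:
            if c not in df.columns:
                raise ValueError(f"records lack column {c!r}")
        df = df.dropna(subset=["followup_years", "event"])
        case = (df["event"] == 1) & (df["followup_years"] <= horizon)
        control = df["followup_years"] > horizon
        if include_censored:
            control = control | ((df["event"] == 0) & (df["followup_years"] <= horizon))
        df = df[case | control].copy()
        df["outcome"] = case[case | control].astype(int)
        df = df.dropna(subset=list(covariates))
        self.horizon = horizon
        self.frame = df
        self.covariates = list(covariates)
        self.category_col = category_col

    def _design(self) -> tuple[pd.DataFrame, pd.Series]:
        df = self.frame
        X = pd.DataFrame(index=df.index)
        X["possible"] = (df[self.category_col] == "possible").astype(float)
        X["probable"] = (df[self.category_col] == "probable").astype(float)
        for c in self.covariates:
            X[c] = df[c].astype(float)
        # drop degenerate category indicators (absent, or the only category)
        for col in ("possible", "probable"):
            if X[col].nunique() < 2:
                X = X.drop(columns=col)
        X = sm.add_constant(X, prepend=True)
        return X, df["outcome"].astype(float)

    def fit(self, tol: float = 1e-10, maxiter: int = 50) -> "LandmarkLogitResults":
        X, y = self._design()
        if y.nunique() < 2:
            raise ValueError("one outcome class is empty at this horizon")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(tol=tol, maxiter=maxiter)
        slopes = res.params.to_numpy()[1:]
        if slopes.size and np.max(np.abs(slopes)) > 15:
            raise SeparationError(
                "separation detected in landmark logistic model "
                f"(|coef| up to {np.max(np.abs(res.params)):.1f})"
            )
        return LandmarkLogitResults(self, res)


class LandmarkLogitResults:
    """Odds ratios with Wald CIs from the landmark logistic fit."""

    def __init__(self, model: LandmarkLogit, glm_results):
        self.model = model
        self._res = glm_results
        self.params = glm_results.params
        self.bse = glm_results.bse
        self.llf = float(glm_results.llf)
        self.n_used = int(glm_results.nobs)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._res.conf_int(alpha).rename(columns={0: "lower", 1: "upper"})

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params.drop("const"))

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        frame = pd.DataFrame({
            "coef": self.params,
            "se": self.bse,
            "or": np.exp(self.params),
            "or_lower": np.exp(ci["lower"]),
            "or_upper": np.exp(ci["upper"]),
            "p": self._res.pvalues,
        })
        return frame.drop(index="const")

    def summary(self) -> str:
        return (
            f"Landmark logistic model, horizon = {self.model.horizon} years, "
            f"n = {self.n_used}, log-likelihood = {self.llf:.4f}\n\n"
            + self.to_frame().to_string(float_format=lambda v: f"{v:.4f}")
        )


# ---------------------------------------------------------------------------
# Fast/slow-progressor biomarker contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginalMeans:
    """Adjusted means per ES category x progression-speed stratum."""

    marker: str
    cells: pd.DataFrame       # category, stratum, mean, lower, upper, n
    contrasts: pd.DataFrame   # category, difference, p (fast - slow)
    n_used: int


def adjusted_biomarker_contrast(records: pd.DataFrame, marker: str,
                                covariates: tuple = ("age", "female", "mmse"),
                                split_time: float = 3.0,
                                category_col: str = "es_category3") -> MarginalMeans:
    """Fast- vs slow-progressor biomarker levels, adjusted for covariates.

    Fast progressors develop dementia within ``split_time`` years; slow
    progressors remain dementia-free beyond it; subjects censored earlier
    without an event are excluded.  Fits an OLS model of the marker on the
    category x speed interaction plus covariates and post-estimates
    population-averaged cell means with the covariates held at their sample
    means.  Categories with an empty stratum get no contrast (NaN), which is
    reported, not raised.
    """
    df = records.dropna(subset=["followup_years", "event"]).copy()
    fast = (df["event"] == 1) & (df["followup_years"] <= split_time)
    slow = df["followup_years"] > split_time
    df = df[fast | slow].copy()
    df["fast"] = fast[fast | slow].astype(float)
    df = df.dropna(subset=[marker, *covariates])
    if df.empty:
        raise ValueError("no usable subjects for the contrast")

    cats = [c for c in CATEGORY3 if (df[category_col] == c).any()]
    # cell-means coding for category x speed; covariates additive
    X = pd.DataFrame(index=df.index)
    for c in cats:
        for s, lab in ((0.0, "slow"), (1.0, "fast")):
            X[f"{c}:{lab}"] = ((df[category_col] == c) & (df["fast"] == s)).astype(float)
    for c in covariates:
        X[c] = df[c].astype(float) - df[c].astype(float).mean()  # centred
    cell_cols = [c for c in X.columns if ":" in c]
    keep = [c for c in cell_cols if X[c].sum() > 0] + list(covariates)
    X = X[keep]
    res = sm.OLS(df[marker].astype(float), X).fit()

    rows, contrasts = [], []
    for cat in cats:
        cell = {}
        for lab in ("slow", "fast"):
            name = f"{cat}:{lab}"
            n_cell = int(((df[category_col] == cat) & (df["fast"] == (lab == "fast"))).sum())
            if name in res.params.index:
                ci = res.conf_int().loc[name]
                cell[lab] = res.params[name]
                rows.append({"category": cat, "stratum": lab,
                             "mean": float(res.params[name]),
                             "lower": float(ci[0]), "upper": float(ci[1]),
                             "n": n_cell})
            else:
                rows.append({"category": cat, "stratum": lab, "mean": np.nan,
                             "lower": np.nan, "upper": np.nan, "n": n_cell})
        if "slow" in cell and "fast" in cell:
            contrast = np.zeros(len(res.params))
            contrast[list(res.params.index).index(f"{cat}:fast")] = 1.0
            contrast[list(res.params.index).index(f"{cat}:slow")] = -1.0
            diff = float(cell["fast"] - cell["slow"])
            p_val = float(res.t_test(contrast).pvalue)
            if not np.isfinite(p_val) and diff == 0.0:
                p_val = 1.0   # degenerate zero-variance case: no evidence
            contrasts.append({"category": cat, "difference": diff, "p": p_val})
        else:
            contrasts.append({"category": cat, "difference": np.nan, "p": np.nan})
    return MarginalMeans(marker=marker, cells=pd.DataFrame(rows),
                         contrasts=pd.DataFrame(contrasts), n_used=int(res.nobs))
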