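"""End-to-end cohort analysis: score, tabulate, test, model, report.

:func:`run_full_analysis` runs the complete pipeline on a cohort frame:

1. group summaries (median/IQR of biomarkers and demographics per group);
2. Erlangen Score distributions (3- and 5-level) with Kruskal-Wallis,
   Dunn-Bonferroni contrasts and diagnostic accuracy;
3. Kaplan-Meier / Nelson-Aalen curves per score category with the weighted
   log-rank family (log-rank, Wilcoxon, trend);
4. Extended Cox Models M0-M3 (score categories with the Heaviside-split
   "possible" effect; M1 adds age and gender, M2 the APOE e4 genotype, M3
   the MMSE score), a time-constant proportional-hazards comparison fit,
   and the Schoenfeld proportionality test on that comparison fit;
5. landmark logistic models of progression within 3 and 5 years;
6. covariate-adjusted fast/slow-progressor biomarker contrasts.

The analysis contains no random element: identical inputs give byte-identical
JSON output.  Any stage that cannot run on the given cohort (e.g. no MCI
follow-up data) is skipped with an explicit notice instead of crashing the
bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from . import survival as sv
from .io import SCORE_COLUMNS, score_cohort
from .scoring import ReferencePanel

__all__ = ["AnalysisBundle", "run_full_analysis"]

_ECM_MODELS = {
    "M0": [],
    "M1": ["age", "female"],
    "M2": ["age", "female", "apoe4"],
    "M3": ["age", "female", "apoe4", "mmse"],
}
_ES_TERMS = ["possible_early", "possible_late", "probable"]
_MARKERS = ["abeta42", "abeta40", "abeta42_40_ratio", "tau", "ptau181"]


@dataclass
class AnalysisBundle:
    """All pipeline outputs: statistics dict, tables, curves, report text."""

    stats: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.stats, sort_keys=True, indent=1, default=_jsonable)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "stats.json").write_text(self.to_json(), encoding="utf-8")
        for name, frame in self.tables.items():
            frame.to_csv(out / f"{name}.tsv", sep="\t", index=True)
        (out / "report.md").write_text(self.report(), encoding="utf-8")

    def report(self) -> str:
        lines = ["# Cohort analysis report", ""]
        if self.notices:
            lines += ["## Notices", ""] + [f"- {n}" for n in self.notices] + [""]
        for name, frame in self.tables.items():
            lines += [f"## {name}", "", frame.to_markdown(), ""]
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _group_summaries(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for group, g in df.groupby("group", sort=False):
        row = {"group": group, "n": len(g)}
        for col in ("age", "mmse", *_MARKERS):
            x = g[col].dropna()
            if len(x):
                row[f"{col}_median"] = float(x.median())
                row[f"{col}_q25"] = float(x.quantile(0.25))
                row[f"{col}_q75"] = float(x.quantile(0.75))
        for col in ("female", "apoe4"):
            x = g[col].dropna()
            if len(x):
                row[f"{col}_pct"] = round(100.0 * float(x.mean()), 1)
        rows.append(row)
    order = [g for g in ("Control", "MCI-Stable", "MCI-AD", "ADD")
             if g in df["group"].unique()]
    frame = pd.DataFrame(rows).set_index("group")
    return frame.reindex(order + [g for g in frame.index if g not in order])


def run_full_analysis(cohort: pd.DataFrame, refs: ReferencePanel | None = None,
                      split_time: float = 3.0, horizons: tuple = (3.0, 5.0),
                      ties: str = "breslow") -> AnalysisBundle:
    """Run every analysis stage that the cohort supports."""
    stats: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    notices: list[str] = []

    # -- scoring -------------------------------------------------------------
    if not all(c in cohort.columns for c in SCORE_COLUMNS):
        cohort, failures = score_cohort(cohort, refs)
        if failures:
            notices.append(f"{len(failures)} subjects unscoreable: "
                           + "; ".join(f"{i} ({r})" for i, r in failures[:5]))
    scored = cohort.dropna(subset=["es_score"]).copy()
    stats["n_subjects"] = int(len(cohort))
    stats["n_scored"] = int(len(scored))

    tables["group_summaries"] = _group_summaries(scored)

    # -- ordinal distribution stage ------------------------------------------
    if scored["group"].nunique() >= 2:
        table3 = cs.es_contingency(scored, levels=3)
        table5 = cs.es_contingency(scored, levels=5)
        tables["es_distribution_3cat"] = table3.counts
        tables["es_distribution_5cat"] = table5.counts
        kw = cs.kruskal_wallis(table3)
        dunn = cs.dunn_pairwise(table3)
        tables["dunn_pairwise"] = dunn.pairs.set_index(["group1", "group2"])
        stats["kruskal_wallis"] = {"h": kw.h, "df": kw.df, "p": kw.p_value}
        stats["dunn"] = {
            f"{r.group1}|{r.group2}": {"z": r.z, "p_raw": r.p_raw,
                                       "p_adjusted": r.p_adjusted}
            for r in dunn.pairs.itertuples()
        }
        try:
            acc = cs.diagnostic_accuracy(table3)
            stats["diagnostic_accuracy"] = {
                "sensitivity_pct": round(100.0 * acc.sensitivity, 1),
                "specificity_pct": round(100.0 * acc.specificity, 1),
                "sensitivity_fraction": [acc.tp, acc.disease_n],
                "specificity_fraction": [acc.tn, acc.control_n],
            }
        except ValueError as exc:
            notices.append(f"diagnostic accuracy skipped: {exc}")
    else:
        notices.append("ordinal distribution stage skipped: fewer than 2 groups")

    # -- survival stage --------------------------------------------------------
    mci = scored[scored["group"].isin(["MCI-Stable", "MCI-AD"])].dropna(
        subset=["followup_years", "event"]
    )
    if len(mci) >= 10 and mci["event"].sum() >= 3:
        time = mci["followup_years"].to_numpy(float)
        event = mci["event"].to_numpy(int)
        cat = mci["es_category3"].to_numpy()
        for c in cs.CATEGORY3:
            mask = cat == c
            if mask.sum():
                km = sv.km_estimator(time[mask], event[mask])
                na = sv.na_estimator(time[mask], event[mask])
                tables[f"km_{c}"] = km.to_frame()
                tables[f"na_{c}"] = na.to_frame()
                tables[f"risk_table_{c}"] = km.risk_table(interval=2.0)
        cat_order = {"improbable": 0, "possible": 1, "probable": 2}
        present = sorted(set(cat), key=lambda c: cat_order[c])
        if len(present) >= 2:
            ordinal = np.array([cat_order[c] for c in cat])
            lr = sv.weighted_logrank(time, event, ordinal, "logrank")
            wx = sv.weighted_logrank(time, event, ordinal, "wilcoxon")
            stats["logrank"] = {"chi2": lr.statistic, "df": lr.df, "p": lr.p_value}
            stats["wilcoxon"] = {"chi2": wx.statistic, "df": wx.df, "p": wx.p_value}
            if len(present) >= 3:
                tr = sv.weighted_logrank(time, event, ordinal, "trend")
                stats["trend"] = {"chi2": tr.statistic, "df": tr.df, "p": tr.p_value}

        episodes = sv.episode_split(mci, split_time=split_time)
        stats["ecm"] = {}
        ecm_rows = []
        for name, extra in _ECM_MODELS.items():
            cols = _ES_TERMS + extra
            sub = episodes.dropna(subset=cols)
            try:
                fit = sv.CoxModel(sub, cols, ties=ties).fit()
            except (sv.ConvergenceError, sv.SingularInformationError,
                    sv.SeparationError, ValueError) as exc:
                notices.append(f"ECM {name} skipped: {exc}")
                continue
            n_subj = sub["id"].nunique()
            stats["ecm"][name] = {
                "n": int(n_subj),
                "loglik": fit.llf,
                "coef": dict(zip(cols, fit.params)),
                "hr": dict(zip(cols, np.exp(fit.params))),
                "se": dict(zip(cols, fit.bse)),
            }
            frame = fit.to_frame()
            frame.insert(0, "model", name)
            ecm_rows.append(frame)
        if ecm_rows:
            tables["ecm_models"] = pd.concat(ecm_rows)

        # time-constant comparison fit + proportionality test
        cph_epi = mci.assign(
            start=0.0, stop=mci["followup_years"],
            possible=(mci["es_category3"] == "possible").astype(int),
            probable=(mci["es_category3"] == "probable").astype(int),
        )[["id", "start", "stop", "event", "possible", "probable"]]
        try:
            cph = sv.CoxModel(cph_epi, ["possible", "probable"], ties=ties).fit()
            ph = cph.schoenfeld_test()
            stats["cph"] = {
                "loglik": cph.llf,
                "hr": dict(zip(["possible", "probable"], np.exp(cph.params))),
            }
            stats["schoenfeld"] = {
                "per_covariate": {c: {"chi2": float(x), "p": float(p)}
                                  for c, x, p in zip(ph.covariates, ph.chi2,
                                                     ph.p_values)},
                "global_chi2": ph.global_chi2,
                "global_p": ph.global_p,
            }
            tables["schoenfeld_test"] = ph.to_frame()
        except (sv.ConvergenceError, sv.SingularInformationError,
                sv.SeparationError, ValueError) as exc:
            notices.append(f"proportional-hazards comparison skipped: {exc}")

        # landmark logistic models
        stats["landmark"] = {}
        for h in horizons:
            try:
                res = cs.LandmarkLogit(mci, horizon=h).fit()
            except (ValueError, sv.SeparationError) as exc:
                notices.append(f"landmark model at {h} years skipped: {exc}")
                continue
            stats["landmark"][f"{h:g}y"] = {
                "n": res.n_used,
                "loglik": res.llf,
                "or": res.odds_ratios.to_dict(),
            }
            tables[f"landmark_{h:g}y"] = res.to_frame()

        # fast/slow progressor contrasts
        stats["fast_slow_contrasts"] = {}
        for marker in _MARKERS:
            try:
                mm = cs.adjusted_biomarker_contrast(mci, marker,
                                                    split_time=split_time)
            except ValueError as exc:
                notices.append(f"contrast for {marker} skipped: {exc}")
                continue
            stats["fast_slow_contrasts"][marker] = {
                r.category: {"difference": r.difference, "p": r.p}
                for r in mm.contrasts.itertuples()
            }
            tables[f"contrast_{marker}"] = mm.cells.set_index(["category", "stratum"])
    else:
        notices.append("survival stage skipped: no MCI follow-up data")

    return AnalysisBundle(stats=stats, tables=tables, notices=notices)
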