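"""Seeded synthetic memory-clinic cohorts for end-to-end testing.

The study cohort behind this kind of analysis (CSF biomarkers at baseline,
follow-up of MCI subjects to dementia or censoring) is typically not
deposited, so this module generates cohorts whose *marginal* biomarker
distributions, demographics and progression hazards emulate a published
single-centre cohort of 66 neurologic controls, 74 stable MCI, 70 MCI-to-AD
progressors and 168 AD-dementia patients.

Biomarkers are drawn from log-normal marginals parameterised by the printed
(median, IQR) summaries — mu = ln(median), sigma = ln(q75/q25) / (2 * z_.75)
— joined by a Gaussian copula.  Abeta42 and Abeta40 are sampled jointly and
the Abeta42/40 ratio is their literal quotient; Abeta40 is then rescaled by a
group constant so that the *ratio's* median matches its printed value (the
printed amyloid medians are not mutually consistent, so the three quantities
cannot all be matched at once; the two score-relevant ones are).

Progression of MCI subjects follows a piecewise-exponential hazard driven by
the scored Erlangen Score category:

    lambda(t) = baseline_rate * HR(category, t)

with the "possible" category's hazard ratio switching at ``split_time``
(default 3 years) from ``hr_possible_early`` to ``hr_possible_late`` and the
"probable" ratio time-constant — i.e. exactly the hazard structure the
Extended Cox Model estimates.  Administrative censoring is uniform on a
configurable window (default 2-12 years); an event at exactly the censoring
time counts as an event.  MCI subjects are relabelled post hoc: observed
progressors become "MCI-AD", the rest "MCI-Stable".

All randomness flows through one ``numpy.random.Generator``; the same
configuration and seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .scoring import BiomarkerPanel, ReferencePanel, batch_score

__all__ = [
    "GroupProfile",
    "HazardSpec",
    "SimulationConfig",
    "DEFAULT_PROFILES",
    "DEFAULT_HAZARD",
    "default_config",
    "sample_biomarkers",
    "sample_progression_time",
    "progression_time_from_uniform",
    "progression_cdf",
    "generate_cohort",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

MARKER_ORDER = ("abeta42", "abeta40", "tau", "ptau181")


@dataclass(frozen=True)
class GroupProfile:
    """Per-group marginal summaries: (median, (q25, q75)) in native units."""

    group: str
    n: int
    abeta42: tuple[float, tuple[float, float]]
    abeta40: tuple[float, tuple[float, float]]
    abeta42_40_ratio: tuple[float, tuple[float, float]]
    tau: tuple[float, tuple[float, float]]
    ptau181: tuple[float, tuple[float, float]]
    age: tuple[float, tuple[float, float]]
    female_fraction: float
    apoe4_fraction: float | None    # None: not determined for this group
    mmse: tuple[float, tuple[float, float]] | None

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("abeta42", "abeta40", "abeta42_40_ratio", "tau", "ptau181", "age"):
            med, (q25, q75) = getattr(self, name)
            if not (q25 < q75):
                raise ValueError(f"{self.group}/{name}: invalid IQR ({q25}, {q75})")
            if not (q25 <= med <= q75):
                raise ValueError(f"{self.group}/{name}: median outside IQR")
        for frac in (self.female_fraction, self.apoe4_fraction):
            if frac is not None and not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class HazardSpec:
    """Piecewise-constant progression hazard by Erlangen Score category.

    ``baseline_rate`` (events/year) applies to the "improbable" category;
    the "possible" category multiplies it by ``hr_possible_early`` up to
    ``split_time`` years and by ``hr_possible_late`` afterwards; "probable"
    multiplies it by the time-constant ``hr_probable``.
    """

    baseline_rate: float = 0.04
    hr_possible_early: float = 7.67
    hr_possible_late: float = 1.04
    hr_probable: float = 12.0
    split_time: float = 3.0

    def __post_init__(self):
        for name in ("baseline_rate", "hr_possible_early", "hr_possible_late",
                     "hr_probable", "split_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rates(self, category3: str) -> tuple[float, float]:
        """(rate on (0, split], rate after split) for one category."""
        b = self.baseline_rate
        if category3 == "improbable":
            return b, b
        if category3 == "possible":
            return b * self.hr_possible_early, b * self.hr_possible_late
        if category3 == "probable":
            return b * self.hr_probable, b * self.hr_probable
        raise ValueError(f"unknown category {category3!r}")


# Published group summaries: median (q25-q75); concentrations pg/ml.
DEFAULT_PROFILES: tuple[GroupProfile, ...] = (
    GroupProfile(
        group="Control", n=66,
        abeta42=(852.9, (637.7, 1041.1)), abeta40=(8833.0, (6537.0, 11471.0)),
        abeta42_40_ratio=(0.100, (0.074, 0.127)), tau=(178.3, (141.7, 221.6)),
        ptau181=(29.6, (22.5, 37.0)), age=(57.5, (51.0, 68.0)),
        female_fraction=0.59, apoe4_fraction=None, mmse=None,
    ),
    GroupProfile(
        group="MCI-Stable", n=74,
        abeta42=(780.0, (572.2, 949.0)), abeta40=(10659.0, (7672.0, 13443.0)),
        abeta42_40_ratio=(0.079, (0.044, 0.108)), tau=(215.5, (139.6, 335.5)),
        ptau181=(33.9, (24.0, 46.7)), age=(65.0, (59.0, 73.0)),
        female_fraction=0.66, apoe4_fraction=0.28, mmse=(28.0, (25.0, 29.0)),
    ),
    GroupProfile(
        group="MCI-AD", n=70,
        abeta42=(459.6, (352.3, 603.8)), abeta40=(10379.0, (8088.0, 12265.0)),
        abeta42_40_ratio=(0.046, (0.035, 0.059)), tau=(448.0, (302.9, 638.8)),
        ptau181=(59.0, (38.3, 75.0)), age=(71.0, (68.0, 76.0)),
        female_fraction=0.63, apoe4_fraction=0.60, mmse=(25.0, (23.0, 28.0)),
    ),
    GroupProfile(
        group="ADD", n=168,
        abeta42=(388.6, (308.2, 532.7)), abeta40=(8410.0, (6803.0, 11489.0)),
        abeta42_40_ratio=(0.046, (0.034, 0.065)), tau=(459.7, (289.3, 702.8)),
        ptau181=(55.2, (39.1, 79.8)), age=(68.5, (62.0, 75.0)),
        female_fraction=0.67, apoe4_fraction=0.46, mmse=(18.0, (14.0, 21.0)),
    ),
)

DEFAULT_HAZARD = HazardSpec()


def _default_correlations() -> np.ndarray:
    # order: abeta42, abeta40, tau, ptau181
    R = np.eye(4)
    R[0, 1] = R[1, 0] = 0.6    # amyloid species move together
    R[2, 3] = R[3, 2] = 0.8    # total and phosphorylated tau
    return R


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort."""

    profiles: tuple[GroupProfile, ...] = DEFAULT_PROFILES
    hazard: HazardSpec = DEFAULT_HAZARD
    copula_correlations: np.ndarray = field(default_factory=_default_correlations)
    censor_window: tuple[float, float] = (2.0, 12.0)
    seed: int = 0

    def __post_init__(self):
        R = np.asarray(self.copula_correlations, dtype=float)
        if R.shape != (len(MARKER_ORDER), len(MARKER_ORDER)):
            raise ValueError("correlation matrix must be 4x4 (abeta42, abeta40, tau, ptau181)")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semidefinite")
        object.__setattr__(self, "copula_correlations", R)
        lo, hi = self.censor_window
        if not (0 < lo < hi):
            raise ValueError("censor window must satisfy 0 < min < max")

    def scaled(self, factor: float) -> "SimulationConfig":
        """Config with every group size multiplied by ``factor``."""
        profiles = tuple(replace(p, n=int(round(p.n * factor))) for p in self.profiles)
        return replace(self, profiles=profiles)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = {}
        if "profiles" in raw:
            profs = []
            for p in raw["profiles"]:
                p = dict(p)
                for name in ("abeta42", "abeta40", "abeta42_40_ratio",
                             "tau", "ptau181", "age", "mmse"):
                    if p.get(name) is not None:
                        med, lo, hi = p[name]
                        p[name] = (float(med), (float(lo), float(hi)))
                profs.append(GroupProfile(**p))
            kwargs["profiles"] = tuple(profs)
        if "hazard" in raw:
            kwargs["hazard"] = HazardSpec(**raw["hazard"])
        if "copula_correlations" in raw:
            kwargs["copula_correlations"] = np.asarray(raw["copula_correlations"], float)
        if "censor_window" in raw:
            kwargs["censor_window"] = tuple(raw["censor_window"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed)


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def _lognorm_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    q25, q75 = iqr
    if not (0 < q25 < q75):
        raise ValueError(f"invalid IQR ({q25}, {q75})")
    return np.log(median), np.log(q75 / q25) / (2.0 * _Z75)


def sample_biomarkers(profile: GroupProfile, n: int,
                      correlations: np.ndarray | None = None,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw ``n`` biomarker panels from a group profile.

    Returns a frame with columns abeta42, abeta40, abeta42_40_ratio, tau,
    ptau181.  Marginals are log-normal matched to the profile's median and
    IQR; the ratio is the literal Abeta42/Abeta40 quotient after the group
    rescaling of Abeta40 that pins the ratio's median to the profile value.
    """
    if rng is None:
        rng = np.random.default_rng()
    if correlations is None:
        correlations = _default_correlations()
    cols = {m: _lognorm_params(*getattr(profile, m)) for m in MARKER_ORDER}
    if n == 0:
        return pd.DataFrame(columns=["abeta42", "abeta40", "abeta42_40_ratio",
                                     "tau", "ptau181"], dtype=float)
    L = np.linalg.cholesky(correlations + 1e-12 * np.eye(4))
    Z = rng.standard_normal((n, 4)) @ L.T
    values = {}
    for j, m in enumerate(MARKER_ORDER):
        mu, sigma = cols[m]
        values[m] = np.exp(mu + sigma * Z[:, j])
    # pin the ratio median: median(ab42/ab40_raw) = exp(mu42 - mu40)
    mu42, mu40 = cols["abeta42"][0], cols["abeta40"][0]
    target_ratio = profile.abeta42_40_ratio[0]
    values["abeta40"] = values["abeta40"] * (np.exp(mu42 - mu40) / target_ratio)
    values["abeta42_40_ratio"] = values["abeta42"] / values["abeta40"]
    return pd.DataFrame(values)[["abeta42", "abeta40", "abeta42_40_ratio",
                                 "tau", "ptau181"]]


def progression_time_from_uniform(u, category3: str, spec: HazardSpec):
    """Deterministic inverse-CDF map from uniform draw(s) to event time(s).

    With cumulative hazard Lambda(t), T = Lambda^{-1}(-ln u).
    """
    u = np.asarray(u, dtype=float)
    r1, r2 = spec.rates(category3)
    E = -np.log(u)
    knee = r1 * spec.split_time
    T = np.where(E <= knee, E / r1, spec.split_time + (E - knee) / r2)
    return float(T) if T.ndim == 0 else T


def sample_progression_time(category3: str, spec: HazardSpec,
                            rng: np.random.Generator, size: int | None = None):
    """Sample latent progression time(s) from the piecewise-exponential hazard."""
    u = rng.uniform(size=size)
    return progression_time_from_uniform(u, category3, spec)


def progression_cdf(t, category3: str, spec: HazardSpec):
    """Closed-form P(T <= t) for the piecewise-exponential progression time."""
    t = np.asarray(t, dtype=float)
    r1, r2 = spec.rates(category3)
    cumhaz = np.where(t <= spec.split_time,
                      r1 * t,
                      r1 * spec.split_time + r2 * (t - spec.split_time))
    out = 1.0 - np.exp(-cumhaz)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig | None = None,
                    refs: ReferencePanel | None = None) -> pd.DataFrame:
    """Generate a full synthetic cohort as a cohort-schema DataFrame.

    Controls and dementia-stage subjects carry no follow-up.  MCI subjects
    (drawn from the stable and progressor profiles) are scored, given a
    latent progression time from their three-level category, censored
    administratively, and relabelled by outcome: observed progressors become
    "MCI-AD", the others "MCI-Stable".
    """
    if config is None:
        config = default_config()
    if refs is None:
        refs = ReferencePanel.default()
    rng = np.random.default_rng(config.seed)
    frames = []
    counter = 0
    for profile in config.profiles:
        n = profile.n
        panel = sample_biomarkers(profile, n, config.copula_correlations, rng)
        age = _truncnorm(rng, *_norm_params(profile.age), lo=40.0, size=n)
        female = (rng.uniform(size=n) < profile.female_fraction).astype(float)
        if profile.apoe4_fraction is None:
            apoe4 = np.full(n, np.nan)
        else:
            apoe4 = (rng.uniform(size=n) < profile.apoe4_fraction).astype(float)
        if profile.mmse is None:
            mmse = np.full(n, np.nan)
        else:
            mmse = np.round(_truncnorm(rng, *_norm_params(profile.mmse),
                                       lo=0.0, hi=30.0, size=n))
        frame = panel.copy()
        frame.insert(0, "group", profile.group)
        frame.insert(1, "age", age)
        frame.insert(2, "female", female)
        frame.insert(3, "apoe4", apoe4)
        frame.insert(4, "mmse", mmse)
        frame.index = np.arange(counter, counter + n)
        counter += n
        frames.append(frame)
    cohort = pd.concat(frames) if frames else pd.DataFrame()
    if cohort.empty:
        from .io import COHORT_COLUMNS
        return pd.DataFrame(columns=COHORT_COLUMNS)
    cohort.insert(0, "id", [f"S{i:05d}" for i in cohort.index])

    # score everyone (needed for MCI progression; kept for all groups)
    panels = [
        BiomarkerPanel(abeta42=r.abeta42, abeta40=r.abeta40,
                       abeta42_40_ratio=r.abeta42_40_ratio,
                       tau=r.tau, ptau181=r.ptau181)
        for r in cohort.itertuples(index=False)
    ]
    results, failures = batch_score(panels, refs)
    assert not failures  # simulated panels are always complete
    cat3 = np.array([r.category3 for r in results])

    followup = np.full(len(cohort), np.nan)
    event = np.full(len(cohort), np.nan)
    is_mci = cohort["group"].isin(["MCI-Stable", "MCI-AD"]).to_numpy()
    idx_mci = np.flatnonzero(is_mci)
    lo, hi = config.censor_window
    # one uniform per MCI subject for the event time, one for censoring,
    # drawn in subject order for reproducibility
    for i in idx_mci:
        T = sample_progression_time(cat3[i], config.hazard, rng)
        C = rng.uniform(lo, hi)
        if T <= C:
            followup[i] = T
            event[i] = 1.0
        else:
            followup[i] = C
            event[i] = 0.0
    group = cohort["group"].to_numpy(dtype=object)
    group[idx_mci] = np.where(event[idx_mci] == 1.0, "MCI-AD", "MCI-Stable")
    cohort["group"] = group
    cohort["followup_years"] = followup
    cohort["event"] = event
    return cohort.reset_index(drop=True)


def _norm_params(summary: tuple[float, tuple[float, float]]) -> tuple[float, float]:
    med, (q25, q75) = summary
    return med, (q75 - q25) / (2.0 * _Z75)


def _truncnorm(rng, mu, sigma, lo=-np.inf, hi=np.inf, size=None):
    """Truncated normal by inverse-CDF (deterministic in the rng stream)."""
    from scipy.stats import norm
    a = norm.cdf((lo - mu) / sigma)
    b = norm.cdf((hi - mu) / sigma)
    u = rng.uniform(a, b, size=size)
    return mu + sigma * norm.ppf(u)
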