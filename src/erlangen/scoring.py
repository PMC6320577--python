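"""Erlangen Score: ordinal interpretation of the CSF Alzheimer biomarker profile.

The score condenses four cerebrospinal-fluid biomarkers into a single ordinal
scale 0-4.  Markers are split into two pathophysiologic groups:

* amyloid group — Abeta1-42 concentration and the Abeta42/40 ratio, pathologic
  when *decreased*;
* tau (neurodegeneration) group — total Tau and pTau181, pathologic when
  *increased*.

Each marker is classified against a laboratory-specific reference value with a
relative border zone (default 10%): ``normal`` (severity 0), ``border``
(severity 1, pathologic by direction but within the band) or ``pathologic``
(severity 2, beyond the band).  A group's severity is the worst of its
available markers, and the total score is the sum of the two group severities:

====================================  =====
pattern                               score
====================================  =====
all markers normal                    0
border change in one group only       1
evident change in one group only      2
border changes in both groups         2
evident in one group, border in the   3
other
evident changes in both groups        4
====================================  =====

Scores 0-1 are reported as "neurochemically improbable AD", 2-3 as
"neurochemically possible AD" and 4 as "neurochemically probable AD".

A value exactly at the cutoff counts as normal; the border zone is strictly
beyond the cutoff up to and including the band edge (0.9x for decreasing,
1.1x for increasing markers).  Comparisons are done at full floating
precision, so the classification is invariant under a common rescaling of
value and cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "AMYLOID_MARKERS",
    "TAU_MARKERS",
    "MarkerSpec",
    "ReferencePanel",
    "BiomarkerPanel",
    "MarkerStatus",
    "ESResult",
    "ScoringError",
    "MissingGroupError",
    "classify_marker",
    "group_severity",
    "erlangen_score",
    "categorize",
    "batch_score",
]

AMYLOID_MARKERS = ("abeta42", "abeta42_40_ratio")
TAU_MARKERS = ("tau", "ptau181")

_DIRECTIONS = {
    "abeta42": "low",
    "abeta42_40_ratio": "low",
    "tau": "high",
    "ptau181": "high",
}

CATEGORY3_LABELS = ("improbable", "possible", "probable")


class ScoringError(ValueError):
    """Invalid biomarker value or reference configuration."""


class MissingGroupError(ScoringError):
    """A whole biomarker group (amyloid or tau) is unavailable."""


@dataclass(frozen=True)
class MarkerSpec:
    """Reference configuration for one marker.

    Parameters
    ----------
    name
        One of ``abeta42``, ``abeta42_40_ratio``, ``tau``, ``ptau181``.
    cutoff
        Reference value in the marker's units (pg/ml, or dimensionless for
        the ratio).
    direction
        ``"low"`` if pathology means a decrease, ``"high"`` for an increase.
    border_fraction
        Relative half-width of the border zone (default 0.10).
    """

    name: str
    cutoff: float
    direction: str
    border_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.name not in _DIRECTIONS:
            raise ScoringError(f"unknown marker name: {self.name!r}")
        if self.direction not in ("low", "high"):
            raise ScoringError(f"direction must be 'low' or 'high', got {self.direction!r}")
        if not (self.cutoff > 0 and math.isfinite(self.cutoff)):
            raise ScoringError(f"cutoff for {self.name} must be positive, got {self.cutoff}")
        if not (0.0 < self.border_fraction < 1.0):
            raise ScoringError(
                f"border_fraction for {self.name} must lie in (0, 1), got {self.border_fraction}"
            )


@dataclass(frozen=True)
class MarkerStatus:
    """Classification of one marker value: normal / border / pathologic."""

    label: str
    severity: int

    _SEVERITY = {"normal": 0, "border": 1, "pathologic": 2}

    def __post_init__(self) -> None:
        if self._SEVERITY.get(self.label) != self.severity:
            raise ScoringError(f"inconsistent status ({self.label}, {self.severity})")


NORMAL = MarkerStatus("normal", 0)
BORDER = MarkerStatus("border", 1)
PATHOLOGIC = MarkerStatus("pathologic", 2)


@dataclass(frozen=True)
class ReferencePanel:
    """Collection of :class:`MarkerSpec`, at most one per marker.

    Must contain at least one amyloid-group and one tau-group marker.
    """

    specs: tuple[MarkerSpec, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(names) != len(set(names)):
            raise ScoringError("duplicate marker spec in reference panel")
        if not any(n in AMYLOID_MARKERS for n in names):
            raise ScoringError("reference panel lacks an amyloid-group marker")
        if not any(n in TAU_MARKERS for n in names):
            raise ScoringError("reference panel lacks a tau-group marker")

    def __getitem__(self, name: str) -> MarkerSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.specs)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Mapping[str, object]]) -> "ReferencePanel":
        """Build a panel from ``{marker: {cutoff, direction, border_fraction}}``."""
        specs = []
        for name, entry in cfg.items():
            specs.append(
                MarkerSpec(
                    name=name,
                    cutoff=float(entry["cutoff"]),
                    direction=str(entry.get("direction", _DIRECTIONS.get(name, ""))),
                    border_fraction=float(entry.get("border_fraction", 0.10)),
                )
            )
        return cls(tuple(specs))

    @classmethod
    def from_yaml(cls, path) -> "ReferencePanel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ReferencePanel":
        """The packaged default reference values (Coimbra laboratory set)."""
        ref = resources.files("erlangen.data").joinpath("reference_panel.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))

    def to_dict(self) -> dict:
        return {
            s.name: {
                "cutoff": s.cutoff,
                "direction": s.direction,
                "border_fraction": s.border_fraction,
            }
            for s in self.specs
        }


@dataclass(frozen=True)
class BiomarkerPanel:
    """One subject's CSF measurements; any subset may be present (None = missing).

    If the ratio was not measured but both Abeta species were, the ratio can
    be derived as ``abeta42 / abeta40``; a measured ratio always wins over a
    derivable one.
    """

    abeta42: float | None = None
    abeta40: float | None = None
    abeta42_40_ratio: float | None = None
    tau: float | None = None
    ptau181: float | None = None

    def __post_init__(self) -> None:
        for name in ("abeta42", "abeta40", "abeta42_40_ratio", "tau", "ptau181"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ScoringError(f"non-positive concentration for {name}: {v}")

    def effective_ratio(self) -> float | None:
        if self.abeta42_40_ratio is not None:
            return self.abeta42_40_ratio
        if self.abeta42 is not None and self.abeta40 is not None:
            return self.abeta42 / self.abeta40
        return None


@dataclass(frozen=True)
class ESResult:
    """Erlangen Score output for one subject."""

    amyloid_severity: int
    tau_severity: int
    score: int
    category5: int
    category3: str
    per_marker: Mapping[str, MarkerStatus] = field(default_factory=dict)


def classify_marker(value: float, spec: MarkerSpec) -> MarkerStatus:
    """Classify a single marker value against its reference spec.

    For decreasing markers (``direction="low"``): normal at or above the
    cutoff, border in ``[(1-b)*cutoff, cutoff)``, pathologic below the band.
    For increasing markers the mirror-image rule applies, with the band
    ``(cutoff, (1+b)*cutoff]``.
    """
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ScoringError(f"non-positive value for {spec.name}: {value!r}")
    b = spec.border_fraction
    if spec.direction == "low":
        if value >= spec.cutoff:
            return NORMAL
        if value >= (1.0 - b) * spec.cutoff:
            return BORDER
        return PATHOLOGIC
    else:
        if value <= spec.cutoff:
            return NORMAL
        if value <= (1.0 + b) * spec.cutoff:
            return BORDER
        return PATHOLOGIC


def group_severity(statuses: Iterable[MarkerStatus]) -> int:
    """Severity of a biomarker group = worst severity among available markers.

    The or-logic mirrors the clinical rule: a decreased Abeta42 *or* a
    decreased ratio makes the amyloid group evident.
    """
    statuses = list(statuses)
    if not statuses:
        raise MissingGroupError("no marker available in group")
    return max(s.severity for s in statuses)


def categorize(score: int) -> tuple[int, str]:
    """Map a total score 0-4 to its five-level and three-level categories."""
    if score not in (0, 1, 2, 3, 4):
        raise ScoringError(f"score out of range: {score}")
    if score <= 1:
        return score, "improbable"
    if score <= 3:
        return score, "possible"
    return score, "probable"


def erlangen_score(panel: BiomarkerPanel, refs: ReferencePanel | None = None) -> ESResult:
    """Compute the Erlangen Score for one biomarker panel.

    Requires at least one available amyloid marker and one tau marker;
    otherwise a :class:`MissingGroupError` is raised and no score is emitted.
    """
    if refs is None:
        refs = ReferencePanel.default()

    per_marker: dict[str, MarkerStatus] = {}

    amyloid_values = {}
    if "abeta42" in refs and panel.abeta42 is not None:
        amyloid_values["abeta42"] = panel.abeta42
    ratio = panel.effective_ratio()
    if "abeta42_40_ratio" in refs and ratio is not None:
        amyloid_values["abeta42_40_ratio"] = ratio

    tau_values = {}
    if "tau" in refs and panel.tau is not None:
        tau_values["tau"] = panel.tau
    if "ptau181" in refs and panel.ptau181 is not None:
        tau_values["ptau181"] = panel.ptau181

    if not amyloid_values:
        raise MissingGroupError("amyloid group missing: no Abeta42 or Abeta42/40 value")
    if not tau_values:
        raise MissingGroupError("tau group missing: no Tau or pTau181 value")

    for name, value in {**amyloid_values, **tau_values}.items():
        per_marker[name] = classify_marker(value, refs[name])

    amy = group_severity(per_marker[n] for n in amyloid_values)
    tau = group_severity(per_marker[n] for n in tau_values)
    score = amy + tau
    cat5, cat3 = categorize(score)
    return ESResult(
        amyloid_severity=amy,
        tau_severity=tau,
        score=score,
        category5=cat5,
        category3=cat3,
        per_marker=per_marker,
    )


def batch_score(
    panels: Iterable[BiomarkerPanel], refs: ReferencePanel | None = None
) -> tuple[list[ESResult | None], list[tuple[int, str]]]:
    """Score a collection of panels, preserving input order.

    Returns ``(results, failures)`` where ``results[i]`` is the
    :class:`ESResult` for panel *i* or ``None`` if it could not be scored,
    and ``failures`` lists ``(index, reason)`` for the unscoreable panels.
    """
    if refs is None:
        refs = ReferencePanel.default()
    results: list[ESResult | None] = []
    failures: list[tuple[int, str]] = []
    for i, panel in enumerate(panels):
        try:
            results.append(erlangen_score(panel, refs))
        except ScoringError as exc:
            results.append(None)
            failures.append((i, str(exc)))
    return results, failures
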