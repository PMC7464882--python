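"""Regional nutrient diagnosis against population-level reference norms.

The regional route diagnoses a specimen against statistics of the
nutritionally balanced, high-yield ("true negative", TN) subpopulation
observed across all survey factors:

* clr means and standard deviations of the TN specimens are the
  **reference norms**;
* a specimen's **CND index** for part i is the standardized deviation
  I_i = (clr_i - clr_i*) / SD_i*, negative meaning relative shortage and
  positive relative excess;
* the squared index sum r^2 = sum(I_i^2) behaves approximately like a
  chi-square variable with D-1 degrees of freedom and gives a global
  imbalance probability (the chi-square reference is approximate, and
  reports say so);
* per-nutrient **compatibility intervals** are the TN concentration
  quartiles (Q1, Q3), classifying each nutrient Low / Normal / High with
  inclusive bounds.

The module also quantifies why univariate intervals fail jointly: the
probability of simultaneously falling inside all 11 marginal quartile
intervals collapses geometrically (~0.5^11 under independence), which is
the argument against assembling per-nutrient critical ranges into a
multivariate diagnosis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .composition import (
    FULL_PARTS,
    NUTRIENTS,
    UNITS,
    ClrVector,
    CompositionError,
    NutrientProfile,
)
from .specimen import Specimen

__all__ = [
    "ReferenceNorms",
    "CndIndexVector",
    "ImbalanceResult",
    "IntervalSet",
    "DiagnosisLabelSet",
    "compute_reference_norms",
    "cnd_indices",
    "global_imbalance",
    "rank_nutrients",
    "quartile_intervals",
    "classify_against_intervals",
    "interval_agreement",
    "joint_interval_survival",
]

_MIN_SD = 1e-6


@dataclass(frozen=True)
class ReferenceNorms:
    """Per-part clr mean and SD of the reference (TN) subpopulation."""

    means: np.ndarray
    sds: np.ndarray
    n: int
    age_window: tuple[float, float] = (0.9, 1.1)
    provenance: str = ""
    parts: tuple[str, ...] = FULL_PARTS

    def __post_init__(self) -> None:
        m = np.asarray(self.means, dtype=float)
        s = np.asarray(self.sds, dtype=float)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)
        if len(m) != len(self.parts) or len(s) != len(self.parts):
            raise ValueError("norms must cover every part")
        if np.any(s < _MIN_SD):
            raise ValueError("reference SD near zero; norms would give unbounded indices")
        # clr means of any population sum to zero; published norms carry
        # rounding, hence the loose tolerance.
        if abs(m.sum()) > 1e-3:
            raise ValueError(f"clr means sum to {m.sum()}, expected ~0")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "age_window": list(self.age_window),
            "provenance": self.provenance,
            "parts": {
                p: {"mean": float(m), "sd": float(s)}
                for p, m, s in zip(self.parts, self.means, self.sds)
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReferenceNorms":
        parts = tuple(d["parts"].keys())
        order = FULL_PARTS if set(parts) == set(FULL_PARTS) else parts
        return cls(
            means=np.array([d["parts"][p]["mean"] for p in order]),
            sds=np.array([d["parts"][p]["sd"] for p in order]),
            n=int(d.get("n", 0)),
            age_window=tuple(d.get("age_window", (0.9, 1.1))),
            provenance=str(d.get("provenance", d.get("description", ""))),
            parts=order,
        )


def compute_reference_norms(
    specimens: Sequence[Specimen],
    age_window: tuple[float, float] = (0.9, 1.1),
    min_n: int = 30,
    provenance: str = "computed TN norms",
) -> ReferenceNorms:
    """clr mean/SD over reference specimens inside the target age window.

    Specimens outside ``age_window`` (inclusive) are discarded before the
    statistics are taken; the retained count is recorded on the result.
    """
    lo, hi = age_window
    retained = [s for s in specimens if lo <= s.age_yr <= hi]
    if len(retained) < min_n:
        raise ValueError(
            f"too few reference specimens: {len(retained)} retained, need >= {min_n}"
        )
    clr = np.array([s.clr.values for s in retained])
    sds = clr.std(axis=0, ddof=1)
    if np.any(sds < _MIN_SD):
        raise ValueError("degenerate reference sample: a clr SD is (near) zero")
    return ReferenceNorms(
        means=clr.mean(axis=0),
        sds=sds,
        n=len(retained),
        age_window=age_window,
        provenance=provenance,
    )


@dataclass(frozen=True)
class CndIndexVector:
    """Standardized clr deviations from the reference norms, one per part."""

    values: np.ndarray
    norms: ReferenceNorms
    parts: tuple[str, ...] = FULL_PARTS

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.parts.index(part)])

    def as_dict(self) -> dict[str, float]:
        return {p: float(v) for p, v in zip(self.parts, self.values)}


def cnd_indices(v: ClrVector | Specimen, norms: ReferenceNorms) -> CndIndexVector:
    """I_i = (clr_i - clr_i*) / SD_i* for every part, Fv included."""
    clr = v.clr if isinstance(v, Specimen) else v
    if clr.parts != norms.parts:
        raise CompositionError("part mismatch between clr vector and norms")
    return CndIndexVector((clr.values - norms.means) / norms.sds, norms=norms, parts=clr.parts)


@dataclass(frozen=True)
class ImbalanceResult:
    """Global nutrient-imbalance summary: r^2 = sum(I_i^2) with an
    approximate upper-tail chi-square probability at D-1 df."""

    r2: float
    df: int
    p_value: float
    note: str = (
        "chi-square reference is approximate; clr indices are correlated "
        "through the zero-sum constraint"
    )


def global_imbalance(idx: CndIndexVector) -> ImbalanceResult:
    r2 = float(np.sum(idx.values**2))
    df = len(idx.parts) - 1
    return ImbalanceResult(r2=r2, df=df, p_value=float(stats.chi2.sf(r2, df)))


def rank_nutrients(
    scores: CndIndexVector | Mapping[str, float],
    exclude_fv: bool = True,
) -> list[str]:
    """Part names ordered from most negative (strongest relative shortage)
    to most positive (strongest relative excess).

    Ties keep the canonical part order.  The filling value is excluded by
    default: it closes the composition but is not a nutrient one would
    correct.
    """
    d = scores.as_dict() if isinstance(scores, CndIndexVector) else dict(scores)
    parts = [p for p in (FULL_PARTS if not exclude_fv else NUTRIENTS) if p in d]
    for p in parts:
        if not np.isfinite(d[p]):
            raise ValueError(f"non-finite score for {p}")
    return sorted(parts, key=lambda p: (d[p], FULL_PARTS.index(p)))


@dataclass(frozen=True)
class IntervalSet:
    """Per-nutrient (lower, upper) compatibility bounds in native units."""

    lower: np.ndarray
    upper: np.ndarray
    provenance: str = ""
    estimator: str = ""
    parts: tuple[str, ...] = NUTRIENTS
    units: Mapping[str, str] = field(default_factory=lambda: dict(UNITS))

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if len(lo) != len(self.parts) or len(hi) != len(self.parts):
            raise ValueError("interval set must cover every nutrient")
        if "Fv" in self.parts:
            raise ValueError("interval sets cover nutrients only, not Fv")
        if np.any(hi <= lo):
            bad = [p for p, l, u in zip(self.parts, lo, hi) if u <= l]
            raise ValueError(f"zero-width interval: {bad}")

    def bounds(self, part: str) -> tuple[float, float]:
        i = self.parts.index(part)
        return float(self.lower[i]), float(self.upper[i])

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "estimator": self.estimator,
            "bounds": {
                p: {"lower": float(l), "upper": float(u), "unit": self.units[p]}
                for p, l, u in zip(self.parts, self.lower, self.upper)
            },
        }

    @classmethod
    def from_bounds(
        cls, bounds: Mapping[str, Sequence[float]], provenance: str = "", estimator: str = ""
    ) -> "IntervalSet":
        return cls(
            lower=np.array([bounds[p][0] for p in NUTRIENTS]),
            upper=np.array([bounds[p][1] for p in NUTRIENTS]),
            provenance=provenance,
            estimator=estimator,
        )


def quartile_intervals(
    specimens: Sequence[Specimen] | Sequence[NutrientProfile],
    provenance: str = "TN quartiles",
) -> IntervalSet:
    """(Q1, Q3) of each nutrient concentration, in native units.

    Quartiles use the linear-interpolation quantile estimator; the
    estimator name is recorded on the result since published interval
    tables rarely state it.
    """
    if len(specimens) < 4:
        raise ValueError(f"too few specimens for quartiles: {len(specimens)}")
    profiles = [s.profile if isinstance(s, Specimen) else s for s in specimens]
    mat = np.array(
        [[p.concentration(part) for part in NUTRIENTS] for p in profiles], dtype=float
    )
    q1 = np.quantile(mat, 0.25, axis=0, method="linear")
    q3 = np.quantile(mat, 0.75, axis=0, method="linear")
    return IntervalSet(lower=q1, upper=q3, provenance=provenance, estimator="linear")


@dataclass(frozen=True)
class DiagnosisLabelSet:
    """Low / Normal / High per nutrient, relative to one interval set."""

    labels: Mapping[str, str]
    provenance: str = ""

    def __getitem__(self, part: str) -> str:
        return self.labels[part]

    def as_dict(self) -> dict[str, str]:
        return dict(self.labels)


def classify_against_intervals(
    profile: NutrientProfile, intervals: IntervalSet
) -> DiagnosisLabelSet:
    """Label each nutrient Low (< lower), Normal (inside, bounds inclusive)
    or High (> upper) against its native-unit compatibility interval."""
    labels: dict[str, str] = {}
    for part in intervals.parts:
        x = profile.concentration(part)
        if x is None:
            raise CompositionError(f"missing part: {part}")
        lo, hi = intervals.bounds(part)
        labels[part] = "Low" if x < lo else ("High" if x > hi else "Normal")
    return DiagnosisLabelSet(labels=labels, provenance=intervals.provenance)


def interval_agreement(
    a: Sequence[DiagnosisLabelSet], b: Sequence[DiagnosisLabelSet]
) -> dict:
    """Count label-identical specimen x nutrient cells between two
    diagnosis routes (e.g. state standards vs TN quartiles)."""
    if len(a) != len(b):
        raise ValueError("misaligned label sets: different specimen counts")
    agreements = attempts = 0
    for la, lb in zip(a, b):
        if set(la.labels) != set(lb.labels):
            raise ValueError("misaligned label sets: different nutrients")
        for part in la.labels:
            attempts += 1
            agreements += la[part] == lb[part]
    return {
        "agreements": agreements,
        "attempts": attempts,
        "fraction": agreements / attempts if attempts else float("nan"),
    }


def joint_interval_survival(
    specimens: Sequence[Specimen] | Sequence[NutrientProfile],
    intervals: IntervalSet,
) -> dict:
    """How many specimens are simultaneously Normal for *all* nutrients.

    Under independence each marginal quartile interval retains ~50%, so
    the joint survival is ~0.5^11 ≈ 5e-4: marginal compatibility
    intervals collapse as a joint diagnostic.
    """
    profiles = [s.profile if isinstance(s, Specimen) else s for s in specimens]
    if not profiles:
        raise ValueError("no specimens")
    survivors = 0
    for p in profiles:
        labels = classify_against_intervals(p, intervals)
        survivors += all(v == "Normal" for v in labels.labels.values())
    return {
        "survivors": survivors,
        "n": len(profiles),
        "fraction": survivors / len(profiles),
    }
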