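"""Compositional machinery for foliar nutrient data.

A leaf-tissue analysis reports 11 nutrient concentrations on a dry-matter
basis (N, P, K, Mg, Ca, S in g kg^-1; B, Cu, Zn, Mn, Fe in mg kg^-1).
Because the measurement scale is bounded (everything is a fraction of the
same kilogram of dry matter), the data are compositional: only ratios
between parts carry information.  This module closes a profile to a
12-part composition by adding a filling value (Fv, the unquantified
remainder of the dry matter), and provides the Aitchison-geometry
transforms used throughout the package:

* clr — centered log ratio, ln(x_i / g(x)) with g the geometric mean over
  all 12 parts; zero-sum coordinates, one per part.
* ilr — isometric log ratios (orthonormal balances) defined by a
  sequential binary partition; 11 coordinates, isometric to clr.
* pwlr — the 66 redundant pairwise log ratios ln(x_i / x_j), i < j.
* Aitchison distance — the Euclidean distance between clr (equivalently
  ilr) images of two compositions.

The fixed part order (N, P, K, Mg, Ca, S, B, Cu, Zn, Mn, Fe, Fv) is used
everywhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "NUTRIENTS",
    "MACRONUTRIENTS",
    "MICRONUTRIENTS",
    "FULL_PARTS",
    "UNITS",
    "NutrientProfile",
    "Composition",
    "ClrVector",
    "SbpMatrix",
    "IlrVector",
    "replace_below_detection",
    "close_composition",
    "clr_transform",
    "clr_inverse",
    "build_default_sbp",
    "build_pivot_sbp",
    "ilr_transform",
    "pwlr_features",
    "pwlr_names",
    "aitchison_distance",
]

#: Macronutrients, reported in g kg^-1 dry matter.
MACRONUTRIENTS: tuple[str, ...] = ("N", "P", "K", "Mg", "Ca", "S")
#: Micronutrients, reported in mg kg^-1 dry matter.
MICRONUTRIENTS: tuple[str, ...] = ("B", "Cu", "Zn", "Mn", "Fe")
#: The 11 measured nutrients, in canonical order.
NUTRIENTS: tuple[str, ...] = MACRONUTRIENTS + MICRONUTRIENTS
#: The 12 composition parts: nutrients plus the filling value.
FULL_PARTS: tuple[str, ...] = NUTRIENTS + ("Fv",)
#: Native reporting unit per nutrient.
UNITS: dict[str, str] = {p: ("g/kg" if p in MACRONUTRIENTS else "mg/kg") for p in NUTRIENTS}

_MG_TO_G = 1e-3


class CompositionError(ValueError):
    """Raised on invalid compositional input (zeros, wrong parts, bad closure)."""


@dataclass(frozen=True)
class NutrientProfile:
    """The 11 measured foliar concentrations in their native units.

    Parameters
    ----------
    values
        Mapping of nutrient name to concentration (g/kg for macronutrients,
        mg/kg for micronutrients).  Zero or ``None`` marks a value below the
        detection limit; it must then have an entry in ``detection_limits``
        before closure.
    detection_limits
        Optional per-nutrient detection limit in the nutrient's native unit.
    """

    values: Mapping[str, float | None]
    detection_limits: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.values) - set(NUTRIENTS)
        if extra:
            raise CompositionError(f"unknown parts: {sorted(extra)}")
        for part, v in self.values.items():
            if v is not None and v < 0:
                raise CompositionError(f"negative concentration for {part}: {v}")

    def concentration(self, part: str) -> float | None:
        """Native-unit concentration of ``part`` (``None`` if missing)."""
        return self.values.get(part)

    def is_complete(self) -> bool:
        """True when every nutrient has a strictly positive value."""
        return all((self.values.get(p) or 0) > 0 for p in NUTRIENTS)

    def as_g_kg(self) -> np.ndarray:
        """The 11 concentrations converted to g kg^-1, in canonical order."""
        out = np.empty(len(NUTRIENTS))
        for i, part in enumerate(NUTRIENTS):
            v = self.values.get(part)
            if v is None or v <= 0:
                raise CompositionError(
                    f"missing part: {part} has no positive value; "
                    "apply replace_below_detection first"
                )
            out[i] = v * _MG_TO_G if part in MICRONUTRIENTS else v
        return out


def replace_below_detection(
    profile: NutrientProfile, multiplier: float = 0.65
) -> NutrientProfile:
    """Replace zero/missing nutrients by ``multiplier`` x detection limit.

    The geometric mean underlying the clr does not accept zeros, so
    censored values are imputed as a fixed fraction of the reporting
    limit before closure.  Raises :class:`CompositionError` when a
    zero has no detection limit to fall back on.
    """
    if not 0 < multiplier < 1:
        raise ValueError(f"multiplier must be in (0, 1), got {multiplier}")
    new_values: dict[str, float] = {}
    changed = False
    for part in NUTRIENTS:
        v = profile.values.get(part)
        if v is None or v == 0:
            dl = profile.detection_limits.get(part)
            if dl is None or dl <= 0:
                raise CompositionError(f"zero without detection limit: {part}")
            new_values[part] = multiplier * dl
            changed = True
        else:
            new_values[part] = v
    if not changed:
        return profile
    return NutrientProfile(new_values, dict(profile.detection_limits))


@dataclass(frozen=True)
class Composition:
    """A closed 12-part composition (11 nutrients + Fv) in g kg^-1.

    Values are strictly positive and sum to the closure constant ``kappa``
    (1000 g kg^-1 dry matter by default).
    """

    values: np.ndarray
    kappa: float = 1000.0
    parts: tuple[str, ...] = FULL_PARTS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(self.parts) != len(v):
            raise CompositionError("part/value length mismatch")
        if len(self.parts) != len(FULL_PARTS):
            raise CompositionError(f"expected {len(FULL_PARTS)} parts, got {len(self.parts)}")
        if np.any(v <= 0):
            bad = [p for p, x in zip(self.parts, v) if x <= 0]
            raise CompositionError(f"non-positive part: {bad}")
        if abs(v.sum() - self.kappa) > 1e-9 * self.kappa:
            raise CompositionError(
                f"values sum to {v.sum()!r}, expected closure to {self.kappa}"
            )

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.parts.index(part)])


def close_composition(profile: NutrientProfile, kappa: float = 1000.0) -> Composition:
    """Close a profile to ``kappa`` g kg^-1 by appending the filling value.

    Micronutrients are converted from mg kg^-1 to g kg^-1; the filling
    value Fv = kappa - sum(nutrients) absorbs the unquantified dry-matter
    remainder (structural carbon, O, H, ...).
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    nutrients = profile.as_g_kg()
    fv = kappa - nutrients.sum()
    if fv <= 1e-9 * kappa:  # tolerance absorbs float round-off at the boundary
        raise CompositionError(
            f"non-positive filling value: nutrient sum {nutrients.sum()} >= kappa {kappa}"
        )
    return Composition(np.append(nutrients, fv), kappa=kappa)


@dataclass(frozen=True)
class ClrVector:
    """Centered log-ratio coordinates, one per part, summing to zero."""

    values: np.ndarray
    parts: tuple[str, ...] = FULL_PARTS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != len(self.parts):
            raise CompositionError("part/value length mismatch")
        if not np.all(np.isfinite(v)):
            raise CompositionError("non-finite clr coordinate")

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.parts.index(part)])

    def as_dict(self) -> dict[str, float]:
        return {p: float(v) for p, v in zip(self.parts, self.values)}


def clr_transform(c: Composition) -> ClrVector:
    """clr_i = ln(x_i / g(x)), geometric mean over all 12 parts."""
    logs = np.log(c.values)
    return ClrVector(logs - logs.mean(), parts=c.parts)


def clr_inverse(v: ClrVector | np.ndarray, kappa: float = 1000.0) -> Composition:
    """Map zero-sum clr coordinates back to a ``kappa``-closed composition.

    The inverse is the softmax of the coordinates rescaled to ``kappa``.
    Coordinates must sum to (numerically) zero: the clr image of any
    composition lies on that hyperplane, and a vector off it does not
    correspond to a unique composition.
    """
    vals = v.values if isinstance(v, ClrVector) else np.asarray(v, dtype=float)
    if abs(vals.sum()) > 1e-6:
        raise CompositionError(f"unnormalized clr: coordinates sum to {vals.sum()}")
    x = np.exp(vals - vals.max())  # guard overflow; closure removes the shift
    x *= kappa / x.sum()
    return Composition(x, kappa=kappa)


@dataclass(frozen=True)
class SbpMatrix:
    """A sequential binary partition of the 12 parts into 11 balances.

    Each contrast i opposes a numerator part set (size r) to a denominator
    part set (size s); the balance coordinate is
    sqrt(rs/(r+s)) * ln(g(numerator)/g(denominator)).  Contrast rows, as
    vectors acting on clr coordinates, are orthonormal.
    """

    contrasts: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    parts: tuple[str, ...] = FULL_PARTS

    def __post_init__(self) -> None:
        d = len(self.parts)
        if len(self.contrasts) != d - 1:
            raise CompositionError(
                f"need {d - 1} contrasts for {d} parts, got {len(self.contrasts)}"
            )
        for num, den in self.contrasts:
            if set(num) & set(den):
                raise CompositionError(f"overlapping contrast: {num} vs {den}")
            if not num or not den:
                raise CompositionError("empty contrast side")
            unknown = (set(num) | set(den)) - set(self.parts)
            if unknown:
                raise CompositionError(f"unknown parts in contrast: {sorted(unknown)}")
        m = self.matrix()
        gram = m @ m.T
        if not np.allclose(gram, np.eye(d - 1), atol=1e-12):
            raise CompositionError("contrast rows are not orthonormal")

    def matrix(self) -> np.ndarray:
        """The (D-1, D) orthonormal contrast matrix Psi with ilr = Psi @ clr."""
        d = len(self.parts)
        idx = {p: i for i, p in enumerate(self.parts)}
        m = np.zeros((len(self.contrasts), d))
        for row, (num, den) in enumerate(self.contrasts):
            r, s = len(num), len(den)
            a = math.sqrt(s / (r * (r + s)))
            b = math.sqrt(r / (s * (r + s)))
            for p in num:
                m[row, idx[p]] = a
            for p in den:
                m[row, idx[p]] = -b
        return m

    def coefficient(self, i: int) -> float:
        """sqrt(rs/(r+s)) for contrast ``i``."""
        num, den = self.contrasts[i]
        r, s = len(num), len(den)
        return math.sqrt(r * s / (r + s))


def build_default_sbp() -> SbpMatrix:
    """The package's canonical sequential binary partition.

    Interpretable cascade: nutrients vs filling value, macronutrients vs
    micronutrients, then bisections within each branch down to single
    parts.  Any valid partition gives the same distances (orthonormality);
    this one groups the contrasts agronomists read most often.
    """
    return SbpMatrix(
        (
            (NUTRIENTS, ("Fv",)),
            (MACRONUTRIENTS, MICRONUTRIENTS),
            (("N", "P", "K"), ("Mg", "Ca", "S")),
            (("N", "P"), ("K",)),
            (("N",), ("P",)),
            (("Mg", "Ca"), ("S",)),
            (("Mg",), ("Ca",)),
            (("B", "Cu"), ("Zn", "Mn", "Fe")),
            (("B",), ("Cu",)),
            (("Zn", "Mn"), ("Fe",)),
            (("Zn",), ("Mn",)),
        )
    )


def build_pivot_sbp() -> SbpMatrix:
    """Pivot-style partition: part i vs all later parts.  Used to check
    that distances do not depend on the choice of partition."""
    contrasts = tuple(
        ((FULL_PARTS[i],), tuple(FULL_PARTS[i + 1 :])) for i in range(len(FULL_PARTS) - 1)
    )
    return SbpMatrix(contrasts)


@dataclass(frozen=True)
class IlrVector:
    """Orthonormal balance coordinates produced by an :class:`SbpMatrix`."""

    values: np.ndarray
    sbp: SbpMatrix

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != len(self.sbp.contrasts):
            raise CompositionError("ilr length does not match SBP")


def ilr_transform(c: Composition, sbp: SbpMatrix | None = None) -> IlrVector:
    """Balance coordinates ilr_i = sqrt(rs/(r+s)) ln(g_N/g_D)."""
    if sbp is None:
        sbp = build_default_sbp()
    if sbp.parts != c.parts:
        raise CompositionError("part mismatch between composition and SBP")
    clr = clr_transform(c)
    return IlrVector(sbp.matrix() @ clr.values, sbp=sbp)


def pwlr_names(parts: Sequence[str] = FULL_PARTS) -> list[str]:
    """Feature names ``pwlr_<i>_<j>`` for i < j in canonical order."""
    return [
        f"pwlr_{parts[i]}_{parts[j]}"
        for i in range(len(parts))
        for j in range(i + 1, len(parts))
    ]


def pwlr_features(c: Composition) -> np.ndarray:
    """All D(D-1)/2 = 66 pairwise log ratios ln(x_i/x_j), i < j.

    Redundant but model-friendly features; reflectivity
    ln(x_i/x_j) = -ln(x_j/x_i) holds by construction since only the
    i < j half is emitted.
    """
    logs = np.log(c.values)
    d = len(logs)
    return np.array([logs[i] - logs[j] for i in range(d) for j in range(i + 1, d)])


def aitchison_distance(a: Composition | ClrVector, b: Composition | ClrVector) -> float:
    """Euclidean distance between clr images (equals the ilr distance)."""
    va = clr_transform(a).values if isinstance(a, Composition) else a.values
    vb = clr_transform(b).values if isinstance(b, Composition) else b.values
    pa = a.parts
    pb = b.parts
    if pa != pb:
        raise CompositionError("part mismatch")
    return float(np.linalg.norm(va - vb))


def profile_from_row(row: Mapping[str, float]) -> NutrientProfile:
    """Build a profile from canonical CSV columns (``n_g_kg`` ... ``fe_mg_kg``)."""
    values = {}
    for part in NUTRIENTS:
        unit = "g_kg" if part in MACRONUTRIENTS else "mg_kg"
        values[part] = float(row[f"{part.lower()}_{unit}"])
    return NutrientProfile(values)
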