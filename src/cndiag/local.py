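"""Local, factor-specific nutrient diagnosis by analogy to successful neighbors.

Instead of standardizing a specimen against region-wide norms, the local
route compares a defective specimen with *successful* reference trees —
balanced high-yield (TN) specimens above a DBH floor — that share its
growth factors (clone, age window, optionally soil type and location).
Closeness between tissue compositions is the Aitchison distance
epsilon = ||clr(query) - clr(neighbor)||; the per-part clr differences
d_i = clr_i(query) - clr_i(neighbor) rank nutrients from relative
shortage (most negative) to relative excess (most positive), and the
selected neighbor's DBH is the attainable yield under the shared factor
combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .composition import FULL_PARTS, ClrVector, CompositionError
from .regional import CndIndexVector, ReferenceNorms, cnd_indices, rank_nutrients
from .specimen import FactorSpec, Specimen

__all__ = [
    "NeighborEntry",
    "NeighborReport",
    "filter_successful",
    "match_factors",
    "match_with_broadening",
    "nearest_neighbors",
    "local_clr_differences",
    "select_reference_neighbor",
    "local_diagnosis_report",
]

logger = logging.getLogger(__name__)

#: clr differences smaller than this are treated as "no shortage".
SHORTAGE_TOL = 1e-6


def filter_successful(
    specimens: Sequence[Specimen],
    dbh_floor: float = 5.0,
    quadrants: Mapping[str, str] | None = None,
    quadrant: str = "TN",
) -> list[Specimen]:
    """Retain the successful reference pool: DBH strictly above the floor,
    and (when quadrant labels are supplied) in the requested confusion
    quadrant, TN by default."""
    kept = [
        s
        for s in specimens
        if s.dbh_cm > dbh_floor and (quadrants is None or quadrants.get(s.id) == quadrant)
    ]
    if not kept:
        raise ValueError(
            f"empty successful set: no specimens with DBH > {dbh_floor}"
            + (f" in quadrant {quadrant}" if quadrants is not None else "")
        )
    return kept


def match_factors(
    query: Specimen, candidates: Sequence[Specimen], spec: FactorSpec
) -> list[Specimen]:
    """Candidates passing every exact categorical match and numeric window,
    in input order (deterministic)."""
    matched = [c for c in candidates if spec.matches(query, c)]
    if not matched:
        raise ValueError(
            "no factor-matched candidates for query "
            f"{query.id!r} under {spec}; consider broadening the factor spec "
            "(drop location, then soil type, relax the age window, drop clone)"
        )
    return matched


def match_with_broadening(
    query: Specimen, candidates: Sequence[Specimen], spec: FactorSpec
) -> tuple[list[Specimen], FactorSpec]:
    """Match factors, progressively broadening the spec when nothing matches.

    Broadening order: drop ``location`` → drop ``soil_type`` → double each
    numeric window → drop ``clone`` → unrestricted.  Each step is logged;
    the spec that finally matched is returned alongside the candidates.
    """
    attempts: list[FactorSpec] = [spec]
    s = spec
    for dropped in ("location", "soil_type"):
        if dropped in s.exact:
            s = replace(s, exact=tuple(f for f in s.exact if f != dropped))
            attempts.append(s)
    if s.windows:
        s = replace(s, windows={k: 2 * v for k, v in s.windows.items()})
        attempts.append(s)
    if "clone" in s.exact:
        s = replace(s, exact=tuple(f for f in s.exact if f != "clone"))
        attempts.append(s)
    attempts.append(FactorSpec(exact=(), windows={}))  # unrestricted last resort
    for i, attempt in enumerate(attempts):
        try:
            matched = match_factors(query, candidates, attempt)
        except ValueError:
            continue
        if i > 0:
            logger.warning(
                "factor spec broadened for query %s: %s -> %s", query.id, spec, attempt
            )
        return matched, attempt
    raise ValueError(f"no factor-matched candidates for query {query.id!r} even after broadening")


@dataclass(frozen=True)
class NeighborEntry:
    id: str
    epsilon: float
    dbh_cm: float
    clr_differences: dict[str, float]


@dataclass(frozen=True)
class NeighborReport:
    """k nearest successful neighbors of a query, by Aitchison distance."""

    query_id: str
    neighbors: tuple[NeighborEntry, ...]
    k_requested: int
    selected: NeighborEntry | None = None
    objective: str = ""

    def __post_init__(self) -> None:
        eps = [n.epsilon for n in self.neighbors]
        if any(e < 0 for e in eps) or any(a > b for a, b in zip(eps, eps[1:])):
            raise ValueError("neighbor distances must be non-negative and non-decreasing")


def local_clr_differences(
    query: ClrVector, reference: ClrVector
) -> tuple[dict[str, float], float]:
    """Per-part d_i = clr_i(query) - clr_i(reference) and their norm epsilon."""
    if query.parts != reference.parts:
        raise CompositionError("part mismatch")
    d = query.values - reference.values
    return {p: float(x) for p, x in zip(query.parts, d)}, float(np.linalg.norm(d))


def nearest_neighbors(
    query: Specimen, matched: Sequence[Specimen], k: int = 10
) -> NeighborReport:
    """Top-k factor-matched specimens by ascending Aitchison distance;
    ties broken by specimen id."""
    if not matched:
        raise ValueError("empty candidate set")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(matched):
        logger.warning(
            "k=%d exceeds the matched pool (%d); returning the whole pool", k, len(matched)
        )
    entries = []
    for cand in matched:
        diffs, eps = local_clr_differences(query.clr, cand.clr)
        entries.append(NeighborEntry(cand.id, eps, cand.dbh_cm, diffs))
    entries.sort(key=lambda e: (e.epsilon, e.id))
    return NeighborReport(query_id=query.id, neighbors=tuple(entries[:k]), k_requested=k)


def _shortage_cost(entry: NeighborEntry) -> tuple[int, float]:
    neg = [
        d
        for p, d in entry.clr_differences.items()
        if p != "Fv" and d < -SHORTAGE_TOL
    ]
    return (len(neg), float(-sum(neg)))


def select_reference_neighbor(
    report: NeighborReport, objective: str = "distance"
) -> NeighborReport:
    """Pick the reference neighbor the diagnosis is made against.

    ``distance`` takes the epsilon-argmin (closest composition);
    ``parsimony`` minimizes corrective effort — fewest nutrients in
    relative shortage, then smallest total shortage magnitude — so the
    recommended intervention is as cheap as possible.
    """
    if not report.neighbors:
        raise ValueError("empty neighbor report")
    if objective == "distance":
        selected = min(report.neighbors, key=lambda e: (e.epsilon, e.id))
    elif objective == "parsimony":
        selected = min(report.neighbors, key=lambda e: (*_shortage_cost(e), e.epsilon, e.id))
    else:
        raise ValueError(f"unknown objective {objective!r}; use 'distance' or 'parsimony'")
    return replace(report, selected=selected, objective=objective)


def local_diagnosis_report(
    query: Specimen,
    specimens: Sequence[Specimen],
    spec: FactorSpec | None = None,
    k: int = 10,
    objective: str = "distance",
    norms: ReferenceNorms | None = None,
    dbh_floor: float = 5.0,
    quadrants: Mapping[str, str] | None = None,
    broaden: bool = True,
) -> dict:
    """Full regional-vs-local diagnosis bundle for one query specimen.

    Returns a JSON-serializable dict with the regional CND indices (when
    norms are given), the neighbor report, the clr differences against
    the selected neighbor, both nutrient rankings, and the attainable
    DBH (the selected neighbor's).
    """
    spec = spec or FactorSpec()
    pool = filter_successful(specimens, dbh_floor=dbh_floor, quadrants=quadrants)
    if broaden:
        matched, used_spec = match_with_broadening(query, pool, spec)
    else:
        matched, used_spec = match_factors(query, pool, spec), spec
    report = select_reference_neighbor(nearest_neighbors(query, matched, k=k), objective)
    sel = report.selected
    assert sel is not None
    shortages = [
        p for p, d in sel.clr_differences.items() if p != "Fv" and d < -SHORTAGE_TOL
    ]
    out: dict = {
        "query_id": query.id,
        "query_dbh_cm": query.dbh_cm,
        "factor_spec": {"exact": list(used_spec.exact), "windows": dict(used_spec.windows)},
        "k": k,
        "objective": objective,
        "neighbors": [
            {
                "id": e.id,
                "epsilon": e.epsilon,
                "dbh_cm": e.dbh_cm,
                "clr_differences": e.clr_differences,
            }
            for e in report.neighbors
        ],
        "selected_neighbor": {
            "id": sel.id,
            "epsilon": sel.epsilon,
            "attainable_dbh_cm": sel.dbh_cm,
        },
        "local": {
            "clr_differences": sel.clr_differences,
            "epsilon": sel.epsilon,
            "ranking": rank_nutrients(
                {p: d for p, d in sel.clr_differences.items() if p != "Fv"}
            ),
            "shortages": sorted(shortages, key=lambda p: sel.clr_differences[p]),
        },
        "no_corrective_action": not shortages,
    }
    if norms is not None:
        idx = cnd_indices(query, norms)
        out["regional"] = {
            "cnd_indices": idx.as_dict(),
            "ranking": rank_nutrients(idx),
        }
    return out
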