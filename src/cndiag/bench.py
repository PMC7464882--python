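"""Yield classification, confusion-quadrant partitioning and ML benchmarking.

The survey population is split at an economically viable DBH cutoff
(4.3 cm by default) into low- and high-yield classes, and a classifier
predicting the yield class from tissue/feature data partitions specimens
into the four diagnostic quadrants:

* TN — high yield, diagnosed balanced (no response to fertilization
  expected; these specimens supply the reference norms);
* FN — low yield despite balance (some other factor limits growth);
* FP — high yield despite imbalance (luxury consumption, contamination);
* TP — low yield and imbalance (fertilization should pay off).

Model quality is summarized by the rank-based AUC (informative between
0.7 and 0.9) and the classification accuracy CA = (TN+TP)/total.  The
benchmark protocol is Monte-Carlo holdout: ten runs, each scoring a
random 10% holdout with a model trained on the remainder, with per-run
seeds recorded for exact replay.  The same folds are reused across
nutrient expressions (raw concentrations, pwlr, clr, ilr) so that
expression comparisons are paired, and feature ablation re-runs the
bench with one feature removed at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .composition import (
    FULL_PARTS,
    NUTRIENTS,
    build_default_sbp,
    ilr_transform,
    clr_transform,
    pwlr_features,
    pwlr_names,
)
from .specimen import Specimen

__all__ = [
    "YieldLabel",
    "ConfusionQuadrants",
    "BenchResult",
    "ModelSpec",
    "default_model_spec",
    "label_yield",
    "confusion_quadrants",
    "classification_accuracy",
    "auc_score",
    "classify_informative",
    "cross_validate",
    "feature_matrix",
    "expression_bench",
    "feature_ablation",
    "EXPRESSIONS",
]

logger = logging.getLogger(__name__)

EXPRESSIONS = ("raw", "pwlr", "clr", "ilr")


@dataclass(frozen=True)
class YieldLabel:
    id: str
    klass: str  # "high" | "low"
    cutoff_cm: float


def label_yield(
    specimens: Sequence[Specimen] | Sequence[float], cutoff: float = 4.3
) -> list[YieldLabel]:
    """Binary yield labels from DBH; a boundary DBH equal to the cutoff
    counts as high (documented convention)."""
    labels = []
    for i, s in enumerate(specimens):
        if isinstance(s, Specimen):
            sid, dbh = s.id, s.dbh_cm
        else:
            sid, dbh = str(i), float(s)
        if dbh is None or not np.isfinite(dbh):
            raise ValueError(f"missing DBH for specimen {sid}")
        labels.append(YieldLabel(sid, "high" if dbh >= cutoff else "low", cutoff))
    return labels


@dataclass(frozen=True)
class ConfusionQuadrants:
    tn: int
    fn: int
    fp: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fn, self.fp, self.tp) < 0:
            raise ValueError("negative quadrant count")

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.fp + self.tp


def confusion_quadrants(
    yield_classes: Sequence[str], balance_classes: Sequence[str]
) -> ConfusionQuadrants:
    """Cross observed yield class with diagnosed balance class.

    ``yield_classes`` in {"high","low"}; ``balance_classes`` in
    {"balanced","imbalanced"}.  TN = high & balanced, FN = low & balanced,
    FP = high & imbalanced, TP = low & imbalanced.
    """
    if len(yield_classes) != len(balance_classes):
        raise ValueError("length mismatch between yield and balance labels")
    tn = fn = fp = tp = 0
    for y, b in zip(yield_classes, balance_classes):
        if y not in ("high", "low") or b not in ("balanced", "imbalanced"):
            raise ValueError(f"unknown label pair ({y!r}, {b!r})")
        if y == "high":
            tn += b == "balanced"
            fp += b == "imbalanced"
        else:
            fn += b == "balanced"
            tp += b == "imbalanced"
    return ConfusionQuadrants(tn=tn, fn=fn, fp=fp, tp=tp)


def classification_accuracy(q: ConfusionQuadrants) -> float:
    """CA = (TN + TP) / (TN + FN + FP + TP)."""
    if q.total == 0:
        raise ValueError("empty confusion matrix")
    return (q.tn + q.tp) / q.total


def auc_score(y_true: Sequence[int] | Sequence[bool], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("length mismatch")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("single-class input: AUC undefined")
    ranks = rankdata(s)  # midranks for ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classify_informative(auc: float) -> str:
    """Qualitative AUC band: <0.7 uninformative, 0.7-0.9 informative,
    >0.9 highly-informative."""
    if not 0 <= auc <= 1:
        raise ValueError(f"AUC out of [0, 1]: {auc}")
    if auc < 0.7:
        return "uninformative"
    if auc <= 0.9:
        return "informative"
    return "highly-informative"


@dataclass(frozen=True)
class ModelSpec:
    """A named, seedable classifier factory."""

    name: str
    factory: Callable[[int], object]


def default_model_spec(n_estimators: int = 200) -> ModelSpec:
    """Random forest with documented hyperparameters (n_estimators trees,
    sqrt-features splits, unlimited depth), seeded per run."""
    return ModelSpec(
        name="random_forest",
        factory=lambda seed: RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            n_jobs=1,
            random_state=seed,
        ),
    )


@dataclass(frozen=True)
class BenchResult:
    expression: str
    model: str
    aucs: tuple[float, ...]
    cas: tuple[float, ...]
    quadrants: tuple[ConfusionQuadrants, ...]
    run_seeds: tuple[int, ...]
    holdout_fraction: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def mean_ca(self) -> float:
        return float(np.mean(self.cas))

    def to_row(self) -> dict:
        q = ConfusionQuadrants(
            tn=sum(x.tn for x in self.quadrants),
            fn=sum(x.fn for x in self.quadrants),
            fp=sum(x.fp for x in self.quadrants),
            tp=sum(x.tp for x in self.quadrants),
        )
        return {
            "expression": self.expression,
            "model": self.model,
            "AUC": round(self.mean_auc, 3),
            "CA": round(self.mean_ca, 3),
            "TN": q.tn,
            "FN": q.fn,
            "FP": q.fp,
            "TP": q.tp,
        }


def _holdout_indices(
    n: int, holdout_fraction: float, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """A random holdout containing both classes (resampled, logged, if not)."""
    n_test = max(1, int(round(holdout_fraction * n)))
    for attempt in range(100):
        test = rng.permutation(n)[:n_test]
        if 0 < y[test].sum() < n_test:
            if attempt:
                logger.warning("holdout resampled %d time(s): class missing", attempt)
            return test
    raise ValueError("class missing from holdout after 100 resampling attempts")


def cross_validate(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int] | Sequence[bool],
    model_spec: ModelSpec | None = None,
    runs: int = 10,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    expression: str = "features",
) -> BenchResult:
    """Monte-Carlo holdout benchmark: ``runs`` seeded random holdouts of
    ``holdout_fraction`` of the data, each scored by a model trained on
    the remainder; AUC/CA averaged over runs.

    Folds depend only on ``(seed, runs, holdout_fraction, n)``, so
    benchmarks with the same seed are paired across feature expressions.
    """
    model_spec = model_spec or default_model_spec()
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=bool)
    n = len(ya)
    if Xa.shape[0] != n:
        raise ValueError("X/y length mismatch")
    for klass, count in (("high", ya.sum()), ("low", (~ya).sum())):
        if count < 20:
            raise ValueError(f"need >= 20 specimens per class, {klass} has {count}")
    run_seeds = tuple(
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(runs)
    )
    aucs, cas, quads = [], [], []
    for rs in run_seeds:
        rng = np.random.default_rng(rs)
        test = _holdout_indices(n, holdout_fraction, ya, rng)
        train = np.setdiff1d(np.arange(n), test)
        model = model_spec.factory(rs)
        model.fit(Xa[train], ya[train])
        scores = model.predict_proba(Xa[test])[:, list(model.classes_).index(True)]
        pred_high = model.predict(Xa[test])
        aucs.append(auc_score(ya[test], scores))
        # predicted high yield <=> diagnosed nutritionally balanced
        q = confusion_quadrants(
            ["high" if v else "low" for v in ya[test]],
            ["balanced" if v else "imbalanced" for v in pred_high],
        )
        quads.append(q)
        cas.append(classification_accuracy(q))
    return BenchResult(
        expression=expression,
        model=model_spec.name,
        aucs=tuple(aucs),
        cas=tuple(cas),
        quadrants=tuple(quads),
        run_seeds=run_seeds,
        holdout_fraction=holdout_fraction,
    )


def feature_matrix(
    specimens: Sequence[Specimen],
    expression: str = "raw",
    include_factors: bool = False,
) -> pd.DataFrame:
    """Feature table for one nutrient expression, optionally with the
    local factors (clone/soil/location as integer category codes, age).

    raw: 11 native-unit concentrations; clr: 12 coordinates;
    ilr: 11 balances (default partition); pwlr: 66 pairwise log ratios.
    """
    if expression == "raw":
        cols = {
            f"conc_{p}": [s.profile.concentration(p) for s in specimens] for p in NUTRIENTS
        }
    elif expression == "clr":
        mat = np.array([s.clr.values for s in specimens])
        cols = {f"clr_{p}": mat[:, i] for i, p in enumerate(FULL_PARTS)}
    elif expression == "ilr":
        sbp = build_default_sbp()
        mat = np.array([ilr_transform(s.composition, sbp).values for s in specimens])
        cols = {f"ilr_{i:02d}": mat[:, i] for i in range(mat.shape[1])}
    elif expression == "pwlr":
        mat = np.array([pwlr_features(s.composition) for s in specimens])
        cols = {name: mat[:, i] for i, name in enumerate(pwlr_names())}
    else:
        raise ValueError(f"unknown expression {expression!r}; use one of {EXPRESSIONS}")
    df = pd.DataFrame(cols)
    if include_factors:
        for f in ("clone", "soil_type", "location"):
            df[f] = pd.Categorical([getattr(s, f) for s in specimens]).codes
        df["age_yr"] = [s.age_yr for s in specimens]
    return df


def expression_bench(
    specimens: Sequence[Specimen],
    expressions: Sequence[str] = EXPRESSIONS,
    model_spec: ModelSpec | None = None,
    runs: int = 10,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    cutoff: float = 4.3,
    include_factors: bool = False,
) -> list[BenchResult]:
    """Benchmark each nutrient expression on identical folds (paired)."""
    y = [lab.klass == "high" for lab in label_yield(specimens, cutoff=cutoff)]
    return [
        cross_validate(
            feature_matrix(specimens, expr, include_factors=include_factors),
            y,
            model_spec=model_spec,
            runs=runs,
            holdout_fraction=holdout_fraction,
            seed=seed,
            expression=expr,
        )
        for expr in expressions
    ]


def feature_ablation(
    X: pd.DataFrame,
    y: Sequence[bool],
    model_spec: ModelSpec | None = None,
    runs: int = 10,
    holdout_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean-AUC change from dropping one feature at a time (same folds).

    Negative delta: the model got worse without the feature, i.e. the
    feature carries unique signal.
    """
    if X.shape[1] < 2:
        raise ValueError("need >= 2 features to ablate")
    full = cross_validate(
        X, y, model_spec, runs, holdout_fraction, seed, expression="full"
    )
    rows = []
    for col in X.columns:
        res = cross_validate(
            X.drop(columns=[col]), y, model_spec, runs, holdout_fraction, seed,
            expression=f"without_{col}",
        )
        rows.append(
            {
                "feature": col,
                "mean_auc_without": res.mean_auc,
                "delta_auc": res.mean_auc - full.mean_auc,
            }
        )
    return pd.DataFrame(rows)
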