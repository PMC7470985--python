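"""Feedback-inhibition quantification for acetate titration experiments.

Three quantities chain together:

* secretion delta   x_sec = x_obs - x_init          (change vs control)
* null expectation  x_null = x_init + A_sup for the supplemented species
                    itself (supplement simply adds), x_init otherwise
* fold variance     x_var = x_obs / x_null - 1      (0 = additive null
                    holds, -1 = complete suppression, negative values are
                    "missing" metabolite)

Regressing x_var on supplement concentration gives the per-metabolite molar
suppression coefficient (slope, per mM) with its Pearson R^2.

The fold-variance formula appears in the source literature in a
typographically garbled form ("xvar=(xobs-Asupxinit)-1"); the ratio form
implemented here is the interpretation that reproduces the published worked
numbers and sign conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SecretionProfile, control_profile

__all__ = [
    "NullModel",
    "SuppressionResult",
    "TestKind",
    "TestResult",
    "secretion_delta",
    "null_expectation",
    "fold_variance",
    "suppression_coefficient",
    "metabolite_ttest",
    "suppression_table",
]


@dataclass(frozen=True)
class NullModel:
    """Additive no-effect expectation for one metabolite.

    ``additive_supplement`` is True only for the supplemented species itself
    (supplementing A mM of acetate makes the null acetate expectation
    x_init + A); every other metabolite's null is its control level.
    """

    metabolite: str
    x_init: float
    additive_supplement: bool = False


@dataclass
class SuppressionResult:
    """OLS slope of fold variance vs supplement (per mM) with Pearson R^2."""

    metabolite: str
    slope: float
    r_squared: float
    n_points: int


class TestKind(str, Enum):
    student_pooled = "student_pooled"
    welch = "welch"


@dataclass
class TestResult:
    metabolite: str
    treatment_pair: tuple[str, str]
    t_statistic: float
    p_value: float
    test_kind: TestKind


def secretion_delta(x_obs: float, x_init: float) -> float:
    """Observed minus control concentration (mM); may be negative."""
    if not (np.isfinite(x_obs) and np.isfinite(x_init)):
        raise ValueError("concentrations must be finite")
    if x_obs < 0 or x_init < 0:
        raise ValueError("concentrations must be non-negative")
    return x_obs - x_init


def null_expectation(model: NullModel, a_sup: float) -> float:
    """Concentration expected if the supplement had no metabolic effect."""
    if a_sup < 0:
        raise ValueError("supplement concentration must be non-negative")
    if model.additive_supplement:
        return model.x_init + a_sup
    return model.x_init


def fold_variance(x_obs: float, model: NullModel, a_sup: float) -> float:
    """Fold deviation of the observation from the additive null model.

    Returns x_obs / x_null - 1.  Zero means the null holds; -1 means
    complete suppression.  Undefined (NaN, with a warning) when the null
    expectation is zero.
    """
    x_null = null_expectation(model, a_sup)
    if x_null == 0:
        warnings.warn(
            f"{model.metabolite}: null expectation is zero; fold variance undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return x_obs / x_null - 1.0


def suppression_coefficient(
    points: Sequence[tuple[float, float]], metabolite: str = ""
) -> SuppressionResult:
    """Unweighted OLS of fold variance on supplement concentration.

    Requires at least three distinct supplement levels including the 0 mM
    control point.  R^2 is the squared Pearson correlation (1.0 reported
    for an exactly flat response, where the correlation is degenerate).
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (a_sup, x_var) pairs")
    a, y = arr[:, 0], arr[:, 1]
    levels = np.unique(a)
    if levels.size < 3:
        raise ValueError("need >= 3 distinct supplement levels")
    if 0.0 not in levels:
        raise ValueError("titration must include the 0 mM control level")

    slope, intercept = np.polyfit(a, y, 1)
    residuals = y - (slope * a + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(residuals**2)) / ss_tot
    return SuppressionResult(
        metabolite=metabolite,
        slope=float(slope),
        r_squared=float(r_squared),
        n_points=len(a),
    )


def metabolite_ttest(
    a: Sequence[float],
    b: Sequence[float],
    kind: TestKind = TestKind.student_pooled,
    metabolite: str = "",
    treatment_pair: tuple[str, str] = ("", ""),
) -> TestResult:
    """Two-sample two-sided t test (pooled-variance Student's by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    kind = TestKind(kind)
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=(kind is TestKind.student_pooled))
    return TestResult(
        metabolite=metabolite,
        treatment_pair=treatment_pair,
        t_statistic=float(t),
        p_value=float(p),
        test_kind=kind,
    )


def suppression_table(
    profiles: Sequence[SecretionProfile],
) -> list[SuppressionResult]:
    """Per-metabolite suppression coefficients from an acetate titration.

    Uses per-treatment mean concentrations (one fold-variance point per
    supplement level, the 0 mM control contributing an exact zero).
    Metabolites missing from any treatment are excluded with a warning.
    Results are sorted by slope magnitude, strongest suppression first.
    """
    control = control_profile(profiles)
    titration = sorted(
        (p for p in profiles if p.treatment.formate_mM == 0),
        key=lambda p: p.treatment.acetate_mM,
    )
    levels = {p.treatment.acetate_mM for p in titration}
    if len(levels) < 3:
        raise ValueError(
            "need an acetate titration with >= 3 levels including the control"
        )

    results: list[SuppressionResult] = []
    for met in control.metabolites:
        if any(met not in p.concentrations for p in titration):
            warnings.warn(
                f"{met}: missing from at least one treatment; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        model = NullModel(
            metabolite=met,
            x_init=control.mean(met),
            additive_supplement=(met == "acetate"),
        )
        points = [
            (p.treatment.acetate_mM,
             fold_variance(p.mean(met), model, p.treatment.acetate_mM))
            for p in titration
        ]
        results.append(suppression_coefficient(points, metabolite=met))
    results.sort(key=lambda r: abs(r.slope), reverse=True)
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p values (FDR). Off by default everywhere: the original
    analysis reports raw per-metabolite p values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def suppression_frame(results: Sequence[SuppressionResult]) -> pd.DataFrame:
    """Tabular view (metabolite, slope, R^2) of suppression results."""
    return pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in results],
            "slope": [r.slope for r in results],
            "r_squared": [r.r_squared for r in results],
        }
    )
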