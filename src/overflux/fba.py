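"""A small self-contained flux-balance-analysis engine.

The engine solves the standard FBA linear program

    maximize  v_biomass   subject to   S v = 0,  lb <= v <= ub

with scipy's HiGHS solver, followed by a lexicographic second stage that
minimizes total absolute flux at the fixed optimum.  Without the second
stage, alternate optima make reaction-by-reaction comparisons between
conditions meaningless; with it, repeated runs are bit-identical.

The packaged model is a curated central-carbon network of an anaerobic
glucose fermenter (EMP glycolysis, pyruvate formate-lyase, pyruvate
dehydrogenase/synthase, Ack/Pta and acetyl-CoA synthetase routes to
acetate, reductive TCA branch to succinate, the methylmalonyl route to
propionate, lactate dehydrogenase, both asparagine-synthesis routes, and a
lumped biomass reaction).  It is deliberately small: a genome-scale
reconstruction is out of scope, and the qualitative behaviours (biomass
invariance at high glucose, asparagine-route interchangeability, overflow
acetate secretion) are the testable surface.

Exchange reactions follow the usual convention: ``EX_x: x_e ->`` with
positive flux = secretion and negative flux = uptake, so a medium is a map
of maximum uptake rates that sets exchange lower bounds to -uptake.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Reaction",
    "ModelMetabolite",
    "StoichiometricModel",
    "MediaSpec",
    "FBAResult",
    "ValidationReport",
    "load_model",
    "default_model",
    "default_media",
    "apply_media",
    "solve_fba",
    "media_grid",
    "knockout",
    "validate_model",
    "flux_change_label",
    "flux_delta_table",
    "GLUCOSE_UPTAKE",
    "SUPPLEMENT_UPTAKE",
]

#: maximum glucose uptake (mmol / gCDW / h) defining the two glucose regimes
GLUCOSE_UPTAKE = {"high": 2.78, "low": 0.1}

#: maximum uptake used when acetate or formate is present in the medium
SUPPLEMENT_UPTAKE = 10.0

_DEFAULT_UB = 1000.0
_FLUX_TOL = 1e-9


@dataclass(frozen=True)
class ModelMetabolite:
    id: str
    compartment: str  # "c" internal, "e" external
    carbon: int = 0
    nitrogen: int = 0
    name: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""
    exempt_balance: bool = False

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        return self.id.startswith("EX_")


@dataclass
class StoichiometricModel:
    name: str
    metabolites: list[ModelMetabolite]
    reactions: list[Reaction]
    objective: str

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if self.objective not in self._rxn_index:
            raise ValueError(f"objective reaction {self.objective!r} not in model")

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"reaction {rxn_id!r} not in model") from None

    def metabolite(self, met_id: str) -> ModelMetabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise KeyError(f"metabolite {met_id!r} not in model") from None

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    def stoichiometric_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                S[self._met_index[met_id], j] = coef
        return S

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            name=self.name,
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            objective=self.objective,
        )


class MediaSpec(dict):
    """Map of external metabolite id -> maximum uptake (mmol/gCDW/h).

    Metabolites absent from the map get zero uptake (secretion stays open).
    """

    def __init__(self, uptakes: Mapping[str, float] | None = None):
        super().__init__()
        for met, rate in (uptakes or {}).items():
            if rate < 0:
                raise ValueError(f"{met}: uptake must be non-negative")
            self[met] = float(rate)


class FBAStatus(str, Enum):
    optimal = "optimal"
    infeasible = "infeasible"


@dataclass
class FBAResult:
    status: FBAStatus
    objective_value: float | None
    reaction_fluxes: dict[str, float]
    exchange_fluxes: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status is FBAStatus.optimal


def _model_from_dict(data: dict) -> StoichiometricModel:
    mets = [ModelMetabolite(**m) for m in data["metabolites"]]
    rxns = [
        Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry=dict(r["stoichiometry"]),
            lower_bound=float(r["lower_bound"]),
            upper_bound=float(r["upper_bound"]),
            exempt_balance=bool(r.get("exempt_balance", False)),
        )
        for r in data["reactions"]
    ]
    return StoichiometricModel(
        name=data.get("name", "model"),
        metabolites=mets,
        reactions=rxns,
        objective=data["objective"],
    )


def load_model(path: str | Path) -> StoichiometricModel:
    with open(path) as fh:
        return _model_from_dict(json.load(fh))


def default_model() -> StoichiometricModel:
    """The packaged curated central-carbon model."""
    text = resources.files("overflux.data").joinpath("model.json").read_text()
    return _model_from_dict(json.loads(text))


def default_media() -> dict:
    """Packaged media definitions (base medium + glucose/supplement levels)."""
    text = resources.files("overflux.data").joinpath("media.json").read_text()
    return json.loads(text)


def _external_id(model: StoichiometricModel, met: str) -> str:
    """Accept either a bare name ('glc') or a model id ('glc_e')."""
    if f"{met}_e" in model._met_index:
        return f"{met}_e"
    if met in model._met_index and model.metabolite(met).compartment == "e":
        return met
    raise KeyError(f"external metabolite {met!r} not in model")


def apply_media(model: StoichiometricModel, media: MediaSpec) -> StoichiometricModel:
    """Return a copy with exchange lower bounds set from the medium."""
    uptake = {_external_id(model, met): rate for met, rate in media.items()}
    new = model.copy()
    for i, rxn in enumerate(new.reactions):
        if not rxn.is_exchange:
            continue
        (met_id,) = rxn.stoichiometry.keys()
        new.reactions[i] = replace(rxn, lower_bound=-uptake.get(met_id, 0.0))
    return new


def solve_fba(
    model: StoichiometricModel, media: MediaSpec | None = None
) -> FBAResult:
    """Maximize the biomass objective, then minimize total absolute flux.

    The second stage pins down a unique, reproducible flux distribution
    among alternate optima.  Returns status='infeasible' with no fluxes if
    the constraints cannot be satisfied.
    """
    if media is not None:
        model = apply_media(model, MediaSpec(media))
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    for r in model.reactions:
        if r.lower_bound > r.upper_bound:
            raise ValueError(f"reaction {r.id}: lower bound exceeds upper bound")
    c = np.zeros(n)
    c[model._rxn_index[model.objective]] = -1.0  # linprog minimizes

    opts = {
        "primal_feasibility_tolerance": 1e-10,
        "dual_feasibility_tolerance": 1e-10,
    }
    first = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
        method="highs", options=opts,
    )
    if not first.success:
        return FBAResult(FBAStatus.infeasible, None, {}, {})
    z_star = -first.fun

    # stage 2: min sum |v| with v = flux vars, u = absolute-value majorants
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq2 = np.hstack([S, np.zeros_like(S)])
    obj_row = np.concatenate([-c, np.zeros(n)])  # biomass coefficient row
    A_eq2 = np.vstack([A_eq2, obj_row])
    b_eq2 = np.concatenate([np.zeros(S.shape[0]), [z_star]])
    # u >= v and u >= -v  <=>  v - u <= 0 and -v - u <= 0
    eye = np.eye(n)
    A_ub = np.vstack(
        [np.hstack([eye, -eye]), np.hstack([-eye, -eye])]
    )
    b_ub = np.zeros(2 * n)
    u_bounds = [(0.0, max(abs(lo), abs(hi))) for lo, hi in bounds]
    second = linprog(
        c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq2, b_eq=b_eq2,
        bounds=bounds + u_bounds, method="highs", options=opts,
    )
    v = second.x[:n] if second.success else first.x

    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FBAResult(
        status=FBAStatus.optimal,
        objective_value=float(z_star),
        reaction_fluxes=fluxes,
        exchange_fluxes={rid: fluxes[rid] for rid in model.exchange_ids},
    )


def knockout(
    model: StoichiometricModel, reaction_ids: Sequence[str] | str
) -> StoichiometricModel:
    """Return a copy with the given reactions' bounds fixed to zero."""
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    new = model.copy()
    for rid in reaction_ids:
        j = new._rxn_index.get(rid)
        if j is None:
            raise KeyError(f"reaction {rid!r} not in model")
        new.reactions[j] = replace(new.reactions[j], lower_bound=0.0, upper_bound=0.0)
    return new


def _grid_media(
    base: Mapping[str, float],
    glucose: str,
    acetate: bool,
    formate: bool,
    glucose_uptake: Mapping[str, float],
    supplement_uptake: float,
) -> MediaSpec:
    media = MediaSpec(base)
    media["glc"] = glucose_uptake[glucose]
    media["ac"] = supplement_uptake if acetate else 0.0
    media["for"] = supplement_uptake if formate else 0.0
    return media


@dataclass
class GridResult:
    """The 8-condition experiment grid (glucose level x +/-acetate x +/-formate)."""

    results: dict[tuple[str, bool, bool], FBAResult]
    deltas: dict[tuple[str, bool, bool], "object"]  # pd.DataFrame per condition

    @staticmethod
    def label(condition: tuple[str, bool, bool]) -> str:
        glucose, ac, fo = condition
        tag = "HG" if glucose == "high" else "LG"
        if ac:
            tag += "+Ac"
        if fo:
            tag += "+Fo"
        return tag


def flux_change_label(v_ref: float, v_new: float, tol: float = 1e-6) -> str:
    """Classify a per-reaction flux change between two conditions."""
    ref_zero, new_zero = abs(v_ref) <= tol, abs(v_new) <= tol
    if ref_zero and new_zero:
        return "no_change"
    if new_zero:
        return "zero_net"
    if not ref_zero and np.sign(v_ref) != np.sign(v_new):
        return "direction_change"
    if abs(v_new) > abs(v_ref) + tol:
        return "increased"
    if abs(v_new) < abs(v_ref) - tol:
        return "decreased"
    return "no_change"


def flux_delta_table(reference: FBAResult, condition: FBAResult):
    """Per-reaction flux comparison between two optimal solutions."""
    import pandas as pd

    rows = []
    for rid in reference.reaction_fluxes:
        v0 = reference.reaction_fluxes[rid]
        v1 = condition.reaction_fluxes.get(rid, 0.0)
        rows.append(
            {
                "reaction": rid,
                "flux_reference": v0,
                "flux_condition": v1,
                "delta": v1 - v0,
                "label": flux_change_label(v0, v1),
            }
        )
    return pd.DataFrame(rows)


def media_grid(
    model: StoichiometricModel,
    base_media: Mapping[str, float] | None = None,
    glucose_uptake: Mapping[str, float] | None = None,
    supplement_uptake: float = SUPPLEMENT_UPTAKE,
) -> GridResult:
    """Run the 8-condition grid and compare against the supplement-free medium.

    Conditions are {high, low} glucose x {0, 10} acetate x {0, 10} formate
    (maximum uptakes, mmol/gCDW/h).  For each glucose level, every
    supplemented condition is compared to the supplement-free condition at
    the same glucose level.
    """
    if base_media is None:
        base_media = default_media()["base"]
    if glucose_uptake is None:
        glucose_uptake = GLUCOSE_UPTAKE
    results: dict[tuple[str, bool, bool], FBAResult] = {}
    for glucose in ("high", "low"):
        for acetate in (False, True):
            for formate in (False, True):
                media = _grid_media(
                    base_media, glucose, acetate, formate,
                    glucose_uptake, supplement_uptake,
                )
                results[(glucose, acetate, formate)] = solve_fba(model, media)
    deltas = {}
    for (glucose, acetate, formate), res in results.items():
        if not (acetate or formate):
            continue
        ref = results[(glucose, False, False)]
        if ref.ok and res.ok:
            deltas[(glucose, acetate, formate)] = flux_delta_table(ref, res)
    return GridResult(results=results, deltas=deltas)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {"ok": self.ok, "violations": self.violations, "warnings": self.warnings}


def validate_model(model: StoichiometricModel) -> ValidationReport:
    """Check elemental balance (C, N), bounds sanity, and dead ends.

    Biomass (the objective), exchange reactions, and reactions flagged
    ``exempt_balance`` are exempt from elemental balance.  Dead-end
    metabolites (never produced or never consumed by any reaction) are
    reported as warnings, not violations.
    """
    report = ValidationReport()
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            report.violations.append(f"{rxn.id}: lower bound exceeds upper bound")
        for met_id in rxn.stoichiometry:
            if met_id not in model._met_index:
                report.violations.append(
                    f"{rxn.id}: unknown metabolite {met_id!r}"
                )
    if model.objective not in model._rxn_index:
        report.violations.append(f"objective {model.objective!r} missing")

    for rxn in model.reactions:
        if rxn.is_exchange or rxn.id == model.objective or rxn.exempt_balance:
            continue
        if any(m not in model._met_index for m in rxn.stoichiometry):
            continue
        for element in ("carbon", "nitrogen"):
            balance = sum(
                coef * getattr(model.metabolite(met_id), element)
                for met_id, coef in rxn.stoichiometry.items()
            )
            if abs(balance) > 1e-9:
                report.violations.append(
                    f"{rxn.id}: {element} imbalance of {balance:+g}"
                )

    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions:
        for met_id, coef in rxn.stoichiometry.items():
            if coef > 0 or rxn.reversible:
                produced.add(met_id)
            if coef < 0 or rxn.reversible:
                consumed.add(met_id)
    for met in model.metabolites:
        if met.id not in produced or met.id not in consumed:
            report.warnings.append(f"{met.id}: dead-end metabolite")
    return report
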