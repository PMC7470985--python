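"""Study-shaped synthetic data with known ground truth.

The generator emulates the titration design of the fermentation study:
acetate supplemented at {0, 0.5, 1, 5, 10} mM (optionally 10 mM formate
and the 10 + 10 combination), 5 biological x 5 technical replicates
(n = 25) per treatment, and replicate noise that is multiplicative
Gaussian with a fixed coefficient of variation (printed SDs scale roughly
with means, e.g. control acetate 6.6 +/- 0.5 mM, cv ~ 0.08).

Baseline (control) secretion means are anchored to the concentrations the
study prints (acetate 6.6 mM; lactate 120, histidine 101, cysteine 242,
cystine 209, glutathione 121 uM).  Baselines for succinate, formate,
propionate, alanine and asparagine are NOT published values; they are
order-of-magnitude placeholders consistent with the reported abundance
ranking.

Per-metabolite feedback is parameterized by a fold-variance slope s (per
mM): the mean observed concentration at supplement level A is
x_null(A) * (1 + s*A), the endpoint form of the feedback-inhibition
scenario.  Because concentrations are non-negative, x_var >= -1, so
feasible generating slopes satisfy |s| <= 1/A_max; defaults preserve the
reported suppression hierarchy (acetate weakest ... alanine strongest)
with magnitudes spread across that feasible range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import MetaboliteRegistry, SecretionProfile, Treatment
from .growth import GrowthCurve
from .scenarios import Scenario

__all__ = [
    "DEFAULT_BASELINES",
    "DEFAULT_SLOPES",
    "GeneratorConfig",
    "GroundTruth",
    "generate_profiles",
    "GrowthGeneratorConfig",
    "generate_growth",
]

#: control means (mM); starred-in-docstring entries are placeholders
DEFAULT_BASELINES: dict[str, float] = {
    "acetate": 6.6,
    "succinate": 3.0,      # placeholder
    "formate": 1.5,        # placeholder
    "propionate": 0.8,     # placeholder
    "lactate": 0.120,
    "histidine": 0.101,
    "cysteine": 0.242,
    "cystine": 0.209,
    "glutathione": 0.121,
    "asparagine": 0.080,   # placeholder
    "alanine": 0.150,      # placeholder
}

#: fold-variance slopes (per mM); hierarchy follows the reported ranking,
#: magnitudes spaced across the feasible range [-1/A_max, 0] for A_max = 10
DEFAULT_SLOPES: dict[str, float] = {
    "acetate": -0.001,
    "succinate": -0.01,
    "formate": -0.02,
    "propionate": -0.03,
    "cysteine": -0.04,
    "cystine": -0.05,
    "glutathione": -0.06,
    "lactate": -0.07,
    "histidine": -0.08,
    "asparagine": -0.09,
    "alanine": -0.10,
}

STUDY_ACETATE_LEVELS = (0.0, 0.5, 1.0, 5.0, 10.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Design and ground truth of a synthetic titration experiment."""

    baseline_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    suppression_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES)
    )
    scenario: Scenario = Scenario.feedback_only
    noise_cv: float = 0.08
    n_biological: int = 5
    n_technical: int = 5
    acetate_levels: tuple[float, ...] = STUDY_ACETATE_LEVELS
    formate_flag: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if 0.0 not in self.acetate_levels:
            raise ValueError("acetate_levels must include the 0 mM control")
        missing = set(self.suppression_slopes) - set(self.baseline_means)
        if missing:
            raise ValueError(f"slopes given for unknown metabolites: {sorted(missing)}")


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery checks."""

    baseline_means: dict[str, float]
    suppression_slopes: dict[str, float]
    noise_cv: float
    seed: int
    clamped_draws: int = 0
    total_draws: int = 0

    @property
    def clamp_fraction(self) -> float:
        return self.clamped_draws / self.total_draws if self.total_draws else 0.0


def _mean_at_level(metabolite: str, baseline: float, slope: float, level: float) -> float:
    """Feedback-scenario endpoint mean: x_null * (1 + s*A), floored at 0."""
    null = baseline + level if metabolite == "acetate" else baseline
    return max(null * (1.0 + slope * level), 0.0)


def generate_profiles(
    config: GeneratorConfig | None = None,
    registry: MetaboliteRegistry | None = None,
) -> tuple[list[SecretionProfile], GroundTruth]:
    """Generate replicate secretion profiles plus their ground truth.

    Replicate values are mean * (1 + cv * z) with standard-normal z,
    clamped at zero (clamp events are counted in the ground truth record).
    Identical seeds give identical tables.
    """
    config = config or GeneratorConfig()
    registry = registry or MetaboliteRegistry.default()
    rng = np.random.default_rng(config.seed)
    n_rep = config.n_biological * config.n_technical

    treatments = [Treatment(acetate_mM=a) for a in sorted(config.acetate_levels)]
    if config.formate_flag:
        treatments.append(Treatment(formate_mM=10.0))
        treatments.append(Treatment(acetate_mM=10.0, formate_mM=10.0))

    truth = GroundTruth(
        baseline_means=dict(config.baseline_means),
        suppression_slopes=dict(config.suppression_slopes),
        noise_cv=config.noise_cv,
        seed=config.seed,
    )

    profiles: list[SecretionProfile] = []
    for treatment in treatments:
        concentrations: dict[str, np.ndarray] = {}
        for met in sorted(config.baseline_means):
            if met not in registry:
                raise KeyError(f"metabolite {met!r} not in registry")
            baseline = config.baseline_means[met]
            slope = config.suppression_slopes.get(met, 0.0)
            mean = _mean_at_level(met, baseline, slope, treatment.acetate_mM)
            if config.noise_cv > 0:
                draws = mean * (1.0 + config.noise_cv * rng.standard_normal(n_rep))
            else:
                draws = np.full(n_rep, mean)
            truth.total_draws += n_rep
            truth.clamped_draws += int(np.sum(draws < 0))
            concentrations[met] = np.clip(draws, 0.0, None)
        profiles.append(
            SecretionProfile(
                treatment=treatment,
                concentrations=concentrations,
                n_biological=config.n_biological,
                n_technical=config.n_technical,
            )
        )
    return profiles, truth


#: dose-response of doubling time (h) vs acetate dose (mM): a downward
#: parabola peaking inside the tested range, anchored so the 0 mM control
#: doubles in 1.322 h (the reported control doubling time)
DEFAULT_TD_COEFFICIENTS = (-0.01948, 0.2188, 1.322)  # highest degree first


@dataclass(frozen=True)
class GrowthGeneratorConfig:
    """Design of a synthetic OD600 growth experiment."""

    td_coefficients: tuple[float, ...] = DEFAULT_TD_COEFFICIENTS
    acetate_levels: tuple[float, ...] = STUDY_ACETATE_LEVELS
    n_replicates: int = 6
    od0: float = 0.02
    od_max: float | None = None  # set to e.g. 1.0 for a stationary plateau
    times: tuple[float, ...] = tuple(0.5 * i for i in range(17))  # 0..8 h
    noise_cv: float = 0.0
    seed: int = 0

    def true_td(self, dose: float) -> float:
        return float(np.polyval(self.td_coefficients, dose))


def generate_growth(
    config: GrowthGeneratorConfig | None = None,
) -> dict[float, list[GrowthCurve]]:
    """Generate replicate OD600 curves per acetate dose.

    Curves are exponential (OD = od0 * 2^(t/Td)), optionally capped at
    ``od_max`` (entry into stationary phase), with optional multiplicative
    observation noise on OD.  The true doubling time per dose follows the
    configured dose-response polynomial.
    """
    config = config or GrowthGeneratorConfig()
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)

    curves: dict[float, list[GrowthCurve]] = {}
    for dose in config.acetate_levels:
        td = config.true_td(dose)
        if td <= 0:
            raise ValueError(f"dose {dose}: non-positive doubling time {td}")
        od = config.od0 * 2.0 ** (times / td)
        if config.od_max is not None:
            od = np.minimum(od, config.od_max)
        replicates = []
        for _ in range(config.n_replicates):
            if config.noise_cv > 0:
                noisy = od * (1.0 + config.noise_cv * rng.standard_normal(od.size))
                noisy = np.clip(noisy, 1e-6, None)
            else:
                noisy = od.copy()
            replicates.append(
                GrowthCurve(times=times, od600=noisy, treatment=Treatment(acetate_mM=dose))
            )
        curves[dose] = replicates
    return curves
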