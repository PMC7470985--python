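"""End-to-end pipeline runner with deterministic, manifest-tracked outputs.

A run executes selected stages in dependency order on one output directory:

    synth -> fluxmap -> suppression -> classify        (secretion analyses)
    growth                                             (doubling times)
    fba                                                (in-silico grid)

All randomness flows from the single top-level seed (stage seeds are fanned
out deterministically).  Outputs contain no timestamps, so re-running the
same configuration produces byte-identical files; the manifest records the
configuration, seed, package version and a SHA-256 digest per output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import MetaboliteRegistry, control_profile, load_profiles, write_profiles
from .fluxmap import build_network_map, carbon_flux, export_network
from .growth import doubling_time, dose_response
from .inhibition import metabolite_ttest, suppression_frame, suppression_table
from .scenarios import classify_scenario
from .synthetic import (
    GeneratorConfig,
    GrowthGeneratorConfig,
    generate_growth,
    generate_profiles,
)
from . import fba as fba_mod

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("synth", "fluxmap", "suppression", "classify", "growth", "fba")

#: offsets fanned out from the top-level seed, one per randomized stage
_SEED_OFFSETS = {"synth_profiles": 1, "synth_growth": 2}


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained with a failure marker."""


@dataclass
class RunConfig:
    outdir: str | Path = "overflux_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    profiles_path: str | Path | None = None  # use existing table instead of synth
    noise_cv: float = 0.08
    growth_noise_cv: float = 0.01

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = MetaboliteRegistry.default()
    outputs: list[Path] = []

    profiles = None
    if config.profiles_path is not None:
        path = Path(config.profiles_path)
        if not path.exists():
            raise FileNotFoundError(f"input profile table not found: {path}")
        profiles = load_profiles(path, registry)

    def needs(stage: str) -> bool:
        return stage in config.stages

    def run_stage(stage: str, fn) -> None:
        try:
            fn()
        except Exception as exc:
            marker = outdir / f"{stage}.FAILED"
            marker.write_text(f"{type(exc).__name__}: {exc}\n")
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    def stage_synth() -> None:
        nonlocal profiles
        gen_config = GeneratorConfig(
            noise_cv=config.noise_cv, seed=config.seed + _SEED_OFFSETS["synth_profiles"]
        )
        profiles, truth = generate_profiles(gen_config, registry)
        table = outdir / "profiles.tsv"
        write_profiles(profiles, table)
        sidecar = outdir / "ground_truth.json"
        sidecar.write_text(
            json.dumps(
                {
                    "baseline_means": truth.baseline_means,
                    "suppression_slopes": truth.suppression_slopes,
                    "noise_cv": truth.noise_cv,
                    "seed": truth.seed,
                    "clamped_draws": truth.clamped_draws,
                    "total_draws": truth.total_draws,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        outputs.extend([table, sidecar])

    def stage_fluxmap() -> None:
        control = control_profile(profiles)
        fmap = carbon_flux(control.means(), registry)
        df = pd.DataFrame(
            {
                "metabolite": list(fmap.fluxes),
                "mM": [control.mean(m) for m in fmap.fluxes],
                "C_mmol": [
                    control.mean(m) * registry.carbon(m) for m in fmap.fluxes
                ],
                "percent": list(fmap.fluxes.values()),
            }
        ).sort_values("percent", ascending=False, kind="stable")
        table = outdir / "fluxmap.tsv"
        _write_tsv(df, table)
        network = build_network_map(fmap, registry)
        dot = outdir / "fluxmap.dot"
        graphml = outdir / "fluxmap.graphml"
        export_network(network, "dot", dot)
        export_network(network, "graphml", graphml)
        outputs.extend([table, dot, graphml])

    def stage_suppression() -> None:
        results = suppression_table(profiles)
        table = outdir / "suppression.tsv"
        _write_tsv(suppression_frame(results), table)
        outputs.append(table)

    def stage_classify() -> None:
        control = control_profile(profiles)
        titration = sorted(
            (p for p in profiles if p.treatment.formate_mM == 0),
            key=lambda p: p.treatment.acetate_mM,
        )
        rows = []
        for met in control.metabolites:
            x_init = control.mean(met)
            endpoints = {
                p.treatment.acetate_mM: p.concentrations[met]
                - (x_init + p.treatment.acetate_mM if met == "acetate" else x_init)
                for p in titration
                if met in p.concentrations
            }
            if len(endpoints) < 3:
                continue
            fit = classify_scenario(endpoints, x_init=x_init)
            rows.append(
                {
                    "metabolite": met,
                    "scenario": fit.best.value,
                    "a_hat": fit.a_hat,
                    "b_hat": fit.b_hat,
                    "p_value_b": fit.p_value_b,
                }
            )
        table = outdir / "scenarios.tsv"
        _write_tsv(pd.DataFrame(rows), table)
        outputs.append(table)

    def stage_growth() -> None:
        growth_config = GrowthGeneratorConfig(
            noise_cv=config.growth_noise_cv,
            seed=config.seed + _SEED_OFFSETS["synth_growth"],
        )
        curves = generate_growth(growth_config)
        tds_by_dose = {
            dose: [doubling_time(c) for c in reps] for dose, reps in curves.items()
        }
        control_tds = tds_by_dose[min(tds_by_dose)]
        rows = []
        for dose, tds in tds_by_dose.items():
            if dose == min(tds_by_dose):
                p_vs_control = 1.0
            else:
                p_vs_control = metabolite_ttest(tds, control_tds).p_value
            rows.append(
                {
                    "acetate_mM": dose,
                    "doubling_time_h": float(pd.Series(tds).mean()),
                    "sd": float(pd.Series(tds).std(ddof=1)),
                    "n": len(tds),
                    "p_vs_control": p_vs_control,
                }
            )
        df = pd.DataFrame(rows)
        fit = dose_response(df["acetate_mM"], df["doubling_time_h"], "parabolic")
        table = outdir / "growth.tsv"
        _write_tsv(df, table)
        summary = outdir / "growth_fit.json"
        summary.write_text(
            json.dumps(
                {
                    "model": fit.model.value,
                    "coefficients": list(fit.coefficients),
                    "r_squared": fit.r_squared,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        outputs.extend([table, summary])

    def stage_fba() -> None:
        model = fba_mod.default_model()
        grid = fba_mod.media_grid(model)
        rows = []
        for condition, res in grid.results.items():
            rows.append(
                {
                    "condition": grid.label(condition),
                    "status": res.status.value,
                    "biomass": res.objective_value,
                }
            )
        table = outdir / "fba_grid.tsv"
        _write_tsv(pd.DataFrame(rows), table)
        outputs.append(table)
        for condition, delta in grid.deltas.items():
            path = outdir / f"fba_delta_{grid.label(condition)}.tsv"
            _write_tsv(delta, path)
            outputs.append(path)

    if needs("synth"):
        run_stage("synth", stage_synth)
    if profiles is None and any(
        needs(s) for s in ("fluxmap", "suppression", "classify")
    ):
        raise PipelineError(
            "secretion stages need profiles: run 'synth' or give profiles_path"
        )
    for stage, fn in (
        ("fluxmap", stage_fluxmap),
        ("suppression", stage_suppression),
        ("classify", stage_classify),
        ("growth", stage_growth),
        ("fba", stage_fba),
    ):
        if needs(stage):
            run_stage(stage, fn)

    config_dict = asdict(config)
    del config_dict["outdir"]  # a location, not semantics: keeps manifests
    # byte-identical when the same run is written to different directories
    if config_dict["profiles_path"] is not None:
        config_dict["profiles_path"] = str(config_dict["profiles_path"])
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
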