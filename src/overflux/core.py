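"""Domain types, metabolite registry, and table readers/writers.

Concentration tables are plain CSV/TSV with one row per sample:

    sample_id, acetate_mM, formate_mM, <metabolite>[, <metabolite>_uM, ...]

``acetate_mM`` and ``formate_mM`` are *treatment* columns (supplement added
to the medium); the remaining columns are measured concentrations of
registered secreted metabolites.  Bare metabolite columns are read as mM;
a ``_uM`` suffix marks micromolar entries, converted to mM on load.  The
internal canonical unit is always mM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import nan
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "MetaboliteRegistry",
    "Treatment",
    "SecretionProfile",
    "SummaryStat",
    "load_profiles",
    "write_profiles",
    "summarize",
]

#: columns that are never interpreted as metabolite measurements
RESERVED_COLUMNS = frozenset(
    {"sample_id", "sample", "acetate_mM", "formate_mM", "bio_rep", "tech_rep"}
)

_UNIT_FACTORS = {"mM": 1.0, "uM": 1e-3}


@dataclass(frozen=True)
class Metabolite:
    """A secreted metabolite and its place in the precursor network.

    ``carbon_count`` is fixed chemistry (C atoms per molecule; cystine, the
    Cys-Cys disulfide, counts 6 as one molecule).  ``network_node`` names the
    undetected intracellular precursor node the metabolite drains from.
    """

    name: str
    carbon_count: int
    network_node: str
    secreted: bool = True

    def __post_init__(self) -> None:
        if self.carbon_count < 1:
            raise ValueError(f"{self.name}: carbon_count must be >= 1")


class MetaboliteRegistry:
    """Lookup table of metabolites with carbon counts and network nodes."""

    def __init__(self, metabolites: Sequence[Metabolite]):
        self._by_name: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.name in self._by_name:
                raise ValueError(f"duplicate metabolite {met.name!r}")
            self._by_name[met.name] = met

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __iter__(self) -> Iterator[Metabolite]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def get(self, name: str) -> Metabolite:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"metabolite {name!r} not in registry") from None

    def carbon(self, name: str) -> int:
        return self.get(name).carbon_count

    @classmethod
    def from_json(cls, path: str | Path) -> "MetaboliteRegistry":
        with open(path) as fh:
            entries = json.load(fh)
        return cls([Metabolite(**e) for e in entries])

    @classmethod
    def default(cls) -> "MetaboliteRegistry":
        """The packaged registry of the eleven detected secreted metabolites."""
        text = resources.files("overflux.data").joinpath("registry.json").read_text()
        return cls([Metabolite(**e) for e in json.loads(text)])


@dataclass(frozen=True)
class Treatment:
    """A supplementation condition: acetate and/or formate added to the medium."""

    acetate_mM: float = 0.0
    formate_mM: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.acetate_mM < 0 or self.formate_mM < 0:
            raise ValueError("supplement concentrations must be non-negative")
        if not self.label:
            object.__setattr__(self, "label", self._auto_label())

    def _auto_label(self) -> str:
        if self.acetate_mM == 0 and self.formate_mM == 0:
            return "control"
        parts = []
        if self.acetate_mM:
            parts.append(f"{self.acetate_mM:g}mM_Ac")
        if self.formate_mM:
            parts.append(f"{self.formate_mM:g}mM_Fo")
        return "+".join(parts)

    @property
    def is_control(self) -> bool:
        return self.acetate_mM == 0 and self.formate_mM == 0


@dataclass
class SummaryStat:
    """Pooled mean +/- sample SD over all replicates of one metabolite."""

    mean: float
    sd: float
    n: int

    @property
    def sd_defined(self) -> bool:
        return self.n >= 2


@dataclass
class SecretionProfile:
    """Replicate concentrations (mM) for one treatment.

    Replicates are stored flat; the biological/technical split is metadata
    only (the study design pools 5 biological x 5 technical = 25 values per
    metabolite and no nested variance components are modelled).
    """

    treatment: Treatment
    concentrations: dict[str, np.ndarray]
    n_biological: int
    n_technical: int = 1

    def __post_init__(self) -> None:
        expected = self.n_biological * self.n_technical
        clean: dict[str, np.ndarray] = {}
        for name, values in self.concentrations.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1 or arr.size != expected:
                raise ValueError(
                    f"{name}: expected {expected} replicate values "
                    f"(n_biological x n_technical), got {arr.size}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{name}: negative concentration in replicates")
            clean[name] = arr
        self.concentrations = clean

    @property
    def metabolites(self) -> list[str]:
        return list(self.concentrations)

    @property
    def n_replicates(self) -> int:
        return self.n_biological * self.n_technical

    def mean(self, metabolite: str) -> float:
        return float(np.mean(self._values(metabolite)))

    def means(self) -> dict[str, float]:
        return {m: self.mean(m) for m in self.concentrations}

    def _values(self, metabolite: str) -> np.ndarray:
        try:
            return self.concentrations[metabolite]
        except KeyError:
            raise KeyError(
                f"metabolite {metabolite!r} not measured in "
                f"treatment {self.treatment.label!r}"
            ) from None


def summarize(profile: SecretionProfile, metabolite: str) -> SummaryStat:
    """Pooled mean and sample SD (n-1 denominator) for one metabolite."""
    values = profile._values(metabolite)
    n = values.size
    sd = float(np.std(values, ddof=1)) if n >= 2 else nan
    return SummaryStat(mean=float(np.mean(values)), sd=sd, n=n)


def _split_unit(column: str, registry: MetaboliteRegistry) -> tuple[str, float]:
    """Resolve a table column to (metabolite name, factor-to-mM)."""
    if column in registry:
        return column, 1.0
    if "_" in column:
        stem, unit = column.rsplit("_", 1)
        if stem in registry:
            try:
                return stem, _UNIT_FACTORS[unit]
            except KeyError:
                raise ValueError(
                    f"column {column!r}: unknown unit suffix {unit!r} "
                    f"(expected one of {sorted(_UNIT_FACTORS)})"
                ) from None
    raise ValueError(f"column {column!r} does not name a registered metabolite")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    # correctly rounded float parsing keeps write -> load round trips bit-exact
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_profiles(
    path: str | Path, registry: MetaboliteRegistry | None = None
) -> list[SecretionProfile]:
    """Read a replicate concentration table and group it by treatment.

    Exactly one (0, 0) control treatment must be present.  Unknown
    metabolite columns and unknown unit suffixes are rejected; negative
    concentrations raise an error naming the offending sample.  A metabolite
    left entirely blank within a treatment is treated as "not measured" for
    that treatment (never imputed as zero).
    """
    registry = registry or MetaboliteRegistry.default()
    df = _read_table(path)

    id_col = next((c for c in ("sample_id", "sample") if c in df.columns), None)
    if id_col is None:
        raise ValueError("table must have a 'sample_id' column")
    for col in ("acetate_mM", "formate_mM"):
        if col not in df.columns:
            raise ValueError(f"table must have a treatment column {col!r}")

    met_columns: dict[str, tuple[str, float]] = {}
    for col in df.columns:
        if col in RESERVED_COLUMNS:
            continue
        name, factor = _split_unit(col, registry)
        if name in (m for m, _ in met_columns.values()):
            raise ValueError(f"metabolite {name!r} appears in more than one column")
        met_columns[col] = (name, factor)

    for col, (name, factor) in met_columns.items():
        bad = df.index[df[col] < 0]
        if len(bad):
            sample = df.loc[bad[0], id_col]
            raise ValueError(
                f"negative concentration for {name!r} in sample {sample!r}"
            )

    profiles: list[SecretionProfile] = []
    for (ac, fo), group in df.groupby(["acetate_mM", "formate_mM"], sort=True):
        concentrations: dict[str, np.ndarray] = {}
        for col, (name, factor) in met_columns.items():
            values = group[col].to_numpy(dtype=float)
            if np.all(np.isnan(values)):
                continue  # not measured under this treatment
            if np.any(np.isnan(values)):
                raise ValueError(
                    f"metabolite {name!r} has partial missing values under "
                    f"treatment (acetate={ac}, formate={fo})"
                )
            concentrations[name] = values * factor
        profiles.append(
            SecretionProfile(
                treatment=Treatment(acetate_mM=float(ac), formate_mM=float(fo)),
                concentrations=concentrations,
                n_biological=len(group),
                n_technical=1,
            )
        )

    n_controls = sum(p.treatment.is_control for p in profiles)
    if n_controls != 1:
        raise ValueError(
            f"profile set must contain exactly one (0, 0) control treatment "
            f"(found {n_controls})"
        )
    return profiles


def write_profiles(profiles: Sequence[SecretionProfile], path: str | Path) -> None:
    """Write profiles back to a table (mM, bare column names).

    Values round-trip bit-exactly through :func:`load_profiles`.
    """
    rows: list[dict[str, object]] = []
    counter = 0
    for profile in profiles:
        for i in range(profile.n_replicates):
            counter += 1
            row: dict[str, object] = {
                "sample_id": f"S{counter:04d}",
                "acetate_mM": repr(profile.treatment.acetate_mM),
                "formate_mM": repr(profile.treatment.formate_mM),
            }
            for met, values in profile.concentrations.items():
                # shortest round-trip repr keeps values bit-exact on reload
                row[met] = repr(float(values[i]))
            rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df.to_csv(path, sep=sep, index=False)


def control_profile(profiles: Sequence[SecretionProfile]) -> SecretionProfile:
    """Return the unique (0, 0) control profile."""
    controls = [p for p in profiles if p.treatment.is_control]
    if len(controls) != 1:
        raise ValueError("profile set must contain exactly one control")
    return controls[0]
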