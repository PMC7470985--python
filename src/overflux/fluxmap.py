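"""Percent-mole-carbon secretion flux maps and annotated network export.

The secretion flux of metabolite x with endpoint concentration c_x (mM) and
C_x carbon atoms is

    F(x) = 100 * c_x * C_x / sum_i c_i * C_i

i.e. the share of total *secreted* carbon carried by x (``secreted_only``
basis).  A separate glucose carbon balance distributes input carbon over
secreted species, biomass, and an inferred CO2 remainder
(``glucose_balance`` basis); the CO2 term cannot come out of the
secreted-only normalization, which sums to 100 by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import networkx as nx

from .core import MetaboliteRegistry

__all__ = [
    "FluxBasis",
    "FluxMap",
    "NetworkMap",
    "carbon_flux",
    "infer_co2",
    "build_network_map",
    "export_network",
]

#: grams of carbon per mole of carbon atoms
CARBON_MOLAR_MASS = 12.011

#: default grams of carbon per gram of cell dry weight
DEFAULT_BIOMASS_CARBON_FRACTION = 0.5

#: default grams dry weight per OD600 unit per litre
OD_TO_GDW_PER_L = 0.54


class FluxBasis(str, Enum):
    secreted_only = "secreted_only"
    glucose_balance = "glucose_balance"


class ChangeDirection(str, Enum):
    increase = "increase"
    decrease = "decrease"
    no_change = "no_change"


#: edge colour convention for change-vs-control annotation
CHANGE_COLORS = {
    ChangeDirection.increase: "green",
    ChangeDirection.decrease: "red",
    ChangeDirection.no_change: "gray",
}


@dataclass
class FluxMap:
    """Percent mole-carbon fluxes per secreted metabolite."""

    fluxes: dict[str, float]
    basis: FluxBasis
    co2_percent: float = 0.0
    biomass_percent: float = 0.0
    co2_clamped: bool = False

    @property
    def total_percent(self) -> float:
        total = sum(self.fluxes.values())
        if self.basis is FluxBasis.glucose_balance:
            total += self.co2_percent + self.biomass_percent
        return total


def _carbon_mmol(
    profile_means: Mapping[str, float], registry: MetaboliteRegistry
) -> dict[str, float]:
    carbon: dict[str, float] = {}
    for name, conc in profile_means.items():
        if name not in registry:
            raise KeyError(f"metabolite {name!r} not registered (no carbon count)")
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        carbon[name] = conc * registry.carbon(name)
    return carbon


def carbon_flux(
    profile_means: Mapping[str, float], registry: MetaboliteRegistry | None = None
) -> FluxMap:
    """Normalize secreted carbon to percent mole-carbon shares (sums to 100)."""
    registry = registry or MetaboliteRegistry.default()
    carbon = _carbon_mmol(profile_means, registry)
    total = sum(carbon.values())
    if total <= 0:
        raise ValueError("all concentrations are zero; flux map undefined")
    return FluxMap(
        fluxes={m: 100.0 * c / total for m, c in carbon.items()},
        basis=FluxBasis.secreted_only,
    )


def infer_co2(
    glucose_consumed_mM: float,
    profile_means: Mapping[str, float],
    biomass_g_per_L: float = 0.0,
    carbon_fraction_biomass: float = DEFAULT_BIOMASS_CARBON_FRACTION,
    registry: MetaboliteRegistry | None = None,
) -> FluxMap:
    """Close the glucose carbon balance and infer the CO2 share.

    CO2 carbon (C-mmol/L) = 6 * glucose_consumed - secreted carbon - biomass
    carbon, with biomass carbon = 1000 * g/L * carbon fraction / 12.011.
    All terms are reported as percent of input carbon (6 * glucose).  A
    small negative remainder (measurement noise) is clamped to zero with
    ``co2_clamped`` set; a deficit beyond 10% of input carbon is a
    mass-balance violation and raises.
    """
    if glucose_consumed_mM <= 0:
        raise ValueError("glucose_consumed must be positive")
    if not 0 < carbon_fraction_biomass < 1:
        raise ValueError("carbon_fraction_biomass must be in (0, 1)")
    registry = registry or MetaboliteRegistry.default()
    carbon = _carbon_mmol(profile_means, registry)

    input_c = 6.0 * glucose_consumed_mM
    secreted_c = sum(carbon.values())
    biomass_c = 1000.0 * biomass_g_per_L * carbon_fraction_biomass / CARBON_MOLAR_MASS

    co2_c = input_c - secreted_c - biomass_c
    clamped = False
    if co2_c < -0.10 * input_c:
        raise ValueError(
            "mass-balance violation: secreted + biomass carbon exceeds "
            f"input carbon by {100 * (-co2_c) / input_c:.1f}% (> 10%)"
        )
    if co2_c < 0:
        co2_c = 0.0
        clamped = True

    return FluxMap(
        fluxes={m: 100.0 * c / input_c for m, c in carbon.items()},
        basis=FluxBasis.glucose_balance,
        co2_percent=100.0 * co2_c / input_c,
        biomass_percent=100.0 * biomass_c / input_c,
        co2_clamped=clamped,
    )


@dataclass
class NetworkMap:
    """Secretion network: intracellular precursor nodes feeding secreted species.

    ``edges`` maps each secreted metabolite to (precursor node, flux percent,
    change-vs-control direction).
    """

    nodes: list[dict]
    backbone: list[tuple[str, str]]
    edges: dict[str, tuple[str, float, ChangeDirection]]


def _load_topology() -> dict:
    text = resources.files("overflux.data").joinpath("network.json").read_text()
    return json.loads(text)


def build_network_map(
    flux_map: FluxMap | None = None,
    registry: MetaboliteRegistry | None = None,
    changes: Mapping[str, str | ChangeDirection] | None = None,
    topology_path: str | Path | None = None,
) -> NetworkMap:
    """Attach flux and change annotations to the packaged network topology."""
    registry = registry or MetaboliteRegistry.default()
    if topology_path is None:
        topo = _load_topology()
    else:
        with open(topology_path) as fh:
            topo = json.load(fh)
    node_ids = {n["id"] for n in topo["nodes"]}

    fluxes = flux_map.fluxes if flux_map is not None else {}
    changes = changes or {}
    edges: dict[str, tuple[str, float, ChangeDirection]] = {}
    for met in registry:
        if not met.secreted:
            continue
        if met.network_node not in node_ids:
            raise ValueError(
                f"{met.name}: precursor node {met.network_node!r} not in topology"
            )
        direction = ChangeDirection(changes.get(met.name, ChangeDirection.no_change))
        edges[met.name] = (met.network_node, float(fluxes.get(met.name, 0.0)), direction)
    return NetworkMap(
        nodes=topo["nodes"],
        backbone=[tuple(e) for e in topo.get("backbone", [])],
        edges=edges,
    )


def _shading(edges: Mapping[str, tuple[str, float, ChangeDirection]]) -> dict[str, float]:
    peak = max((flux for _, flux, _ in edges.values()), default=0.0)
    if peak <= 0:
        return {m: 0.0 for m in edges}
    return {m: flux / peak for m, (_, flux, _) in edges.items()}


def _to_graph(network: NetworkMap) -> nx.DiGraph:
    g = nx.DiGraph()
    shade = _shading(network.edges)
    for node in sorted(network.nodes, key=lambda n: n["id"]):
        g.add_node(node["id"], label=node.get("label", node["id"]), kind=node["kind"])
    for src, dst in sorted(network.backbone):
        if src != dst:
            g.add_edge(src, dst, kind="backbone", color="black")
    for met in sorted(network.edges):
        node, flux, direction = network.edges[met]
        g.add_node(met, label=met, kind="secreted")
        g.add_edge(
            node,
            met,
            kind="secretion",
            flux_percent=round(flux, 6),
            shading=round(shade[met], 6),
            color=CHANGE_COLORS[direction],
        )
    return g


def _to_dot(g: nx.DiGraph) -> str:
    lines = ["digraph secretion {"]
    for node in sorted(g.nodes):
        attrs = g.nodes[node]
        shape = "ellipse" if attrs.get("kind") == "intracellular" else "circle"
        lines.append(f'  "{node}" [label="{attrs.get("label", node)}", shape={shape}];')
    for src, dst in sorted(g.edges):
        attrs = g.edges[src, dst]
        parts = [f'color={attrs.get("color", "black")}']
        if "flux_percent" in attrs:
            parts.append(f'label="{attrs["flux_percent"]:g}"')
            parts.append(f'penwidth={1.0 + 3.0 * attrs.get("shading", 0.0):g}')
        lines.append(f'  "{src}" -> "{dst}" [{", ".join(parts)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_network(
    network: NetworkMap, format: str = "dot", path: str | Path | None = None
) -> str:
    """Serialize a network map to DOT or GraphML with stable ordering.

    Output is deterministic: two calls on the same input are byte-identical.
    Edge colours follow the change-vs-control convention (green = increased
    secretion, red = decreased, gray = no change).
    """
    g = _to_graph(network)
    if format == "dot":
        text = _to_dot(g)
    elif format == "graphml":
        text = "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"
    else:
        raise ValueError(f"unknown export format {format!r} (use 'dot' or 'graphml')")
    if path is not None:
        Path(path).write_text(text)
    return text
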