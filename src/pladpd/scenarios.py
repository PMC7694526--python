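"""Shipped simulation scenarios at the study's geometries and compositions.

Each scenario records the full-size geometry; a ``scale`` factor in (0, 1]
shrinks every linear dimension for desk-scale runs (droplet compositions
rescale with the droplet volume so the interior stays at liquid density).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .builder import (
    droplet_scale_for_density,
    droplet_setup,
    pam_droplet_composition,
    random_mixed_box,
    slab_setup,
    vitamin_e_droplet_composition,
)
from .topology import build_template, default_bead_registry
from .units import DEFAULT_UNITS

__all__ = ["Scenario", "SCENARIOS", "build_scenario", "scenario_from_yaml"]


@dataclass(frozen=True)
class Scenario:
    name: str
    kind: str  # box | droplet | slab
    matrix: str  # table1 | table2
    box: tuple[float, float, float]  # angstrom, full scale
    solute: str | None = None
    solute_pct: float = 0.0
    # solute beads per 100 water beads; the reading under which the
    # nominal concentrations stay water-continuous (docs/methods.md)
    pct_basis: str = "beads"
    droplet_radius: float = 0.0  # angstrom
    layer_thickness: float = 0.0  # angstrom
    composition_unit: dict = field(default_factory=dict)
    run_ns: float = 10.0


def _box_scn(name, solute, pct, ns=10.0):
    return Scenario(name, "box", "table1", (280.0, 280.0, 280.0),
                    solute=solute, solute_pct=pct, run_ns=ns)


SCENARIOS: dict[str, Scenario] = {
    **{
        f"pam{k}_box_{p}": _box_scn(f"pam{k}_box_{p}", f"Pam{k}CSK4", p)
        for k in (1, 3) for p in (3, 10, 30)
    },
    "pam1_droplet": Scenario(
        "pam1_droplet", "droplet", "table1", (280.0,) * 3,
        droplet_radius=130.0,
        composition_unit=pam_droplet_composition("Pam1CSK4"), run_ns=30.0,
    ),
    "pam3_droplet": Scenario(
        "pam3_droplet", "droplet", "table1", (280.0,) * 3,
        droplet_radius=130.0,
        composition_unit=pam_droplet_composition("Pam3CSK4"), run_ns=30.0,
    ),
    "vitE_droplet": Scenario(
        "vitE_droplet", "droplet", "table2", (280.0,) * 3,
        droplet_radius=130.0,
        composition_unit=vitamin_e_droplet_composition(), run_ns=30.0,
    ),
    **{
        f"pam3_slab_{p}": Scenario(
            f"pam3_slab_{p}", "slab", "table1", (500.0, 100.0, 100.0),
            solute="Pam3CSK4", solute_pct=p, layer_thickness=100.0,
            run_ns=300.0,
        )
        for p in (1, 5, 10)
    },
}


def build_scenario(scenario: Scenario | str, seed: int, scale: float = 1.0,
                   units=DEFAULT_UNITS, registry=None):
    """Build the initial Configuration for a scenario at a linear scale."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    registry = registry or default_bead_registry()
    box = tuple(L * scale for L in scenario.box)
    if scenario.kind == "box":
        solute = build_template(scenario.solute, registry)
        return random_mixed_box(box, solute, scenario.solute_pct, seed,
                                registry, units, pct_basis=scenario.pct_basis)
    if scenario.kind == "droplet":
        radius = scenario.droplet_radius * scale
        f = droplet_scale_for_density(radius, scenario.composition_unit,
                                      registry, units)
        composition = {k: v * f for k, v in scenario.composition_unit.items()}
        return droplet_setup(box, radius, composition, seed, registry, units)
    if scenario.kind == "slab":
        solute = build_template(scenario.solute, registry)
        return slab_setup(box, scenario.layer_thickness * scale, solute,
                          scenario.solute_pct, seed, registry, units,
                          pct_basis=scenario.pct_basis)
    raise ValueError(f"unknown scenario kind {scenario.kind!r}")


def scenario_from_yaml(text: str) -> Scenario:
    d = yaml.safe_load(text)
    d["box"] = tuple(d["box"])
    return Scenario(**d)
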