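"""Initial-configuration builders for the three experiment geometries.

All builders fill space at the reduced liquid density rho = 3 beads / r_c^3
and express the solute amount as a number ratio against water.  Two bases
are supported for the percentage (``pct_basis``): "molecules" counts solute
molecules against water beads (the literal composition statement), and
"beads" counts solute beads against water beads.  The shipped study
scenarios use the bead basis: with 12-70 beads per solute molecule the
molecule basis puts nominal 5-30% systems at 50-90% solute by volume, a
dense mesophase regime incompatible with the water-continuous micellar
behavior the model is meant to reproduce (docs/methods.md discusses this).
The geometries:

* :func:`random_mixed_box` - concentrated amphiphile solutions (3/10/30%);
* :func:`droplet_setup`    - nanoprecipitation: a solvent droplet holding
  water + PLA + solute at the stated composition, immersed in bulk water
  (default compositions 201:67:1 water:PLA:Pam and 750:125:117
  water:PLA:vitamin E per integer scale factor);
* :func:`slab_setup`       - saturation: a PLA layer at one end of an
  elongated box, solute dispersed in the water phase.

Chains are grown as random walks with bond length r_c/2; the soft DPD cores
tolerate the resulting overlaps, which a short small-timestep warm-up
relaxes.  Velocities are drawn from the Maxwell-Boltzmann distribution at
kT = 1 and the net momentum is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import BeadSpec, MoleculeTemplate, default_bead_registry, molecule_mass
from .units import DEFAULT_UNITS, SimulationUnits

__all__ = [
    "Configuration",
    "random_mixed_box",
    "droplet_setup",
    "slab_setup",
    "mass_ratio",
    "pam_droplet_composition",
    "vitamin_e_droplet_composition",
    "droplet_scale_for_density",
]

BOND_LENGTH = 0.5  # reduced; initial random-walk bond length


@dataclass
class Configuration:
    """Complete simulator state in reduced units, periodic in all axes."""

    box: np.ndarray  # (3,) edge lengths
    positions: np.ndarray  # (N, 3), wrapped into [0, box)
    velocities: np.ndarray  # (N, 3)
    species: np.ndarray  # (N,) bead-species names
    masses: np.ndarray  # (N,) reduced masses
    molecule_id: np.ndarray  # (N,) int
    molecule_templates: np.ndarray  # (n_molecules,) template name per molecule
    bonds: np.ndarray  # (M, 2) global bead indices
    rng_seed: int = 0
    units: SimulationUnits = field(default_factory=SimulationUnits)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_templates)

    def copy(self) -> "Configuration":
        return Configuration(
            self.box.copy(), self.positions.copy(), self.velocities.copy(),
            self.species.copy(), self.masses.copy(), self.molecule_id.copy(),
            self.molecule_templates.copy(), self.bonds.copy(),
            self.rng_seed, self.units,
        )

    def molecules_of(self, template_name: str) -> np.ndarray:
        """Molecule ids whose template matches `template_name`."""
        return np.flatnonzero(self.molecule_templates == template_name)

    def total_momentum(self) -> np.ndarray:
        return (self.masses[:, None] * self.velocities).sum(axis=0)

    def kinetic_temperature(self) -> float:
        dof = 3 * self.n_beads - 3
        return float((self.masses[:, None] * self.velocities**2).sum() / dof)

    def validate(self) -> None:
        if np.any(self.positions < 0) or np.any(self.positions >= self.box):
            raise ValueError("positions not wrapped into [0, box)")
        if self.bonds.size and np.any(
            self.molecule_id[self.bonds[:, 0]] != self.molecule_id[self.bonds[:, 1]]
        ):
            raise ValueError("bond connects beads of different molecules")


class _Assembler:
    """Accumulates molecules, then emits a Configuration."""

    def __init__(self, box_reduced: np.ndarray, registry: list[BeadSpec],
                 units: SimulationUnits, seed: int):
        self.box = np.asarray(box_reduced, float)
        self.units = units
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.mass_of = {b.name: b.mass / units.mass_unit for b in registry}
        self.pos: list[np.ndarray] = []
        self.spec: list[str] = []
        self.mol: list[int] = []
        self.bonds: list[tuple[int, int]] = []
        self.mol_templates: list[str] = []

    def add_molecule(self, template: MoleculeTemplate, first_bead: np.ndarray,
                     inside=None) -> None:
        """Grow one molecule as a random walk from `first_bead`.

        `inside(point) -> bool` optionally constrains every bead to a region;
        walk steps leaving the region are re-drawn (up to a retry cap, after
        which the step is accepted to guarantee termination).
        """
        mol_id = len(self.mol_templates)
        offset = len(self.pos)
        coords = [np.asarray(first_bead, float)]
        order = _bond_growth_order(template)
        placed = {0: coords[0]}
        for child, parent in order:
            for _ in range(40):
                step = self.rng.normal(size=3)
                step *= BOND_LENGTH / np.linalg.norm(step)
                cand = placed[parent] + step
                if inside is None or inside(cand):
                    break
            placed[child] = cand
        for k in range(template.n_beads):
            self.pos.append(placed[k])
            self.spec.append(template.beads[k])
            self.mol.append(mol_id)
        for i, j in template.bonds:
            self.bonds.append((offset + i, offset + j))
        self.mol_templates.append(template.name)

    def finish(self) -> Configuration:
        pos = np.array(self.pos, float).reshape(-1, 3) % self.box
        n = len(pos)
        species = np.array(self.spec, dtype="U4")
        masses = np.array([self.mass_of[s] for s in self.spec], float)
        vel = self.rng.normal(size=(n, 3)) * np.sqrt(
            self.units.kT / masses[:, None]
        )
        vel -= (masses[:, None] * vel).sum(axis=0) / masses.sum()
        bonds = (
            np.array(self.bonds, dtype=np.int64).reshape(-1, 2)
            if self.bonds else np.empty((0, 2), np.int64)
        )
        return Configuration(
            box=self.box, positions=pos, velocities=vel, species=species,
            masses=masses, molecule_id=np.array(self.mol, np.int64),
            molecule_templates=np.array(self.mol_templates, dtype="U16"),
            bonds=bonds, rng_seed=self.seed, units=self.units,
        )


def _bond_growth_order(template: MoleculeTemplate) -> list[tuple[int, int]]:
    """(child, parent) pairs in BFS order from bead 0."""
    adj: dict[int, list[int]] = {k: [] for k in range(template.n_beads)}
    for i, j in template.bonds:
        adj[i].append(j)
        adj[j].append(i)
    order, seen, queue = [], {0}, [0]
    while queue:
        parent = queue.pop(0)
        for child in adj[parent]:
            if child not in seen:
                seen.add(child)
                order.append((child, parent))
                queue.append(child)
    return order


def _solute_water_counts(n_beads_target: int, solute_nbeads: int,
                         solute_pct: float, basis: str) -> tuple[int, int]:
    """Molecule counts (n_solute, n_water) hitting the bead budget.

    basis="molecules": solute:water molecule ratio = solute_pct:100 (the
    literal composition statement).  basis="beads": solute:water bead
    ratio = solute_pct:100 — the reading under which the nominally
    concentrated systems remain water-continuous (see docs/methods.md).
    """
    frac = solute_pct / 100.0
    if basis == "molecules":
        n_water = n_beads_target / (1.0 + frac * solute_nbeads)
        n_solute = int(round(frac * n_water))
    elif basis == "beads":
        n_water = n_beads_target / (1.0 + frac)
        n_solute = int(round(frac * n_water / solute_nbeads))
    else:
        raise ValueError("basis must be 'molecules' or 'beads'")
    n_water = max(0, int(round(n_beads_target - n_solute * solute_nbeads)))
    return n_solute, n_water


def random_mixed_box(
    box_angstrom: tuple[float, float, float],
    solute: MoleculeTemplate | None,
    solute_pct: float,
    seed: int,
    registry: list[BeadSpec] | None = None,
    units: SimulationUnits = DEFAULT_UNITS,
    pct_basis: str = "molecules",
) -> Configuration:
    """Water box with randomly dispersed solute at a number ratio vs water.

    `pct_basis` selects whether `solute_pct` counts solute molecules or
    solute beads against water beads.
    """
    if not 0 <= solute_pct <= 100:
        raise ValueError("solute_pct must be in [0, 100]")
    registry = registry or default_bead_registry()
    box = np.array([units.to_reduced(L) for L in box_angstrom])
    n_target = int(round(units.rho * box.prod()))
    from .topology import build_template

    water = build_template("water", registry)
    asm = _Assembler(box, registry, units, seed)
    if solute is None or solute_pct == 0:
        n_solute, n_water = 0, n_target
    else:
        n_solute, n_water = _solute_water_counts(
            n_target, solute.n_beads, solute_pct, pct_basis
        )
        if n_solute < 1:
            raise ValueError("box too small for one solute molecule")
    for _ in range(n_solute):
        asm.add_molecule(solute, asm.rng.uniform(0, box))
    for _ in range(n_water):
        asm.add_molecule(water, asm.rng.uniform(0, box))
    return asm.finish()


def pam_droplet_composition(template_name: str = "Pam3CSK4", scale: int = 1):
    """water:PLA:Pam = 201:67:1 per unit scale."""
    return {"water": 201 * scale, "PLA_70": 67 * scale, template_name: scale}


def vitamin_e_droplet_composition(scale: int = 1):
    """water:PLA:vitaminE = 750:125:117 per unit scale."""
    return {"water": 750 * scale, "PLA_70": 125 * scale, "vitaminE": 117 * scale}


def droplet_scale_for_density(
    droplet_radius_angstrom: float,
    composition_unit: dict[str, int],
    registry: list[BeadSpec] | None = None,
    units: SimulationUnits = DEFAULT_UNITS,
) -> int:
    """Integer scale factor filling the droplet at rho = 3."""
    from .topology import build_template

    registry = registry or default_bead_registry()
    r = units.to_reduced(droplet_radius_angstrom)
    beads_per_unit = sum(
        count * build_template(name, registry).n_beads
        for name, count in composition_unit.items()
    )
    return max(1, round(units.rho * 4.0 / 3.0 * np.pi * r**3 / beads_per_unit))


def droplet_setup(
    box_angstrom: tuple[float, float, float],
    droplet_radius_angstrom: float,
    composition: dict[str, int],
    seed: int,
    registry: list[BeadSpec] | None = None,
    units: SimulationUnits = DEFAULT_UNITS,
) -> Configuration:
    """Central droplet holding `composition`, bulk water elsewhere at rho=3."""
    registry = registry or default_bead_registry()
    from .topology import build_template

    box = np.array([units.to_reduced(L) for L in box_angstrom])
    r_drop = units.to_reduced(droplet_radius_angstrom)
    if np.any(2 * r_drop > box):
        raise ValueError("droplet does not fit in box")
    center = box / 2.0
    v_drop = 4.0 / 3.0 * np.pi * r_drop**3

    templates = {name: build_template(name, registry) for name in composition}
    n_drop_beads = sum(
        count * templates[name].n_beads for name, count in composition.items()
    )
    if n_drop_beads > 1.5 * units.rho * v_drop:
        raise ValueError("droplet overfull: interior density exceeds 1.5 rho")

    def in_sphere(p: np.ndarray) -> bool:
        return float(((p - center) ** 2).sum()) < r_drop**2

    asm = _Assembler(box, registry, units, seed)
    rng = asm.rng
    for name, count in composition.items():
        tpl = templates[name]
        for _ in range(count):
            while True:  # uniform point in the sphere
                p = rng.uniform(-r_drop, r_drop, size=3)
                if (p**2).sum() < r_drop**2:
                    break
            asm.add_molecule(tpl, center + p, inside=in_sphere)

    water = build_template("water", registry)
    # top up with exterior water so the whole box sits at rho
    n_outside = int(round(units.rho * box.prod())) - n_drop_beads
    placed = 0
    while placed < n_outside:
        p = rng.uniform(0, box)
        if not in_sphere(p):
            asm.add_molecule(water, p)
            placed += 1
    return asm.finish()


def slab_setup(
    box_angstrom: tuple[float, float, float],
    layer_thickness_angstrom: float,
    solute: MoleculeTemplate | None,
    solute_pct: float,
    seed: int,
    registry: list[BeadSpec] | None = None,
    units: SimulationUnits = DEFAULT_UNITS,
    pct_basis: str = "molecules",
) -> Configuration:
    """PLA layer in [0, thickness) along x, solute + water in the rest."""
    registry = registry or default_bead_registry()
    from .topology import build_template

    box = np.array([units.to_reduced(L) for L in box_angstrom])
    t = units.to_reduced(layer_thickness_angstrom)
    if t >= box[0]:
        raise ValueError("layer thickness must be smaller than the box length")

    pla = build_template("PLA_70", registry)
    water = build_template("water", registry)
    n_slab_beads = units.rho * t * box[1] * box[2]
    n_chains = max(1, int(round(n_slab_beads / pla.n_beads)))

    def in_slab(p: np.ndarray) -> bool:
        return 0.0 <= p[0] < t

    def in_solution(p: np.ndarray) -> bool:
        return t <= p[0] < box[0]

    asm = _Assembler(box, registry, units, seed)
    rng = asm.rng
    for _ in range(n_chains):
        start = np.array([rng.uniform(0, t), rng.uniform(0, box[1]),
                          rng.uniform(0, box[2])])
        asm.add_molecule(pla, start, inside=in_slab)

    n_solution_beads = int(round(units.rho * (box[0] - t) * box[1] * box[2]))
    if solute is None or solute_pct == 0:
        n_solute, n_water = 0, n_solution_beads
    else:
        n_solute, n_water = _solute_water_counts(
            n_solution_beads, solute.n_beads, solute_pct, pct_basis
        )
    for _ in range(n_solute):
        start = np.array([rng.uniform(t, box[0]), rng.uniform(0, box[1]),
                          rng.uniform(0, box[2])])
        asm.add_molecule(solute, start, inside=in_solution)
    for _ in range(n_water):
        p = np.array([rng.uniform(t, box[0]), rng.uniform(0, box[1]),
                      rng.uniform(0, box[2])])
        asm.add_molecule(water, p)
    return asm.finish()


def mass_ratio(
    composition: dict[str, int],
    numerator: str,
    denominator: str,
    registry: list[BeadSpec] | None = None,
) -> float:
    """w/w percentage of `numerator` relative to `denominator`."""
    from .topology import build_template

    registry = registry or default_bead_registry()
    if denominator not in composition or composition[denominator] == 0:
        raise ValueError("denominator molecule absent or zero count")
    if numerator not in composition:
        raise ValueError("numerator molecule absent from composition")
    m_num = composition[numerator] * molecule_mass(
        build_template(numerator, registry), registry
    )
    m_den = composition[denominator] * molecule_mass(
        build_template(denominator, registry), registry
    )
    return 100.0 * m_num / m_den
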