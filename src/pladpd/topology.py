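"""Coarse-grained bead species and molecule templates.

Nine bead species cover the chemistry of the model: water (W, three H2O per
bead), lactic acid monomer (LA) for the PLA chain, the lipopeptide beads
(F fatty-acid unit, C modified cysteine, S serine, K lysine, G modified
glycerol) and the vitamin E beads (CHR chromanol bicycle, C5 five-carbon
tail unit).  Molecules are bead-and-spring trees built from these species:

* ``water``     - a single W bead;
* ``PLA_70``    - a linear chain of 70 LA beads;
* ``Pam1CSK4``  - CSKKKK backbone, one G bead on C, one 5xF palmitoyl tail
  on G (12 beads);
* ``Pam3CSK4``  - CSKKKK backbone with three 5xF tails; by default one G
  bead carries two tails (ester positions) and the third sits on C (amide),
  22 beads.  A flag drops the G bead (21 beads, all tails on C) for the
  alternative reading of the bead scheme;
* ``vitaminE``  - CHR-C5-C5-C5 linear (4 beads).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "BeadSpec",
    "MoleculeTemplate",
    "default_bead_registry",
    "build_template",
    "molecule_mass",
    "registry_to_yaml",
    "registry_from_yaml",
    "template_to_yaml",
    "template_from_yaml",
    "TEMPLATE_NAMES",
]


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead species."""

    name: str
    mass: float  # daltons
    radius: float  # angstrom; metadata only, the force field has one cutoff
    fragment_note: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.radius <= 0:
            raise ValueError(f"bead {self.name!r}: mass and radius must be > 0")


@dataclass
class MoleculeTemplate:
    """Bead-and-bond blueprint for one molecule.

    ``hydrophilic_beads`` / ``hydrophobic_beads`` are index subsets used by
    the analysis layer (surface-vs-core localization, cluster contacts).
    """

    name: str
    beads: list[str]
    bonds: list[tuple[int, int]]
    kind_tags: frozenset[str] = frozenset()
    hydrophilic_beads: list[int] = field(default_factory=list)
    hydrophobic_beads: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.beads)
        seen: set[tuple[int, int]] = set()
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"{self.name}: bond ({i},{j}) out of range")
            if i == j:
                raise ValueError(f"{self.name}: self-bond at {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"{self.name}: duplicate bond {key}")
            seen.add(key)
        if n > 1 and not self._connected():
            raise ValueError(f"{self.name}: bond graph is not connected")

    def _connected(self) -> bool:
        n = len(self.beads)
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, j in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        seen = {0}
        stack = [0]
        while stack:
            for k in adj[stack.pop()]:
                if k not in seen:
                    seen.add(k)
                    stack.append(k)
        return len(seen) == n

    @property
    def n_beads(self) -> int:
        return len(self.beads)


# Masses in daltons. W, F and CHR are fixed by the model definition; the
# rest are the fragment masses of the mapped chemical groups and may be
# overridden when constructing a custom registry.
_DEFAULT_BEADS = [
    ("W", 54.0, 3.23, "3 water molecules"),
    ("LA", 72.06, 3.23, "lactic acid monomer of the PLA chain"),
    ("F", 42.0, 3.23, "C3H6 fatty-acid unit of the palmitoyl tail"),
    ("C", 160.0, 3.23, "modified cysteine (residue + thioether linker)"),
    ("S", 87.1, 3.23, "serine residue"),
    ("K", 128.2, 3.23, "lysine residue"),
    ("G", 74.1, 3.23, "modified glycerol unit"),
    ("CHR", 219.0, 3.23, "chromanol double cycle of vitamin E"),
    ("C5", 70.1, 3.23, "five-carbon unit of the vitamin E tail"),
]

TEMPLATE_NAMES = ("water", "PLA_70", "Pam1CSK4", "Pam3CSK4", "vitaminE")


def default_bead_registry(**mass_overrides: float) -> list[BeadSpec]:
    """The nine bead species of the model, optionally with mass overrides."""
    registry = []
    for name, mass, radius, note in _DEFAULT_BEADS:
        registry.append(
            BeadSpec(name, float(mass_overrides.get(name, mass)), radius, note)
        )
    return registry


def _registry_map(registry: list[BeadSpec]) -> dict[str, BeadSpec]:
    out = {b.name: b for b in registry}
    if len(out) != len(registry):
        raise ValueError("duplicate bead names in registry")
    return out


def _require(registry: list[BeadSpec], names: set[str]) -> None:
    have = {b.name for b in registry}
    missing = names - have
    if missing:
        raise KeyError(f"missing bead species: {sorted(missing)}")


def _chain(species: str, n: int, offset: int = 0):
    beads = [species] * n
    bonds = [(offset + k, offset + k + 1) for k in range(n - 1)]
    return beads, bonds


def build_template(
    name: str,
    registry: list[BeadSpec] | None = None,
    *,
    pam3_glycerol: bool = True,
) -> MoleculeTemplate:
    """Construct one of the model's molecule templates.

    ``pam3_glycerol=False`` selects the 21-bead Pam3CSK4 variant without a
    glycerol bead (all three tails bonded to the cysteine bead).
    """
    registry = registry if registry is not None else default_bead_registry()

    if name == "water":
        _require(registry, {"W"})
        return MoleculeTemplate("water", ["W"], [], frozenset({"solvent"}))

    if name == "PLA_70":
        _require(registry, {"LA"})
        beads, bonds = _chain("LA", 70)
        return MoleculeTemplate(
            "PLA_70", beads, bonds, frozenset({"polymer"}),
            hydrophobic_beads=list(range(70)),
        )

    if name == "vitaminE":
        _require(registry, {"CHR", "C5"})
        beads = ["CHR", "C5", "C5", "C5"]
        bonds = [(0, 1), (1, 2), (2, 3)]
        return MoleculeTemplate(
            "vitaminE", beads, bonds, frozenset({"hydrophobe"}),
            hydrophobic_beads=[0, 1, 2, 3],
        )

    if name == "Pam1CSK4":
        _require(registry, {"C", "S", "K", "G", "F"})
        beads = ["C", "S", "K", "K", "K", "K", "G"]
        bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 6)]
        tail, tail_bonds = _chain("F", 5, offset=7)
        beads += tail
        bonds += [(6, 7)] + tail_bonds
        return MoleculeTemplate(
            "Pam1CSK4", beads, bonds, frozenset({"amphiphile"}),
            hydrophilic_beads=[i for i, b in enumerate(beads) if b in ("S", "K")],
            hydrophobic_beads=[i for i, b in enumerate(beads) if b == "F"],
        )

    if name == "Pam3CSK4":
        if pam3_glycerol:
            _require(registry, {"C", "S", "K", "G", "F"})
            beads = ["C", "S", "K", "K", "K", "K", "G"]
            bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 6)]
            # two tails on the glycerol bead, one directly on cysteine
            for anchor in (6, 6, 0):
                off = len(beads)
                tail, tail_bonds = _chain("F", 5, offset=off)
                beads += tail
                bonds += [(anchor, off)] + tail_bonds
        else:
            _require(registry, {"C", "S", "K", "F"})
            beads = ["C", "S", "K", "K", "K", "K"]
            bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
            for _ in range(3):
                off = len(beads)
                tail, tail_bonds = _chain("F", 5, offset=off)
                beads += tail
                bonds += [(0, off)] + tail_bonds
        return MoleculeTemplate(
            "Pam3CSK4", beads, bonds, frozenset({"amphiphile"}),
            hydrophilic_beads=[i for i, b in enumerate(beads) if b in ("S", "K")],
            hydrophobic_beads=[i for i, b in enumerate(beads) if b == "F"],
        )

    raise KeyError(f"unknown template {name!r}")


def molecule_mass(
    template: MoleculeTemplate, registry: list[BeadSpec] | None = None
) -> float:
    """Total mass of a molecule in daltons (empty template -> 0)."""
    registry = registry if registry is not None else default_bead_registry()
    bead_map = _registry_map(registry)
    try:
        return float(sum(bead_map[b].mass for b in template.beads))
    except KeyError as exc:
        raise KeyError(f"missing bead species: {exc.args[0]!r}") from None


# -- plain-text (YAML) serialization ----------------------------------------

def registry_to_yaml(registry: list[BeadSpec]) -> str:
    return yaml.safe_dump(
        [
            {"name": b.name, "mass": b.mass, "radius": b.radius,
             "fragment_note": b.fragment_note}
            for b in registry
        ],
        sort_keys=False,
    )


def registry_from_yaml(text: str) -> list[BeadSpec]:
    return [BeadSpec(**d) for d in yaml.safe_load(text)]


def template_to_yaml(template: MoleculeTemplate) -> str:
    return yaml.safe_dump(
        {
            "name": template.name,
            "beads": list(template.beads),
            "bonds": [list(b) for b in template.bonds],
            "kind_tags": sorted(template.kind_tags),
            "hydrophilic_beads": list(template.hydrophilic_beads),
            "hydrophobic_beads": list(template.hydrophobic_beads),
        },
        sort_keys=False,
    )


def template_from_yaml(text: str) -> MoleculeTemplate:
    d = yaml.safe_load(text)
    return MoleculeTemplate(
        name=d["name"],
        beads=list(d["beads"]),
        bonds=[tuple(b) for b in d["bonds"]],
        kind_tags=frozenset(d.get("kind_tags", ())),
        hydrophilic_beads=list(d.get("hydrophilic_beads", ())),
        hydrophobic_beads=list(d.get("hydrophobic_beads", ())),
    )
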