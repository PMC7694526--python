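"""Flory-Huggins / DPD repulsion parameterization.

The conservative DPD force amplitude between species i and j follows from
their thermodynamic incompatibility: Hildebrand solubility parameters give
the Flory-Huggins parameter

    chi_ij = (v / R T) (delta_i - delta_j)^2

with v the mean molar volume of the pair (cm^3/mol), delta in (J/cm^3)^1/2
and R = 8.314 J/(mol K), and the repulsion amplitude is the affine map

    a_ij = 25 + 3.50 chi_ij .

Like-pair amplitudes are not taken from this map: the shipped interaction
tables use the Groot-Rabone value 78 on the diagonal, appropriate for a
three-water coarse-graining, and the tables are authoritative for all
simulations.  The formula pathway exists for parameterizing new molecules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "R_GAS",
    "SolubilityTable",
    "InteractionMatrix",
    "flory_huggins_chi",
    "chi_to_repulsion",
    "repulsion_to_chi",
    "load_interaction_matrix",
    "build_matrix_from_solubilities",
]

R_GAS = 8.314  # J / (mol K)

#: like-pair repulsion for the 3-water mapping (shipped-table diagonal)
DEFAULT_DIAGONAL = 78.0

_SHIPPED = {"table1": "table1_pam.txt", "table2": "table2_vite.txt"}


def flory_huggins_chi(delta_i: float, delta_j: float, v: float, T: float) -> float:
    """Flory-Huggins chi from Hildebrand solubility parameters.

    delta in (J/cm^3)^1/2, v in cm^3/mol, T in kelvin; dimensionless result,
    symmetric and non-negative.
    """
    if v <= 0 or T <= 0:
        raise ValueError("molar volume and temperature must be positive")
    return (v / (R_GAS * T)) * (delta_i - delta_j) ** 2


def chi_to_repulsion(chi: float) -> float:
    """Map chi to the DPD repulsion amplitude a = 25 + 3.50 chi."""
    if chi < 0:
        warnings.warn("negative chi passed to chi_to_repulsion", stacklevel=2)
    return 25.0 + 3.50 * chi


def repulsion_to_chi(a: float) -> float:
    """Inverse of :func:`chi_to_repulsion`."""
    return (a - 25.0) / 3.50


@dataclass(frozen=True)
class SolubilityTable:
    """Per-species Hildebrand solubility parameters and molar volumes."""

    delta: dict[str, float]  # (J/cm^3)^1/2
    molar_volume: dict[str, float]  # cm^3/mol
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if any(d < 0 for d in self.delta.values()):
            raise ValueError("solubility parameters must be >= 0")
        if any(v <= 0 for v in self.molar_volume.values()):
            raise ValueError("molar volumes must be positive")


@dataclass
class InteractionMatrix:
    """Symmetric bead-pair repulsion amplitudes a_ij in reduced units."""

    species: tuple[str, ...]
    a: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        n = len(self.species)
        if self.a.shape != (n, n):
            raise ValueError("matrix shape does not match species list")
        if not np.allclose(self.a, self.a.T, rtol=0, atol=1e-9):
            raise ValueError("asymmetric table")
        if np.any(self.a <= 0):
            raise ValueError("repulsion parameters must be positive")
        self._index = {s: k for k, s in enumerate(self.species)}

    def get(self, i: str, j: str) -> float:
        try:
            return float(self.a[self._index[i], self._index[j]])
        except KeyError as exc:
            raise KeyError(f"species not covered: {exc.args[0]!r}") from None

    def submatrix(self, species: list[str]) -> np.ndarray:
        """Dense a-matrix over `species` in the given order (for the engine)."""
        missing = [s for s in species if s not in self._index]
        if missing:
            raise KeyError(f"species not covered: {missing}")
        idx = np.array([self._index[s] for s in species])
        return self.a[np.ix_(idx, idx)].copy()

    def to_text(self) -> str:
        lines = ["species " + " ".join(self.species)]
        for k, s in enumerate(self.species):
            row = " ".join(f"{self.a[k, m]:g}" for m in range(k + 1))
            lines.append(f"{s} {row}")
        return "\n".join(lines) + "\n"


def _parse_matrix_text(text: str) -> InteractionMatrix:
    rows: list[tuple[str, list[float]]] = []
    species: list[str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "species":
            species = parts[1:]
        else:
            try:
                rows.append((parts[0], [float(x) for x in parts[1:]]))
            except ValueError:
                raise ValueError(f"malformed matrix row at line {lineno}") from None
    if species is None:
        raise ValueError("matrix document lacks a 'species' header")
    if [r[0] for r in rows] != list(species):
        raise ValueError("row order does not match species header")
    n = len(species)
    a = np.zeros((n, n))
    full = all(len(vals) == n for _, vals in rows)
    for k, (_, vals) in enumerate(rows):
        if full:
            a[k, :] = vals
        elif len(vals) == k + 1:  # lower triangular
            a[k, : k + 1] = vals
            a[: k + 1, k] = vals
        elif len(vals) == n - k:  # upper triangular
            a[k, k:] = vals
            a[k:, k] = vals
        else:
            raise ValueError(f"row {species[k]!r} has {len(vals)} entries")
    if full and not np.allclose(a, a.T, rtol=0, atol=1e-9):
        raise ValueError("asymmetric table")
    return InteractionMatrix(tuple(species), a)


def load_interaction_matrix(source: str | Path) -> InteractionMatrix:
    """Load an interaction matrix document.

    `source` is ``"table1"`` (water/PLA/Pam systems), ``"table2"``
    (water/PLA/vitamin E systems), a path to a document, or document text.
    """
    if isinstance(source, str) and source in _SHIPPED:
        text = (
            resources.files("pladpd").joinpath("data", _SHIPPED[source]).read_text()
        )
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    return _parse_matrix_text(text)


def build_matrix_from_solubilities(
    table: SolubilityTable,
    species: list[str] | None = None,
    diagonal: float = DEFAULT_DIAGONAL,
) -> InteractionMatrix:
    """Build a repulsion matrix from solubility parameters.

    Off-diagonals apply the chi -> a map with the pair's mean molar volume;
    the diagonal is the configured like-pair convention (default 78).
    """
    names = list(species) if species is not None else sorted(table.delta)
    missing = [s for s in names if s not in table.delta or s not in table.molar_volume]
    if missing:
        raise KeyError(f"species missing from solubility table: {missing}")
    n = len(names)
    a = np.full((n, n), float(diagonal))
    for i in range(n):
        for j in range(i + 1, n):
            v = 0.5 * (table.molar_volume[names[i]] + table.molar_volume[names[j]])
            chi = flory_huggins_chi(
                table.delta[names[i]], table.delta[names[j]], v, table.temperature
            )
            a[i, j] = a[j, i] = chi_to_repulsion(chi)
    return InteractionMatrix(tuple(names), a)
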