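"""DPD integrator: soft conservative repulsion, pairwise thermostat, springs.

The equations of motion are integrated with the modified velocity-Verlet
scheme: half-kick, drift with periodic wrapping, force evaluation at a
predicted velocity v + lambda dt f, corrector half-kick.  Between beads i
and j within the cutoff r_c = 1 act

* a conservative force  a_ij (1 - r) e_ij,
* a dissipative force  -gamma (1 - r)^2 (e_ij . v_ij) e_ij,
* a random force  sigma (1 - r) theta_ij dt^(-1/2) e_ij,

with sigma^2 = 2 gamma kT (fluctuation-dissipation) and theta_ij a
unit-variance symmetric draw shared by the pair, so the dissipative/random
pair is a momentum-conserving thermostat.  Bonded beads feel a harmonic
spring k (r - r0).  Default constants are the standard DPD choices
gamma = 4.5, kT = 1, dt = 0.04, lambda = 0.65, k = 4, r0 = 0 (lambda =
0.65 is the Groot-Warren predictor giving accurate temperature control at
gamma = 4.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .builder import Configuration

__all__ = [
    "SimulationParams",
    "Trajectory",
    "conservative_force",
    "thermostat_forces",
    "bond_force",
    "step",
    "run",
    "all_pairs_forces",
]


@dataclass(frozen=True)
class SimulationParams:
    """Integrator and force-field constants (reduced units)."""

    dt: float = 0.04
    gamma: float = 4.5
    kT: float = 1.0
    sigma: float | None = None  # derived from gamma, kT unless given
    lambda_vv: float = 0.65
    k_bond: float = 4.0
    r0_bond: float = 0.0
    n_steps: int = 0
    seed: int = 0
    neighbor_skin: float = 0.0  # cell lists are rebuilt every step

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        target = math.sqrt(2.0 * self.gamma * self.kT)
        if self.sigma is None:
            object.__setattr__(self, "sigma", target)
        elif not math.isclose(self.sigma**2, 2.0 * self.gamma * self.kT,
                              rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError(
                "fluctuation-dissipation violated: sigma^2 must equal 2 gamma kT"
            )


@dataclass
class Trajectory:
    """Snapshots at a fixed stride plus per-snapshot scalar diagnostics."""

    snapshots: list[Configuration]
    scalars: "object" = None  # pandas.DataFrame: step, time_ps, kT, |p|

    def __len__(self) -> int:
        return len(self.snapshots)

    @property
    def final(self) -> Configuration:
        return self.snapshots[-1]

    def tail(self, fraction: float = 0.2) -> list[Configuration]:
        """Final-`fraction` snapshots (at least one) for headline averages."""
        k = max(1, int(round(fraction * len(self.snapshots))))
        return self.snapshots[-k:]


# -- single-pair force laws (reference forms, used by tests and docs) -------

def conservative_force(r_vec: np.ndarray, a: float, r_c: float = 1.0) -> np.ndarray:
    """Soft linear repulsion a (1 - r/r_c) e for r < r_c, else zero."""
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    r_vec = np.asarray(r_vec, float)
    r = float(np.linalg.norm(r_vec))
    if r >= r_c or r == 0.0:
        return np.zeros(3)
    return a * (1.0 - r / r_c) * r_vec / r


def thermostat_forces(
    r_vec: np.ndarray,
    v_rel: np.ndarray,
    params: SimulationParams,
    pair_noise: float,
    r_c: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dissipative and random force on bead i for one pair (j fixed)."""
    r_vec = np.asarray(r_vec, float)
    r = float(np.linalg.norm(r_vec))
    if r >= r_c or r == 0.0:
        return np.zeros(3), np.zeros(3)
    e = r_vec / r
    w = 1.0 - r / r_c
    f_d = -params.gamma * w * w * float(np.dot(e, v_rel)) * e
    f_r = params.sigma * w * pair_noise / math.sqrt(params.dt) * e
    return f_d, f_r


def bond_force(r_vec: np.ndarray, k_bond: float, r0_bond: float) -> np.ndarray:
    """Harmonic spring force on bead i: -k (r - r0) e."""
    r_vec = np.asarray(r_vec, float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        return np.zeros(3)
    return -k_bond * (r - r0_bond) * r_vec / r


# -- integration ------------------------------------------------------------

def _engine_arrays(config: Configuration, matrix) -> tuple[np.ndarray, np.ndarray]:
    names = sorted(set(config.species.tolist()))
    amat = matrix.submatrix(names)
    lookup = {s: k for k, s in enumerate(names)}
    types = np.array([lookup[s] for s in config.species.tolist()], np.int64)
    return types, amat


def _forces_at(config, types, amat, params, step_index, velocities=None):
    vel = config.velocities if velocities is None else velocities
    forces = np.zeros((config.n_beads, 3))
    _kernels.compute_nonbonded_forces(
        config.positions, vel, types, amat, config.box,
        params.gamma, params.sigma, 1.0 / math.sqrt(params.dt),
        params.seed, step_index, forces,
    )
    _kernels.compute_bond_forces(
        config.positions, config.bonds, params.k_bond, params.r0_bond,
        config.box, forces,
    )
    return forces


def all_pairs_forces(config, matrix, params, step_index: int) -> np.ndarray:
    """O(N^2) reference force evaluation sharing the engine's noise stream."""
    types, amat = _engine_arrays(config, matrix)
    n = config.n_beads
    inv_sqrt_dt = 1.0 / math.sqrt(params.dt)
    forces = np.zeros((n, 3))
    for i in range(n):
        for j in range(i + 1, n):
            r_vec = config.positions[i] - config.positions[j]
            r_vec -= config.box * np.round(r_vec / config.box)
            theta = _kernels._pair_noise(params.seed, step_index, i, j)
            f_c = conservative_force(r_vec, amat[types[i], types[j]])
            f_d, f_r = thermostat_forces(
                r_vec, config.velocities[i] - config.velocities[j], params, theta
            )
            f = f_c + f_d + f_r
            forces[i] += f
            forces[j] -= f
    bf = np.zeros((n, 3))
    _kernels.compute_bond_forces(
        config.positions, config.bonds, params.k_bond, params.r0_bond,
        config.box, bf,
    )
    return forces + bf


def step(
    config: Configuration,
    matrix,
    params: SimulationParams,
    step_index: int = 0,
    _state: dict | None = None,
) -> Configuration:
    """Advance one step, returning a new Configuration (input untouched)."""
    out = config.copy()
    types, amat = _engine_arrays(out, matrix)
    forces = _forces_at(out, types, amat, params, step_index - 1)
    _kernels.integrate_step(
        out.positions, out.velocities, out.masses, types, amat, out.bonds,
        params.k_bond, params.r0_bond, out.box, params.dt, params.lambda_vv,
        params.gamma, params.sigma, params.seed, step_index, forces,
    )
    if not np.isfinite(out.positions).all():
        raise FloatingPointError(f"numerical blow-up at step {step_index}")
    return out


def run(
    config: Configuration,
    matrix,
    params: SimulationParams,
    stride: int = 100,
    warmup_steps: int = 0,
    check_every: int = 200,
) -> Trajectory:
    """Integrate `params.n_steps` steps, recording every `stride`.

    `warmup_steps` extra steps at dt/10 relax builder overlaps before
    production; they are not recorded and use their own step counter.
    """
    import pandas as pd

    state = config.copy()
    types, amat = _engine_arrays(state, matrix)

    if warmup_steps:
        wp = replace(params, dt=params.dt / 10.0, sigma=None)
        forces = _forces_at(state, types, amat, wp, -warmup_steps - 1)
        for s in range(warmup_steps):
            forces = _kernels.integrate_step(
                state.positions, state.velocities, state.masses, types, amat,
                state.bonds, wp.k_bond, wp.r0_bond, state.box, wp.dt,
                wp.lambda_vv, wp.gamma, wp.sigma, wp.seed,
                -warmup_steps + s, forces,
            )

    snapshots = [state.copy()]
    rows = [_scalar_row(state, 0)]
    forces = _forces_at(state, types, amat, params, 0)
    for s in range(1, params.n_steps + 1):
        forces = _kernels.integrate_step(
            state.positions, state.velocities, state.masses, types, amat,
            state.bonds, params.k_bond, params.r0_bond, state.box, params.dt,
            params.lambda_vv, params.gamma, params.sigma, params.seed, s, forces,
        )
        if s % check_every == 0 and not np.isfinite(state.positions).all():
            raise FloatingPointError(f"numerical blow-up at step {s}")
        if s % stride == 0 or s == params.n_steps:
            snapshots.append(state.copy())
            rows.append(_scalar_row(state, s))
    scalars = pd.DataFrame(rows)
    scalars["time_ps"] = scalars["step"] * config.units.time_per_step_ps
    return Trajectory(snapshots, scalars)


def _scalar_row(config: Configuration, step_index: int) -> dict:
    return {
        "step": step_index,
        "kinetic_temperature": config.kinetic_temperature(),
        "momentum_norm": float(np.linalg.norm(config.total_momentum())),
    }
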