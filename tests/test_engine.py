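import numpy as np
import pytest

from pladpd import _kernels
from pladpd.builder import random_mixed_box
from pladpd.engine import (
    SimulationParams,
    all_pairs_forces,
    bond_force,
    conservative_force,
    run,
    step,
    thermostat_forces,
)
from tests.conftest import make_config


@pytest.fixture(scope="module")
def water_box(registry):
    # 5 r_c cube of pure DPD water
    return random_mixed_box((32.3,) * 3, None, 0.0, seed=21, registry=registry)


@pytest.fixture(scope="module")
def params():
    return SimulationParams(n_steps=0, seed=5)


def test_fluctuation_dissipation_enforced():
    p = SimulationParams(gamma=4.5, kT=1.0)
    assert p.sigma == pytest.approx(3.0)
    with pytest.raises(ValueError, match="fluctuation-dissipation"):
        SimulationParams(gamma=4.5, kT=1.0, sigma=2.0)
    with pytest.raises(ValueError):
        SimulationParams(dt=-0.01)


def test_conservative_force_form():
    assert np.allclose(conservative_force(np.array([1.0, 0, 0]), 25.0), 0.0)
    f = conservative_force(np.array([0.5, 0.0, 0.0]), 25.0)
    assert f == pytest.approx([12.5, 0.0, 0.0])
    # Newton's third law
    f_rev = conservative_force(np.array([-0.5, 0.0, 0.0]), 25.0)
    assert np.allclose(f, -f_rev)
    assert np.allclose(conservative_force(np.zeros(3), 25.0), 0.0)


def test_thermostat_force_form(params):
    r = np.array([0.5, 0.0, 0.0])
    # both vanish beyond the cutoff
    fd, fr = thermostat_forces(np.array([1.2, 0, 0]), np.ones(3), params, 0.3)
    assert np.allclose(fd, 0) and np.allclose(fr, 0)
    # perpendicular relative velocity gives no dissipative force
    fd, _ = thermostat_forces(r, np.array([0.0, 1.0, 0.0]), params, 0.3)
    assert np.allclose(fd, 0)
    fd, fr = thermostat_forces(r, np.array([2.0, 0.0, 0.0]), params, 0.5)
    assert fd[0] == pytest.approx(-params.gamma * 0.25 * 2.0)
    assert fr[0] == pytest.approx(
        params.sigma * 0.5 * 0.5 / np.sqrt(params.dt)
    )


def test_bond_force_form():
    assert np.allclose(bond_force(np.array([0.3, 0, 0]), 4.0, 0.3), 0.0)
    f = bond_force(np.array([0.5, 0.0, 0.0]), 4.0, 0.0)
    assert f == pytest.approx([-2.0, 0.0, 0.0])
    assert np.allclose(
        bond_force(np.array([0.5, 0, 0]), 8.0, 0.0), 2.0 * f
    )


def test_pair_noise_statistics():
    draws = np.array(
        [_kernels._pair_noise(1, s, 3, 7) for s in range(20000)]
    )
    assert abs(draws.mean()) < 0.02
    assert draws.var() == pytest.approx(1.0, abs=0.03)
    # symmetric stream: same counter, same draw
    assert _kernels._pair_noise(1, 5, 3, 7) == _kernels._pair_noise(1, 5, 3, 7)


def test_cell_list_matches_all_pairs_oracle(registry, table1):
    # <= 50 beads, box large enough for a 4^3 cell grid
    rng = np.random.default_rng(2)
    n = 50
    cfg = make_config(
        rng.uniform(0, 5.0, (n, 3)), ["W"] * (n - 10) + ["LA"] * 10,
        [5.0, 5.0, 5.0],
        molecule_id=np.arange(n), velocities=rng.normal(size=(n, 3)),
        bonds=[[0, 1], [2, 3]],
    )
    cfg.molecule_id[1] = 0
    cfg.molecule_id[3] = 2
    params = SimulationParams(seed=9)
    ref = all_pairs_forces(cfg, table1, params, step_index=4)
    types, amat = _engine_arrays(cfg, table1)
    forces = np.zeros((n, 3))
    _kernels.compute_nonbonded_forces(
        cfg.positions, cfg.velocities, types, amat, cfg.box,
        params.gamma, params.sigma, 1.0 / np.sqrt(params.dt),
        params.seed, 4, forces,
    )
    _kernels.compute_bond_forces(
        cfg.positions, cfg.bonds, params.k_bond, params.r0_bond, cfg.box, forces
    )
    np.testing.assert_allclose(forces, ref, rtol=0, atol=1e-12)


def _engine_arrays(cfg, matrix):
    from pladpd.engine import _engine_arrays as ea

    return ea(cfg, matrix)


def test_momentum_conserved_over_many_steps(water_box, table1):
    params = SimulationParams(n_steps=10_000, seed=31)
    traj = run(water_box, table1, params, stride=2000)
    n = water_box.n_beads
    assert traj.scalars["momentum_norm"].max() < 1e-6 * n


def test_thermostat_reaches_unit_temperature(registry, table1):
    # 8 r_c cube: large enough that the ensemble mean dominates the noise
    box = random_mixed_box((51.7,) * 3, None, 0.0, seed=22, registry=registry)
    params = SimulationParams(n_steps=3000, seed=32)
    traj = run(box, table1, params, stride=100)
    tail = traj.scalars["kinetic_temperature"].iloc[15:]
    assert tail.mean() == pytest.approx(1.0, abs=0.03)


def test_energy_conservation_symplectic_limit(table1):
    # gamma = sigma = 0: an isolated bonded pair conserves E to O(dt^2)
    drifts = {}
    for dt in (0.04, 0.02):
        cfg = make_config(
            [[1.0, 1.0, 1.0], [1.8, 1.0, 1.0]], ["W", "W"], [4.0, 4.0, 4.0],
            molecule_id=[0, 0], bonds=[[0, 1]],
        )
        params = SimulationParams(dt=dt, gamma=0.0, n_steps=1000, seed=0)
        types, amat = _engine_arrays(cfg, table1)

        def energy(c):
            kin = 0.5 * float((c.masses[:, None] * c.velocities**2).sum())
            pot = _kernels.conservative_energy(
                c.positions, types, amat, c.bonds, params.k_bond,
                params.r0_bond, c.box,
            )
            return kin + pot

        traj = run(cfg, table1, params, stride=50)
        energies = np.array([energy(s) for s in traj.snapshots])
        drifts[dt] = np.abs(energies - energies[0]).max()
    # dt*omega ~ 0.5 for this stiff soft-core pair: a few-percent bound
    assert drifts[0.04] < 0.1
    # halving dt cuts the error by ~4 (second-order integrator)
    assert drifts[0.02] < drifts[0.04] / 2.5


def test_run_bookkeeping(water_box, table1):
    params = SimulationParams(n_steps=0, seed=1)
    traj = run(water_box, table1, params, stride=10)
    assert len(traj) == 1
    params = SimulationParams(n_steps=100, seed=1)
    traj = run(water_box, table1, params, stride=25)
    assert len(traj) == 5
    assert traj.scalars["time_ps"].iloc[-1] == pytest.approx(300.0)
    # 10 ns at 3 ps/step
    assert water_box.units.steps_for(10.0) == 3334


def test_step_determinism_and_seed_sensitivity(water_box, table1):
    params = SimulationParams(n_steps=50, seed=77)
    t1 = run(water_box, table1, params, stride=50)
    t2 = run(water_box, table1, params, stride=50)
    np.testing.assert_array_equal(t1.final.positions, t2.final.positions)
    np.testing.assert_array_equal(t1.final.velocities, t2.final.velocities)
    t3 = run(water_box, table1, SimulationParams(n_steps=50, seed=78), stride=50)
    assert not np.array_equal(t1.final.positions, t3.final.positions)


def test_water_structure_is_liquid_like(water_box, table1):
    """Radial distribution of DPD water: soft first peak inside r_c, no
    long-range order."""
    from scipy.spatial import cKDTree

    traj = run(water_box, table1, SimulationParams(n_steps=800, seed=55),
               stride=800)
    cfg = traj.final
    tree = cKDTree(cfg.positions, boxsize=cfg.box)
    pairs = tree.query_pairs(2.4, output_type="ndarray")
    d = cfg.positions[pairs[:, 0]] - cfg.positions[pairs[:, 1]]
    d -= cfg.box * np.round(d / cfg.box)
    r = np.linalg.norm(d, axis=1)
    edges = np.arange(0.1, 2.4, 0.1)
    hist, _ = np.histogram(r, bins=edges)
    shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    rho_pair = cfg.n_beads / float(cfg.box.prod())
    g = hist / (shell * 0.5 * cfg.n_beads * rho_pair)
    mids = 0.5 * (edges[1:] + edges[:-1])
    peak = mids[np.argmax(g)]
    assert peak < 1.0  # soft-core liquid: first peak inside the cutoff
    assert abs(g[mids > 2.0].mean() - 1.0) < 0.15  # no long-range order


def test_static_configuration_stays_put(table1):
    # beads farther apart than the cutoff, no velocity, no thermostat
    cfg = make_config(
        [[0.5, 0.5, 0.5], [2.5, 2.5, 2.5]], ["W", "W"], [5.0, 5.0, 5.0],
        molecule_id=[0, 1],
    )
    params = SimulationParams(gamma=0.0, n_steps=5, seed=0)
    out = step(cfg, table1, params)
    np.testing.assert_allclose(out.positions, cfg.positions, atol=1e-15)
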