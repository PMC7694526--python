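import numpy as np
import pytest

from pladpd import analysis
from pladpd.units import SimulationUnits
from tests.conftest import make_config

U = SimulationUnits()


def _ball(rng, n, radius, center=(0, 0, 0)):
    p = rng.normal(size=(n, 3))
    p /= np.linalg.norm(p, axis=1)[:, None]
    r = radius * rng.uniform(0, 1, n) ** (1 / 3)
    return np.asarray(center) + p * r[:, None]


# -- clustering -------------------------------------------------------------

def _brute_force_clusters(config, bead_filter, cutoff):
    """O(N^2) union-find over molecules (independent oracle)."""
    mask = np.isin(config.species, bead_filter)
    mols = np.unique(config.molecule_id[mask])
    parent = {int(m): int(m) for m in mols}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    idx = np.flatnonzero(mask)
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            d = config.positions[idx[a]] - config.positions[idx[b]]
            d -= config.box * np.round(d / config.box)
            if (d**2).sum() <= cutoff**2:
                ra, rb = find(int(config.molecule_id[idx[a]])), find(
                    int(config.molecule_id[idx[b]])
                )
                parent[ra] = rb
    groups = {}
    for m in mols:
        groups.setdefault(find(int(m)), set()).add(int(m))
    return sorted((sorted(g) for g in groups.values()))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_clusters_match_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n_mol = 30
    pos, mol, spec = [], [], []
    for m in range(n_mol):
        start = rng.uniform(0, 8.0, 3)
        for k in range(3):
            pos.append(start + rng.normal(scale=0.3, size=3))
            mol.append(m)
            spec.append("F" if k < 2 else "K")
    cfg = make_config(pos, spec, [8.0, 8.0, 8.0], molecule_id=mol)
    cs = analysis.find_clusters(cfg, bead_filter=("F",), cutoff=1.0)
    ours = sorted(sorted(c) for c in cs.clusters)
    assert ours == _brute_force_clusters(cfg, ("F",), 1.0)


def test_cluster_edge_cases():
    cfg = make_config(
        [[1, 1, 1], [1.4, 1, 1], [5, 5, 5], [5.4, 5, 5]],
        ["F", "F", "F", "F"], [10.0] * 3, molecule_id=[0, 0, 1, 1],
    )
    cs = analysis.find_clusters(cfg, bead_filter=("F",), cutoff=1.0)
    assert sorted(cs.sizes) == [1, 1]  # farther than cutoff: singletons
    near = make_config(
        [[1, 1, 1], [1.5, 1, 1]], ["F", "F"], [10.0] * 3, molecule_id=[0, 1]
    )
    cs = analysis.find_clusters(near, bead_filter=("F",), cutoff=1.0)
    assert cs.sizes == [2]  # closest beads at 0.5 r_c: one cluster
    with pytest.raises(ValueError):
        analysis.find_clusters(near, bead_filter=(), cutoff=1.0)
    with pytest.raises(ValueError):
        analysis.find_clusters(near, bead_filter=("F",), cutoff=-1.0)


def test_clusters_connect_across_periodic_boundary():
    cfg = make_config(
        [[0.2, 5, 5], [9.8, 5, 5]], ["F", "F"], [10.0] * 3, molecule_id=[0, 1]
    )
    cs = analysis.find_clusters(cfg, bead_filter=("F",), cutoff=1.0)
    assert cs.sizes == [2]


# -- size and shape ---------------------------------------------------------

def test_uniform_ball_diameter_and_translation_invariance():
    rng = np.random.default_rng(3)
    R = 3.0
    pos = _ball(rng, 6000, R, center=(10, 10, 10))
    cfg = make_config(pos, ["LA"] * 6000, [20.0] * 3)
    d_nm = analysis.cluster_diameter(cfg, {0})
    assert d_nm == pytest.approx(U.to_nm(2 * R), rel=0.02)
    # shift across the periodic boundary: unchanged
    cfg2 = make_config(pos + np.array([9.5, 0, 0]), ["LA"] * 6000, [20.0] * 3)
    assert analysis.cluster_diameter(cfg2, {0}) == pytest.approx(d_nm, rel=1e-6)


def test_single_bead_diameter_zero():
    cfg = make_config([[1, 1, 1]], ["LA"], [5.0] * 3)
    assert analysis.cluster_diameter(cfg, {0}) == 0.0


def test_shape_classification_sphere_cylinder_rotation():
    rng = np.random.default_rng(4)
    shell = _ball(rng, 2000, 2.0, center=(8, 8, 8))
    mols = np.arange(2000) % 10
    cfg = make_config(shell, ["F"] * 2000, [16.0] * 3, molecule_id=mols)
    cluster = set(range(10))
    assert analysis.shape_class(cfg, cluster) == "sphere"

    # cylinder with length 10x its radius
    z = rng.uniform(-5, 5, 2000)
    phi = rng.uniform(0, 2 * np.pi, 2000)
    r = np.sqrt(rng.uniform(0, 1, 2000))
    cyl = np.c_[r * np.cos(phi), r * np.sin(phi), z]
    rot = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    for coords in (cyl, cyl @ rot.T):
        cfg = make_config(coords + 8.0, ["F"] * 2000, [16.0] * 3,
                          molecule_id=mols)
        assert analysis.shape_class(cfg, cluster) == "wormlike"
    with pytest.raises(ValueError):
        analysis.shape_class(cfg, {0, 1})


def test_bilayer_thickness_uniform_slab_oracle():
    rng = np.random.default_rng(5)
    t_half = 1.0
    n = 4000
    slab = np.c_[
        rng.uniform(-6, 6, n), rng.uniform(-6, 6, n),
        rng.uniform(-t_half, t_half, n),
    ]
    mols = np.arange(n) % 12
    cfg = make_config(slab + 8.0, ["F"] * n, [16.0] * 3, molecule_id=mols)
    cluster = set(range(12))
    th = analysis.bilayer_thickness(cfg, cluster)
    assert th == pytest.approx(U.to_nm(2 * t_half), rel=0.03)
    # in-plane stretching leaves the thickness unchanged
    wide = slab * np.array([1.3, 1.2, 1.0])
    cfg_w = make_config(wide + 8.0, ["F"] * n, [24.0] * 3, molecule_id=mols)
    assert analysis.bilayer_thickness(cfg_w, cluster) == pytest.approx(
        th, rel=0.03
    )
    # doubling all coordinates doubles the thickness
    cfg_2 = make_config(slab * 2 + 8.0, ["F"] * n, [32.0] * 3, molecule_id=mols)
    assert analysis.bilayer_thickness(cfg_2, cluster) == pytest.approx(
        2 * th, rel=0.03
    )
    # a sphere-class cluster is rejected
    ball_cfg = make_config(_ball(rng, 1000, 2.0, (8, 8, 8)), ["F"] * 1000,
                           [16.0] * 3, molecule_id=np.arange(1000) % 8)
    with pytest.raises(ValueError, match="sphere"):
        analysis.bilayer_thickness(ball_cfg, set(range(8)))


def test_local_thickness_matches_slab_oracle_when_percolating():
    # a slab spanning the box: the global gyration is meaningless, the
    # local estimator must recover the true width
    rng = np.random.default_rng(12)
    t_true = 4.0
    box = 24.0
    n = int(3 * box * box * t_true * 0.7)
    slab = np.c_[
        rng.uniform(0, box, n), rng.uniform(0, box, n),
        rng.uniform(12 - t_true / 2, 12 + t_true / 2, n),
    ]
    mols = np.arange(n) % 200
    cfg = make_config(slab, ["F"] * n, [box] * 3, molecule_id=mols)
    cluster = set(range(200))
    assert analysis.is_percolating(cfg, cluster)
    th = analysis.bilayer_thickness(cfg, cluster)  # dispatches to local
    assert th == pytest.approx(U.to_nm(t_true), rel=0.08)


# -- particle metrics -------------------------------------------------------

def test_particle_diameter_half_max_uniform_ball():
    rng = np.random.default_rng(6)
    R = 5.0
    pos = _ball(rng, 20000, R, center=(12, 12, 12))
    cfg = make_config(pos, ["LA"] * 20000, [24.0] * 3)
    res = analysis.particle_diameter(cfg, {0})
    assert res.method == "half-max"
    assert res.angstrom == pytest.approx(U.to_angstrom(2 * R), abs=U.to_angstrom(0.6))


def test_particle_diameter_fallback_small_cluster():
    rng = np.random.default_rng(7)
    pos = _ball(rng, 50, 2.0, center=(8, 8, 8))
    cfg = make_config(pos, ["LA"] * 50, [16.0] * 3)
    res = analysis.particle_diameter(cfg, {0})
    assert res.method == "gyration-fallback"
    assert float(res) > 0


def test_radial_ordering_constructed_shells():
    rng = np.random.default_rng(8)
    R = 4.0
    n = 800
    # K beads on a shell at 1.2 R, F beads on a shell at 0.6 R
    def shell(rad):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        return v * rad

    pos = np.vstack([shell(1.2 * R), shell(0.6 * R)]) + 10.0
    spec = ["K"] * n + ["F"] * n
    mols = np.zeros(2 * n, int)
    cfg = make_config(pos, spec, [20.0] * 3, molecule_id=mols,
                      molecule_templates=["Pam3CSK4"])
    means = analysis.radial_ordering(cfg, {0}, "Pam3CSK4")
    assert means["K"] / means["F"] == pytest.approx(2.0, rel=0.05)
    # global translation leaves the ordering unchanged
    cfg_t = make_config(pos + 5.0, spec, [20.0] * 3, molecule_id=mols,
                        molecule_templates=["Pam3CSK4"])
    means_t = analysis.radial_ordering(cfg_t, {0}, "Pam3CSK4")
    assert means_t["K"] == pytest.approx(means["K"], rel=1e-6)


def test_solvent_exposure_orders_wet_and_dry_species():
    rng = np.random.default_rng(13)
    w = rng.uniform(0, 10, (2000, 3))
    # K beads sit among the water, F beads in a dry corner pocket
    k = rng.uniform(0, 10, (100, 3))
    f = rng.uniform(4.5, 5.5, (100, 3))
    w = w[np.any(np.abs(w - 5.0) > 1.6, axis=1)]  # carve the pocket dry
    pos = np.vstack([w, k, f])
    spec = ["W"] * len(w) + ["K"] * 100 + ["F"] * 100
    mol = list(range(len(w))) + [len(w)] * 200
    tmpl = ["water"] * len(w) + ["Pam3CSK4"]
    cfg = make_config(pos, spec, [10.0] * 3, molecule_id=mol,
                      molecule_templates=tmpl)
    exp = analysis.solvent_exposure(cfg, "Pam3CSK4", ("K", "F"))
    assert exp["K"] < exp["F"]
    with pytest.raises(ValueError):
        analysis.solvent_exposure(cfg, "Pam3CSK4", ("CHR",))


def test_encapsulated_fraction_direct_count():
    rng = np.random.default_rng(9)
    pos, spec, mol = [], [], []
    # host: LA slab around x ~ 2
    for k in range(300):
        pos.append([2.0 + rng.uniform(-1, 1), rng.uniform(0, 10),
                    rng.uniform(0, 10)])
        spec.append("LA")
        mol.append(0)
    next_mol = 1
    # 9 solutes touching the slab
    for k in range(9):
        base = np.array([3.2, 1.0 + k, 5.0])
        for b in range(2):
            pos.append(base + [0.3 * b - 0.25, 0, 0])
            spec.append("F")
            mol.append(next_mol)
        next_mol += 1
    # 3 solutes in one far micelle
    for k in range(3):
        base = np.array([8.0, 5.0, 5.0])
        for b in range(2):
            pos.append(base + [0.3 * (b + k), 0, 0])
            spec.append("F")
            mol.append(next_mol)
        next_mol += 1
    templates = ["PLA_70"] + ["Pam3CSK4"] * 12
    cfg = make_config(pos, spec, [12.0, 10.0, 10.0], molecule_id=mol,
                      molecule_templates=templates)
    rep = analysis.encapsulated_fraction(cfg, {0}, "Pam3CSK4", cutoff=1.0)
    assert rep.fraction_inside == pytest.approx(0.75)
    assert rep.fraction_micelles == pytest.approx(0.25)
    assert rep.free_count == 0
    labels = list(rep.labels.values())
    assert labels.count("inside") + labels.count("micelle") + labels.count(
        "free"
    ) == rep.total


def test_encapsulated_fraction_all_touching():
    pos = [[1, 1, 1], [1.5, 1, 1]]
    spec = ["LA", "F"]
    cfg = make_config(pos, spec, [8.0] * 3, molecule_id=[0, 1],
                      molecule_templates=["PLA_70", "Pam3CSK4"])
    rep = analysis.encapsulated_fraction(cfg, {0}, "Pam3CSK4")
    assert rep.fraction_inside == 1.0
    with pytest.raises(ValueError):
        analysis.encapsulated_fraction(cfg, set(), "Pam3CSK4")


def test_water_exclusion_limits():
    rng = np.random.default_rng(10)
    R = 4.0
    ball = _ball(rng, 8000, R, center=(10, 10, 10))
    box = [20.0] * 3
    # dry core: no W anywhere near the particle
    w_far = rng.uniform(0, 3.0, (500, 3))
    pos = np.vstack([ball, w_far])
    spec = ["LA"] * 8000 + ["W"] * 500
    mol = [0] * 8000 + list(range(1, 501))
    tmpl = ["PLA_70"] + ["water"] * 500
    cfg = make_config(pos, spec, box, molecule_id=mol, molecule_templates=tmpl)
    assert analysis.water_exclusion(cfg, {0}) == 0.0
    # uniform mixture: ratio ~ 1
    w_mix = rng.uniform(0, 20.0, (20000, 3))
    pos = np.vstack([ball, w_mix])
    spec = ["LA"] * 8000 + ["W"] * 20000
    mol = [0] * 8000 + list(range(1, 20001))
    tmpl = ["PLA_70"] + ["water"] * 20000
    cfg = make_config(pos, spec, box, molecule_id=mol, molecule_templates=tmpl)
    assert analysis.water_exclusion(cfg, {0}) == pytest.approx(1.0, abs=0.35)


def test_percolation_detection():
    rng = np.random.default_rng(11)
    line = np.c_[np.linspace(0, 9.9, 200), np.full(200, 5.0), np.full(200, 5.0)]
    cfg = make_config(line, ["F"] * 200, [10.0] * 3,
                      molecule_id=np.arange(200) % 5)
    assert analysis.is_percolating(cfg, set(range(5)))
    blob = make_config(_ball(rng, 200, 1.0, (5, 5, 5)), ["F"] * 200,
                       [10.0] * 3, molecule_id=np.arange(200) % 5)
    assert not analysis.is_percolating(blob, set(range(5)))
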