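"""Pair potentials and total energy/force/torque evaluation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import shellcargo.constants as C
from shellcargo.interactions import (InteractionTable, cargo_lj_energy,
                                     morse_energy, repulsive_lj_energy,
                                     total_energy_forces)

WCA_CUT = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# scalar potentials
# ---------------------------------------------------------------------------

def test_morse_minimum_and_cutoff():
    eps, req, alpha, rcut = 2.0, 0.3, 5.0, 2.0
    shift = eps * ((1 - np.exp(-alpha * (rcut - req))) ** 2 - 1)
    assert morse_energy(req, eps, req, alpha, rcut) == pytest.approx(
        -eps - shift, abs=1e-12)
    assert morse_energy(rcut, eps, req, alpha, rcut) == 0.0
    assert morse_energy(rcut + 1.0, eps, req, alpha, rcut) == 0.0
    # closed form at r = req + ln(2)/alpha: (1 - 1/2)^2 - 1 = -3/4
    r = req + np.log(2) / alpha
    assert morse_energy(r, eps, req, alpha, rcut) == pytest.approx(
        -0.75 * eps - shift, abs=1e-12)
    with pytest.raises(ValueError):
        morse_energy(-0.1, eps, req, alpha, rcut)
    with pytest.raises(ValueError):
        morse_energy(1.0, eps, req, alpha, rcut=req)


def test_wca_examples():
    sigma, eps_rep = 0.7, 1.3
    assert repulsive_lj_energy(sigma, sigma, eps_rep) == pytest.approx(eps_rep)
    assert repulsive_lj_energy(WCA_CUT * sigma, sigma, eps_rep) == 0.0
    assert repulsive_lj_energy(2 * sigma, sigma, eps_rep) == 0.0
    # monotonically decreasing on (0, cutoff]
    r = np.linspace(0.3 * sigma, WCA_CUT * sigma, 200)
    v = repulsive_lj_energy(r, sigma, eps_rep)
    assert (np.diff(v) <= 1e-12).all()
    with pytest.raises(ValueError):
        repulsive_lj_energy(0.0, sigma)


def test_cargo_lj_examples():
    s6c = (1.0 / C.RCUT_CARGO) ** 6
    shift = 4 * 1.3 * (s6c * s6c - s6c)
    assert cargo_lj_energy(2 ** (1 / 6), 1.3) == pytest.approx(-1.3 - shift)
    # LJ crosses zero at r = sigma: only the cutoff shift remains
    assert cargo_lj_energy(1.0, 1.3) == pytest.approx(-shift, abs=1e-12)
    assert cargo_lj_energy(C.RCUT_CARGO + 0.5, 1.3) == 0.0


def test_cargo_lj_against_symbolic_oracle():
    """Tabulated values on r in [0.9, 2.5] match an independent symbolic
    evaluation to 1e-12."""
    import sympy as sp
    r_, e_, s_, rc_ = sp.symbols("r e s rc", positive=True)
    v = 4 * e_ * ((s_ / r_) ** 12 - (s_ / r_) ** 6)
    vfun = sp.lambdify((r_, e_, s_), v, "numpy")
    eps = 1.3
    grid = np.linspace(0.9, 2.4999, 50)
    expect = vfun(grid, eps, 1.0) - vfun(C.RCUT_CARGO, eps, 1.0)
    got = cargo_lj_energy(grid, eps)
    assert np.abs(got - expect).max() < 1e-12


def test_unknown_species_pair_rejected(table):
    with pytest.raises(ValueError):
        table.cargo_eps(0, 2)


def test_complementarity_matrix(table):
    m = table.complementarity
    assert (m == m.T).all()
    assert m.sum() == 2 * len(C.COMPLEMENTARY_PAIRS)
    # non-complementary attractor pairs have no interaction at all
    t = table.compile()
    for a in range(10):
        for b in range(10):
            if not m[a, b]:
                assert t.kind[a, b] == 0


def test_eps_sc_shared_by_both_cargo_species(table):
    t = table.compile()
    for cg in (C.TYPE_CARGO_R, C.TYPE_CARGO_G):
        assert t.kind[C.TYPE_BH_A, cg] == 1
        assert t.eps[C.TYPE_BH_A, cg] == table.eps_sc


# ---------------------------------------------------------------------------
# total energy / forces
# ---------------------------------------------------------------------------

def test_single_subunit_has_zero_energy(table, templates):
    from shellcargo.state import SimulationState
    st = SimulationState(templates, np.array([1]), np.array([[5.0, 5, 5]]),
                         np.array([[1.0, 0, 0, 0]]), np.zeros((0, 3)),
                         np.zeros(0, dtype=np.int64), 12.0)
    res = total_energy_forces(st, table)
    assert res.energy == 0.0
    assert np.abs(res.body_force).max() == 0.0


def test_bonded_hexamer_pair_attractive(blueprint, table):
    from shellcargo.state import SimulationState, state_from_blueprint
    i, j = next((e[0], e[1]) for e in blueprint.edges if e[2] == "hex-hex")
    full = state_from_blueprint(blueprint, box=20.0)
    st = SimulationState(full.templates, full.body_species[[i, j]],
                         full.body_pos[[i, j]], full.body_quat[[i, j]],
                         np.zeros((0, 3)), np.zeros(0, dtype=np.int64), 20.0)
    assert total_energy_forces(st, table).energy < -4 * table.eps_ss * 0.9


def test_neighbor_list_matches_brute_force(random_soup, table):
    """20 random bodies + cargo: cell/Verlet evaluation equals the all-pairs
    double loop to 1e-8 relative."""
    r1 = total_energy_forces(random_soup, table, use_neighbor_list=True)
    r2 = total_energy_forces(random_soup, table, use_neighbor_list=False)
    scale = max(1.0, abs(r2.energy))
    assert abs(r1.energy - r2.energy) / scale < 1e-8
    assert np.abs(r1.body_force - r2.body_force).max() < 1e-8 * max(
        1.0, np.abs(r2.body_force).max())
    assert np.abs(r1.cargo_force - r2.cargo_force).max() < 1e-8


def test_forces_sum_to_zero(random_soup, table):
    res = total_energy_forces(random_soup, table)
    total = res.body_force.sum(axis=0) + res.cargo_force.sum(axis=0)
    assert np.abs(total).max() < 1e-8


def test_forces_are_negative_gradients(random_soup, table):
    """Finite-difference check |F - (-grad U)| / |F| < 1e-5 on body centers
    and cargo positions."""
    res = total_energy_forces(random_soup, table, use_neighbor_list=False)
    h = 1e-6
    fnorm = max(np.abs(res.body_force).max(), np.abs(res.cargo_force).max())

    def energy(st):
        return total_energy_forces(st, table, use_neighbor_list=False).energy

    rng = np.random.default_rng(4)
    for b in rng.choice(random_soup.n_bodies, 3, replace=False):
        for k in range(3):
            up = random_soup.copy()
            dn = random_soup.copy()
            up.body_pos[b, k] += h
            dn.body_pos[b, k] -= h
            fd = -(energy(up) - energy(dn)) / (2 * h)
            assert abs(fd - res.body_force[b, k]) < 1e-5 * max(1.0, fnorm)
    for c in rng.choice(random_soup.n_cargo, 3, replace=False):
        for k in range(3):
            up = random_soup.copy()
            dn = random_soup.copy()
            up.cargo_pos[c, k] += h
            dn.cargo_pos[c, k] -= h
            fd = -(energy(up) - energy(dn)) / (2 * h)
            assert abs(fd - res.cargo_force[c, k]) < 1e-5 * max(1.0, fnorm)


def test_torques_consistent_with_forces(random_soup, table):
    """dU/dtheta about a body axis equals minus the torque component."""
    from scipy.spatial.transform import Rotation as Rot
    res = total_energy_forces(random_soup, table, use_neighbor_list=False)
    h = 1e-6

    def energy(st):
        return total_energy_forces(st, table, use_neighbor_list=False).energy

    tnorm = max(1.0, np.abs(res.body_torque).max())
    for b in (0, 5):
        for k in range(3):
            rv = np.zeros(3)
            rv[k] = h
            up = random_soup.copy()
            dn = random_soup.copy()
            for s, sgn in ((up, 1.0), (dn, -1.0)):
                q = s.body_quat[b, [1, 2, 3, 0]]
                s.body_quat[b] = (Rot.from_rotvec(sgn * rv)
                                  * Rot.from_quat(q)).as_quat()[[3, 0, 1, 2]]
            fd = -(energy(up) - energy(dn)) / (2 * h)
            assert abs(fd - res.body_torque[b, k]) < 1e-5 * tnorm


def test_global_translation_rotation_invariance(random_soup, table):
    from scipy.spatial.transform import Rotation as Rot
    e0 = total_energy_forces(random_soup, table, use_neighbor_list=False).energy
    st = random_soup.copy()
    st.body_pos += 1.234
    st.cargo_pos += 1.234
    st.wrap()
    e1 = total_energy_forces(st, table, use_neighbor_list=False).energy
    assert abs(e1 - e0) < 1e-8 * max(1.0, abs(e0))
    # global rotation: valid for an isolated cluster (rotations are not
    # compatible with the periodic images of a dense box)
    from shellcargo.dynamics import init_random
    iso = init_random(2, 3, 10, 10, box=8.0, seed=9, table=table)
    iso.box = 40.0
    iso.body_pos += 16.0
    iso.cargo_pos += 16.0
    ei = total_energy_forces(iso, table, use_neighbor_list=False).energy
    rot = Rot.from_rotvec([0.3, -0.2, 0.5])
    st = iso.copy()
    c = 20.0
    st.body_pos = rot.apply(st.body_pos - c) + c
    st.cargo_pos = rot.apply(st.cargo_pos - c) + c
    q = st.body_quat[:, [1, 2, 3, 0]]
    st.body_quat = (rot * Rot.from_quat(q)).as_quat()[:, [3, 0, 1, 2]]
    e2 = total_energy_forces(st, table, use_neighbor_list=False).energy
    assert abs(e2 - ei) < 1e-7 * max(1.0, abs(ei))


def test_species_swap_symmetry(table):
    """Swapping all R<->G labels together with eps_RR<->eps_GG leaves the
    energy unchanged."""
    from shellcargo.dynamics import init_random
    t1 = InteractionTable(eps_rr=1.7, eps_gg=1.1, eps_rg=1.3)
    st = init_random(2, 3, 12, 8, box=12.0, seed=5, table=t1)
    e1 = total_energy_forces(st, t1, use_neighbor_list=False).energy
    st2 = st.copy()
    st2.cargo_species = 1 - st2.cargo_species
    t2 = InteractionTable(eps_rr=1.1, eps_gg=1.7, eps_rg=1.3)
    e2 = total_energy_forces(st2, t2, use_neighbor_list=False).energy
    assert e2 == pytest.approx(e1, rel=1e-12)


def test_box_smaller_than_twice_cutoff_rejected(table, templates):
    from shellcargo.state import SimulationState
    st = SimulationState(templates, np.zeros(0, dtype=np.int64),
                         np.zeros((0, 3)), np.zeros((0, 4)),
                         np.array([[1.0, 1, 1], [2.0, 2, 2]]),
                         np.array([0, 1]), box=4.0)
    with pytest.raises(ValueError, match="twice the largest cutoff"):
        total_energy_forces(st, table)


@given(st.floats(min_value=0.05, max_value=3.0),
       st.floats(min_value=0.5, max_value=4.0))
def test_morse_bounded_below_by_minus_eps(r, eps):
    v = morse_energy(r, eps, C.MORSE_REQ_SS, C.MORSE_ALPHA_SS,
                     C.MORSE_RCUT_SS)
    assert v >= -eps - 1e-9
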