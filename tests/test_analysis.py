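"""Observables: bond graph, shell detection, encapsulation census, mixing
metrics and phase classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shellcargo.analysis import (MixingMetrics, ShellCluster, bond_graph,
                                 cargo_pair_counts, classify_phase,
                                 compute_observables, detect_shells,
                                 encapsulated_cargo, mixing_metrics,
                                 shell_variability)
from shellcargo.scenarios import make_fixture
from shellcargo.state import SimulationState, state_from_blueprint


# ---------------------------------------------------------------------------
# bond graph
# ---------------------------------------------------------------------------

def test_bond_graph_blueprint_has_90_edges(blueprint, table):
    st = state_from_blueprint(blueprint, box=20.0)
    g = bond_graph(st, table)
    assert g.number_of_edges() == 90
    # idempotent on a static state
    g2 = bond_graph(st, table)
    assert set(g.edges) == set(g2.edges)


def test_bond_graph_dilute_random_has_no_edges(table):
    from shellcargo.dynamics import init_random
    total = 0
    for seed in range(10):
        st = init_random(6, 10, 0, 0, box=40.0, seed=seed, table=table)
        total += bond_graph(st, table).number_of_edges()
    assert total <= 2


def test_bond_graph_separated_pair_has_no_edge(blueprint, table):
    full = state_from_blueprint(blueprint, box=30.0)
    st = SimulationState(full.templates, full.body_species[[12, 13]],
                         np.array([[10.0, 10, 10], [13.0, 10, 10]]),
                         np.array([[1.0, 0, 0, 0], [1.0, 0, 0, 0]]),
                         np.zeros((0, 3)), np.zeros(0, dtype=np.int64), 30.0)
    assert bond_graph(st, table).number_of_edges() == 0


# ---------------------------------------------------------------------------
# shell detection
# ---------------------------------------------------------------------------

def test_detect_complete_shell(blueprint, table):
    st = state_from_blueprint(blueprint, box=20.0)
    shells, f_s = detect_shells(bond_graph(st, table), st)
    assert len(shells) == 1
    assert shells[0].complete
    assert shells[0].n_pent == 12 and shells[0].n_hex == 20
    assert f_s == 1.0


def test_missing_pentamer_breaks_completeness(blueprint, table):
    st = state_from_blueprint(blueprint, box=20.0, drop_bodies=(0,))
    shells, f_s = detect_shells(bond_graph(st, table), st)
    assert len(shells) == 1
    assert not shells[0].complete
    assert f_s == 0.0


def test_two_disjoint_shells(blueprint, table):
    a = state_from_blueprint(blueprint, box=40.0,
                             center=np.array([10.0, 10, 10]))
    b = state_from_blueprint(blueprint, box=40.0,
                             center=np.array([28.0, 28, 28]))
    st = SimulationState(a.templates,
                         np.concatenate([a.body_species, b.body_species]),
                         np.vstack([a.body_pos, b.body_pos]),
                         np.vstack([a.body_quat, b.body_quat]),
                         np.zeros((0, 3)), np.zeros(0, dtype=np.int64), 40.0)
    shells, f_s = detect_shells(bond_graph(st, table), st)
    assert sum(s.complete for s in shells) == 2
    assert f_s == 1.0


@given(st.integers(min_value=1, max_value=20), st.integers(0, 10**6))
def test_blueprint_subgraph_never_complete(blueprint, n_remove, seed):
    """Removing any edges from the blueprint bond graph destroys the closed
    topology, so no proper sub-graph is ever reported complete."""
    import networkx as nx

    from shellcargo.state import PENTAMER
    g = nx.Graph()
    for b in range(32):
        g.add_node(b)
    for i, j, _ in blueprint.edges:
        g.add_edge(i, j)
    rng = np.random.default_rng(seed)
    edges = list(g.edges)
    idx = rng.choice(len(edges), size=n_remove, replace=False)
    for k in idx:
        g.remove_edge(*edges[k])

    class FakeState:
        body_species = np.array([PENTAMER if s == "pentamer" else 1
                                 for s in blueprint.species])
        n_bodies = 32
        n_cargo = 0
    shells, f_s = detect_shells(g, FakeState())
    assert not any(s.complete for s in shells)
    assert f_s == 0.0


# ---------------------------------------------------------------------------
# encapsulated cargo / point-in-polyhedron
# ---------------------------------------------------------------------------

def test_planted_interior_lattice_is_fully_counted(table):
    st, truth = make_fixture("filled_shell", n=150, box=30.0)
    rec = compute_observables(st, table)
    assert rec.n_complete_shells == 1
    assert rec.mean_n_c == truth["n_c"] == 150
    assert rec.f_r == pytest.approx(truth["f_r"], abs=1e-9)


def test_far_cargo_is_excluded(blueprint, table):
    st = state_from_blueprint(blueprint, box=40.0)
    # one cargo at the center, one at twice the shell radius
    st = SimulationState(st.templates, st.body_species, st.body_pos,
                         st.body_quat,
                         np.array([[20.0, 20, 20], [20.0, 20, 20 + 6.0]]),
                         np.array([0, 0]), 40.0)
    shells, _ = detect_shells(bond_graph(st, table), st)
    assert shells[0].n_c == 1
    assert list(shells[0].cargo_ids) == [0]


def _winding_number(points, verts, simplices, normals):
    """Generalized winding number via the van Oosterom-Strackee solid-angle
    formula (independent inside/outside oracle).  Triangles are oriented
    outward using the supplied facet normals."""
    simplices = [tri if np.dot(np.cross(verts[tri[1]] - verts[tri[0]],
                                        verts[tri[2]] - verts[tri[0]]),
                               n) > 0 else (tri[0], tri[2], tri[1])
                 for tri, n in zip(simplices, normals)]
    w = np.zeros(len(points))
    for tri in simplices:
        a = verts[tri[0]] - points
        b = verts[tri[1]] - points
        c = verts[tri[2]] - points
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
               + np.einsum("ij,ij->i", a, c) * lb
               + np.einsum("ij,ij->i", b, c) * la)
        w += 2 * np.arctan2(num, den)
    return np.abs(w) / (4 * np.pi)


def test_point_in_polyhedron_matches_winding_oracle(blueprint, table):
    """500 planted interior/exterior points: 100% agreement with the
    winding-number oracle."""
    from scipy.spatial import ConvexHull
    st = state_from_blueprint(blueprint, box=40.0)
    rng = np.random.default_rng(12)
    pts = rng.uniform(-4.5, 4.5, size=(500, 3)) + 20.0
    st = SimulationState(st.templates, st.body_species, st.body_pos,
                         st.body_quat, pts,
                         np.zeros(500, dtype=np.int64), 40.0)
    shells, _ = detect_shells(bond_graph(st, table), st)
    inside_impl = np.zeros(500, dtype=bool)
    inside_impl[shells[0].cargo_ids] = True
    hull = ConvexHull(st.body_pos - 20.0)
    w = _winding_number(pts - 20.0, st.body_pos - 20.0, hull.simplices,
                        hull.equations[:, :3])
    inside_oracle = w > 0.5
    assert (inside_impl == inside_oracle).all()


def test_incomplete_cluster_census_is_flagged(blueprint, table):
    st = state_from_blueprint(blueprint, box=30.0, drop_bodies=(0,))
    st = SimulationState(st.templates, st.body_species, st.body_pos,
                         st.body_quat, np.array([[15.0, 15, 15]]),
                         np.array([0]), 30.0)
    shells, _ = detect_shells(bond_graph(st, table), st)
    cl = encapsulated_cargo(st, shells[0])
    assert not cl.complete
    assert cl.f_r_shell is None
    assert cl.adsorbed_cargo_ids is not None


# ---------------------------------------------------------------------------
# pair counts and mixing metrics
# ---------------------------------------------------------------------------

def test_pair_count_examples(templates):
    def two(p1, p2, s1, s2):
        return SimulationState(templates, np.zeros(0, dtype=np.int64),
                               np.zeros((0, 3)), np.zeros((0, 4)),
                               np.array([p1, p2]), np.array([s1, s2]), 20.0)
    st = two([5.0, 5, 5], [6.0, 5, 5], 0, 0)
    assert cargo_pair_counts(st) == (1, 0, 0)
    st = two([5.0, 5, 5], [6.3, 5, 5], 0, 1)
    assert cargo_pair_counts(st) == (0, 0, 0)
    st = two([5.0, 5, 5], [6.0, 5, 5], 1, 1)
    assert cargo_pair_counts(st) == (0, 1, 0)
    st = two([5.0, 5, 5], [6.1, 5, 5], 0, 1)
    assert cargo_pair_counts(st) == (0, 0, 1)


def test_pair_counts_match_brute_force(templates):
    rng = np.random.default_rng(3)
    pos = rng.uniform(0, 10, (200, 3))
    spc = rng.integers(0, 2, 200)
    st = SimulationState(templates, np.zeros(0, dtype=np.int64),
                         np.zeros((0, 3)), np.zeros((0, 4)), pos, spc, 10.0)
    got = cargo_pair_counts(st, rcut=1.2)
    n = np.zeros(3, dtype=int)
    for i in range(200):
        for j in range(i + 1, 200):
            d = pos[i] - pos[j]
            d -= 10.0 * np.round(d / 10.0)
            if d @ d < 1.2 ** 2:
                n[spc[i] + spc[j]] += 1
    assert got == (int(n[0]), int(n[2]), int(n[1]))


def test_mixing_metric_identities():
    m = mixing_metrics((0, 10, 0), f_r=0.0)
    assert m.f_bar_ul == 0.0 and m.f_rand == 0.0 and m.f_ul == 0.0
    m = mixing_metrics((5, 5, 10), f_r=0.5)
    assert m.f_rand == pytest.approx(0.5)
    assert m.f_bar_ul == pytest.approx(0.5)
    assert m.f_ul == pytest.approx(0.0)
    m = mixing_metrics((0, 0, 0), f_r=0.3)
    assert m.f_bar_ul is None and m.f_ul is None


@given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
       st.floats(0.0, 1.0))
def test_mixing_metric_ranges(n_rr, n_gg, n_rg, f_r):
    m = mixing_metrics((n_rr, n_gg, n_rg), f_r)
    assert 0.0 <= m.f_rand <= 0.5 + 1e-12
    if m.f_bar_ul is not None:
        assert 0.0 <= m.f_bar_ul <= 1.0
        assert -1.0 <= m.f_ul <= 1.0


def _shell_with_fr(f_r):
    return ShellCluster([], 12, 20, True, n_c=10, f_r_shell=f_r)


def test_shell_variability_examples():
    assert shell_variability([_shell_with_fr(0.0), _shell_with_fr(1.0)]) \
        == pytest.approx(0.5)
    assert shell_variability([_shell_with_fr(0.3)] * 4) == pytest.approx(0.0)
    v = shell_variability([_shell_with_fr(x) for x in (0.2, 0.4, 0.6, 0.8)])
    assert v == pytest.approx(np.sqrt(0.05), abs=1e-12)   # ~0.2236
    assert shell_variability([_shell_with_fr(0.5)]) is None


def test_symmetric_mixture_has_no_excess_mixing(templates):
    """A well-mixed random fluid with equal affinities has f_UL = 0 within
    sampling error."""
    from shellcargo.dynamics import RunConfig, init_random, step
    from shellcargo.interactions import InteractionTable
    t = InteractionTable(eps_rr=1.0, eps_gg=1.0, eps_rg=1.0)
    st = init_random(0, 0, 300, 300, box=12.0, seed=4, table=t)
    st = step(st, RunConfig(friction=1.0, seed=5), n=5000, table=t)
    counts = cargo_pair_counts(st)
    f_r = float(np.mean(st.cargo_species == 0))
    m = mixing_metrics(counts, f_r)
    n_pairs = sum(counts)
    assert n_pairs > 200
    assert abs(m.f_ul) < 4.0 / np.sqrt(n_pairs)


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind,expected", [
    ("janus_globule", "demixed_condensate"),
    ("mixed_globule", "mixed_condensate"),
    ("vapor", "homogeneous"),
])
def test_classify_planted_phases(kind, expected):
    st, truth = make_fixture(kind, n=300, box=40.0)
    assert classify_phase(st).label == expected


def test_classify_pure_condensate():
    st, _ = make_fixture("janus_globule", n=200, f_r=1.0, box=40.0)
    ph = classify_phase(st)
    assert ph.label == "one_species_condensate"
    assert ph.dense_f_r > 0.95


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

def test_observables_invariant_under_rotation_and_relabeling(table):
    from scipy.spatial.transform import Rotation as Rot
    st, _ = make_fixture("filled_shell", n=80, box=40.0)
    rec0 = compute_observables(st, table)
    # global rotation about the box center
    rot = Rot.from_rotvec([0.4, 0.1, -0.7])
    st2 = st.copy()
    c = st.box / 2
    st2.body_pos = rot.apply(st2.body_pos - c) + c
    st2.cargo_pos = rot.apply(st2.cargo_pos - c) + c
    q = st2.body_quat[:, [1, 2, 3, 0]]
    st2.body_quat = (rot * Rot.from_quat(q)).as_quat()[:, [3, 0, 1, 2]]
    rec2 = compute_observables(st2, table)
    assert rec2.f_s == rec0.f_s
    assert rec2.mean_n_c == rec0.mean_n_c
    assert rec2.f_r == pytest.approx(rec0.f_r)
    # cargo index relabeling
    rng = np.random.default_rng(5)
    perm = rng.permutation(st.n_cargo)
    st3 = st.copy()
    st3.cargo_pos = st3.cargo_pos[perm]
    st3.cargo_species = st3.cargo_species[perm]
    rec3 = compute_observables(st3, table)
    assert rec3.mean_n_c == rec0.mean_n_c
    assert rec3.f_r == pytest.approx(rec0.f_r)
    assert (rec3.f_ul is None) == (rec0.f_ul is None)
    if rec0.f_ul is not None:
        assert rec3.f_ul == pytest.approx(rec0.f_ul)


def test_no_double_counting_of_encapsulated_cargo(table):
    st, _ = make_fixture("filled_shell", n=120, box=40.0)
    rec = compute_observables(st, table)
    assert sum(s.n_c for s in rec.shells) <= st.n_cargo
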