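"""Subunit templates and the ideal T=3 shell blueprint."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as Rot

import shellcargo.constants as C
from shellcargo.geometry import (ShellBlueprint, SubunitTemplate,
                                 build_shell_blueprint,
                                 build_subunit_template, quat_to_matrix,
                                 matrix_to_quat)


def _attractors(tpl):
    sel = np.isin(tpl.types, C.ATTRACTOR_TYPES)
    return tpl.positions[sel], tpl.types[sel]


@pytest.mark.parametrize("species,n_edges,n_att", [
    ("pentamer", 5, 15),          # 3 attractors on each of 5 edges
    ("hexamer", 6, 21),           # 3 + 4 alternating over 6 edges
])
def test_template_layout(species, n_edges, n_att):
    tpl = build_subunit_template(species)
    apos, atyp = _attractors(tpl)
    assert len(apos) == n_att
    # attractors in the z=0 plane, on the polygon perimeter
    assert np.abs(apos[:, 2]).max() < 1e-12
    verts = np.array([[tpl.circumradius * np.cos(2 * np.pi * k / n_edges),
                       tpl.circumradius * np.sin(2 * np.pi * k / n_edges), 0]
                      for k in range(n_edges)])
    for p in apos:
        d = min(_point_segment_dist(p, verts[k], verts[(k + 1) % n_edges])
                for k in range(n_edges))
        assert d < 1e-12
    # Tops strictly above, Bottoms strictly below the attractor plane
    tops = tpl.positions[np.isin(tpl.types, C.TOP_TYPES)]
    bots = tpl.positions[np.isin(tpl.types, C.BOTTOM_TYPES)]
    assert (tops[:, 2] > 0).all() and (bots[:, 2] < 0).all()
    # Excluders lie in the Top plane
    exc = tpl.positions[tpl.types == C.TYPE_EXC]
    assert np.allclose(exc[:, 2], tops[:, 2].max())


def _point_segment_dist(p, a, b):
    t = np.clip(np.dot(p - a, b - a) / np.dot(b - a, b - a), 0, 1)
    return np.linalg.norm(p - (a + t * (b - a)))


def test_pentamer_fivefold_symmetry():
    """Rotating the pentamer by 72 degrees maps every pseudoatom onto one of
    the same type within 1e-12."""
    tpl = build_subunit_template("pentamer", 1.0)
    r = Rot.from_euler("z", 72, degrees=True).as_matrix()
    rot = tpl.positions @ r.T
    for t in np.unique(tpl.types):
        sub = tpl.positions[tpl.types == t]
        for p in rot[tpl.types == t]:
            assert np.min(np.linalg.norm(sub - p, axis=1)) < 1e-12


def test_hexamer_symmetry_and_edge_classes():
    """Hexamer frame sites have 6-fold symmetry, the attractor layout
    3-fold: exactly 3 of 6 edges carry pentamer-compatible classes."""
    tpl = build_subunit_template("hexamer")
    r6 = Rot.from_euler("z", 60, degrees=True).as_matrix()
    # the non-attractor sites (Tops, Bottoms, Excluders) are 6-fold
    # symmetric; the attractor layout alternates between pentamer- and
    # hexamer-compatible edges and is 3-fold
    non_att = ~np.isin(tpl.types, C.ATTRACTOR_TYPES)
    pos6 = tpl.positions[non_att] @ r6.T
    for p in pos6:
        assert np.min(np.linalg.norm(tpl.positions[non_att] - p,
                                     axis=1)) < 1e-9
    # all sites and classes map under 120 degrees (per-type matching)
    r3 = Rot.from_euler("z", 120, degrees=True).as_matrix()
    pos3 = tpl.positions @ r3.T
    for t in np.unique(tpl.types):
        sub = tpl.positions[tpl.types == t]
        for p in pos3[tpl.types == t]:
            assert np.min(np.linalg.norm(sub - p, axis=1)) < 1e-9
    # exactly 3 edges carry the pentamer-compatible classes (3 attractors
    # each), the other 3 carry 4 hexamer-compatible attractors each
    _, atyp = _attractors(tpl)
    counts = {t: int((atyp == t).sum()) for t in np.unique(atyp)}
    assert counts == {C.ATT_HL: 3, C.ATT_HM: 3, C.ATT_HR: 3,
                      C.ATT_GL2: 3, C.ATT_GL1: 3, C.ATT_GR1: 3,
                      C.ATT_GR2: 3}


def test_template_mass_inertia():
    tpl = build_subunit_template("hexamer")
    # center of mass at the origin, diagonal inertia, symmetric top
    com = (tpl.site_mass[:, None] * tpl.positions).sum(axis=0) / tpl.mass
    assert np.abs(com).max() < 1e-12
    assert np.allclose(tpl.inertia_tensor, np.diag(tpl.inertia))
    assert abs(tpl.inertia[0] - tpl.inertia[1]) < 1e-9


def test_template_errors():
    with pytest.raises(ValueError):
        build_subunit_template("trimer")
    with pytest.raises(ValueError):
        build_subunit_template("pentamer", -1.0)


def test_template_json_roundtrip():
    tpl = build_subunit_template("pentamer")
    tpl2 = SubunitTemplate.from_json(tpl.to_json())
    assert np.allclose(tpl.positions, tpl2.positions)
    assert (tpl.types == tpl2.types).all()
    assert tpl.mass == tpl2.mass


# ---------------------------------------------------------------------------
# blueprint
# ---------------------------------------------------------------------------

def test_blueprint_census(blueprint):
    assert blueprint.n_subunits == 32
    assert blueprint.n_pentamers == 12
    assert blueprint.n_hexamers == 20
    census = blueprint.edge_census()
    assert len(blueprint.edges) == 90
    assert census["pent-hex"] == 60
    assert census["hex-hex"] == 30


def test_blueprint_edge_census_brute_force(blueprint):
    """Independent adjacency count: two subunits are in contact iff they
    share coincident complementary attractor pairs (brute-force scan)."""
    pos, typ, bod = blueprint.site_positions()
    comp = np.zeros((10, 10), dtype=bool)
    for a, b in C.COMPLEMENTARY_PAIRS:
        comp[a, b] = comp[b, a] = True
    att = np.isin(typ, C.ATTRACTOR_TYPES)
    pos, typ, bod = pos[att], typ[att], bod[att]
    found = {}
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if bod[i] == bod[j] or not comp[typ[i], typ[j]]:
                continue
            if np.linalg.norm(pos[i] - pos[j]) < 1e-8:
                key = (min(bod[i], bod[j]), max(bod[i], bod[j]))
                found[key] = found.get(key, 0) + 1
    assert len(found) == 90
    # 3 bonds on pentamer-hexamer contacts, 4 on hexamer-hexamer
    species = blueprint.species
    for (i, j), n in found.items():
        expected = 4 if species[i] == species[j] == "hexamer" else 3
        assert n == expected
    assert sum(found.values()) == 60 * 3 + 30 * 4


def test_blueprint_degrees(blueprint):
    """Each pentamer has 5 neighbors, each hexamer 3 pentamers + 3 hexamers."""
    import networkx as nx
    g = nx.Graph()
    for i, j, _ in blueprint.edges:
        g.add_edge(i, j)
    for n in range(32):
        nbrs = list(g.neighbors(n))
        if blueprint.species[n] == "pentamer":
            assert len(nbrs) == 5
            assert all(blueprint.species[m] == "hexamer" for m in nbrs)
        else:
            assert len(nbrs) == 6
            kinds = [blueprint.species[m] for m in nbrs]
            assert kinds.count("pentamer") == 3
            assert kinds.count("hexamer") == 3


def test_blueprint_icosahedral_invariance(blueprint):
    """The placement set is invariant under all 60 rotations of the
    icosahedral rotation group (generated by brute-force closure)."""
    axes = blueprint.centers[:12]
    r5 = Rot.from_rotvec(axes[0] / np.linalg.norm(axes[0]) * 2 * np.pi / 5)
    # a two-fold axis through the midpoint of two adjacent pentamer centers
    d = np.linalg.norm(axes - axes[0], axis=1)
    j = int(np.argsort(d)[1])
    mid = 0.5 * (axes[0] + axes[j])
    r2 = Rot.from_rotvec(mid / np.linalg.norm(mid) * np.pi)
    group = {}
    frontier = [np.eye(3)]
    while frontier:
        m = frontier.pop()
        key = tuple(np.round(m.ravel(), 6))
        if key in group:
            continue
        group[key] = m
        for g in (r5.as_matrix(), r2.as_matrix()):
            frontier.append(g @ m)
    assert len(group) == 60
    centers = blueprint.centers
    for m in group.values():
        mapped = centers @ m.T
        for p in mapped:
            assert np.min(np.linalg.norm(centers - p, axis=1)) < 1e-6


def test_blueprint_is_local_energy_minimum(blueprint, table):
    """Random small rigid perturbations (<= 0.01 r*) never lower the energy
    of the relaxed blueprint over 1000 trials."""
    from conftest import rigid_perturb

    from shellcargo.interactions import FrozenPairEvaluator, relax_state
    from shellcargo.state import state_from_blueprint
    st = relax_state(state_from_blueprint(blueprint, box=20.0), table)
    ev = FrozenPairEvaluator(st, table, skin=0.3)
    e0, _, _ = ev.forces(st.body_pos, st.body_quat)
    rng = np.random.default_rng(0)
    for _ in range(1000):
        pert = rigid_perturb(st, rng, 0.01)
        e, _, _ = ev.forces(pert.body_pos, pert.body_quat)
        assert e >= e0 - 1e-9


def test_blueprint_incompatible_inputs():
    with pytest.raises(ValueError, match="incommensurate"):
        build_shell_blueprint(build_subunit_template("pentamer", 1.0),
                              build_subunit_template("hexamer", 1.0))
    with pytest.raises(ValueError, match="shell_radius"):
        build_shell_blueprint(shell_radius=5.0)


def test_blueprint_json(blueprint):
    import json
    d = json.loads(blueprint.to_json())
    assert len(d["species"]) == 32
    assert len(d["edges"]) == 90


def test_quaternion_matrix_roundtrip():
    rng = np.random.default_rng(3)
    for _ in range(50):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        m = quat_to_matrix(q)
        q2 = matrix_to_quat(m)
        assert np.allclose(quat_to_matrix(q2), m, atol=1e-12)
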