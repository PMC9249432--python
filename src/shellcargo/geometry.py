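"""Body-frame subunit templates and the ideal T=3 shell blueprint.

The shell is a truncated icosahedron: 12 pentameric subunits on the sites of
an icosahedron's vertices and 20 hexameric subunits on its faces, giving 90
edge contacts (60 pentamer-hexamer, 30 hexamer-hexamer).  Each rigid subunit
carries four classes of pseudoatoms:

* Attractors on the perimeter (in the z=0 body plane) that drive edge-edge
  binding through short-range Morse attractions between complementary
  classes;
* Top and Bottom pseudoatoms at z = +/-h: one pair just inside each edge
  midpoint, whose cross-subunit repulsions select the preferred dihedral
  angle (spontaneous curvature), and one axial pair for central excluded
  volume and (hexamer Bottom) cargo binding;
* Excluders in the Top plane that provide shell-cargo excluded volume.

Excluders are interaction-only sites and carry no mass, so the center of
mass and the principal frame of every subunit coincide with the geometric
center and the attractor plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import constants as C

__all__ = [
    "SubunitTemplate",
    "ShellBlueprint",
    "build_subunit_template",
    "build_shell_blueprint",
    "quat_to_matrix",
    "matrix_to_quat",
]

KIND_NAMES = {**{t: "Attractor" for t in C.ATTRACTOR_TYPES},
              **{t: "Top" for t in C.TOP_TYPES},
              **{t: "Bottom" for t in C.BOTTOM_TYPES},
              C.TYPE_EXC: "Excluder"}


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) from a proper rotation matrix."""
    t = np.trace(m)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        q = np.array([0.25 * s, (m[2, 1] - m[1, 2]) / s,
                      (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s])
    else:
        i = int(np.argmax(np.diag(m)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1.0 + m[i, i] - m[j, j] - m[k, k]) * 2
        q = np.empty(4)
        q[0] = (m[k, j] - m[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (m[j, i] + m[i, j]) / s
        q[1 + k] = (m[k, i] + m[i, k]) / s
    return q / np.linalg.norm(q)


@dataclass
class SubunitTemplate:
    """Rigid-body pseudoatom layout of one shell subunit (body frame).

    ``positions`` are in the body frame with the attractor plane at z = 0
    and the n-fold symmetry axis along z; Top points at +z ("outside" of an
    assembled shell), Bottom at -z (cargo side).
    """

    species: str                      # "pentamer" | "hexamer"
    circumradius: float
    positions: np.ndarray             # (n_sites, 3)
    types: np.ndarray                 # (n_sites,) int site-type codes
    site_mass: np.ndarray             # (n_sites,) 1 for massive sites, 0 excluders
    mass: float = field(init=False)
    inertia: np.ndarray = field(init=False)   # principal moments (3,)

    def __post_init__(self) -> None:
        self.mass = float(self.site_mass.sum())
        r = self.positions
        m = self.site_mass
        it = np.zeros((3, 3))
        for mi, ri in zip(m, r):
            it += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
        off = np.abs(it - np.diag(np.diag(it))).max()
        if off > 1e-9:
            raise ValueError("template inertia tensor is not diagonal in the body frame")
        self.inertia = np.diag(it).copy()

    # -- spec-facing views ---------------------------------------------------
    @property
    def inertia_tensor(self) -> np.ndarray:
        return np.diag(self.inertia)

    @property
    def n_edges(self) -> int:
        return 5 if self.species == "pentamer" else 6

    def pseudoatoms(self):
        """List of (position, kind, attractor_class or None)."""
        out = []
        for p, t in zip(self.positions, self.types):
            out.append((p.copy(), KIND_NAMES[int(t)],
                        C.ATTRACTOR_CLASS_NAMES.get(int(t))))
        return out

    def to_json(self) -> str:
        return json.dumps({
            "species": self.species,
            "circumradius": self.circumradius,
            "positions": self.positions.tolist(),
            "types": self.types.tolist(),
            "site_mass": self.site_mass.tolist(),
        })

    @classmethod
    def from_json(cls, s: str) -> "SubunitTemplate":
        d = json.loads(s)
        return cls(d["species"], d["circumradius"], np.asarray(d["positions"]),
                   np.asarray(d["types"], dtype=np.int64),
                   np.asarray(d["site_mass"], dtype=float))


def _polygon_vertices(n: int, radius: float) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            np.zeros(n)])


def build_subunit_template(species: str, circumradius: float | None = None) -> SubunitTemplate:
    """Construct the body-frame pseudoatom template for one subunit.

    Parameters
    ----------
    species
        ``"pentamer"`` or ``"hexamer"``.
    circumradius
        Distance from the subunit center to its vertices, in r*.  Defaults
        to 1 (pentamer) and to the common edge length (hexamer) so that the
        two species have commensurate edges.

    Hexamer edges alternate between pentamer-compatible attractor classes
    (edges 0, 2, 4: three attractors) and hexamer-compatible classes
    (edges 1, 3, 5: four attractors), so only three of the six hexamer edges
    can bind pentamers.  Pentamer edges never bind each other.
    """
    if species == "pentamer":
        default_r = C.PENTAMER_CIRCUMRADIUS
        n = 5
    elif species == "hexamer":
        default_r = C.HEXAMER_CIRCUMRADIUS
        n = 6
    else:
        raise ValueError(f"unknown subunit species: {species!r}")
    if circumradius is None:
        circumradius = default_r
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    scale = circumradius / default_r

    verts = _polygon_vertices(n, circumradius)
    h = C.TB_HEIGHT * scale

    pos, typ, msk = [], [], []

    def add(p, t, massive=True):
        pos.append(np.asarray(p, dtype=float))
        typ.append(t)
        msk.append(1.0 if massive else 0.0)

    t_edge = C.TYPE_TP_E if species == "pentamer" else C.TYPE_TH_E
    b_edge = C.TYPE_BP_E if species == "pentamer" else C.TYPE_BH_E
    inset_t = C.EDGE_TOP_INSET * scale
    inset_b = C.EDGE_BOTTOM_INSET * scale
    for k in range(n):
        a, b = verts[k], verts[(k + 1) % n]
        if species == "pentamer":
            fracs, classes = C.ATT_FRAC_PENT_EDGE, (C.ATT_PL, C.ATT_PM, C.ATT_PR)
        elif k % 2 == 0:
            fracs, classes = C.ATT_FRAC_PENT_EDGE, (C.ATT_HL, C.ATT_HM, C.ATT_HR)
        else:
            fracs, classes = (C.ATT_FRAC_HEX_EDGE,
                              (C.ATT_GL2, C.ATT_GL1, C.ATT_GR1, C.ATT_GR2))
        for f, cl in zip(fracs, classes):
            add(a + f * (b - a), cl)
        # edge Top/Bottom: just inside the edge midpoint, at z = +/- h
        mid = 0.5 * (a + b)
        ap = np.linalg.norm(mid)
        add(mid * (1.0 - inset_t / ap) + np.array([0.0, 0.0, h]), t_edge)
        add(mid * (1.0 - inset_b / ap) - np.array([0.0, 0.0, h]), b_edge)

    add([0.0, 0.0, h], C.TYPE_TP_A if species == "pentamer" else C.TYPE_TH_A)
    add([0.0, 0.0, -h], C.TYPE_BP_A if species == "pentamer" else C.TYPE_BH_A)
    # Excluders: massless interaction sites in the Top plane (center + ring).
    add([0.0, 0.0, h], C.TYPE_EXC, massive=False)
    for v in verts:
        add([v[0], v[1], h], C.TYPE_EXC, massive=False)

    return SubunitTemplate(species, float(circumradius),
                           np.array(pos), np.array(typ, dtype=np.int64),
                           np.array(msk))


# ---------------------------------------------------------------------------
# Truncated icosahedron blueprint
# ---------------------------------------------------------------------------

def _icosahedron():
    phi = (1 + np.sqrt(5)) / 2
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [[0, a, b], [a, b, 0], [b, 0, a]]
    v = np.array(v)
    # edges: pairs at minimal distance 2
    d = np.linalg.norm(v[:, None] - v[None, :], axis=-1)
    edges = [(i, j) for i in range(12) for j in range(i + 1, 12)
             if abs(d[i, j] - 2.0) < 1e-9]
    faces = []
    for i in range(12):
        for j in range(i + 1, 12):
            for k in range(j + 1, 12):
                if (abs(d[i, j] - 2) < 1e-9 and abs(d[j, k] - 2) < 1e-9
                        and abs(d[i, k] - 2) < 1e-9):
                    faces.append((i, j, k))
    assert len(edges) == 30 and len(faces) == 20
    return v, edges, faces


def _order_ccw(points: np.ndarray, center: np.ndarray, normal: np.ndarray):
    """Indices ordering `points` counterclockwise about `normal` seen from outside."""
    x = points[0] - center
    x -= np.dot(x, normal) * normal
    x /= np.linalg.norm(x)
    y = np.cross(normal, x)
    ang = np.arctan2((points - center) @ y, (points - center) @ x)
    return np.argsort(ang)


@dataclass
class ShellBlueprint:
    """Ideal complete T=3 shell: subunit placements plus contact topology."""

    templates: dict                     # {"pentamer": tpl, "hexamer": tpl}
    species: list                       # per subunit, "pentamer"/"hexamer"
    centers: np.ndarray                 # (32, 3)
    quats: np.ndarray                   # (32, 4) (w,x,y,z)
    edges: list                         # [(i, j, "pent-hex"|"hex-hex"), ...]
    radius_pent: float = 0.0            # distance of pentamer centers from origin
    radius_hex: float = 0.0

    @property
    def n_subunits(self) -> int:
        return len(self.species)

    @property
    def n_pentamers(self) -> int:
        return sum(1 for s in self.species if s == "pentamer")

    @property
    def n_hexamers(self) -> int:
        return sum(1 for s in self.species if s == "hexamer")

    def edge_census(self):
        from collections import Counter
        return Counter(t for _, _, t in self.edges)

    def to_json(self) -> str:
        return json.dumps({
            "species": self.species,
            "centers": self.centers.tolist(),
            "quats": self.quats.tolist(),
            "edges": [[i, j, t] for i, j, t in self.edges],
            "templates": {k: json.loads(v.to_json())
                          for k, v in self.templates.items()},
        })

    def site_positions(self):
        """All pseudoatom lab-frame positions and types (for export/tests)."""
        pos, typ, body = [], [], []
        for b, (sp, c, q) in enumerate(zip(self.species, self.centers, self.quats)):
            tpl = self.templates[sp]
            R = quat_to_matrix(q)
            pos.append(c + tpl.positions @ R.T)
            typ.append(tpl.types)
            body.append(np.full(len(tpl.types), b))
        return np.concatenate(pos), np.concatenate(typ), np.concatenate(body)


def build_shell_blueprint(pent: SubunitTemplate | None = None,
                          hexa: SubunitTemplate | None = None,
                          shell_radius: float | None = None,
                          tol: float = 1e-6) -> ShellBlueprint:
    """Place 12 pentamers and 20 hexamers on a truncated icosahedron.

    Pentamer centers sit above the icosahedron vertices, hexamer centers on
    its faces; bonded edges of neighboring subunits coincide, so every
    complementary attractor pair meets at zero separation (the Morse
    minimum).  Raises if the two templates' edge lengths are incommensurate
    or if an explicit ``shell_radius`` is incompatible with the subunit size.
    """
    pent = pent or build_subunit_template("pentamer")
    hexa = hexa or build_subunit_template("hexamer")
    s_p = 2 * pent.circumradius * np.sin(np.pi / 5)
    s_h = hexa.circumradius
    if abs(s_p - s_h) > 1e-6 * max(s_p, s_h):
        raise ValueError(
            f"incommensurate subunit edges: pentamer edge {s_p:.6f} r*, "
            f"hexamer edge {s_h:.6f} r* - bonded edges would leave gaps/overlaps")
    edge = s_p

    iv, _, ifaces = _icosahedron()
    # truncation points: one per (vertex, adjacent vertex) directed pair
    tp = {}
    verts = []
    d = np.linalg.norm(iv[:, None] - iv[None, :], axis=-1)
    for i in range(12):
        for j in range(12):
            if abs(d[i, j] - 2.0) < 1e-9:
                tp[(i, j)] = len(verts)
                verts.append(iv[i] + (iv[j] - iv[i]) / 3.0)
    verts = np.array(verts)
    # every edge of the 1/3-truncation has length |icosa edge|/3 = 2/3;
    # scale so it equals the subunit edge length
    scale = edge / (2.0 / 3.0)
    verts *= scale

    natural_rp = None

    species, centers, quats, face_verts = [], [], [], []

    # pentagon faces (one per icosahedron vertex)
    for i in range(12):
        nbrs = [j for j in range(12) if abs(d[i, j] - 2.0) < 1e-9]
        pts_idx = np.array([tp[(i, j)] for j in nbrs])
        pts = verts[pts_idx]
        c = pts.mean(axis=0)
        nrm = c / np.linalg.norm(c)
        order = _order_ccw(pts, c, nrm)
        pts_idx = pts_idx[order]
        pts = pts[order]
        x = pts[0] - c
        x -= np.dot(x, nrm) * nrm
        x /= np.linalg.norm(x)
        y = np.cross(nrm, x)
        R = np.column_stack([x, y, nrm])
        species.append("pentamer")
        centers.append(c)
        quats.append(matrix_to_quat(R))
        face_verts.append(list(pts_idx))
        natural_rp = np.linalg.norm(c)

    # hexagon faces (one per icosahedron face); edges alternate between
    # pentagon-adjacent and hexagon-adjacent, so start the vertex ordering at
    # a pentagon-adjacent edge to match the template's edge classes.
    vert_owner = {}          # truncated vertex -> icosa vertex it belongs to
    for (i, j), k in tp.items():
        vert_owner[k] = i
    for (i, j, k) in ifaces:
        idx = [tp[(i, j)], tp[(j, i)], tp[(j, k)], tp[(k, j)], tp[(k, i)], tp[(i, k)]]
        pts = verts[idx]
        c = pts.mean(axis=0)
        nrm = c / np.linalg.norm(c)
        order = _order_ccw(pts, c, nrm)
        idx = [idx[o] for o in order]
        # rotate so that edge (0 -> 1) joins two vertices owned by the same
        # icosahedron vertex (i.e. a pentagon-adjacent edge)
        for r0 in range(6):
            if vert_owner[idx[r0]] == vert_owner[idx[(r0 + 1) % 6]]:
                break
        else:  # pragma: no cover - geometry guarantees a pentagon edge
            raise RuntimeError("no pentagon-adjacent edge found on hexagon face")
        idx = idx[r0:] + idx[:r0]
        pts = verts[idx]
        x = pts[0] - c
        x -= np.dot(x, nrm) * nrm
        x /= np.linalg.norm(x)
        y = np.cross(nrm, x)
        R = np.column_stack([x, y, nrm])
        species.append("hexamer")
        centers.append(c)
        quats.append(matrix_to_quat(R))
        face_verts.append(idx)

    centers = np.array(centers)
    quats = np.array(quats)

    if shell_radius is not None and abs(shell_radius - natural_rp) > max(tol, 1e-6):
        raise ValueError(
            f"shell_radius {shell_radius:.6f} incompatible with subunit "
            f"circumradius (pentamer centers sit at {natural_rp:.6f} r* for "
            f"edge length {edge:.6f} r*)")

    # contacts: faces sharing two vertices
    edges = []
    nf = len(face_verts)
    for a in range(nf):
        sa = set(face_verts[a])
        for b in range(a + 1, nf):
            if len(sa & set(face_verts[b])) == 2:
                ta = species[a], species[b]
                if ta == ("pentamer", "pentamer"):
                    raise RuntimeError("unexpected pentamer-pentamer contact")
                kind = "hex-hex" if ta == ("hexamer", "hexamer") else "pent-hex"
                edges.append((a, b, kind))

    bp = ShellBlueprint({"pentamer": pent, "hexamer": hexa}, species, centers,
                        quats, edges,
                        radius_pent=float(np.linalg.norm(centers[0])),
                        radius_hex=float(np.linalg.norm(centers[12])))
    _validate_blueprint(bp)
    return bp


def _validate_blueprint(bp: ShellBlueprint) -> None:
    census = bp.edge_census()
    if bp.n_pentamers != 12 or bp.n_hexamers != 20:
        raise RuntimeError("blueprint stoichiometry is not 12 + 20")
    if census.get("pent-hex") != 60 or census.get("hex-hex") != 30:
        raise RuntimeError(f"blueprint adjacency wrong: {dict(census)}")
    # bonded edges must bring complementary attractors into near-coincidence
    pos, typ, body = bp.site_positions()
    comp = {frozenset(p) for p in C.COMPLEMENTARY_PAIRS}
    for i, j, _ in bp.edges:
        ai = (body == i) & np.isin(typ, C.ATTRACTOR_TYPES)
        aj = (body == j) & np.isin(typ, C.ATTRACTOR_TYPES)
        n_hit = 0
        for pa, ta in zip(pos[ai], typ[ai]):
            for pb, tb in zip(pos[aj], typ[aj]):
                if frozenset((int(ta), int(tb))) in comp and \
                        np.linalg.norm(pa - pb) < 1e-6:
                    n_hit += 1
        expect = 4 if _ == "hex-hex" else 3
        if n_hit != expect:
            raise RuntimeError(
                f"edge ({i},{j},{_}): {n_hit} coincident complementary "
                f"attractor pairs, expected {expect}")


_PAIR_FLAVORS = {
    # dict key -> (type code on pentamer side / first subunit, type code on hexamer)
    "hex-hex": {("TH_E", "TH_E"): (C.TYPE_TH_E, C.TYPE_TH_E),
                ("BH_E", "BH_E"): (C.TYPE_BH_E, C.TYPE_BH_E),
                ("TH_A", "TH_A"): (C.TYPE_TH_A, C.TYPE_TH_A),
                ("BH_A", "BH_A"): (C.TYPE_BH_A, C.TYPE_BH_A)},
    "pent-hex": {("TP_E", "TH_E"): (C.TYPE_TP_E, C.TYPE_TH_E),
                 ("BP_E", "BH_E"): (C.TYPE_BP_E, C.TYPE_BH_E),
                 ("TP_A", "TH_A"): (C.TYPE_TP_A, C.TYPE_TH_A),
                 ("BP_A", "BH_A"): (C.TYPE_BP_A, C.TYPE_BH_A)},
}


def hinge_pair_distances(delta: float = 0.0, blueprint: ShellBlueprint | None = None):
    """Minimal Top-Top and Bottom-Bottom distances across bonded blueprint
    edges after hinging one partner by ``delta`` (radians) about the shared
    edge axis.

    For Top flavors the hinge direction that brings the Tops together
    (flattening) is used; for Bottom flavors the direction that brings the
    Bottoms together (over-bending).  The returned distances define the
    curvature-selecting WCA cutoffs: with cutoffs placed at them, neither
    repulsion acts within +/- delta of the ideal dihedral angle and each
    engages past it on its own side.  Keys are name pairs such as
    ``("TH_E", "TH_E")`` (hexamer-hexamer edge Tops) or ``("BP_E", "BH_E")``
    (pentamer-hexamer edge Bottoms), plus the axial ``*_A`` analogues.
    """
    from scipy.spatial.transform import Rotation as Rot

    bp = blueprint or build_shell_blueprint()
    tpl = bp.templates
    out = {}
    for (i, j, kind) in bp.edges:
        if kind == "pent-hex" and bp.species[i] == "hexamer":
            i, j = j, i  # put the pentamer first
        flavors = _PAIR_FLAVORS[kind]
        if all(k in out for k in flavors):
            continue
        Ri, Rj = quat_to_matrix(bp.quats[i]), quat_to_matrix(bp.quats[j])
        ti, tj = tpl[bp.species[i]], tpl[bp.species[j]]
        pi = bp.centers[i] + ti.positions @ Ri.T
        pj = bp.centers[j] + tj.positions @ Rj.T
        ai = pi[np.isin(ti.types, C.ATTRACTOR_TYPES)]
        aj = pj[np.isin(tj.types, C.ATTRACTOR_TYPES)]
        shared = np.array([a for a in ai
                           if np.min(np.linalg.norm(aj - a, axis=1)) < 1e-8])
        axis = shared[-1] - shared[0]
        axis /= np.linalg.norm(axis)
        origin = shared.mean(axis=0)

        def mindist(code_i, code_j, ang):
            r = Rot.from_rotvec(ang * axis).as_matrix()
            qi = pi[ti.types == code_i]
            qj = origin + (pj[tj.types == code_j] - origin) @ r.T
            return float(np.min(np.linalg.norm(qi[:, None] - qj[None, :], axis=-1)))

        for key, (ci, cj) in flavors.items():
            if key in out:
                continue
            if delta == 0.0:
                out[key] = mindist(ci, cj, 0.0)
            else:
                # the repulsion must engage on its own side of the window
                out[key] = min(mindist(ci, cj, delta), mindist(ci, cj, -delta))
    return out
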