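"""Simulation state container: rigid subunits + point cargo in a periodic box."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .geometry import ShellBlueprint, SubunitTemplate, build_subunit_template

PENTAMER, HEXAMER = 0, 1
SPECIES_R, SPECIES_G = 0, 1


@dataclass
class SimulationState:
    """Positions/orientations of rigid subunits plus cargo particles.

    Subunit orientations are unit quaternions (w, x, y, z); angular momenta
    are stored in the body (principal) frame.  All lengths are in r*,
    energies in k_B*T, masses in pseudoatom masses.
    """

    templates: dict                    # {"pentamer": tpl, "hexamer": tpl}
    body_species: np.ndarray           # (Nb,) 0 = pentamer, 1 = hexamer
    body_pos: np.ndarray               # (Nb, 3)
    body_quat: np.ndarray              # (Nb, 4)
    cargo_pos: np.ndarray              # (Nc, 3)
    cargo_species: np.ndarray          # (Nc,) 0 = R, 1 = G
    box: float
    time: float = 0.0
    body_vel: np.ndarray = None
    body_angmom: np.ndarray = None     # body-frame angular momentum
    cargo_vel: np.ndarray = None
    body_fixed: np.ndarray = None      # bool: excluded from integration

    def __post_init__(self):
        nb, nc = len(self.body_species), len(self.cargo_pos)
        if len(self.cargo_species) != nc:
            raise ValueError("cargo_species and cargo_pos lengths differ")
        if len(self.body_pos) != nb or len(self.body_quat) != nb:
            raise ValueError("body array lengths differ")
        self.body_species = np.asarray(self.body_species, dtype=np.int64)
        self.body_pos = np.ascontiguousarray(self.body_pos, dtype=float).reshape(nb, 3)
        self.body_quat = np.ascontiguousarray(self.body_quat, dtype=float).reshape(nb, 4)
        self.cargo_pos = np.ascontiguousarray(self.cargo_pos, dtype=float).reshape(nc, 3)
        self.cargo_species = np.asarray(self.cargo_species, dtype=np.int64)
        if self.body_vel is None:
            self.body_vel = np.zeros((nb, 3))
        if self.body_angmom is None:
            self.body_angmom = np.zeros((nb, 3))
        if self.cargo_vel is None:
            self.cargo_vel = np.zeros((nc, 3))
        if self.body_fixed is None:
            self.body_fixed = np.zeros(nb, dtype=bool)

    # ------------------------------------------------------------------
    @property
    def n_bodies(self) -> int:
        return len(self.body_species)

    @property
    def n_cargo(self) -> int:
        return len(self.cargo_pos)

    @property
    def n_pentamers(self) -> int:
        return int(np.sum(self.body_species == PENTAMER))

    @property
    def n_hexamers(self) -> int:
        return int(np.sum(self.body_species == HEXAMER))

    def copy(self) -> "SimulationState":
        return SimulationState(
            self.templates, self.body_species.copy(), self.body_pos.copy(),
            self.body_quat.copy(), self.cargo_pos.copy(),
            self.cargo_species.copy(), self.box, self.time,
            self.body_vel.copy(), self.body_angmom.copy(),
            self.cargo_vel.copy(), self.body_fixed.copy())

    def template_for(self, b: int) -> SubunitTemplate:
        return self.templates["pentamer" if self.body_species[b] == PENTAMER
                              else "hexamer"]

    def wrap(self) -> None:
        """Wrap body centers and cargo into the primary box [0, L)."""
        self.body_pos %= self.box
        self.cargo_pos %= self.box

    # ------------------------------------------------------------------
    def site_arrays(self):
        """Flattened static site topology + current site positions.

        Returns (site_rel, site_type, site_body, site_pos): subunit
        pseudoatoms first (grouped by body), then one site per cargo
        particle (site_body = -1).  Site positions of a body are expressed
        relative to its (possibly wrapped) center, i.e. they are never
        wrapped themselves; pair distances use the minimum-image convention.
        """
        rel, typ, bod = _site_topology(self.templates, self.body_species,
                                       self.cargo_species)
        pos = np.empty((len(typ), 3))
        _fill_site_positions(pos, rel, bod, self.body_pos, self.body_quat,
                             self.cargo_pos)
        return rel, typ, bod, pos


def _site_topology(templates, body_species, cargo_species):
    key = (id(templates["pentamer"]), id(templates["hexamer"]),
           body_species.tobytes(), cargo_species.tobytes())
    cached = _TOPO_CACHE.get(key)
    if cached is not None:
        return cached
    rel_list, typ_list, bod_list = [], [], []
    for b, sp in enumerate(body_species):
        tpl = templates["pentamer" if sp == PENTAMER else "hexamer"]
        rel_list.append(tpl.positions)
        typ_list.append(tpl.types)
        bod_list.append(np.full(len(tpl.types), b, dtype=np.int64))
    nc = len(cargo_species)
    rel_list.append(np.zeros((nc, 3)))
    typ_list.append(np.where(cargo_species == SPECIES_R,
                             C.TYPE_CARGO_R, C.TYPE_CARGO_G).astype(np.int64))
    bod_list.append(np.full(nc, -1, dtype=np.int64))
    out = (np.ascontiguousarray(np.concatenate(rel_list), dtype=float),
           np.concatenate(typ_list),
           np.concatenate(bod_list))
    if len(_TOPO_CACHE) > 32:
        _TOPO_CACHE.clear()
    _TOPO_CACHE[key] = out
    return out


_TOPO_CACHE: dict = {}


def _fill_site_positions(pos, rel, bod, body_pos, body_quat, cargo_pos):
    from ._nb import fill_site_positions
    fill_site_positions(pos, rel, bod, body_pos, body_quat, cargo_pos)


def default_templates() -> dict:
    return {"pentamer": build_subunit_template("pentamer"),
            "hexamer": build_subunit_template("hexamer")}


def state_from_blueprint(bp: ShellBlueprint, box: float,
                         center: np.ndarray | None = None,
                         drop_bodies: tuple = (),
                         fixed: bool = False) -> SimulationState:
    """Embed a shell blueprint in a periodic box (no cargo).

    ``drop_bodies`` removes the given subunit indices (e.g. one pentamer for
    the permeable-shell protocol); ``fixed=True`` marks all bodies immobile.
    """
    keep = [i for i in range(bp.n_subunits) if i not in set(drop_bodies)]
    if center is None:
        center = np.full(3, box / 2.0)
    species = np.array([PENTAMER if bp.species[i] == "pentamer" else HEXAMER
                        for i in keep])
    st = SimulationState(
        templates=bp.templates,
        body_species=species,
        body_pos=bp.centers[keep] + center,
        body_quat=bp.quats[keep],
        cargo_pos=np.zeros((0, 3)),
        cargo_species=np.zeros(0, dtype=np.int64),
        box=float(box))
    if fixed:
        st.body_fixed[:] = True
    return st
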