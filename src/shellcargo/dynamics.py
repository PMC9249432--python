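"""Rigid-body Langevin dynamics in a periodic cubic box.

Subunits are rigid bodies integrated with a BAOAB splitting: velocity/angular
momentum half-kicks (B), free drift with a symplectic Trotterized free-rotor
quaternion update (A), and an Ornstein-Uhlenbeck thermostat step (O) applied
to both linear velocities and body-frame angular momenta.  With zero friction
the scheme reduces to a symplectic NVE rigid-body integrator.  Cargo
particles are point masses integrated by the same splitting without the
rotational part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import constants as C
from ._nb import (_grid_fill, ef_pairs_lin, fill_site_positions, quat_mul,
                  quat_to_mat, reduce_body_forces, max_displacement2)
from .interactions import InteractionTable
from .state import PENTAMER, SimulationState, default_templates

__all__ = ["RunConfig", "init_random", "step", "IntegrationError"]


class IntegrationError(RuntimeError):
    """Raised when a coordinate becomes non-finite (instability diagnostic)."""


@dataclass
class RunConfig:
    """Langevin integration parameters (reduced units, k_B T = 1).

    ``friction`` is the translational drag coefficient (mass/time), the same
    for every body, so all species share the long-time diffusion constant
    D = kT / friction (the Einstein relation).  Rotational drag uses the
    same per-body relaxation rate.  friction = 0 gives symplectic NVE
    dynamics."""

    timestep: float = C.DEFAULT_TIMESTEP
    n_steps: int = 0
    temperature: float = C.DEFAULT_TEMPERATURE
    friction: float = C.DEFAULT_FRICTION
    seed: int = 0
    thermostat_stride: int = 4

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")


# ---------------------------------------------------------------------------
# random initial conditions
# ---------------------------------------------------------------------------

def _random_quat(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def init_random(n_pentamers: int, n_hexamers: int, n_cargo_r: int,
                n_cargo_g: int, box: float, seed: int,
                min_separation: float = 0.9, templates: dict | None = None,
                max_attempts: int = 400,
                table: InteractionTable | None = None) -> SimulationState:
    """Uniformly random, non-overlapping initial configuration.

    Positions and orientations are sampled uniformly; a candidate is
    rejected if any of its pseudoatoms comes within ``min_separation`` of an
    already placed pseudoatom, or inside the repulsive core of an
    interacting pair (so the initial potential energy carries no significant
    overlaps).  Minimum-image convention; reproducible for a given seed.
    """
    templates = templates or default_templates()
    table = table or InteractionTable()
    t = table.compile()
    # per-type-pair exclusion distance: repulsive-core extent (WCA cutoff)
    # for repulsive pairs, the LJ/Morse core radius for attractive ones,
    # floored at min_separation
    import math
    T = t.kind.shape[0]
    dmin = np.full((T, T), float(min_separation))
    for a in range(T):
        for b in range(T):
            k = t.kind[a, b]
            if k == 2:  # WCA: exclude the whole repulsive range
                dmin[a, b] = max(dmin[a, b], math.sqrt(t.rcut2[a, b]))
            elif k == 3:  # LJ: exclude inside sigma
                dmin[a, b] = max(dmin[a, b], t.par[a, b])
    dmin2 = dmin ** 2

    rng = np.random.default_rng(seed)
    placed = np.zeros((0, 3))
    placed_typ = np.zeros(0, dtype=np.int64)

    def too_close(pts, ptyp):
        if placed.shape[0] == 0:
            return False
        d = placed[None, :, :] - pts[:, None, :]
        d -= box * np.round(d / box)
        d2 = np.einsum("ijk,ijk->ij", d, d)
        return bool((d2 < dmin2[ptyp[:, None], placed_typ[None, :]]).any())

    species, centers, quats = [], [], []
    for sp, count in ((0, n_pentamers), (1, n_hexamers)):
        tpl = templates["pentamer" if sp == PENTAMER else "hexamer"]
        for _ in range(count):
            for attempt in range(max_attempts):
                c = rng.uniform(0.0, box, size=3)
                q = _random_quat(rng)
                from .geometry import quat_to_matrix
                pts = c + tpl.positions @ quat_to_matrix(q).T
                if not too_close(pts, tpl.types):
                    break
            else:
                raise RuntimeError(
                    "init_random: could not place a subunit after "
                    f"{max_attempts} attempts; lower the density or "
                    "min_separation")
            species.append(sp)
            centers.append(c)
            quats.append(q)
            placed = np.vstack([placed, pts])
            placed_typ = np.concatenate([placed_typ, tpl.types])

    cargo, cargo_sp = [], []
    ctype = {0: C.TYPE_CARGO_R, 1: C.TYPE_CARGO_G}
    for sp, count in ((0, n_cargo_r), (1, n_cargo_g)):
        for _ in range(count):
            for attempt in range(max_attempts):
                c = rng.uniform(0.0, box, size=3)
                if not too_close(c[None, :], np.array([ctype[sp]])):
                    break
            else:
                raise RuntimeError(
                    "init_random: could not place a cargo particle after "
                    f"{max_attempts} attempts; lower the density or "
                    "min_separation")
            cargo.append(c)
            cargo_sp.append(sp)
            placed = np.vstack([placed, c[None, :]])
            placed_typ = np.concatenate([placed_typ, [ctype[sp]]])

    nb = len(species)
    return SimulationState(
        templates=templates,
        body_species=np.asarray(species, dtype=np.int64).reshape(nb),
        body_pos=np.asarray(centers, dtype=float).reshape(nb, 3),
        body_quat=np.asarray(quats, dtype=float).reshape(nb, 4),
        cargo_pos=(np.asarray(cargo, dtype=float).reshape(len(cargo), 3)
                   if cargo else np.zeros((0, 3))),
        cargo_species=np.asarray(cargo_sp, dtype=np.int64),
        box=float(box))


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _free_rotor(q, L, inertia, dt):
    """Symplectic Trotterized free rigid-rotor update (quaternion + body-frame
    angular momentum), axis sequence z, y, x, y, z."""
    r = np.empty(4)
    tmp = np.empty(4)
    for step_idx in range(5):
        if step_idx == 0 or step_idx == 4:
            k = 2
            h = 0.5 * dt
        elif step_idx == 1 or step_idx == 3:
            k = 1
            h = 0.5 * dt
        else:
            k = 0
            h = dt
        if inertia[k] <= 0.0:
            continue
        phi = h * L[k] / inertia[k]
        half = 0.5 * phi
        s = np.sin(half)
        r[0] = np.cos(half)
        r[1] = 0.0
        r[2] = 0.0
        r[3] = 0.0
        r[1 + k] = s
        quat_mul(q, r, tmp)
        q[0], q[1], q[2], q[3] = tmp[0], tmp[1], tmp[2], tmp[3]
        i = (k + 1) % 3
        j = (k + 2) % 3
        cp = np.cos(phi)
        sp = np.sin(phi)
        li = cp * L[i] + sp * L[j]
        lj = -sp * L[i] + cp * L[j]
        L[i] = li
        L[j] = lj
    # renormalize to guard against drift
    nrm = np.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    q[0] /= nrm
    q[1] /= nrm
    q[2] /= nrm
    q[3] /= nrm


@njit(cache=True)
def _integrate(body_pos, body_quat, body_vel, body_L, body_species, body_free,
               body_fixed, tpl_mass, tpl_inertia, cargo_pos, cargo_vel,
               site_rel, site_typ, site_bod, idx_a, idx_b, cell_a, cell_b,
               box, dt, gamma, kT, n_steps, seed, ostride,
               kind, eps, par, req, rcut2, shift, rcutb2, skin):
    np.random.seed(seed)
    nb = body_pos.shape[0]
    nc = cargo_pos.shape[0]
    ns = site_rel.shape[0]
    site_pos = np.empty((ns, 3))
    site_F = np.zeros((ns, 3))
    body_F = np.zeros((nb, 3))
    body_T = np.zeros((nb, 3))
    cargo_F = np.zeros((nc, 3))
    m = np.empty((3, 3))

    # gamma is the translational drag coefficient (mass/time): every body
    # relaxes at rate gamma/m, so all species share the diffusion constant
    # D = kT/gamma.  Rotations use the same relaxation rate per body.
    # The OU thermostat step is exact, so it may be applied every
    # ``ostride`` steps with the compounded decay factor; this leaves the
    # stationary (NVT) distribution unchanged and only coarsens the
    # velocity-relaxation sampling.
    dt_o = dt * ostride
    c1 = np.exp(-gamma * dt_o)        # cargo (unit mass)
    c2 = np.sqrt(max(0.0, (1.0 - c1 * c1) * kT))
    c1b = np.empty(2)
    c2b = np.empty(2)
    for sp in range(2):
        c1b[sp] = np.exp(-gamma * dt_o / tpl_mass[sp])
        c2b[sp] = np.sqrt(max(0.0, (1.0 - c1b[sp] * c1b[sp]) * kT))

    # reusable pair buffers (regrown on overflow)
    cap = 96 * ns + 4096
    pi = np.empty(cap, dtype=np.int32)
    pj = np.empty(cap, dtype=np.int32)
    pk = np.empty(cap, dtype=np.int8)
    pe = np.empty(cap)
    pp = np.empty(cap)
    pq = np.empty(cap)
    pr2 = np.empty(cap)
    ps = np.empty(cap)

    # positions are wrapped at every neighbor-list rebuild so that the
    # single-shift minimum-image convention stays valid between rebuilds
    for b in range(nb):
        for k in range(3):
            body_pos[b, k] %= box
    for c in range(nc):
        for k in range(3):
            cargo_pos[c, k] %= box
    fill_site_positions(site_pos, site_rel, site_bod, body_pos, body_quat,
                        cargo_pos)
    npairs = -1
    while npairs < 0:
        npairs = _grid_fill(site_pos, site_typ, site_bod, body_fixed, box,
                            kind, rcutb2, eps, par, req, rcut2, shift, idx_a,
                            cell_a, False, pi, pj, pk, pe, pp, pq, pr2, ps, 0)
        if npairs >= 0:
            npairs = _grid_fill(site_pos, site_typ, site_bod, body_fixed, box,
                                kind, rcutb2, eps, par, req, rcut2, shift,
                                idx_b, cell_b, True, pi, pj, pk, pe, pp, pq,
                                pr2, ps, npairs)
        if npairs < 0:
            cap *= 2
            pi = np.empty(cap, dtype=np.int32)
            pj = np.empty(cap, dtype=np.int32)
            pk = np.empty(cap, dtype=np.int8)
            pe = np.empty(cap)
            pp = np.empty(cap)
            pq = np.empty(cap)
            pr2 = np.empty(cap)
            ps = np.empty(cap)
    ref_pos = site_pos.copy()
    ef_pairs_lin(site_pos, box, npairs, pi, pj, pk, pe, pp, pq, pr2, ps,
                 site_F)
    reduce_body_forces(site_F, site_pos, site_bod, body_pos, body_F, body_T,
                       cargo_F)

    half = 0.5 * dt
    for istep in range(n_steps):
        # B: half kick
        for b in range(nb):
            if body_free[b] == 0:
                continue
            sp = body_species[b]
            im = 1.0 / tpl_mass[sp]
            quat_to_mat(body_quat[b], m)
            for k in range(3):
                body_vel[b, k] += half * body_F[b, k] * im
                # torque to body frame: tau_b = R^T tau_lab
                body_L[b, k] += half * (m[0, k] * body_T[b, 0]
                                        + m[1, k] * body_T[b, 1]
                                        + m[2, k] * body_T[b, 2])
        for c in range(nc):
            for k in range(3):
                cargo_vel[c, k] += half * cargo_F[c, k]
        # A: half drift
        for b in range(nb):
            if body_free[b] == 0:
                continue
            for k in range(3):
                body_pos[b, k] += half * body_vel[b, k]
            _free_rotor(body_quat[b], body_L[b],
                        tpl_inertia[body_species[b]], half)
        for c in range(nc):
            for k in range(3):
                cargo_pos[c, k] += half * cargo_vel[c, k]
        # O: thermostat
        if gamma > 0.0 and istep % ostride == 0:
            for b in range(nb):
                if body_free[b] == 0:
                    continue
                sp = body_species[b]
                sv = c2b[sp] * np.sqrt(tpl_mass[sp])
                for k in range(3):
                    body_vel[b, k] = (c1b[sp] * body_vel[b, k]
                                      + sv / tpl_mass[sp]
                                      * np.random.normal())
                    body_L[b, k] = (c1b[sp] * body_L[b, k]
                                    + c2b[sp] * np.sqrt(tpl_inertia[sp][k])
                                    * np.random.normal())
            for c in range(nc):
                for k in range(3):
                    cargo_vel[c, k] = (c1 * cargo_vel[c, k]
                                       + c2 * np.random.normal())
        # A: half drift
        for b in range(nb):
            if body_free[b] == 0:
                continue
            for k in range(3):
                body_pos[b, k] += half * body_vel[b, k]
            _free_rotor(body_quat[b], body_L[b],
                        tpl_inertia[body_species[b]], half)
        for c in range(nc):
            for k in range(3):
                cargo_pos[c, k] += half * cargo_vel[c, k]

        # forces at new positions
        fill_site_positions(site_pos, site_rel, site_bod, body_pos, body_quat,
                            cargo_pos)
        if max_displacement2(site_pos, ref_pos, box) > 0.25 * skin * skin:
            for b in range(nb):
                for k in range(3):
                    body_pos[b, k] %= box
            for c in range(nc):
                for k in range(3):
                    cargo_pos[c, k] %= box
            fill_site_positions(site_pos, site_rel, site_bod, body_pos,
                                body_quat, cargo_pos)
            npairs = -1
            while npairs < 0:
                npairs = _grid_fill(site_pos, site_typ, site_bod, body_fixed,
                                    box, kind, rcutb2, eps, par, req, rcut2,
                                    shift, idx_a, cell_a, False, pi, pj, pk,
                                    pe, pp, pq, pr2, ps, 0)
                if npairs >= 0:
                    npairs = _grid_fill(site_pos, site_typ, site_bod,
                                        body_fixed, box, kind, rcutb2, eps,
                                        par, req, rcut2, shift, idx_b, cell_b,
                                        True, pi, pj, pk, pe, pp, pq, pr2, ps,
                                        npairs)
                if npairs < 0:
                    cap *= 2
                    pi = np.empty(cap, dtype=np.int32)
                    pj = np.empty(cap, dtype=np.int32)
                    pk = np.empty(cap, dtype=np.int8)
                    pe = np.empty(cap)
                    pp = np.empty(cap)
                    pq = np.empty(cap)
                    pr2 = np.empty(cap)
                    ps = np.empty(cap)
            ref_pos = site_pos.copy()
        ef_pairs_lin(site_pos, box, npairs, pi, pj, pk, pe, pp, pq, pr2, ps,
                     site_F)
        reduce_body_forces(site_F, site_pos, site_bod, body_pos, body_F,
                           body_T, cargo_F)

        # B: half kick
        for b in range(nb):
            if body_free[b] == 0:
                continue
            sp = body_species[b]
            im = 1.0 / tpl_mass[sp]
            quat_to_mat(body_quat[b], m)
            for k in range(3):
                body_vel[b, k] += half * body_F[b, k] * im
                body_L[b, k] += half * (m[0, k] * body_T[b, 0]
                                        + m[1, k] * body_T[b, 1]
                                        + m[2, k] * body_T[b, 2])
        for c in range(nc):
            for k in range(3):
                cargo_vel[c, k] += half * cargo_F[c, k]

        if (istep + 1) % 200 == 0 or istep + 1 == n_steps:
            # instability diagnostic: non-finite coordinates or a velocity
            # explosion (thermal speeds are O(1) in reduced units)
            ok = True
            for b in range(nb):
                for k in range(3):
                    if not (np.isfinite(body_pos[b, k])
                            and np.abs(body_vel[b, k]) < 1e4):
                        ok = False
            for c in range(nc):
                for k in range(3):
                    if not (np.isfinite(cargo_pos[c, k])
                            and np.abs(cargo_vel[c, k]) < 1e4):
                        ok = False
            if not ok:
                return istep + 1
    return 0


def step(state: SimulationState, config: RunConfig,
         n: int | None = None, table: InteractionTable | None = None,
         skin: float = 0.4) -> SimulationState:
    """Advance ``n`` Langevin steps (default ``config.n_steps``).

    Returns a new state; the input state is not modified.  The trajectory is
    reproducible for a given ``config.seed``.  Bodies flagged fixed are
    excluded from integration but still exert forces.
    """
    if table is None:
        table = InteractionTable()
    n = int(config.n_steps if n is None else n)
    st = state.copy()
    t = table.compile()
    rel, typ, bod, _ = st.site_arrays()
    tpl_mass = np.array([st.templates["pentamer"].mass,
                         st.templates["hexamer"].mass])
    tpl_inertia = np.vstack([st.templates["pentamer"].inertia,
                             st.templates["hexamer"].inertia])
    body_free = (~st.body_fixed).astype(np.int8)
    body_fixed = st.body_fixed.astype(np.int8)
    # split neighbor grids: subunit-subunit sites vs cargo-interacting sites
    cargo_types = (C.TYPE_CARGO_R, C.TYPE_CARGO_G)
    grid_b_types = cargo_types + (C.TYPE_EXC, C.TYPE_BP_A, C.TYPE_BH_A)
    in_a = (bod >= 0) & (typ < C.TYPE_EXC)
    in_b = np.isin(typ, grid_b_types)
    idx_a = np.where(in_a)[0].astype(np.int64)
    idx_b = np.where(in_b)[0].astype(np.int64)
    rc = np.sqrt(t.rcut2)
    sub_types = np.arange(C.TYPE_EXC)
    cell_a = float(rc[np.ix_(sub_types, sub_types)].max()) + skin
    cell_b = float(rc[:, list(cargo_types)].max()) + skin
    rcutb2 = (rc + skin) ** 2
    bad = _integrate(st.body_pos, st.body_quat, st.body_vel, st.body_angmom,
                     st.body_species, body_free, body_fixed, tpl_mass,
                     tpl_inertia, st.cargo_pos, st.cargo_vel, rel, typ, bod,
                     idx_a, idx_b, cell_a, cell_b, st.box,
                     config.timestep, config.friction, config.temperature,
                     n, int(config.seed) % (2**31 - 1),
                     int(config.thermostat_stride),
                     t.kind, t.eps, t.par, t.req, t.rcut2, t.shift, rcutb2,
                     skin)
    if bad:
        raise IntegrationError(
            f"non-finite coordinate detected at step {st.time / config.timestep + bad:.0f} "
            f"(local step {bad}); the timestep may be too large for the "
            "current interaction strengths")
    st.time += n * config.timestep
    st.wrap()
    return st


def kinetic_energy(state: SimulationState) -> tuple:
    """Translational and rotational kinetic energy."""
    tpl_mass = {0: state.templates["pentamer"].mass,
                1: state.templates["hexamer"].mass}
    ke_t = 0.0
    for b in range(state.n_bodies):
        ke_t += 0.5 * tpl_mass[int(state.body_species[b])] * \
            np.dot(state.body_vel[b], state.body_vel[b])
    ke_t += 0.5 * float(np.einsum("ij,ij->", state.cargo_vel, state.cargo_vel))
    ke_r = 0.0
    for b in range(state.n_bodies):
        inertia = state.template_for(b).inertia
        ke_r += 0.5 * float(np.sum(state.body_angmom[b] ** 2 / inertia))
    return ke_t, ke_r
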