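"""Binding free energies and dissociation constants from configurational
integrals, plus reduced-unit to molar concentration conversion.

All binding free energies use the 1 M standard state: for two rigid bodies

    g = -ln( Z_b / (8 pi^2 v0) ),   Z_b = mult * int_D d^3r dOmega e^{-U}

with v0 the volume per particle at 1 M (in r*^3, so the result depends on
the physical length mapping r* ~ 13 nm), D the attractive basin of one
binding contact, and ``mult`` the number of symmetry-equivalent basins.
The basin is defined by the fully engaged contact: every attractor pair of
the contact registry within the half-depth radius of the Morse well, and the
dimerization free energy is quoted per binding interface.  (A looser "any
pair bound" region is dominated by barely touching configurations and
cannot reproduce positive dimerization free energies; see docs/methods.md.)

Z_b is evaluated in two stages.  At an intermediate coupling lambda_1 the
integral is measured directly by importance sampling over a box in pose
space (rotations parametrized as rotation vectors about the contact-edge
midpoint, so the soft hinge mode is axis-aligned); from lambda_1 the well
depth is switched on by thermodynamic integration with Metropolis chains
confined to the basin:

    -ln Z(eps) = -ln Z(lambda_1) + int_{lambda_1}^{eps} <u_att>_lambda dlambda

where u_att is the attractive energy at unit well depth.

The per-subunit free energy of a complete shell uses an independent-cell
approximation: the blueprint energy plus one pose integral per
symmetry-distinct subunit in the field of its frozen neighbors.  The
shell-cargo free energy per subunit is the binding free energy of one cargo
particle at the interior wall site of a hexamer of the complete shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import constants as C
from . import geometry
from ._nb import pair_ef
from .interactions import (FrozenPairEvaluator, InteractionTable,
                           relax_state, total_energy_forces)
from .state import state_from_blueprint

__all__ = [
    "BindingFreeEnergy", "dimer_free_energy", "shell_site_free_energy",
    "shell_cargo_site_free_energy", "dissociation_constant", "to_molar",
    "table_one",
]


@dataclass
class BindingFreeEnergy:
    g: float                       # k_B T
    mc_error: float                # k_B T (one standard error)
    standard_concentration: float = 1.0   # molar
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mc_error < 0:
            raise ValueError("mc_error must be non-negative")


class ConvergenceError(RuntimeError):
    def __init__(self, msg, running_error):
        super().__init__(f"{msg} (running mc_error = {running_error:.3f} kT)")
        self.running_error = running_error


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rotmat(q, m):
    w, x, y, z = q[0], q[1], q[2], q[3]
    m[0, 0] = 1 - 2 * (y * y + z * z)
    m[0, 1] = 2 * (x * y - w * z)
    m[0, 2] = 2 * (x * z + w * y)
    m[1, 0] = 2 * (x * y + w * z)
    m[1, 1] = 1 - 2 * (x * x + z * z)
    m[1, 2] = 2 * (y * z - w * x)
    m[2, 0] = 2 * (x * z - w * y)
    m[2, 1] = 2 * (y * z + w * x)
    m[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=True)
def _moved_sites(mov_rel, p, q, out):
    m = np.empty((3, 3))
    _rotmat(q, m)
    for s in range(mov_rel.shape[0]):
        for k in range(3):
            out[s, k] = (p[k] + m[k, 0] * mov_rel[s, 0]
                         + m[k, 1] * mov_rel[s, 1] + m[k, 2] * mov_rel[s, 2])


@njit(cache=True)
def _pose_energy(static_pos, mpos, pis, pim, patt, pkind, peps, ppar, preq,
                 prcut2, pshift):
    u_att = 0.0
    u_rep = 0.0
    for t in range(pis.shape[0]):
        a = static_pos[pis[t]]
        b = mpos[pim[t]]
        dx = a[0] - b[0]
        dy = a[1] - b[1]
        dz = a[2] - b[2]
        r2 = dx * dx + dy * dy + dz * dz
        e, _ = pair_ef(pkind[t], peps[t], ppar[t], preq[t], prcut2[t],
                       pshift[t], r2)
        if patt[t]:
            u_att += e
        else:
            u_rep += e
    return u_att, u_rep


@njit(cache=True)
def _in_basin(static_pos, mpos, pis, pim, bond_sel, bond_rcut2, need_all):
    any_hit = False
    for t in range(pis.shape[0]):
        if not bond_sel[t]:
            continue
        a = static_pos[pis[t]]
        b = mpos[pim[t]]
        dx = a[0] - b[0]
        dy = a[1] - b[1]
        dz = a[2] - b[2]
        hit = dx * dx + dy * dy + dz * dz < bond_rcut2
        if need_all and not hit:
            return False
        if hit:
            any_hit = True
    return any_hit


@njit(cache=True)
def _quat_from_rotvec(v, q):
    th = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if th < 1e-12:
        q[0] = 1.0
        q[1] = q[2] = q[3] = 0.0
        return
    s = np.sin(0.5 * th) / th
    q[0] = np.cos(0.5 * th)
    q[1] = v[0] * s
    q[2] = v[1] * s
    q[3] = v[2] * s


@njit(cache=True)
def _quat_mul(a, b, out):
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]


@njit(cache=True)
def _z_stage(static_pos, mov_rel, p_ref, q_ref, rot_origin, rot_axes, rot_w,
             w_t, lam1, bond_sel, bond_rcut2, need_all, u_att_ref, u_rep_ref,
             n, seed, pis, pim, patt, pkind, peps, ppar, preq, prcut2,
             pshift):
    """Importance-sampled Z(lambda_1) over the pose box, per unit measure.

    Returns (mean, stderr) of J(theta) * 1_basin * exp(-(lam1*(u_att-ref) +
    (u_rep-ref))) under uniform sampling of translations (cube half-width
    w_t) and rotation vectors (box half-widths rot_w along rot_axes, applied
    about rot_origin).  Multiply by the box measure to get Z(lambda_1).
    """
    np.random.seed(seed)
    has_rot = rot_w[0] > 0 or rot_w[1] > 0 or rot_w[2] > 0
    nm = mov_rel.shape[0]
    mpos = np.empty((nm, 3))
    p = np.empty(3)
    q = np.empty(4)
    dq = np.empty(4)
    v = np.empty(3)
    rm = np.empty((3, 3))
    arm = np.empty(3)
    s1 = 0.0
    s2 = 0.0
    for it in range(n):
        jac = 1.0
        if has_rot:
            vl0 = (2.0 * np.random.random() - 1.0) * rot_w[0]
            vl1 = (2.0 * np.random.random() - 1.0) * rot_w[1]
            vl2 = (2.0 * np.random.random() - 1.0) * rot_w[2]
            for k in range(3):
                v[k] = (rot_axes[k, 0] * vl0 + rot_axes[k, 1] * vl1
                        + rot_axes[k, 2] * vl2)
            th2 = v[0] * v[0] + v[1] * v[1] + v[2] * v[2]
            if th2 > 1e-14:
                th = np.sqrt(th2)
                jac = 2.0 * (1.0 - np.cos(th)) / th2
            _quat_from_rotvec(v, dq)
            _quat_mul(dq, q_ref, q)
            _rotmat(dq, rm)
            for k in range(3):
                arm[k] = p_ref[k] - rot_origin[k]
            for k in range(3):
                p[k] = (rot_origin[k] + rm[k, 0] * arm[0]
                        + rm[k, 1] * arm[1] + rm[k, 2] * arm[2])
        else:
            q[:] = q_ref
            p[:] = p_ref
        for k in range(3):
            p[k] += (2.0 * np.random.random() - 1.0) * w_t
        _moved_sites(mov_rel, p, q, mpos)
        val = 0.0
        if _in_basin(static_pos, mpos, pis, pim, bond_sel, bond_rcut2,
                     need_all):
            ua, ur = _pose_energy(static_pos, mpos, pis, pim, patt, pkind,
                                  peps, ppar, preq, prcut2, pshift)
            ex = -(lam1 * (ua - u_att_ref) + (ur - u_rep_ref))
            if ex > -60.0:
                val = jac * np.exp(ex)
        s1 += val
        s2 += val * val
    mean = s1 / n
    var = max(0.0, s2 / n - mean * mean) / n
    return mean, np.sqrt(var)


@njit(cache=True)
def _ti_chain(static_pos, mov_rel, p_ref, q_ref, lam, bond_sel, bond_rcut2,
              need_all, u_att_ref, n_steps, n_burn, step_t, step_r, seed,
              pis, pim, patt, pkind, peps, ppar, preq, prcut2, pshift):
    """Metropolis average of (u_att - u_att_ref) at coupling lam over the
    basin (moves leaving the basin are rejected)."""
    np.random.seed(seed)
    nm = mov_rel.shape[0]
    p = p_ref.copy()
    q = q_ref.copy()
    mpos = np.empty((nm, 3))
    mpos_n = np.empty((nm, 3))
    _moved_sites(mov_rel, p, q, mpos)
    ua, ur = _pose_energy(static_pos, mpos, pis, pim, patt, pkind, peps,
                          ppar, preq, prcut2, pshift)
    pn = np.empty(3)
    qn = np.empty(4)
    dq = np.empty(4)
    v = np.empty(3)
    acc = 0
    nblock = 16
    block = np.zeros(nblock)
    per_block = max(1, n_steps // nblock)
    for it in range(n_burn + n_steps):
        for k in range(3):
            pn[k] = p[k] + step_t * np.random.normal()
        if step_r > 0.0:
            for k in range(3):
                v[k] = step_r * np.random.normal()
            _quat_from_rotvec(v, dq)
            _quat_mul(dq, q, qn)
        else:
            qn[:] = q
        _moved_sites(mov_rel, pn, qn, mpos_n)
        if _in_basin(static_pos, mpos_n, pis, pim, bond_sel, bond_rcut2,
                     need_all):
            ua_n, ur_n = _pose_energy(static_pos, mpos_n, pis, pim, patt,
                                      pkind, peps, ppar, preq, prcut2,
                                      pshift)
            du = lam * (ua_n - ua) + (ur_n - ur)
            if du <= 0.0 or np.random.random() < np.exp(-du):
                p[:] = pn
                q[:] = qn
                ua = ua_n
                ur = ur_n
                acc += 1
        if it >= n_burn:
            b = min(nblock - 1, (it - n_burn) // per_block)
            block[b] += ua - u_att_ref
    means = block / per_block
    mean = 0.0
    for b in range(nblock):
        mean += means[b]
    mean /= nblock
    var = 0.0
    for b in range(nblock):
        var += (means[b] - mean) ** 2
    var /= (nblock - 1) * nblock
    return mean, np.sqrt(var), acc / (n_burn + n_steps)


# ---------------------------------------------------------------------------
# pose-integral driver
# ---------------------------------------------------------------------------

class _PoseIntegral:
    """Configurational integral of one rigid probe in a static site field."""

    def __init__(self, static_pos, static_typ, mov_rel, mov_typ, table,
                 p_ref, q_ref, reach=1.0):
        t = table.compile()
        self.table = table
        self.static_pos = np.ascontiguousarray(static_pos, dtype=float)
        self.p_ref = np.asarray(p_ref, dtype=float)
        self.q_ref = np.asarray(q_ref, dtype=float)
        self.mov_rel = np.ascontiguousarray(mov_rel, dtype=float)
        R = geometry.quat_to_matrix(self.q_ref)
        mpos = self.p_ref + self.mov_rel @ R.T
        rows = []
        for a in range(len(static_pos)):
            ta = int(static_typ[a])
            for b in range(len(mov_rel)):
                tb = int(mov_typ[b])
                k = t.kind[ta, tb]
                if k == 0:
                    continue
                d = np.linalg.norm(static_pos[a] - mpos[b])
                rc = np.sqrt(t.rcut2[ta, tb])
                if d > rc + reach:
                    continue
                is_att = (k == 1)
                rows.append((a, b, is_att, k,
                             1.0 if is_att else t.eps[ta, tb],
                             t.par[ta, tb], t.req[ta, tb], t.rcut2[ta, tb],
                             t.shift[ta, tb] / t.eps[ta, tb] if is_att
                             else t.shift[ta, tb], d))
        self.ref_dist = np.array([r[9] for r in rows])
        self.pairs = (np.array([r[0] for r in rows], dtype=np.int64),
                      np.array([r[1] for r in rows], dtype=np.int64),
                      np.array([r[2] for r in rows], dtype=np.bool_),
                      np.array([r[3] for r in rows], dtype=np.int8),
                      np.array([r[4] for r in rows]),
                      np.array([r[5] for r in rows]),
                      np.array([r[6] for r in rows]),
                      np.array([r[7] for r in rows]),
                      np.array([r[8] for r in rows]))
        mpos_arr = np.ascontiguousarray(mpos)
        self.u_att_ref, self.u_rep_ref = _pose_energy(
            self.static_pos, mpos_arr, *self.pairs[:4], *self.pairs[4:])

    def registry_pairs(self, tol=0.05) -> np.ndarray:
        """Attractor pairs coincident at the reference pose (the contact)."""
        return self.pairs[2] & (self.ref_dist < tol)

    def integrate(self, eps, v0, n_samples, seed, *, multiplicity,
                  bond_rcut, bond_sel=None, need_all=True, w_t=0.08,
                  rot_axes=None, rot_w=(0.0, 0.0, 0.0), rot_origin=None,
                  lambda1_frac=0.5, relative_to_ref=False, n_lambda=10,
                  step_t=0.02, step_r=0.02):
        """-ln(mult * Z(eps) / (8 pi^2 v0)), with mc error.

        ``relative_to_ref=True`` measures energies relative to the reference
        pose (for in-shell cell integrals); otherwise absolute (dimer and
        cargo binding).  Orientation-free probes (all rot_w zero) use v0
        without the 8 pi^2 factor.
        """
        bond_sel = self.registry_pairs() if bond_sel is None else bond_sel
        if not bond_sel.any():
            raise ValueError("no contact pairs define the basin")
        rot_axes = np.eye(3) if rot_axes is None else np.asarray(rot_axes)
        rot_w = np.asarray(rot_w, dtype=float)
        rot_origin = (self.p_ref if rot_origin is None
                      else np.asarray(rot_origin, dtype=float))
        ua_ref = self.u_att_ref if relative_to_ref else 0.0
        ur_ref = self.u_rep_ref if relative_to_ref else 0.0
        lam1 = lambda1_frac * eps

        n0 = max(20_000, n_samples // 2)
        m, merr = _z_stage(self.static_pos, self.mov_rel, self.p_ref,
                           self.q_ref, rot_origin, rot_axes, rot_w, w_t,
                           lam1, bond_sel, bond_rcut ** 2, need_all, ua_ref,
                           ur_ref, n0, seed, *self.pairs[:4], *self.pairs[4:])
        if m <= 0:
            raise ConvergenceError("no basin configurations sampled", np.inf)
        measure = (2.0 * w_t) ** 3
        has_rot = bool(np.any(rot_w > 0))
        for k in range(3):
            if rot_w[k] > 0:
                measure *= 2.0 * rot_w[k]
        z1 = measure * m
        denom = 8.0 * np.pi ** 2 * v0 if has_rot else v0
        g = -np.log(multiplicity * z1 / denom)
        err2 = (merr / m) ** 2

        if lam1 < eps:
            x, w = np.polynomial.legendre.leggauss(n_lambda)
            lam = lam1 + 0.5 * (eps - lam1) * (x + 1.0)
            wts = 0.5 * (eps - lam1) * w
            n_chain = max(4000, (n_samples - n0) // n_lambda)
            for i in range(n_lambda):
                mi, ei, acc = _ti_chain(
                    self.static_pos, self.mov_rel, self.p_ref, self.q_ref,
                    lam[i], bond_sel, bond_rcut ** 2, need_all, ua_ref,
                    n_chain, n_chain // 5, step_t, step_r, seed + 1000 + i,
                    *self.pairs[:4], *self.pairs[4:])
                g += wts[i] * mi
                err2 += (wts[i] * ei) ** 2
        return float(g), float(np.sqrt(err2))


# ---------------------------------------------------------------------------
# collective-mode (phonon) correction to the independent-cell model
# ---------------------------------------------------------------------------

def _collective_correction(table, st, fixed_body: int = 0, h: float = 2e-5):
    """(1/2)[ln det H - sum_i ln det H_ii] for the shell Hessian over
    rigid-body coordinates (3 translations + 3 rotations per body), with one
    body held fixed to remove the global zero modes.  By Fischer's
    inequality this is always <= 0: collective modes are softer than the
    independent-cell blocks, so the cell model overestimates the shell free
    energy by -C.  Returned per free body (C / (N - 1))."""
    from scipy.spatial.transform import Rotation as Rot

    ev = FrozenPairEvaluator(st, table)
    free = [b for b in range(st.n_bodies) if b != fixed_body]
    n = 6 * len(free)
    H = np.empty((n, n))

    def gen_forces(body_pos, body_quat):
        _, bF, bT = ev.forces(body_pos, body_quat)
        out = np.empty(n)
        for col, b in enumerate(free):
            out[6 * col:6 * col + 3] = bF[b]
            out[6 * col + 3:6 * col + 6] = bT[b]
        return out

    for col, b in enumerate(free):
        for a in range(6):
            gp = []
            for s in (h, -h):
                bp = st.body_pos.copy()
                bq = st.body_quat.copy()
                if a < 3:
                    bp[b, a] += s
                else:
                    rv = np.zeros(3)
                    rv[a - 3] = s
                    dq = Rot.from_rotvec(rv)
                    q = bq[b, [1, 2, 3, 0]]
                    bq[b] = (dq * Rot.from_quat(q)).as_quat()[[3, 0, 1, 2]]
                gp.append(gen_forces(bp, bq))
            H[:, 6 * col + a] = -(gp[0] - gp[1]) / (2 * h)
    H = 0.5 * (H + H.T)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        raise RuntimeError("shell Hessian is not positive definite")
    log_blocks = 0.0
    for col in range(len(free)):
        blk = H[6 * col:6 * col + 6, 6 * col:6 * col + 6]
        s, ld = np.linalg.slogdet(blk)
        if s <= 0:
            raise RuntimeError("cell Hessian block is not positive definite")
        log_blocks += ld
    return 0.5 * (logdet - log_blocks) / len(free)


# ---------------------------------------------------------------------------
# reference geometry helpers
# ---------------------------------------------------------------------------

def _relaxed_shell(table):
    bp = geometry.build_shell_blueprint()
    st = relax_state(state_from_blueprint(bp, box=30.0), table, max_iter=120)
    return bp, st


def _body_sites(st, b):
    tpl = st.template_for(b)
    R = geometry.quat_to_matrix(st.body_quat[b])
    return st.body_pos[b] + tpl.positions @ R.T, tpl.types


def _edge_frame(integ, p_ref):
    """Rotation basis (edge axis, in-plane normal, out-of-plane) and origin
    at the contact-edge midpoint, from the coincident registry pairs."""
    sel = integ.registry_pairs()
    pts = integ.static_pos[integ.pairs[0][sel]]
    origin = pts.mean(axis=0)
    e1 = pts[-1] - pts[0]
    e1 = e1 / np.linalg.norm(e1)
    r = p_ref - origin
    r -= np.dot(r, e1) * e1
    e2 = r / np.linalg.norm(r)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3]), origin


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def dimer_free_energy(table: InteractionTable, templates=None,
                      n_samples: int = 400_000, seed: int = 0,
                      max_mc_error: float = 0.3) -> BindingFreeEnergy:
    """Hexamer-hexamer dimerization free energy g_hh at 1 M standard state.

    Monte Carlo configurational integration of the two-body Boltzmann factor
    over relative separation and orientation.  The bound region is the
    attractive basin of one edge-edge contact: all four registry attractor
    pairs within the half-depth radius of the Morse well.  The free energy
    is quoted per binding interface (equivalent interfaces on other edges
    are not multiplied in).
    """
    bp, st = _relaxed_shell(table)
    i, j = next((e[0], e[1]) for e in bp.edges if e[2] == "hex-hex")
    static_pos, static_typ = _body_sites(st, i)
    tpl = bp.templates["hexamer"]
    integ = _PoseIntegral(static_pos, static_typ, tpl.positions, tpl.types,
                          table, st.body_pos[j], st.body_quat[j])
    axes, origin = _edge_frame(integ, integ.p_ref)
    hinge_w = table.hinge_window + 0.2
    rb = table.basin_cutoff
    g, err = integ.integrate(
        table.eps_ss, C.standard_volume(), n_samples, seed, multiplicity=1,
        bond_rcut=rb, w_t=min(0.10, 1.2 * rb), rot_axes=axes,
        rot_w=(hinge_w, min(0.25, 2.8 * rb), min(0.12, 1.2 * rb)),
        rot_origin=origin, step_t=0.3 * rb, step_r=0.3 * rb)
    if err > max_mc_error:
        raise ConvergenceError("dimer free energy did not converge", err)
    return BindingFreeEnergy(g, err, metadata={
        "kind": "hexamer-hexamer dimerization", "eps_ss": table.eps_ss})


def _shell_site_integral(table, which, n_samples, seed, shell_state):
    st = shell_state
    idx = 0 if which == "pentamer" else 12
    tpl = st.templates[which]
    pos_list, typ_list = [], []
    for b in range(st.n_bodies):
        if b == idx:
            continue
        p, t = _body_sites(st, b)
        pos_list.append(p)
        typ_list.append(t)
    integ = _PoseIntegral(np.concatenate(pos_list), np.concatenate(typ_list),
                          tpl.positions, tpl.types, table,
                          st.body_pos[idx], st.body_quat[idx])
    mult = 5 if which == "pentamer" else 3
    rb = table.basin_cutoff
    g, err = integ.integrate(
        table.eps_ss, C.standard_volume(), n_samples, seed,
        multiplicity=mult, bond_rcut=rb, w_t=min(0.08, 1.2 * rb),
        rot_axes=np.eye(3), rot_w=(min(0.12, 2.0 * rb),) * 3,
        relative_to_ref=True, step_t=0.25 * rb, step_r=0.25 * rb)
    return g, err


def shell_cargo_site_free_energy(table: InteractionTable,
                                 n_samples: int = 200_000,
                                 seed: int = 0) -> BindingFreeEnergy:
    """Shell-cargo free energy per subunit, g_SC: the binding free energy of
    one cargo particle at the interior wall site of a hexamer of the
    complete shell (1 M standard state), shell-cargo terms only."""
    bp, st = _relaxed_shell(table)
    idx = 12
    spos, styp = _body_sites(st, idx)
    b_site = spos[np.where(styp == C.TYPE_BH_A)[0][0]]
    center = st.body_pos.mean(axis=0)
    nrm = b_site - center
    nrm /= np.linalg.norm(nrm)
    p_ref = b_site - nrm * table.morse_req_sc
    pos_list, typ_list = [], []
    for b in range(st.n_bodies):
        p, t = _body_sites(st, b)
        pos_list.append(p)
        typ_list.append(t)
    integ = _PoseIntegral(np.concatenate(pos_list), np.concatenate(typ_list),
                          np.zeros((1, 3)),
                          np.array([C.TYPE_CARGO_R], dtype=np.int64),
                          table, p_ref, np.array([1.0, 0.0, 0.0, 0.0]),
                          reach=1.6)
    # basin: cargo within the shell-cargo Morse range of any wall site
    bond_sel = integ.pairs[2].copy()
    g, err = integ.integrate(
        table.eps_sc, C.standard_volume(), n_samples, seed, multiplicity=1,
        bond_rcut=table.morse_rcut_sc, bond_sel=bond_sel, need_all=False,
        w_t=1.0, rot_w=(0.0, 0.0, 0.0), lambda1_frac=0.0, step_t=0.06)
    return BindingFreeEnergy(g, err, metadata={
        "kind": "shell-cargo site", "eps_sc": table.eps_sc})


def shell_site_free_energy(blueprint=None, table: InteractionTable = None,
                           with_cargo_layer: bool = True,
                           n_samples: int = 200_000,
                           seed: int = 0) -> BindingFreeEnergy:
    """Free energy per subunit in the complete shell, Delta g_shell.

    Shell-shell contribution: relaxed-blueprint energy plus independent-cell
    pose integrals (12 pentamer + 20 hexamer cells), divided by 32.
    Shell-cargo contribution: the per-subunit wall-site binding free energy
    when ``with_cargo_layer`` is set.  Cargo-cargo contributions are
    excluded by construction (they shift the effective shell stability
    depending on the cargo phase).
    """
    table = table or InteractionTable()
    bp, st = _relaxed_shell(table)
    g_p, e_p = _shell_site_integral(table, "pentamer", n_samples, seed, st)
    g_h, e_h = _shell_site_integral(table, "hexamer", n_samples, seed + 7, st)
    u0 = total_energy_forces(st, table).energy
    n = st.n_bodies
    c_corr = _collective_correction(table, st)
    g = (u0 + 12 * g_p + 20 * g_h) / n + c_corr
    err2 = (12 * e_p / n) ** 2 + (20 * e_h / n) ** 2
    meta = {"kind": "per-subunit shell free energy",
            "eps_ss": table.eps_ss, "eps_sc": table.eps_sc,
            "caveat": "does not include cargo-cargo contributions",
            "collective_correction": float(c_corr),
            "shell_shell_part": float(g)}
    if with_cargo_layer:
        gsc = shell_cargo_site_free_energy(table, n_samples, seed + 13)
        g += gsc.g
        err2 += gsc.mc_error ** 2
        meta["shell_cargo_part"] = gsc.g
    return BindingFreeEnergy(float(g), float(np.sqrt(err2)), metadata=meta)


def dissociation_constant(g) -> float:
    """Kd in micromolar from a binding free energy (k_B T, 1 M standard
    state): Kd = c0 * exp(g); monotone increasing in g."""
    gv = g.g if isinstance(g, BindingFreeEnergy) else float(g)
    return 1.0e6 * float(np.exp(gv))


def to_molar(count: int, box_side: float,
             r_star_nm: float = C.R_STAR_NM) -> float:
    """Concentration in micromolar of ``count`` particles in a cubic box of
    side ``box_side`` (in r*), with the given physical length mapping."""
    if box_side <= 0 or r_star_nm <= 0:
        raise ValueError("box_side and r_star_nm must be positive")
    vol_l = (box_side * r_star_nm * 1e-9) ** 3 * 1000.0   # liters
    return count / (C.AVOGADRO * vol_l) * 1e6


def table_one(eps_ss_values=(2.0, 3.5), eps_sc: float = 6.0,
              n_samples: int = 300_000, seed: int = 0):
    """Recompute the shell binding-thermodynamics table.

    Returns a pandas DataFrame with one column per shell-shell affinity:
    hexamer dimerization free energy and Kd, per-subunit shell free energy
    (with the eps_SC cargo layer) and the corresponding Kd.
    """
    import pandas as pd
    rows = {}
    for eps in eps_ss_values:
        tab = InteractionTable(eps_ss=eps, eps_sc=eps_sc)
        ghh = dimer_free_energy(tab, n_samples=n_samples, seed=seed)
        gsh = shell_site_free_energy(table=tab, n_samples=n_samples,
                                     seed=seed + 1)
        rows[eps] = {
            "g_hh / kT": ghh.g,
            "Kd_hh / uM": dissociation_constant(ghh),
            "dg_shell / kT": gsh.g,
            "Kd_shell / uM": dissociation_constant(gsh),
            "g_SC / kT": gsh.metadata.get("shell_cargo_part"),
        }
    return pd.DataFrame(rows)
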