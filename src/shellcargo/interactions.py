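"""Pair potentials, the attractor complementarity matrix, and total
energy/force/torque evaluation.

Three potential families cover every interaction in the model:

* a Morse potential between complementary perimeter Attractors (well depth
  ``eps_ss``) and between hexamer cargo-binding Bottoms and cargo particles
  (well depth ``eps_sc``, identical for both cargo species);
* purely repulsive Lennard-Jones (WCA) interactions among Top/Bottom
  pseudoatoms of different subunits, whose diameters are derived from the
  ideal shell geometry and select the preferred dihedral angle, plus
  Excluder-cargo and pentamer-Bottom-cargo excluded volume;
* a cut-and-shifted 12-6 Lennard-Jones attraction between cargo pairs with
  well depths ``eps_rr``, ``eps_gg``, ``eps_rg`` by species pair.

All potentials are shifted to vanish continuously at their cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from . import constants as C
from . import geometry
from ._nb import (build_pairs, ef_brute, ef_pairs, fill_site_positions,
                  reduce_body_forces)
from .state import SimulationState

__all__ = [
    "InteractionTable", "PairTables", "morse_energy", "repulsive_lj_energy",
    "cargo_lj_energy", "total_energy_forces", "ForceResult",
]

KIND_NONE, KIND_MORSE, KIND_WCA, KIND_LJ = 0, 1, 2, 3
_WCA_CUT = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# scalar potentials (reference implementations, also used by the tests)
# ---------------------------------------------------------------------------

def morse_energy(r, eps: float, req: float, alpha: float, rcut: float):
    """Morse potential V(r) = eps[(1 - e^{-alpha (r - req)})^2 - 1], shifted
    so V(rcut) = 0; zero beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative separation")
    if not rcut > req:
        raise ValueError("rcut must exceed req")
    x = np.exp(-alpha * (r - req))
    xc = math.exp(-alpha * (rcut - req))
    shift = eps * ((1.0 - xc) ** 2 - 1.0)
    v = np.where(r < rcut, eps * ((1.0 - x) ** 2 - 1.0) - shift, 0.0)
    return v if v.ndim else float(v)


def repulsive_lj_energy(r, sigma: float, eps_rep: float = 1.0):
    """Weeks-Chandler-Andersen potential: LJ truncated at 2^(1/6) sigma and
    shifted up by eps_rep; purely repulsive, zero beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    s6 = (sigma / r) ** 6
    v = np.where(r < _WCA_CUT * sigma, 4 * eps_rep * (s6 * s6 - s6) + eps_rep, 0.0)
    return v if v.ndim else float(v)


def cargo_lj_energy(r, eps_ij: float, sigma: float = C.SIGMA_CARGO,
                    rcut: float = C.RCUT_CARGO):
    """Cut-and-shifted 12-6 Lennard-Jones for a cargo pair of well depth
    eps_ij (selected by the unordered species pair)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation must be positive")
    s6 = (sigma / r) ** 6
    s6c = (sigma / rcut) ** 6
    shift = 4 * eps_ij * (s6c * s6c - s6c)
    v = np.where(r < rcut, 4 * eps_ij * (s6 * s6 - s6) - shift, 0.0)
    return v if v.ndim else float(v)


# ---------------------------------------------------------------------------
# interaction table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTables:
    """Per-type-pair parameter arrays consumed by the numba kernels."""
    kind: np.ndarray      # (T, T) int8
    eps: np.ndarray
    par: np.ndarray       # Morse alpha or LJ sigma
    req: np.ndarray
    rcut2: np.ndarray
    shift: np.ndarray
    max_rcut: float


@lru_cache(maxsize=1)
def _hinge_sigma_table(window: float) -> dict:
    """Curvature-selecting WCA sigmas derived from the ideal shell geometry."""
    d = geometry.hinge_pair_distances(window)
    name2code = {"TP_E": C.TYPE_TP_E, "TH_E": C.TYPE_TH_E,
                 "BP_E": C.TYPE_BP_E, "BH_E": C.TYPE_BH_E,
                 "TP_A": C.TYPE_TP_A, "TH_A": C.TYPE_TH_A,
                 "BP_A": C.TYPE_BP_A, "BH_A": C.TYPE_BH_A}
    sig = {}
    for (a, b), dist in d.items():
        sig[(name2code[a], name2code[b])] = dist / _WCA_CUT
    # pentamer-pentamer contacts never occur in a well-formed shell; give
    # them the pentamer-hexamer excluded volume.
    sig[(C.TYPE_TP_E, C.TYPE_TP_E)] = sig[(C.TYPE_TP_E, C.TYPE_TH_E)]
    sig[(C.TYPE_BP_E, C.TYPE_BP_E)] = sig[(C.TYPE_BP_E, C.TYPE_BH_E)]
    sig[(C.TYPE_TP_A, C.TYPE_TP_A)] = sig[(C.TYPE_TP_A, C.TYPE_TH_A)]
    sig[(C.TYPE_BP_A, C.TYPE_BP_A)] = sig[(C.TYPE_BP_A, C.TYPE_BH_A)]
    return sig


@dataclass
class InteractionTable:
    """All pair-potential parameters of the model.

    Energies are in k_B T.  ``eps_sc`` applies identically to both cargo
    species; complementary attractor classes follow the fixed registry
    pairing in ``constants.COMPLEMENTARY_PAIRS``; all other attractor pairs
    do not interact.
    """

    eps_ss: float = 2.0
    eps_sc: float = 6.0
    eps_rr: float = 1.3
    eps_gg: float = 1.3
    eps_rg: float = 1.3

    morse_alpha_ss: float = C.MORSE_ALPHA_SS
    morse_req_ss: float = C.MORSE_REQ_SS
    morse_rcut_ss: float = C.MORSE_RCUT_SS
    morse_alpha_sc: float = C.MORSE_ALPHA_SC
    morse_req_sc: float = C.MORSE_REQ_SC
    morse_rcut_sc: float = C.MORSE_RCUT_SC
    eps_rep: float = C.EPS_REP
    hinge_window: float = C.HINGE_HALF_WINDOW
    sigma_cargo: float = C.SIGMA_CARGO
    rcut_cargo: float = C.RCUT_CARGO
    sigma_bp_cargo: float = C.SIGMA_BP_CARGO
    sigma_exc_cargo: float = C.SIGMA_EXC_CARGO

    def __post_init__(self):
        for name in ("eps_ss", "eps_sc", "eps_rr", "eps_gg", "eps_rg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.morse_rcut_ss <= self.morse_req_ss:
            raise ValueError("shell-shell Morse cutoff must exceed req")
        self._tables = None

    # -- spec-facing -------------------------------------------------------
    @property
    def complementarity(self) -> np.ndarray:
        """Boolean matrix over the 10 attractor classes."""
        m = np.zeros((10, 10), dtype=bool)
        for a, b in C.COMPLEMENTARY_PAIRS:
            m[a, b] = m[b, a] = True
        return m

    def cargo_eps(self, s1: int, s2: int) -> float:
        key = frozenset((s1, s2))
        if key == frozenset((0,)):
            return self.eps_rr
        if key == frozenset((1,)):
            return self.eps_gg
        if key == frozenset((0, 1)):
            return self.eps_rg
        raise ValueError(f"unknown cargo species pair ({s1}, {s2})")

    def with_eps(self, **kw) -> "InteractionTable":
        return replace(self, **kw)

    @property
    def bond_cutoff(self) -> float:
        """Distance criterion for a subunit-subunit bond (the Morse cutoff)."""
        return self.morse_rcut_ss

    @property
    def basin_cutoff(self) -> float:
        """Attractor-pair distance bounding the thermodynamic binding basin:
        the half-depth radius of the Morse well (a pair farther out retains
        less than half its binding energy and is not 'engaged')."""
        return float(np.log(1.0 / (1.0 - np.sqrt(0.5))) / self.morse_alpha_ss)

    # -- compiled tables ---------------------------------------------------
    def compile(self) -> PairTables:
        if self._tables is not None:
            return self._tables
        T = C.N_TYPES
        kind = np.zeros((T, T), dtype=np.int8)
        eps = np.zeros((T, T))
        par = np.zeros((T, T))
        req = np.zeros((T, T))
        rcut2 = np.zeros((T, T))
        shift = np.zeros((T, T))

        def set_pair(a, b, k, e, p, q=0.0, rc=0.0):
            for i, j in ((a, b), (b, a)):
                kind[i, j] = k
                eps[i, j] = e
                par[i, j] = p
                req[i, j] = q
                if k == KIND_WCA:
                    rc_ = _WCA_CUT * p
                    rcut2[i, j] = rc_ * rc_
                    shift[i, j] = 0.0
                else:
                    rcut2[i, j] = rc * rc
                    if k == KIND_MORSE:
                        xc = math.exp(-p * (rc - q))
                        shift[i, j] = e * ((1 - xc) ** 2 - 1)
                    elif k == KIND_LJ:
                        s6 = (p / rc) ** 6
                        shift[i, j] = 4 * e * (s6 * s6 - s6)

        # attractor Morse (complementary classes only)
        for a, b in C.COMPLEMENTARY_PAIRS:
            set_pair(a, b, KIND_MORSE, self.eps_ss, self.morse_alpha_ss,
                     self.morse_req_ss, self.morse_rcut_ss)
        # curvature-selecting Top/Bottom WCA
        for (a, b), s in _hinge_sigma_table(self.hinge_window).items():
            set_pair(a, b, KIND_WCA, self.eps_rep, s)
        # Top-Bottom cross repulsions (anti-stacking excluded volume)
        sig = _hinge_sigma_table(self.hinge_window)
        s_ta = sig[(C.TYPE_TH_A, C.TYPE_TH_A)]
        s_ba = sig[(C.TYPE_BH_A, C.TYPE_BH_A)]
        for t in (C.TYPE_TP_A, C.TYPE_TH_A):
            for b in (C.TYPE_BP_A, C.TYPE_BH_A):
                set_pair(t, b, KIND_WCA, self.eps_rep, 0.5 * (s_ta + s_ba))
        for t in (C.TYPE_TP_E, C.TYPE_TH_E):
            for b in (C.TYPE_BP_E, C.TYPE_BH_E):
                set_pair(t, b, KIND_WCA, self.eps_rep, 0.3)
        # shell-cargo: hexamer axial Bottom binds cargo (both species alike)
        for cg in (C.TYPE_CARGO_R, C.TYPE_CARGO_G):
            set_pair(C.TYPE_BH_A, cg, KIND_MORSE, self.eps_sc,
                     self.morse_alpha_sc, self.morse_req_sc,
                     rc=self.morse_rcut_sc)
            set_pair(C.TYPE_BP_A, cg, KIND_WCA, self.eps_rep,
                     self.sigma_bp_cargo)
            set_pair(C.TYPE_EXC, cg, KIND_WCA, self.eps_rep,
                     self.sigma_exc_cargo)
        # cargo-cargo LJ
        set_pair(C.TYPE_CARGO_R, C.TYPE_CARGO_R, KIND_LJ, self.eps_rr,
                 self.sigma_cargo, rc=self.rcut_cargo)
        set_pair(C.TYPE_CARGO_G, C.TYPE_CARGO_G, KIND_LJ, self.eps_gg,
                 self.sigma_cargo, rc=self.rcut_cargo)
        set_pair(C.TYPE_CARGO_R, C.TYPE_CARGO_G, KIND_LJ, self.eps_rg,
                 self.sigma_cargo, rc=self.rcut_cargo)

        self._tables = PairTables(kind, eps, par, req, rcut2, shift,
                                  float(np.sqrt(rcut2.max())))
        return self._tables


# ---------------------------------------------------------------------------
# total energy / forces / torques
# ---------------------------------------------------------------------------

@dataclass
class ForceResult:
    energy: float
    body_force: np.ndarray     # (Nb, 3)
    body_torque: np.ndarray    # (Nb, 3) lab frame, about body centers
    cargo_force: np.ndarray    # (Nc, 3)
    site_force: np.ndarray = field(repr=False, default=None)


def total_energy_forces(state: SimulationState, table: InteractionTable,
                        use_neighbor_list: bool = True,
                        skin: float = 0.4) -> ForceResult:
    """Total potential energy plus per-body forces and torques.

    Equals the all-pairs double loop over pseudoatom interactions with the
    minimum-image convention; forces are exact negative gradients and sum to
    zero.  ``use_neighbor_list=False`` forces the brute-force O(N^2) path
    (the reference oracle used in the tests).
    """
    t = table.compile()
    if state.box < 2.0 * t.max_rcut:
        raise ValueError(
            f"box ({state.box}) smaller than twice the largest cutoff "
            f"({t.max_rcut:.3f}): minimum-image convention invalid")
    rel, typ, bod, pos = state.site_arrays()
    if use_neighbor_list:
        pairs = build_pairs(pos, typ, bod, state.box, t.kind, t.rcut2, skin,
                            t.max_rcut)
        F = np.zeros_like(pos)
        E = ef_pairs(pos, typ, bod, state.box, pairs, t.kind, t.eps, t.par,
                     t.req, t.rcut2, t.shift, F)
    else:
        E, F = ef_brute(pos, typ, bod, state.box, t.kind, t.eps, t.par,
                        t.req, t.rcut2, t.shift)
    nb = state.n_bodies
    body_F = np.zeros((nb, 3))
    body_T = np.zeros((nb, 3))
    cargo_F = np.zeros((state.n_cargo, 3))
    reduce_body_forces(F, pos, bod, state.body_pos, body_F, body_T, cargo_F)
    return ForceResult(float(E), body_F, body_T, cargo_F, F)


class FrozenPairEvaluator:
    """Energy/forces/torques on rigid bodies with a fixed neighbor list
    (valid for infinitesimal displacements around a reference state)."""

    def __init__(self, state, table, skin=0.3):
        self._ef_pairs = ef_pairs
        self._fill = fill_site_positions
        self._reduce = reduce_body_forces
        self.t = table.compile()
        self.state = state
        self.rel, self.typ, self.bod, pos = state.site_arrays()
        self.pairs = build_pairs(pos, self.typ, self.bod, state.box,
                                 self.t.kind, self.t.rcut2, skin,
                                 self.t.max_rcut)
        self._pos = np.empty_like(pos)
        self._F = np.zeros_like(pos)

    def forces(self, body_pos, body_quat):
        st = self.state
        self._fill(self._pos, self.rel, self.bod, body_pos, body_quat,
                   st.cargo_pos)
        e = self._ef_pairs(self._pos, self.typ, self.bod, st.box, self.pairs,
                           self.t.kind, self.t.eps, self.t.par, self.t.req,
                           self.t.rcut2, self.t.shift, self._F)
        nb = st.n_bodies
        bF = np.zeros((nb, 3))
        bT = np.zeros((nb, 3))
        cF = np.zeros((st.n_cargo, 3))
        self._reduce(self._F, self._pos, self.bod, body_pos, bF, bT, cF)
        return e, bF, bT



def relax_state(state: SimulationState, table: InteractionTable,
                max_iter: int = 400, force_tol: float = 0.02,
                step0: float = 2e-4) -> SimulationState:
    """Relax rigid-body poses to a nearby local energy minimum.

    Adaptive steepest descent on body centers and orientations (cargo is
    relaxed too if present).  Used to polish the ideal blueprint, whose
    residual generalized forces come from sub-cutoff Morse tails between
    non-paired complementary attractors.
    """
    from scipy.spatial.transform import Rotation as Rot

    st = state.copy()
    eta = step0
    res = total_energy_forces(st, table)
    for _ in range(max_iter):
        fmax = max(np.abs(res.body_force).max() if st.n_bodies else 0.0,
                   np.abs(res.body_torque).max() if st.n_bodies else 0.0,
                   np.abs(res.cargo_force).max() if st.n_cargo else 0.0)
        if fmax < force_tol:
            break
        trial = st.copy()
        trial.body_pos += eta * res.body_force
        if st.n_bodies:
            rv = eta * res.body_torque
            dq = Rot.from_rotvec(rv)
            q = trial.body_quat[:, [1, 2, 3, 0]]   # to scipy (x,y,z,w)
            qn = (dq * Rot.from_quat(q)).as_quat()
            trial.body_quat = qn[:, [3, 0, 1, 2]]
        if st.n_cargo:
            trial.cargo_pos += eta * res.cargo_force
        res_t = total_energy_forces(trial, table)
        if res_t.energy <= res.energy:
            st = trial
            res = res_t
            eta = min(eta * 1.3, 5e-3)
        else:
            eta *= 0.5
            if eta < 1e-9:
                break
    return st
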