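"""Observables: subunit bond graph, shell detection and completeness,
encapsulated-cargo census, mixing metrics, shell-to-shell variability, and
bulk phase classification.

Definitions (reduced units):

* two subunits are bonded iff at least one complementary attractor pair is
  within the bond cutoff (default: the attractor Morse cutoff);
* a shell is complete iff its bonded cluster has exactly 12 pentamers and
  20 hexamers AND closed topology (every pentamer 5 bonds, every hexamer 6);
* f_s = fraction of all subunits residing in complete shells;
* a cargo neighbor pair is a pair at separation r < 1.2;
* f_bar_UL = n_RG / (n_RR + n_GG + n_RG), f_rand = 2 f_R (1 - f_R),
  f_UL = f_bar_UL - f_rand (excess mixing relative to random);
* sigma_R,shell = population standard deviation of f_R over complete shells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, cKDTree

from . import constants as C
from .interactions import InteractionTable
from .state import PENTAMER, SimulationState

__all__ = [
    "ShellCluster", "MixingMetrics", "PhaseLabel", "ObservableRecord",
    "bond_graph", "detect_shells", "encapsulated_cargo", "cargo_pair_counts",
    "mixing_metrics", "shell_variability", "classify_phase",
    "compute_observables",
]

NEIGHBOR_CUTOFF = 1.2          # first-solvation-shell pair criterion
CONDENSATE_MIN_SIZE = 20       # particles in the largest cluster
PURITY_BOUND = 0.2             # dense-phase f_R in [f_lo, 1-f_lo] = two species
DEMIX_THRESHOLD = -0.1         # f_UL below this = demixed condensate


# ---------------------------------------------------------------------------
# bond graph and shell detection
# ---------------------------------------------------------------------------

def bond_graph(state: SimulationState, table: InteractionTable | None = None,
               bond_cutoff: float | None = None) -> nx.Graph:
    """Graph over subunits with an edge for every bonded pair."""
    table = table or InteractionTable()
    rcut = bond_cutoff if bond_cutoff is not None else table.bond_cutoff
    g = nx.Graph()
    for b in range(state.n_bodies):
        g.add_node(b, species=int(state.body_species[b]))
    if state.n_bodies < 2:
        return g
    _, typ, bod, pos = state.site_arrays()
    att = np.where((bod >= 0) & (typ < 10))[0]
    apos = pos[att] % state.box
    atyp = typ[att]
    abod = bod[att]
    comp = table.complementarity
    tree = cKDTree(apos, boxsize=state.box)
    for i, j in tree.query_pairs(rcut):
        if abod[i] != abod[j] and comp[atyp[i], atyp[j]]:
            g.add_edge(int(abod[i]), int(abod[j]))
    return g


@dataclass
class ShellCluster:
    """A connected cluster of bonded subunits."""

    subunit_ids: list
    n_pent: int
    n_hex: int
    complete: bool
    cargo_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    n_c: int = 0                       # encapsulated cargo count N_C
    f_r_shell: float | None = None     # fraction of R among encapsulated
    f_ul_shell: float | None = None    # excess mixing among encapsulated
    adsorbed_cargo_ids: np.ndarray | None = None  # incomplete clusters only

    @property
    def size(self) -> int:
        return self.n_pent + self.n_hex


def detect_shells(graph: nx.Graph, state: SimulationState,
                  census_cargo: bool = True):
    """Connected components of the bond graph, with completeness flags.

    Returns ``(clusters, f_s)``.  Completeness requires the exact 12 + 20
    stoichiometry and closed topology (every pentamer with 5 bonds, every
    hexamer with 6).  For complete shells the encapsulated cargo census is
    attached (unless ``census_cargo=False``).
    """
    clusters = []
    n_in_complete = 0
    for comp_nodes in nx.connected_components(graph):
        ids = sorted(comp_nodes)
        sp = state.body_species[ids]
        n_pent = int(np.sum(sp == PENTAMER))
        n_hex = len(ids) - n_pent
        complete = (n_pent == 12 and n_hex == 20)
        if complete:
            for b in ids:
                want = 5 if state.body_species[b] == PENTAMER else 6
                if graph.degree[b] != want:
                    complete = False
                    break
        cl = ShellCluster(ids, n_pent, n_hex, complete)
        if complete:
            n_in_complete += len(ids)
            if census_cargo and state.n_cargo:
                encapsulated_cargo(state, cl)
        clusters.append(cl)
    f_s = n_in_complete / state.n_bodies if state.n_bodies else 0.0
    return clusters, f_s


def _unwrapped_centers(state, ids):
    ref = state.body_pos[ids[0]]
    d = state.body_pos[ids] - ref
    d -= state.box * np.round(d / state.box)
    return ref, d


def encapsulated_cargo(state: SimulationState, shell: ShellCluster):
    """Census of cargo inside a shell cluster.

    A cargo particle counts as encapsulated iff it lies inside the closed
    polyhedral surface through the subunit centers (for the convex complete
    shell this is the convex hull of the centers, tested by its half-space
    equations).  For incomplete clusters the surface is not closed: the
    result is flagged (``complete=False``) and nearby adsorbed cargo is
    reported separately instead.
    """
    ids = list(shell.subunit_ids)
    ref, centers = _unwrapped_centers(state, ids)
    d = state.cargo_pos - ref
    d -= state.box * np.round(d / state.box)
    if not shell.complete or len(ids) < 4:
        # flagged: report cargo adsorbed within one cargo diameter of any
        # subunit center instead of an interior count
        if len(ids):
            tree = cKDTree(centers)
            near = tree.query_ball_point(d, r=2.0)
            shell.adsorbed_cargo_ids = np.array(
                [i for i, lst in enumerate(near) if lst], dtype=int)
        shell.n_c = 0
        shell.f_r_shell = None
        return shell
    hull = ConvexHull(centers)
    inside = np.all(d @ hull.equations[:, :3].T + hull.equations[:, 3]
                    <= 0.0, axis=1)
    ids_in = np.where(inside)[0]
    shell.cargo_ids = ids_in
    shell.n_c = int(len(ids_in))
    if shell.n_c:
        f_r = float(np.mean(state.cargo_species[ids_in] == 0))
        shell.f_r_shell = f_r
        counts = cargo_pair_counts(state, subset=ids_in)
        m = mixing_metrics(counts, f_r)
        shell.f_ul_shell = m.f_ul
    else:
        shell.f_r_shell = None
    return shell


# ---------------------------------------------------------------------------
# mixing metrics
# ---------------------------------------------------------------------------

def cargo_pair_counts(state: SimulationState,
                      rcut: float = NEIGHBOR_CUTOFF,
                      subset: np.ndarray | None = None):
    """Unordered neighbor-pair counts (n_RR, n_GG, n_RG) at r < rcut."""
    if subset is None:
        pos = state.cargo_pos
        spc = state.cargo_species
    else:
        pos = state.cargo_pos[subset]
        spc = state.cargo_species[subset]
    if len(pos) < 2:
        return (0, 0, 0)
    tree = cKDTree(pos % state.box, boxsize=state.box)
    n = np.zeros(3, dtype=int)   # index = s_i + s_j: 0 = RR, 1 = RG, 2 = GG
    for i, j in tree.query_pairs(rcut):
        n[spc[i] + spc[j]] += 1
    return (int(n[0]), int(n[2]), int(n[1]))


@dataclass
class MixingMetrics:
    n_rr: int
    n_gg: int
    n_rg: int
    f_r: float
    f_bar_ul: float | None      # None when there are no neighbor pairs
    f_rand: float
    f_ul: float | None


def mixing_metrics(counts, f_r: float) -> MixingMetrics:
    """Mixing metrics from neighbor-pair counts and composition f_R."""
    n_rr, n_gg, n_rg = counts
    tot = n_rr + n_gg + n_rg
    f_rand = 2.0 * f_r * (1.0 - f_r)
    if tot == 0:
        return MixingMetrics(n_rr, n_gg, n_rg, f_r, None, f_rand, None)
    f_bar = n_rg / tot
    return MixingMetrics(n_rr, n_gg, n_rg, f_r, f_bar, f_rand, f_bar - f_rand)


def shell_variability(shells) -> float | None:
    """sigma_R,shell: population standard deviation of f_R over complete
    shells with encapsulated cargo.  None (flagged) below two shells."""
    vals = [s.f_r_shell for s in shells
            if s.complete and s.n_c > 0 and s.f_r_shell is not None]
    if len(vals) < 2:
        return None
    v = np.asarray(vals)
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


# ---------------------------------------------------------------------------
# bulk phase classification
# ---------------------------------------------------------------------------

@dataclass
class PhaseLabel:
    label: str                   # homogeneous | one_species_condensate |
    #                              mixed_condensate | demixed_condensate
    dense_f_r: float | None = None
    dense_f_ul: float | None = None
    largest_cluster: int = 0


def classify_phase(state: SimulationState,
                   min_size: int = CONDENSATE_MIN_SIZE,
                   f_lo: float = PURITY_BOUND,
                   demix_threshold: float = DEMIX_THRESHOLD,
                   rcut: float = NEIGHBOR_CUTOFF) -> PhaseLabel:
    """Classify the cargo phase state of a configuration.

    Condensates are connected components of the r < rcut cargo contact
    graph.  A condensate is present iff the largest component exceeds
    ``min_size``; it is classified by its composition (``one_species`` when
    the dense-phase f_R lies outside [f_lo, 1 - f_lo]) and by its excess
    mixing (``demixed`` when f_UL < demix_threshold, else ``mixed``).
    """
    n = state.n_cargo
    if n == 0:
        return PhaseLabel("homogeneous")
    pos = state.cargo_pos % state.box
    tree = cKDTree(pos, boxsize=state.box)
    import scipy.sparse as sp
    pairs = tree.query_pairs(rcut, output_type="ndarray")
    adj = sp.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                        shape=(n, n))
    from scipy.sparse.csgraph import connected_components
    ncomp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    big = int(sizes.argmax())
    largest = int(sizes[big])
    if largest <= min_size:
        return PhaseLabel("homogeneous", largest_cluster=largest)
    members = np.where(labels == big)[0]
    f_r = float(np.mean(state.cargo_species[members] == 0))
    counts = cargo_pair_counts(state, rcut=rcut, subset=members)
    m = mixing_metrics(counts, f_r)
    if f_r < f_lo or f_r > 1.0 - f_lo:
        label = "one_species_condensate"
    elif m.f_ul is not None and m.f_ul < demix_threshold:
        label = "demixed_condensate"
    else:
        label = "mixed_condensate"
    return PhaseLabel(label, f_r, m.f_ul, largest)


# ---------------------------------------------------------------------------
# aggregated observable record
# ---------------------------------------------------------------------------

@dataclass
class ObservableRecord:
    time: float
    f_s: float
    n_complete_shells: int
    mean_n_c: float | None
    f_r: float | None            # fraction of R among all encapsulated cargo
    f_ul: float | None           # mean over complete shells with pairs
    sigma_r_shell: float | None
    shells: list = field(default_factory=list)

    def row(self) -> dict:
        return {"time": self.time, "f_s": self.f_s,
                "n_complete_shells": self.n_complete_shells,
                "mean_N_C": self.mean_n_c, "f_R": self.f_r,
                "f_UL": self.f_ul, "sigma_R_shell": self.sigma_r_shell}


def compute_observables(state: SimulationState,
                        table: InteractionTable | None = None) -> ObservableRecord:
    """Shell and encapsulation observables of one configuration."""
    g = bond_graph(state, table)
    shells, f_s = detect_shells(g, state)
    complete = [s for s in shells if s.complete]
    mean_nc = float(np.mean([s.n_c for s in complete])) if complete else None
    tot_in = sum(s.n_c for s in complete)
    if tot_in:
        n_r = sum(int(round(s.f_r_shell * s.n_c)) for s in complete if s.n_c)
        f_r = n_r / tot_in
    else:
        f_r = None
    fuls = [s.f_ul_shell for s in complete if s.f_ul_shell is not None]
    f_ul = float(np.mean(fuls)) if fuls else None
    return ObservableRecord(state.time, f_s, len(complete), mean_nc, f_r,
                            f_ul, shell_variability(shells), shells)
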