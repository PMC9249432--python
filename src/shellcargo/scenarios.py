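"""Simulation protocols: dynamical assembly, bulk cargo phase behavior, and
the permeable-shell equilibrium reference, plus planted test fixtures.

Reference conditions (overridable for scaled-down runs, which keep the same
concentrations in a smaller box):

* assembly: 48 pentamers + 80 hexamers (four shells' worth) and 854 cargo
  (half R, half G) in a cubic box of side 40 r*, 2e6 steps (2e7 in the
  two-step regime);
* bulk: 46 938 cargo in a box of side 160 (same cargo concentration), no
  subunits;
* permeable shell: a complete shell with one pentamer removed, held fixed
  at the box center with its cargo attraction active, plus 854 cargo in a
  box of side 40, run until the interior census plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .analysis import (ObservableRecord, classify_phase, compute_observables,
                       encapsulated_cargo, mixing_metrics, cargo_pair_counts,
                       ShellCluster)
from .dynamics import RunConfig, init_random, step
from .geometry import build_shell_blueprint
from .interactions import InteractionTable
from .state import SimulationState, default_templates, state_from_blueprint

__all__ = ["ScenarioSpec", "ScenarioResult", "run_assembly", "run_bulk",
           "run_permeable_shell", "run_trials", "make_fixture"]

_DEFAULTS = {
    "assembly": dict(n_pentamers=48, n_hexamers=80, n_cargo_r=427,
                     n_cargo_g=427, box=40.0, n_steps=2_000_000,
                     snapshot_stride=20_000),
    "bulk": dict(n_pentamers=0, n_hexamers=0, n_cargo_r=23_469,
                 n_cargo_g=23_469, box=160.0, n_steps=2_000_000,
                 snapshot_stride=20_000),
    "permeable_shell": dict(n_pentamers=0, n_hexamers=0, n_cargo_r=427,
                            n_cargo_g=427, box=40.0, n_steps=2_000_000,
                            snapshot_stride=20_000),
}


@dataclass
class ScenarioSpec:
    kind: str = "assembly"
    n_pentamers: int = 48
    n_hexamers: int = 80
    n_cargo_r: int = 427
    n_cargo_g: int = 427
    box: float = 40.0
    n_steps: int = 2_000_000
    snapshot_stride: int = 20_000
    seed: int = 0
    n_trials: int = 10
    min_separation: float = 0.9

    @classmethod
    def with_defaults(cls, kind: str, **overrides) -> "ScenarioSpec":
        if kind not in _DEFAULTS and kind != "fixture":
            raise ValueError(f"unknown scenario kind {kind!r}")
        base = dict(_DEFAULTS.get(kind, _DEFAULTS["assembly"]))
        base.update(overrides)
        return cls(kind=kind, **base)

    def scaled(self, factor: float) -> "ScenarioSpec":
        """Shrink particle counts by ``factor`` at fixed concentration."""
        s = factor ** (1.0 / 3.0)
        return replace(self,
                       n_pentamers=round(self.n_pentamers * factor),
                       n_hexamers=round(self.n_hexamers * factor),
                       n_cargo_r=round(self.n_cargo_r * factor),
                       n_cargo_g=round(self.n_cargo_g * factor),
                       box=self.box * s)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    final_state: SimulationState
    records: list                      # ObservableRecord per snapshot
    phases: list = field(default_factory=list)   # PhaseLabel per snapshot

    def records_frame(self):
        import pandas as pd
        return pd.DataFrame([r.row() for r in self.records])


def _chunked_run(state, table, run, spec, observe, writer=None):
    records = []
    stride = max(1, int(spec.snapshot_stride))
    n_left = int(run.n_steps)
    chunk_idx = 0
    while n_left > 0:
        n = min(stride, n_left)
        cfg = RunConfig(timestep=run.timestep, friction=run.friction,
                        temperature=run.temperature,
                        seed=(run.seed * 7919 + chunk_idx) % (2**31 - 1))
        state = step(state, cfg, n=n, table=table)
        records.append(observe(state))
        if writer is not None:
            writer(state)
        n_left -= n
        chunk_idx += 1
    return state, records


def run_assembly(spec: ScenarioSpec, table: InteractionTable,
                 run: RunConfig | None = None, traj_path=None) -> ScenarioResult:
    """Dynamical shell assembly and cargo encapsulation from random initial
    conditions.  Particle counts are conserved throughout."""
    assert spec.kind == "assembly"
    run = run or RunConfig(n_steps=spec.n_steps, seed=spec.seed)
    state = init_random(spec.n_pentamers, spec.n_hexamers, spec.n_cargo_r,
                        spec.n_cargo_g, spec.box, spec.seed,
                        min_separation=spec.min_separation, table=table)
    n0 = (state.n_bodies, state.n_cargo)
    writer = None
    if traj_path:
        from .io import write_frames
        write_frames(state, traj_path, mode="w")
        writer = lambda st: write_frames(st, traj_path, mode="a")  # noqa: E731
    state, records = _chunked_run(state, table, run, spec,
                                  lambda st: compute_observables(st, table),
                                  writer)
    assert (state.n_bodies, state.n_cargo) == n0
    return ScenarioResult(spec, state, records)


def run_bulk(spec: ScenarioSpec, table: InteractionTable,
             run: RunConfig | None = None, traj_path=None) -> ScenarioResult:
    """Cargo-only dynamics at the assembly-simulation concentration, with
    phase classification sampled on every snapshot."""
    assert spec.kind == "bulk"
    run = run or RunConfig(n_steps=spec.n_steps, seed=spec.seed)
    state = init_random(0, 0, spec.n_cargo_r, spec.n_cargo_g, spec.box,
                        spec.seed, min_separation=spec.min_separation,
                        table=table)
    phases = []

    def observe(st):
        ph = classify_phase(st)
        phases.append(ph)
        return ObservableRecord(st.time, 0.0, 0, None, ph.dense_f_r,
                                ph.dense_f_ul, None)

    writer = None
    if traj_path:
        from .io import write_frames
        write_frames(state, traj_path, mode="w")
        writer = lambda st: write_frames(st, traj_path, mode="a")  # noqa: E731
    state, records = _chunked_run(state, table, run, spec, observe, writer)
    return ScenarioResult(spec, state, records, phases)


def run_droplet_bulk(spec: ScenarioSpec, table: InteractionTable,
                     droplet_frac: float = 0.3,
                     run: RunConfig | None = None) -> ScenarioResult:
    """Direct-coexistence bulk run: a dense droplet planted in its vapor.

    At this cargo concentration, homogeneous nucleation is barrier-limited
    and unobservable on desk-scale runs, so the vapor-liquid threshold is
    bracketed by droplet stability instead: below coexistence the planted
    droplet evaporates, above it it persists (an equilibrium criterion,
    insensitive to the nucleation barrier).
    """
    assert spec.kind == "bulk"
    run = run or RunConfig(n_steps=spec.n_steps, seed=spec.seed)
    n_tot = spec.n_cargo_r + spec.n_cargo_g
    n_drop = int(round(droplet_frac * n_tot))
    rng = np.random.default_rng(spec.seed)
    radius = (n_drop * 3.0 / (4.0 * np.pi * 0.8)) ** (1.0 / 3.0)
    pts = _lattice_ball(radius, 1.08, np.zeros(3))
    while len(pts) < n_drop:
        radius *= 1.05
        pts = _lattice_ball(radius, 1.08, np.zeros(3))
    order = np.argsort(np.linalg.norm(pts, axis=1))
    drop = pts[order[:n_drop]] + spec.box / 2.0
    # vapor: uniform random outside the droplet, mutually non-overlapping
    n_vap = n_tot - n_drop
    placed = drop.copy()
    while placed.shape[0] < n_tot:
        c = rng.uniform(0, spec.box, size=3)
        d = c - spec.box / 2.0
        d -= spec.box * np.round(d / spec.box)
        if np.linalg.norm(d) <= radius + 1.5:
            continue
        dd = placed - c
        dd -= spec.box * np.round(dd / spec.box)
        if (np.einsum("ij,ij->i", dd, dd) < spec.min_separation ** 2).any():
            continue
        placed = np.vstack([placed, c])
    pos = placed
    spc = np.zeros(n_tot, dtype=np.int64)
    spc[rng.permutation(n_tot)[:spec.n_cargo_g]] = 1
    state = SimulationState(default_templates(), np.zeros(0, dtype=np.int64),
                            np.zeros((0, 3)), np.zeros((0, 4)), pos, spc,
                            spec.box)
    phases = []

    def observe(st):
        ph = classify_phase(st)
        phases.append(ph)
        return ObservableRecord(st.time, 0.0, 0, None, ph.dense_f_r,
                                ph.dense_f_ul, None)

    state, records = _chunked_run(state, table, run, spec, observe)
    return ScenarioResult(spec, state, records, phases)


def droplet_persists(result: ScenarioResult, fraction: float = 0.2,
                     tail: float = 1.0 / 3.0) -> bool:
    """Condensation criterion: the largest r < 1.2 contact cluster exceeds
    ``fraction`` of all cargo in every snapshot of the trailing window."""
    n_tot = result.final_state.n_cargo
    sizes = [p.largest_cluster for p in result.phases]
    k = max(1, int(len(sizes) * tail))
    return all(s > fraction * n_tot for s in sizes[-k:])


def condensation_threshold(eps_values=(1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6),
                           n_cargo: int = 850, box: float = 40.0,
                           n_steps: int = 100_000, seeds=(1, 2, 3),
                           snapshot_stride: int = 10_000):
    """Single-species vapor-liquid threshold at the working concentration.

    Scans the cargo-cargo well depth; each point is declared condensed when
    the planted droplet persists (majority of seeds).  Returns
    ``(midpoint, details)`` where the midpoint brackets the threshold
    between the highest evaporating and lowest persisting well depth.
    """
    details = {}
    for eps in eps_values:
        table = InteractionTable(eps_rr=eps, eps_gg=eps, eps_rg=eps)
        votes = []
        for sd in seeds:
            spec = ScenarioSpec(kind="bulk", n_cargo_r=n_cargo, n_cargo_g=0,
                                box=box, n_steps=n_steps,
                                snapshot_stride=snapshot_stride, seed=sd)
            res = run_droplet_bulk(spec, table)
            votes.append(droplet_persists(res))
        details[eps] = votes
    condensed = {e: (sum(v) * 2 > len(v)) for e, v in details.items()}
    evap = [e for e, c in sorted(condensed.items()) if not c]
    cond = [e for e, c in sorted(condensed.items()) if c]
    if not cond:
        raise RuntimeError(f"no condensation in scan: {details}")
    if not evap:
        raise RuntimeError(f"condensation at every well depth: {details}")
    lo = max(evap)
    hi = min(e for e in cond if e > lo)
    return 0.5 * (lo + hi), details


def _interior_census(state, table, hull):
    d = state.cargo_pos - state.box / 2.0
    d -= state.box * np.round(d / state.box)
    inside = np.all(d @ hull.equations[:, :3].T + hull.equations[:, 3] <= 0.0,
                    axis=1)
    ids = np.where(inside)[0]
    n_c = len(ids)
    f_r = float(np.mean(state.cargo_species[ids] == 0)) if n_c else None
    f_ul = None
    if n_c >= 2:
        counts = cargo_pair_counts(state, subset=ids)
        f_ul = mixing_metrics(counts, f_r).f_ul
    return ids, n_c, f_r, f_ul


def run_permeable_shell(spec: ScenarioSpec, table: InteractionTable,
                        run: RunConfig | None = None) -> ScenarioResult:
    """Equilibrium encapsulation reference: a complete, immobile shell with
    one pentamer removed (permeable to cargo, shell-cargo attraction
    active), immersed in the reference cargo bath.

    Records the interior cargo census (N_C, f_R, f_UL) per snapshot;
    equilibration is monitored by the plateau of these observables
    (two-window mean difference within the combined standard error).
    """
    assert spec.kind == "permeable_shell"
    from scipy.spatial import ConvexHull

    run = run or RunConfig(n_steps=spec.n_steps, seed=spec.seed)
    bp = build_shell_blueprint()
    shell = state_from_blueprint(bp, box=spec.box, drop_bodies=(0,),
                                 fixed=True)
    bath = init_random(0, 0, spec.n_cargo_r, spec.n_cargo_g, spec.box,
                       spec.seed, min_separation=spec.min_separation,
                       table=table)
    # drop bath cargo that overlaps any shell pseudoatom (cargo may start
    # inside the shell; only wall contacts are forbidden)
    from scipy.spatial import cKDTree
    _, _, _, shell_sites = shell.site_arrays()
    tree = cKDTree(shell_sites % spec.box, boxsize=spec.box)
    dist, _ = tree.query(bath.cargo_pos % spec.box)
    keep = dist > 1.2
    state = SimulationState(
        templates=shell.templates, body_species=shell.body_species,
        body_pos=shell.body_pos, body_quat=shell.body_quat,
        cargo_pos=bath.cargo_pos[keep],
        cargo_species=bath.cargo_species[keep], box=spec.box)
    state.body_fixed[:] = True
    hull = ConvexHull(shell.body_pos - spec.box / 2.0)

    def observe(st):
        ids, n_c, f_r, f_ul = _interior_census(st, table, hull)
        return ObservableRecord(st.time, 0.0, 0, float(n_c), f_r, f_ul, None)

    state, records = _chunked_run(state, table, run, spec, observe)
    return ScenarioResult(spec, state, records)


def equilibrated(records, window: int = 5) -> bool:
    """Plateau test on the interior census: the difference of the last two
    window means is within their combined standard error."""
    vals = np.array([r.mean_n_c for r in records if r.mean_n_c is not None])
    if len(vals) < 2 * window:
        return False
    a = vals[-2 * window:-window]
    b = vals[-window:]
    se = np.sqrt(a.var() / window + b.var() / window)
    return bool(abs(a.mean() - b.mean()) <= max(se, 1.0))


def run_trials(runner, spec: ScenarioSpec, table: InteractionTable,
               n_trials: int | None = None):
    """Independent trials with seeds spec.seed, spec.seed + 1, ..."""
    n = spec.n_trials if n_trials is None else n_trials
    out = []
    for k in range(n):
        out.append(runner(replace(spec, seed=spec.seed + k), table))
    return out


# ---------------------------------------------------------------------------
# planted fixtures (deterministic configurations with known ground truth)
# ---------------------------------------------------------------------------

def _lattice_ball(radius: float, spacing: float, center, jitter=0.0, rng=None):
    n = int(np.ceil(2 * radius / spacing)) + 1
    ax = (np.arange(n) - (n - 1) / 2.0) * spacing
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    g = g[np.linalg.norm(g, axis=1) <= radius]
    if jitter and rng is not None:
        g = g + rng.uniform(-jitter, jitter, size=g.shape)
    return g + np.asarray(center)


def make_fixture(kind: str, box: float = 40.0, n: int = 150,
                 f_r: float = 0.5, seed: int = 0, spacing: float | None = None):
    """Planted configurations with known ground truth.

    Returns ``(state, truth)`` where ``truth`` records the planted values
    (shell completeness, N_C, f_R, phase label).  The filled-shell cargo
    lattice is geometric (spacing chosen to fit ``n`` points), intended for
    analysis tests rather than as a physical configuration.
    """
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0)
    if kind == "complete_shell":
        bp = build_shell_blueprint()
        st = state_from_blueprint(bp, box=box)
        return st, {"complete": True, "n_pent": 12, "n_hex": 20}
    if kind == "filled_shell":
        bp = build_shell_blueprint()
        st = state_from_blueprint(bp, box=box)
        from scipy.spatial import ConvexHull
        hull = ConvexHull(st.body_pos - center)
        if spacing is None:
            spacing = 0.55
            while spacing > 0.2:
                pts = _lattice_ball(2.4, spacing, np.zeros(3))
                pts = pts[np.all(pts @ hull.equations[:, :3].T
                                 + hull.equations[:, 3] <= -0.15, axis=1)]
                if len(pts) >= n:
                    break
                spacing *= 0.95
        else:
            pts = _lattice_ball(2.4, spacing, np.zeros(3))
            pts = pts[np.all(pts @ hull.equations[:, :3].T
                             + hull.equations[:, 3] <= -0.15, axis=1)]
        if len(pts) < n:
            raise ValueError(f"cannot plant {n} interior cargo")
        pts = pts[rng.permutation(len(pts))[:n]] + center
        spc = np.zeros(n, dtype=np.int64)
        spc[rng.permutation(n)[:n - int(round(f_r * n))]] = 1
        st = SimulationState(st.templates, st.body_species, st.body_pos,
                             st.body_quat, pts, spc, box)
        return st, {"complete": True, "n_c": n,
                    "f_r": float(np.mean(spc == 0))}
    if kind in ("janus_globule", "mixed_globule"):
        radius = (n * 3.0 / (4.0 * np.pi * 0.9)) ** (1.0 / 3.0)
        pts = _lattice_ball(radius, 1.05, np.zeros(3))
        while len(pts) < n:
            radius *= 1.05
            pts = _lattice_ball(radius, 1.05, np.zeros(3))
        order = np.argsort(np.linalg.norm(pts, axis=1))
        pts = pts[order[:n]]
        if kind == "janus_globule":
            spc = (pts[:, 2] < np.quantile(pts[:, 2], 1.0 - f_r)).astype(np.int64)
            label = "demixed_condensate"
        else:
            # checkerboard assignment: every lattice-neighbor pair is unlike
            idx = np.round((pts - pts.min(axis=0)) / 1.05).astype(int)
            spc = (idx.sum(axis=1) % 2).astype(np.int64)
            label = "mixed_condensate"
        st = SimulationState(default_templates(),
                             np.zeros(0, dtype=np.int64), np.zeros((0, 3)),
                             np.zeros((0, 4)), pts + center, spc, box)
        return st, {"phase": label, "n": n,
                    "f_r": float(np.mean(spc == 0))}
    if kind == "vapor":
        st = init_random(0, 0, int(round(n * f_r)), n - int(round(n * f_r)),
                         box, seed, min_separation=1.1)
        return st, {"phase": "homogeneous", "n": n}
    raise ValueError(f"unknown fixture kind {kind!r}")
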