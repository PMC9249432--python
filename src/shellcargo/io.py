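"""Trajectory and configuration I/O.

Trajectories use an extended-XYZ dialect.  Each frame holds one line per
rigid-subunit root and one per cargo particle:

    <n_records>
    Lattice="L 0 0 0 L 0 0 0 L" Properties=species:S:1:pos:R:3:body:I:1:\
quat:R:4:vel:R:3:angmom:R:3 time=<float>
    PEN x y z body qw qx qy qz vx vy vz lx ly lz
    HEX ...
    R   x y z -1   0 0 0 0    vx vy vz 0 0 0
    G   ...

Orientation quaternions and body-frame angular momenta are carried only by
body roots; the reader tolerates unknown extra columns and reconstructs a
``SimulationState`` losslessly (17 significant digits).  Pseudoatom
positions can additionally be exported for visualization.
"""

from __future__ import annotations

import numpy as np

from . import constants as C
from .geometry import KIND_NAMES
from .state import SimulationState, default_templates

__all__ = ["write_frames", "read_frames", "write_sites_xyz", "load_config",
           "ConfigError"]

_SPECIES = {0: "PEN", 1: "HEX"}
_CARGO = {0: "R", 1: "G"}


def write_frames(states, path, mode: str = "w") -> None:
    """Write one or more simulation states as extended-XYZ frames."""
    if isinstance(states, SimulationState):
        states = [states]
    with open(path, mode) as fh:
        for st in states:
            n = st.n_bodies + st.n_cargo
            fh.write(f"{n}\n")
            L = st.box
            fh.write(
                f'Lattice="{L:.17g} 0 0 0 {L:.17g} 0 0 0 {L:.17g}" '
                "Properties=species:S:1:pos:R:3:body:I:1:quat:R:4:"
                "vel:R:3:angmom:R:3 "
                f"time={st.time:.17g}\n")
            for b in range(st.n_bodies):
                row = [_SPECIES[int(st.body_species[b])],
                       *st.body_pos[b], b, *st.body_quat[b],
                       *st.body_vel[b], *st.body_angmom[b]]
                fh.write(_fmt(row))
            for c in range(st.n_cargo):
                row = [_CARGO[int(st.cargo_species[c])],
                       *st.cargo_pos[c], -1, 0.0, 0.0, 0.0, 0.0,
                       *st.cargo_vel[c], 0.0, 0.0, 0.0]
                fh.write(_fmt(row))


def _fmt(row):
    out = []
    for x in row:
        if isinstance(x, str):
            out.append(x)
        elif isinstance(x, (int, np.integer)):
            out.append(str(int(x)))
        else:
            out.append(f"{float(x):.17g}")
    return " ".join(out) + "\n"


def read_frames(path, templates: dict | None = None):
    """Read an extended-XYZ trajectory back into SimulationState frames."""
    templates = templates or default_templates()
    frames = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                if not header:
                    break
                continue
            try:
                n = int(header)
            except ValueError as e:
                raise ValueError(
                    f"{path}:{lineno}: expected an atom count") from e
            comment = fh.readline()
            lineno += 1
            box, t = _parse_comment(comment, path, lineno)
            bs, bp, bq, bv, bl = [], [], [], [], []
            cs, cp, cv = [], [], []
            for _ in range(n):
                parts = fh.readline().split()
                lineno += 1
                if len(parts) < 15:
                    raise ValueError(
                        f"{path}:{lineno}: truncated record")
                name = parts[0]
                vals = [float(x) for x in parts[1:15]]
                if name in ("PEN", "HEX"):
                    bs.append(0 if name == "PEN" else 1)
                    bp.append(vals[0:3])
                    bq.append(vals[4:8])
                    bv.append(vals[8:11])
                    bl.append(vals[11:14])
                elif name in ("R", "G"):
                    cs.append(0 if name == "R" else 1)
                    cp.append(vals[0:3])
                    cv.append(vals[8:11])
                else:
                    raise ValueError(
                        f"{path}:{lineno}: unknown record type {name!r}")
            nb, nc = len(bs), len(cs)
            frames.append(SimulationState(
                templates=templates,
                body_species=np.array(bs, dtype=np.int64),
                body_pos=np.array(bp).reshape(nb, 3),
                body_quat=(np.array(bq).reshape(nb, 4) if nb
                           else np.zeros((0, 4))),
                cargo_pos=np.array(cp).reshape(nc, 3),
                cargo_species=np.array(cs, dtype=np.int64),
                box=box, time=t,
                body_vel=np.array(bv).reshape(nb, 3),
                body_angmom=np.array(bl).reshape(nb, 3),
                cargo_vel=np.array(cv).reshape(nc, 3)))
    return frames


def _parse_comment(comment, path, lineno):
    import re
    m = re.search(r'Lattice="([^"]+)"', comment)
    if not m:
        raise ValueError(f"{path}:{lineno}: missing Lattice in comment line")
    vals = [float(x) for x in m.group(1).split()]
    box = vals[0]
    m = re.search(r"time=([0-9eE+.\-]+)", comment)
    t = float(m.group(1)) if m else 0.0
    return box, t


def write_sites_xyz(state: SimulationState, path) -> None:
    """Export every pseudoatom and cargo particle (visualization only)."""
    _, typ, bod, pos = state.site_arrays()
    names = {**{k: v for k, v in KIND_NAMES.items()},
             C.TYPE_CARGO_R: "R", C.TYPE_CARGO_G: "G"}
    with open(path, "w") as fh:
        fh.write(f"{len(typ)}\n")
        L = state.box
        fh.write(f'Lattice="{L} 0 0 0 {L} 0 0 0 {L}" '
                 "Properties=species:S:1:pos:R:3:body:I:1\n")
        for t, b, p in zip(typ, bod, pos):
            fh.write(f"{names[int(t)]} {p[0]:.8g} {p[1]:.8g} {p[2]:.8g} "
                     f"{int(b)}\n")


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


_SCENARIO_KEYS = {
    "scenario", "eps_ss", "eps_sc", "eps_rr", "eps_gg", "eps_rg",
    "n_pentamers", "n_hexamers", "n_cargo_r", "n_cargo_g", "box",
    "timestep", "n_steps", "friction", "seed", "n_trials",
    "snapshot_stride", "min_separation",
}


def load_config(path):
    """Load a YAML scenario configuration.

    Returns ``(ScenarioSpec, InteractionTable, RunConfig)``.  Omitted fields
    take the scenario's reference defaults (timestep 0.005; for assembly:
    48 pentamers + 80 hexamers + 854 cargo in a box of side 40).  Every
    problem found is reported at once.
    """
    import yaml

    from .dynamics import RunConfig
    from .interactions import InteractionTable
    from .scenarios import ScenarioSpec

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems = []
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = sorted(set(raw) - _SCENARIO_KEYS)
    for k in unknown:
        hint = ""
        if k in ("eps_sc_r", "eps_sc_g", "eps_scr", "eps_scg"):
            hint = (" (the shell-cargo affinity is a single eps_sc, "
                    "identical for both cargo species)")
        problems.append(f"unknown key {k!r}{hint}")
    ts = raw.get("timestep", C.DEFAULT_TIMESTEP)
    if not isinstance(ts, (int, float)) or ts <= 0:
        problems.append(f"timestep must be positive, got {ts!r}")
    fr = raw.get("friction", C.DEFAULT_FRICTION)
    if not isinstance(fr, (int, float)) or fr < 0:
        problems.append(f"friction must be non-negative, got {fr!r}")
    for k in ("eps_ss", "eps_sc", "eps_rr", "eps_gg", "eps_rg"):
        v = raw.get(k, 0.0)
        if not isinstance(v, (int, float)) or v < 0:
            problems.append(f"{k} must be a non-negative number, got {v!r}")
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))

    kind = raw.get("scenario", "assembly")
    spec = ScenarioSpec.with_defaults(
        kind,
        **{k: raw[k] for k in raw if k in {
            "n_pentamers", "n_hexamers", "n_cargo_r", "n_cargo_g", "box",
            "n_steps", "seed", "n_trials", "snapshot_stride",
            "min_separation"}})
    table = InteractionTable(
        eps_ss=float(raw.get("eps_ss", 2.0)),
        eps_sc=float(raw.get("eps_sc", 6.0)),
        eps_rr=float(raw.get("eps_rr", 1.3)),
        eps_gg=float(raw.get("eps_gg", 1.3)),
        eps_rg=float(raw.get("eps_rg", 1.3)))
    run = RunConfig(timestep=float(ts), n_steps=spec.n_steps,
                    friction=float(fr), seed=spec.seed)
    return spec, table, run
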