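"""Spatial embedding of a simulated lineage by overdamped particle dynamics.

Each cell is a particle with a position, an outward apicobasal axis and an
interaction radius derived from its current cycle-mean volume
(R = (3 v / 4 pi)^(1/3)). Neighbouring particles interact through:

* an attraction-repulsion force along the particle-particle direction:
  repulsive below the equilibrium distance r_eq (coefficient ``omega_rep``),
  adhesive between r_eq and the maximum contact distance r_max (homotypic or
  heterotypic coefficient depending on the pair's types), zero at r_eq and
  beyond r_max, continuous in r;
* a planarity-conservation force (coefficient ``k_rig``) restoring each pair
  to the local tangent plane, referenced to the bisector of the two cells'
  outward normals; it stands in for the blastocoel turgor pressure keeping
  the epithelium monolayered (an explicit outward pressure term is available
  but off by default).

Motion is overdamped: velocity = total force / damping. Divisions scheduled
by the lineage are executed by replacing the mother with two daughters
separated along a uniformly random direction in the tangential plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from blastula.simulator import LineageArrays

BAND_ORDER = ("Mes", "Mac", "LMic", "SMic")  # animal pole to vegetal pole


class MechanicsError(RuntimeError):
    pass


@dataclass(frozen=True)
class MechParams:
    """Force coefficients and integration settings.

    ``c_eq`` and ``c_max`` are dimensionless multipliers of the mean pair
    radius: r_eq = c_eq (R_i + R_j)/2, r_max = c_max (R_i + R_j)/2.
    """

    omega_rep: float = 250.0
    omega_adh_homo: float = 100.0
    omega_adh_hetero: float = 100.0
    k_rig: float = 1000.0
    c_eq: float = 0.9
    c_max: float = 1.3
    damping: float = 1000.0
    dt: float = 0.1
    max_disp_factor: float = 0.1  # displacement cap per step, units of min r_eq
    instab_factor: float = 0.5  # abort threshold, units of min r_eq
    dt_floor: float = 1e-5
    #: outward turgor pressure per cell. Without it the shell has no way to
    #: grow its radius as divisions add surface area, and buckles inward at
    #: moderate adhesion regardless of k_rig; a modest default keeps the
    #: monolayer under tension as in the living blastula.
    pressure: float = 100.0

    def __post_init__(self):
        if not (0 < self.c_eq < self.c_max):
            raise ValueError("require 0 < c_eq < c_max")
        if self.dt <= 0 or self.damping <= 0:
            raise ValueError("dt and damping must be > 0")
        for name in ("omega_rep", "omega_adh_homo", "omega_adh_hetero", "k_rig"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def radius_from_volume(vol) -> np.ndarray:
    return (3.0 * np.asarray(vol) / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class MechanicalState:
    """Particle snapshot plus its cached contact graph."""

    pos: np.ndarray  # (n, 3)
    axis: np.ndarray  # (n, 3) unit outward
    radius: np.ndarray  # (n,)
    type_code: np.ndarray  # (n,) int
    types: Tuple[str, ...]
    cell_index: np.ndarray  # (n,) int index into the lineage arrays
    time: float = 0.0
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    edge_r: np.ndarray = field(default_factory=lambda: np.empty(0))
    edge_u: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __len__(self) -> int:
        return len(self.radius)

    @property
    def centroid(self) -> np.ndarray:
        return self.pos.mean(axis=0)

    def copy(self) -> "MechanicalState":
        return MechanicalState(
            pos=self.pos.copy(),
            axis=self.axis.copy(),
            radius=self.radius.copy(),
            type_code=self.type_code.copy(),
            types=self.types,
            cell_index=self.cell_index.copy(),
            time=self.time,
            edges=self.edges.copy(),
            edge_r=self.edge_r.copy(),
            edge_u=self.edge_u.copy(),
        )

    def degrees(self) -> np.ndarray:
        d = np.zeros(len(self), dtype=np.int64)
        if len(self.edges):
            np.add.at(d, self.edges[:, 0], 1)
            np.add.at(d, self.edges[:, 1], 1)
        return d


# ------------------------------------------------------------- contact graph


def pair_r_eq(state: MechanicalState, params: MechParams, i, j) -> np.ndarray:
    return params.c_eq * (state.radius[i] + state.radius[j]) / 2.0


def pair_r_max(state: MechanicalState, params: MechParams, i, j) -> np.ndarray:
    return params.c_max * (state.radius[i] + state.radius[j]) / 2.0


def contact_graph(
    state: MechanicalState, params: MechParams, rng: Optional[np.random.Generator] = None
) -> MechanicalState:
    """Refresh the contact graph: edge (i, j) iff r_ij < c_max (R_i + R_j)/2.

    Caches pair distances and unit vectors (from j to i). Coincident
    particles get a seeded random direction and a warning.
    """
    if not np.all(np.isfinite(state.pos)):
        raise MechanicsError("non-finite particle positions")
    reach = params.c_max * float(state.radius.max()) if len(state) else 0.0
    tree = cKDTree(state.pos)
    pairs = tree.query_pairs(r=reach, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = state.pos[i] - state.pos[j]
        r = np.linalg.norm(d, axis=1)
        keep = r < pair_r_max(state, params, i, j)
        pairs, d, r = pairs[keep], d[keep], r[keep]
    else:
        d = np.empty((0, 3))
        r = np.empty(0)
    u = np.zeros_like(d)
    tiny = r < 1e-9
    if np.any(tiny):
        warnings.warn("coincident particles; using seeded random separation direction")
        rand = (rng or np.random.default_rng(0)).normal(size=(int(tiny.sum()), 3))
        u[tiny] = rand / np.linalg.norm(rand, axis=1, keepdims=True)
    ok = ~tiny
    u[ok] = d[ok] / r[ok, None]
    state.edges = pairs.astype(np.int64)
    state.edge_r = r
    state.edge_u = u
    return state


# -------------------------------------------------------------------- forces


def _pair_force_mag(
    r: np.ndarray, r_eq: np.ndarray, r_max: np.ndarray, omega_rep: float, omega_adh
) -> np.ndarray:
    """Signed magnitude along u_ij: positive pushes the pair apart.

    Repulsion omega_rep (r_eq - r)/r_eq below r_eq; a single adhesive lobe
    -omega_adh 4 (r - r_eq)(r_max - r)/(r_max - r_eq)^2 between r_eq and
    r_max; zero at r_eq and beyond r_max, continuous everywhere.
    """
    rep = omega_rep * (r_eq - r) / r_eq
    adh = -omega_adh * 4.0 * (r - r_eq) * (r_max - r) / (r_max - r_eq) ** 2
    return np.where(r < r_eq, rep, np.where(r < r_max, adh, 0.0))


def _edge_adhesion(state: MechanicalState, params: MechParams) -> np.ndarray:
    same = state.type_code[state.edges[:, 0]] == state.type_code[state.edges[:, 1]]
    return np.where(same, params.omega_adh_homo, params.omega_adh_hetero)


def attraction_repulsion(
    i: int, j: int, state: MechanicalState, params: MechParams
) -> np.ndarray:
    """Force exerted by particle j on particle i (requires a cached edge)."""
    for e, (a, b) in enumerate(state.edges):
        if (a, b) in ((i, j), (j, i)):
            sign = 1.0 if a == i else -1.0
            omega = (
                params.omega_adh_homo
                if state.type_code[i] == state.type_code[j]
                else params.omega_adh_hetero
            )
            mag = _pair_force_mag(
                state.edge_r[e : e + 1],
                pair_r_eq(state, params, i, j),
                pair_r_max(state, params, i, j),
                params.omega_rep,
                omega,
            )
            return sign * mag[0] * state.edge_u[e]
    raise MechanicsError(f"no contact edge between {i} and {j}")


def _normals(state: MechanicalState) -> np.ndarray:
    d = state.pos - state.centroid
    nrm = np.linalg.norm(d, axis=1, keepdims=True)
    nrm[nrm < 1e-12] = 1.0
    return d / nrm


def _scatter_pair_forces(
    F: np.ndarray, i: np.ndarray, j: np.ndarray, fvec: np.ndarray
) -> None:
    n = len(F)
    for c in range(3):
        F[:, c] += np.bincount(i, weights=fvec[:, c], minlength=n)
        F[:, c] -= np.bincount(j, weights=fvec[:, c], minlength=n)


def pairwise_forces(state: MechanicalState, params: MechParams) -> np.ndarray:
    """Total attraction-repulsion force per particle (Newton's third law holds)."""
    F = np.zeros_like(state.pos)
    if not len(state.edges):
        return F
    i, j = state.edges[:, 0], state.edges[:, 1]
    mag = _pair_force_mag(
        state.edge_r,
        pair_r_eq(state, params, i, j),
        pair_r_max(state, params, i, j),
        params.omega_rep,
        _edge_adhesion(state, params),
    )
    _scatter_pair_forces(F, i, j, mag[:, None] * state.edge_u)
    return F


def planarity_forces(state: MechanicalState, params: MechParams) -> np.ndarray:
    """Planarity-conservation force per particle.

    For each contact pair the relative position is projected on the bisector
    of the two outward normals; the projection is restored with coefficient
    k_rig. Zero for locally coplanar neighbourhoods with aligned normals.
    """
    F = np.zeros_like(state.pos)
    if not len(state.edges) or params.k_rig == 0:
        return F
    n = _normals(state)
    i, j = state.edges[:, 0], state.edges[:, 1]
    b = n[i] + n[j]
    norm = np.linalg.norm(b, axis=1, keepdims=True)
    norm[norm < 1e-12] = 1.0
    b = b / norm
    d = np.einsum("ij,ij->i", state.pos[i] - state.pos[j], b)
    _scatter_pair_forces(F, i, j, -params.k_rig * d[:, None] * b)
    return F


def planarity_force(i: int, state: MechanicalState, params: MechParams) -> np.ndarray:
    """Planarity force on a single particle (test/inspection helper)."""
    return planarity_forces(state, params)[i]


def total_forces(state: MechanicalState, params: MechParams) -> np.ndarray:
    F = pairwise_forces(state, params) + planarity_forces(state, params)
    if params.pressure:
        F = F + params.pressure * _normals(state)
    return F


# ---------------------------------------------------------------- integration


def _stable_dt(state: MechanicalState, params: MechParams) -> float:
    """Explicit-Euler stability bound: dt <= damping / max nodal stiffness.

    Per-edge stiffness is the steepest force slope (repulsion omega_rep/r_eq
    or the adhesion lobe's 4 omega_adh / (r_max - r_eq)) plus the planarity
    coefficient; nodal stiffness sums over incident edges. The bound keeps a
    factor-2 margin below the oscillatory limit 2 damping / k.
    """
    if not len(state.edges):
        return params.dt
    i, j = state.edges[:, 0], state.edges[:, 1]
    r_eq = pair_r_eq(state, params, i, j)
    r_max = pair_r_max(state, params, i, j)
    k_edge = (
        np.where(
            state.edge_r < r_eq,
            params.omega_rep / r_eq,
            4.0 * _edge_adhesion(state, params) / (r_max - r_eq),
        )
        + params.k_rig
    )
    n = len(state)
    k_node = np.bincount(i, weights=k_edge, minlength=n) + np.bincount(
        j, weights=k_edge, minlength=n
    )
    k_max = float(k_node.max())
    return params.damping / k_max if k_max > 0 else params.dt


def step(
    state: MechanicalState,
    params: MechParams,
    rng: Optional[np.random.Generator] = None,
    dt: Optional[float] = None,
) -> float:
    """Advance one adaptive step in place; returns the time step actually taken.

    The displacement per step is capped at ``max_disp_factor`` times the
    smallest pair equilibrium distance; a step exceeding ``instab_factor``
    of it (possible only at the dt floor) aborts with a diagnostic.
    """
    contact_graph(state, params, rng)
    F = total_forces(state, params)
    vel = F / params.damping
    speed = float(np.max(np.linalg.norm(vel, axis=1))) if len(vel) else 0.0
    r_eq_min = params.c_eq * float(state.radius.min()) if len(state) else 1.0
    dt_eff = dt if dt is not None else params.dt
    if speed > 0:
        dt_eff = min(dt_eff, params.max_disp_factor * r_eq_min / speed)
    dt_eff = min(dt_eff, _stable_dt(state, params))
    if dt_eff < params.dt_floor:
        dt_eff = params.dt_floor
        if speed * dt_eff > params.instab_factor * r_eq_min:
            raise MechanicsError(
                f"instability at t={state.time:.3f}: max speed {speed:.3g}, "
                f"dt floor {params.dt_floor}, r_eq_min {r_eq_min:.3g}"
            )
    state.pos = state.pos + vel * dt_eff
    if not np.all(np.isfinite(state.pos)):
        raise MechanicsError(f"non-finite position at t={state.time:.3f}")
    state.axis = _normals(state)
    state.time += dt_eff
    return dt_eff


def advance(
    state: MechanicalState,
    params: MechParams,
    t_target: float,
    rng: Optional[np.random.Generator] = None,
) -> None:
    while state.time < t_target - 1e-9:
        step(state, params, rng, dt=min(params.dt, t_target - state.time))


# ------------------------------------------------------------------ divisions


def _tangent_basis(axis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(axis, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(axis, e1)


def divide(
    state: MechanicalState,
    lineage: LineageArrays,
    mother_row: int,
    rng: np.random.Generator,
    params: MechParams,
) -> MechanicalState:
    """Replace one particle by its two daughters.

    The separation direction lies in the mother's tangential plane at a
    uniformly random angle; daughters start 0.5 r_eq apart (their own pair
    equilibrium distance), symmetric about the mother centre, with radii set
    from their cycle-mean volumes and outward radial axes.
    """
    mi = int(state.cell_index[mother_row])
    kids = lineage.children_of(mi)
    if len(kids) != 2:
        raise MechanicsError(f"lineage cell {mi} has {len(kids)} daughters")
    axis = state.axis[mother_row]
    e1, e2 = _tangent_basis(axis)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    direction = np.cos(theta) * e1 + np.sin(theta) * e2
    r_kids = radius_from_volume(lineage.vol[kids])
    sep = 0.5 * params.c_eq * float(r_kids.sum()) / 2.0
    p0 = state.pos[mother_row]
    new_pos = np.stack([p0 + 0.5 * sep * direction, p0 - 0.5 * sep * direction])

    keep = np.arange(len(state)) != mother_row
    pos = np.vstack([state.pos[keep], new_pos])
    radius = np.concatenate([state.radius[keep], r_kids])
    type_code = np.concatenate(
        [state.type_code[keep], lineage.type_code[kids]]
    )
    cell_index = np.concatenate([state.cell_index[keep], kids])
    out = MechanicalState(
        pos=pos,
        axis=np.zeros_like(pos),
        radius=radius,
        type_code=type_code,
        types=state.types,
        cell_index=cell_index,
        time=state.time,
    )
    out.axis = _normals(out)
    return out


def contact_source(
    states: List[MechanicalState],
    params: MechParams,
    id_format: str = "c{:04d}",
) -> dict:
    """Contact edges per checkpoint time, keyed for lineage-level analysis.

    Returns {time: [(cell_id_i, cell_id_j), ...]} with ids formatted like the
    tree exporter's, so the result feeds
    :func:`blastula.lineage.contact_degrees` directly.
    """
    out = {}
    for st in states:
        contact_graph(st, params)
        out[st.time] = [
            (id_format.format(st.cell_index[i]), id_format.format(st.cell_index[j]))
            for i, j in st.edges
        ]
    return out


# -------------------------------------------------------------- initial state


def initial_layout(
    lineage: LineageArrays,
    c_eq: float = 0.9,
    shell_radius: Optional[float] = None,
) -> MechanicalState:
    """Deterministic 32-cell spherical shell with latitudinal type bands.

    Root cells are placed on a Fibonacci sphere ordered from the animal pole
    (+z) to the vegetal pole, with types assigned in band order (Mes cap,
    Mac band, LMic, then SMic at the pole). The shell radius targets a
    hexagonal packing with nearest-neighbour spacing equal to the pair
    equilibrium distance c_eq * mean radius, so the layout starts near
    mechanical equilibrium.
    """
    roots = np.flatnonzero(lineage.mother == -1)
    radius = radius_from_volume(lineage.vol[roots])
    if shell_radius is None:
        spacing = c_eq * float(radius.mean())
        shell_radius = spacing * float(
            np.sqrt(len(roots) * np.sqrt(3.0) / (8.0 * np.pi))
        )
    n = len(roots)
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)  # z descending

    labels = [lineage.types[c] for c in lineage.type_code[roots]]
    band_rank = {k: r for r, k in enumerate(BAND_ORDER)}
    order = np.argsort([band_rank.get(lab, len(BAND_ORDER)) for lab in labels], kind="stable")
    pos = np.empty((n, 3))
    pos[order] = pts * shell_radius  # band-ordered cells fill top-to-bottom slots

    state = MechanicalState(
        pos=pos,
        axis=np.zeros_like(pos),
        radius=radius,
        type_code=lineage.type_code[roots].copy(),
        types=lineage.types,
        cell_index=roots,
        time=0.0,
    )
    state.axis = _normals(state)
    return state


# --------------------------------------------------------------------- embed


def embed(
    lineage: LineageArrays,
    params: MechParams,
    seed: int,
    t_end: Optional[float] = None,
    settle: float = 20.0,
    checkpoint_every: Optional[float] = None,
    initial_state: Optional[MechanicalState] = None,
    monitor=None,
) -> List[MechanicalState]:
    """Run the full spatial embedding of a lineage; returns state checkpoints.

    Divisions are executed at the lineage's mitosis times (cells without
    instantiated daughters never divide). The run ends ``settle`` minutes
    after the last executed division unless ``t_end`` is given. The final
    state is always the last checkpoint. ``monitor``, if given, is called
    with the state after each division batch and may return True to stop the
    run early (used by the sweep to cut short irreversibly collapsed runs).
    Deterministic given (lineage, params, seed).
    """
    rng = np.random.default_rng(seed)
    state = (
        initial_state.copy()
        if initial_state is not None
        else initial_layout(lineage, c_eq=params.c_eq)
    )

    has_kids = np.zeros(len(lineage), dtype=bool)
    has_kids[lineage.mother[lineage.mother >= 0]] = True
    div_times = lineage.division.copy()
    div_times[~has_kids] = np.inf
    if t_end is None:
        executed = div_times[np.isfinite(div_times)]
        t_end = (float(executed.max()) if len(executed) else 0.0) + settle

    checkpoints = [state.copy()]
    next_cp = checkpoint_every
    while state.time < t_end - 1e-9:
        pending = div_times[state.cell_index]
        future = pending[pending > state.time + 1e-9]
        t_next_div = float(future.min()) if len(future) else np.inf
        target = min(t_end, t_next_div)
        if next_cp is not None:
            target = min(target, next_cp)
        advance(state, params, target, rng)
        # execute divisions due now, in deterministic lineage order
        while True:
            due = np.flatnonzero(div_times[state.cell_index] <= state.time + 1e-9)
            if not len(due):
                break
            row = int(due[np.argmin(state.cell_index[due])])
            state = divide(state, lineage, row, rng, params)
        if monitor is not None and monitor(state):
            break
        if next_cp is not None and state.time >= next_cp - 1e-9:
            checkpoints.append(state.copy())
            next_cp += checkpoint_every
    contact_graph(state, params, rng)
    checkpoints.append(state.copy())
    return checkpoints
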