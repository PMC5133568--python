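"""Objective functions and the 2-D adhesion-parameter sweep.

Three objective scores describe a mechanical state: sphericity of the global
shape, planarity of the epithelial monolayer, and similarity of the borders
between cell populations (Mic/Mac and Mac/Mes) to a reference layout. A
combined fitness (weighted sum) and threshold-based phase labels
(spherical-planar, polylobular, collapsed, other) summarise each point of a
grid over the homotypic/heterotypic adhesion coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from blastula.mechanics import (
    MechParams,
    MechanicalState,
    MechanicsError,
    contact_graph,
    embed,
    initial_layout,
)
from blastula.simulator import LineageArrays

#: population pairs defining the scored borders
BORDERS: Dict[str, Tuple[frozenset, frozenset]] = {
    "Mic/Mac": (frozenset({"LMic", "SMic"}), frozenset({"Mac"})),
    "Mac/Mes": (frozenset({"Mac"}), frozenset({"Mes"})),
}

PHASES = ("spherical-planar", "polylobular", "collapsed", "other")


@dataclass
class ObjectiveScores:
    sphericity: float
    planarity: float
    borders: Dict[str, float]
    n_low_degree: int = 0

    @property
    def border_total(self) -> float:
        return float(sum(self.borders.values()))

    def fitness(self, weights: Tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
        w1, w2, w3 = weights
        return w1 * self.sphericity + w2 * self.planarity - w3 * self.border_total


# ----------------------------------------------------------------- objectives


def sphericity(state: MechanicalState) -> float:
    """1 - coefficient of variation of particle distances to the centroid."""
    if len(state) < 4:
        raise ValueError("sphericity needs at least 4 particles")
    r = np.linalg.norm(state.pos - state.centroid, axis=1)
    mean = r.mean()
    if mean <= 0:
        return 0.0
    return float(np.clip(1.0 - r.std() / mean, 0.0, 1.0))


def planarity(
    state: MechanicalState, params: Optional[MechParams] = None
) -> Tuple[float, int]:
    """Mean local coplanarity of each cell's neighbourhood, in [0, 1].

    For each cell with >= 3 neighbours, the out-of-plane dispersion is the
    smallest eigenvalue share of the neighbourhood covariance (cell plus
    neighbours): local = 1 - sqrt(3 * lambda_min / sum(lambda)), which is 1
    for a perfect plane and 0 for an isotropic cloud. Cells with fewer
    neighbours are neutral (excluded from the mean); their count is the
    second return value.
    """
    if params is not None:
        contact_graph(state, params)
    neigh: List[List[int]] = [[] for _ in range(len(state))]
    for a, b in state.edges:
        neigh[a].append(b)
        neigh[b].append(a)
    scores = []
    n_low = 0
    for i, nb in enumerate(neigh):
        if len(nb) < 3:
            n_low += 1
            continue
        pts = state.pos[[i] + nb]
        cov = np.cov((pts - pts.mean(axis=0)).T)
        ev = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        tot = ev.sum()
        scores.append(1.0 - np.sqrt(3.0 * ev[0] / tot) if tot > 0 else 0.0)
    if not scores:
        return 0.0, n_low
    return float(np.clip(np.mean(scores), 0.0, 1.0)), n_low


def border_descriptor(
    state: MechanicalState, params: Optional[MechParams] = None
) -> Dict[str, Dict[str, int]]:
    """Per-border interface size: heterotypic edge count and border-cell count."""
    if params is not None:
        contact_graph(state, params)
    labels = np.asarray(state.types)[state.type_code]
    present = set(labels)
    out: Dict[str, Dict[str, int]] = {}
    for name, (pa, pb) in BORDERS.items():
        if not (present & pa) or not (present & pb):
            continue  # a population is absent: border skipped
        in_a = np.isin(labels, list(pa))
        in_b = np.isin(labels, list(pb))
        if len(state.edges):
            i, j = state.edges[:, 0], state.edges[:, 1]
            cross = (in_a[i] & in_b[j]) | (in_b[i] & in_a[j])
            cells = np.unique(np.concatenate([i[cross], j[cross]]))
            out[name] = {"edges": int(cross.sum()), "border_cells": int(len(cells))}
        else:
            out[name] = {"edges": 0, "border_cells": 0}
    return out


def border_similarity(
    state: MechanicalState,
    reference: Mapping[str, Mapping[str, int]],
    params: Optional[MechParams] = None,
) -> Dict[str, float]:
    """Discrepancy per border between the state's interface and a reference.

    Combines the relative differences of the heterotypic edge count (size of
    the interface) and of the border-cell count (a tortuosity proxy: a
    wiggly interface involves more cells for the same populations).
    Zero for a state matching the reference; symmetric in the two
    populations of each border.
    """
    desc = border_descriptor(state, params)
    out = {}
    for name, ref in reference.items():
        if name not in desc:
            continue
        d = desc[name]
        out[name] = float(
            abs(d["edges"] - ref["edges"]) / max(ref["edges"], 1)
            + abs(d["border_cells"] - ref["border_cells"]) / max(ref["border_cells"], 1)
        )
    return out


def banded_reference(
    lineage: LineageArrays, params: MechParams
) -> Dict[str, Dict[str, int]]:
    """Reference border descriptor from the idealised latitudinal band layout.

    Builds a banded Fibonacci shell with the lineage's *final* per-type cell
    composition and measures its borders. Used when no measured specimen
    descriptor is supplied.
    """
    has_kids = np.zeros(len(lineage), dtype=bool)
    has_kids[lineage.mother[lineage.mother >= 0]] = True
    leaves = ~has_kids & ~lineage.is_stub
    final = LineageArrays(
        types=lineage.types,
        mother=np.full(int(leaves.sum()), -1, dtype=np.int64),
        type_code=lineage.type_code[leaves],
        generation=lineage.generation[leaves],
        birth=lineage.birth[leaves],
        division=lineage.division[leaves],
        x=lineage.x[leaves],
        vol=lineage.vol[leaves],
        surf=lineage.surf[leaves],
        is_stub=np.zeros(int(leaves.sum()), dtype=bool),
    )
    state = initial_layout(final, c_eq=params.c_eq)
    contact_graph(state, params)
    return border_descriptor(state)


def score_state(
    state: MechanicalState,
    params: MechParams,
    reference: Mapping[str, Mapping[str, int]],
) -> ObjectiveScores:
    contact_graph(state, params)
    p, n_low = planarity(state)
    return ObjectiveScores(
        sphericity=sphericity(state),
        planarity=p,
        borders=border_similarity(state, reference),
        n_low_degree=n_low,
    )


# -------------------------------------------------------------------- phases


def phase_label(
    s: float,
    p: float,
    planar_hi: float = 0.9,
    spherical_hi: float = 0.9,
    spherical_lo: float = 0.7,
    collapse_lo: float = 0.6,
) -> str:
    """Mutually exclusive threshold labels covering every completed run."""
    if p < collapse_lo:
        return "collapsed"
    if p > planar_hi and s > spherical_hi:
        return "spherical-planar"
    if p > planar_hi and s < spherical_lo:
        return "polylobular"
    return "other"


# --------------------------------------------------------------------- sweep


@dataclass
class SweepResult:
    runs: pd.DataFrame  # one row per (grid point, replicate)
    summary: pd.DataFrame  # one row per grid point, with phase and mask
    omega_homo: np.ndarray
    omega_hetero: np.ndarray
    weights: Tuple[float, float, float]


def default_grid(num: int = 5, lo: float = 10.0, hi: float = 1000.0) -> np.ndarray:
    return np.geomspace(lo, hi, num)


def _run_seed(base_seed: int, gi: int, gj: int, rep: int) -> int:
    return int(
        np.random.SeedSequence([base_seed, gi, gj, rep]).generate_state(1)[0]
    )


def sweep(
    lineage: LineageArrays,
    mech_base: MechParams,
    omega_homo: Optional[Sequence[float]] = None,
    omega_hetero: Optional[Sequence[float]] = None,
    replicates: int = 3,
    base_seed: int = 0,
    reference: Optional[Mapping[str, Mapping[str, int]]] = None,
    weights: Tuple[float, float, float] = (1.0, 1.0, 1.0),
    t_end: Optional[float] = None,
    early_stop_planarity: Optional[float] = 0.25,
    early_stop_after: float = 60.0,
) -> SweepResult:
    """Exhaustive exploration of the (homotypic, heterotypic) adhesion plane.

    Runs ``replicates`` seeded embeddings per grid point, scores the final
    states, averages, labels the phase and computes the best-fit mask
    (spherical-planar points whose border discrepancy is at or below the
    median of that phase). Unstable runs are recorded as failed and excluded
    from the means. Fully deterministic given ``base_seed``.

    A run whose planarity drops below ``early_stop_planarity`` after
    ``early_stop_after`` minutes is scored in place: a collapsed aggregate
    does not recover, and integrating it further only burns time.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    oh = np.asarray(omega_homo if omega_homo is not None else default_grid(), dtype=float)
    oe = np.asarray(omega_hetero if omega_hetero is not None else default_grid(), dtype=float)
    if reference is None:
        reference = banded_reference(lineage, mech_base)

    rows = []
    for gi, o in enumerate(oh):
        for gj, e in enumerate(oe):
            params = replace(mech_base, omega_adh_homo=float(o), omega_adh_hetero=float(e))
            for rep in range(replicates):
                seed = _run_seed(base_seed, gi, gj, rep)
                rec = dict(
                    omega_homo=float(o),
                    omega_hetero=float(e),
                    gi=gi,
                    gj=gj,
                    replicate=rep,
                    seed=seed,
                    failed=False,
                )
                monitor = None
                if early_stop_planarity is not None:

                    def monitor(st, _p=params):  # noqa: B023 (bound via default)
                        if st.time < early_stop_after:
                            return False
                        contact_graph(st, _p)
                        return planarity(st)[0] < early_stop_planarity

                try:
                    final = embed(lineage, params, seed, t_end=t_end, monitor=monitor)[-1]
                    sc = score_state(final, params, reference)
                    rec.update(
                        sphericity=sc.sphericity,
                        planarity=sc.planarity,
                        border=sc.border_total,
                        fitness=sc.fitness(weights),
                        n_cells=len(final),
                    )
                except MechanicsError as err:
                    rec.update(
                        failed=True,
                        sphericity=np.nan,
                        planarity=np.nan,
                        border=np.nan,
                        fitness=np.nan,
                        n_cells=np.nan,
                        error=str(err),
                    )
                rows.append(rec)
    runs = pd.DataFrame(rows)

    grp = runs[~runs["failed"]].groupby(["gi", "gj"], as_index=False)
    summary = grp.agg(
        omega_homo=("omega_homo", "first"),
        omega_hetero=("omega_hetero", "first"),
        sphericity=("sphericity", "mean"),
        planarity=("planarity", "mean"),
        border=("border", "mean"),
        fitness=("fitness", "mean"),
        n_ok=("failed", "size"),
    )
    fails = runs.groupby(["gi", "gj"])["failed"].sum().rename("n_failed").reset_index()
    summary = summary.merge(fails, on=["gi", "gj"], how="left")
    summary["phase"] = [
        phase_label(s, p) for s, p in zip(summary["sphericity"], summary["planarity"])
    ]
    sp = summary["phase"] == "spherical-planar"
    if sp.any():
        med = float(summary.loc[sp, "border"].median())
        summary["best_fit"] = sp & (summary["border"] <= med + 1e-12)
    else:
        summary["best_fit"] = False
    return SweepResult(
        runs=runs, summary=summary, omega_homo=oh, omega_hetero=oe, weights=weights
    )
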