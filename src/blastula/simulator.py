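"""Stochastic artificial cell lineages drawn from a :class:`GroupModel`.

Simulation starts at the 32-cell stage (16 Mes, 8 Mac, 4 LMic, 4 SMic by
default). Each root draws its division time, mean volume and mean surface
from the initial-generation laws; each daughter draws its cycle length from
the group's normal law and its volume/surface from the mother's via
independent log-normal ratio draws. The mitosis time of a cell is the sum of
its ancestors' cycle lengths (plus the root division time), so division
times desynchronise as variances accumulate along the lineage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from blastula.lineage import CellTrack, EmbryoCurves, LineageTree
from blastula.model import GroupModel, ModelError

#: floor applied to drawn cycle lengths (minutes); normal laws have unbounded
#: support, but a non-positive cycle would break the tree ordering.
MIN_CYCLE = 1.0


@dataclass
class LineageArrays:
    """Array-of-columns representation of one simulated lineage.

    ``division`` is the mitosis time m_i; for terminal-generation cells it is
    the drawn (but not executed) division time. ``is_stub`` marks optional
    post-terminal daughters instantiated only so that the terminal
    generation's division is observable in the exported tree.
    """

    types: Tuple[str, ...]
    mother: np.ndarray  # int, -1 for roots
    type_code: np.ndarray  # int index into types
    generation: np.ndarray  # int
    birth: np.ndarray  # float, minutes
    division: np.ndarray  # float, minutes
    x: np.ndarray  # cycle length = division - birth
    vol: np.ndarray  # cycle-mean volume
    surf: np.ndarray  # cycle-mean surface
    is_stub: np.ndarray  # bool
    seed: Optional[int] = None

    def __len__(self) -> int:
        return len(self.mother)

    @property
    def type_labels(self) -> np.ndarray:
        return np.asarray(self.types)[self.type_code]

    def children_of(self, idx: int) -> np.ndarray:
        return np.flatnonzero(self.mother == idx)


def simulate(
    model: GroupModel,
    seed: int,
    generations: Optional[Tuple[int, int]] = None,
    terminal_stubs: bool = False,
) -> LineageArrays:
    """Draw one artificial lineage. Deterministic given (model, seed).

    ``generations`` restricts the simulated range (default: the model's
    root to max generation). With ``terminal_stubs`` the last generation's
    divisions are executed into inert daughter cells, which makes those
    divisions observable by feature extraction on the exported tree.
    """
    if generations is None:
        generations = (model.root_generation, model.max_generation)
    g0, g1 = generations
    if g0 != model.root_generation:
        raise ModelError("simulation must start at the model root generation")
    if g1 < g0:
        raise ModelError("empty generation range")
    rng = np.random.default_rng(seed)

    n_gens = g1 - g0 + 1 + (1 if terminal_stubs else 0)
    n_roots = sum(model.root_counts.get(k, 0) for k in model.types)
    total = n_roots * (2**n_gens - 1)

    mother = np.full(total, -1, dtype=np.int64)
    tcode = np.empty(total, dtype=np.int64)
    gen = np.empty(total, dtype=np.int64)
    birth = np.zeros(total)
    division = np.empty(total)
    vol = np.empty(total)
    surf = np.empty(total)
    stub = np.zeros(total, dtype=bool)

    # roots, grouped by type in declared order
    blocks: Dict[Tuple[int, str], slice] = {}
    off = 0
    for k in model.types:
        c = model.root_counts.get(k, 0)
        if c == 0:
            continue
        for d, name in (
            (model.init_m, "init_m"),
            (model.init_vol, "init_vol"),
            (model.init_surf, "init_surf"),
        ):
            if k not in d:
                raise ModelError(f"missing {name} law for type {k}")
        sl = slice(off, off + c)
        ki = model.types.index(k)
        tcode[sl] = ki
        gen[sl] = g0
        division[sl] = np.maximum(model.init_m[k].sample(rng, c), MIN_CYCLE)
        vol[sl] = model.init_vol[k].sample(rng, c)
        surf[sl] = model.init_surf[k].sample(rng, c)
        blocks[(g0, k)] = sl
        off += c

    for n in range(g0 + 1, g0 + n_gens):
        is_stub_gen = n > g1
        law_n = min(n, g1)  # stubs reuse the terminal generation's ratio laws
        for ki, k in enumerate(model.types):
            psl = blocks.get((n - 1, k))
            if psl is None:
                continue
            parents = np.arange(psl.start, psl.stop)
            P = len(parents)
            if not is_stub_gen and (n, k) not in model.cycle:
                raise ModelError(f"missing cycle law for group ({n}, {k})")
            for name, d in (
                ("vol_ratio", model.vol_ratio),
                ("surf_ratio", model.surf_ratio),
            ):
                if (law_n, k) not in d:
                    raise ModelError(f"missing {name} law for group ({law_n}, {k})")
            sl = slice(off, off + 2 * P)
            mother[sl] = np.repeat(parents, 2)
            tcode[sl] = ki
            gen[sl] = n
            pb = np.repeat(division[psl], 2)
            birth[sl] = pb
            if is_stub_gen:
                division[sl] = np.inf
                stub[sl] = True
            else:
                division[sl] = pb + np.maximum(
                    model.cycle[(n, k)].sample(rng, 2 * P), MIN_CYCLE
                )
            vol[sl] = np.repeat(vol[psl], 2) * model.vol_ratio[(law_n, k)].sample(
                rng, 2 * P
            )
            surf[sl] = np.repeat(surf[psl], 2) * model.surf_ratio[(law_n, k)].sample(
                rng, 2 * P
            )
            blocks[(n, k)] = sl
            off += 2 * P
    x = division - birth
    x[stub] = np.nan
    return LineageArrays(
        types=model.types,
        mother=mother[:off],
        type_code=tcode[:off],
        generation=gen[:off],
        birth=birth[:off],
        division=division[:off],
        x=x[:off],
        vol=vol[:off],
        surf=surf[:off],
        is_stub=stub[:off],
        seed=seed,
    )


# ------------------------------------------------------------------ to tree


def to_tree(
    arrays: LineageArrays,
    step: float = 2.0,
    stub_margin_steps: int = 4,
    cell_prefix: str = "c",
) -> LineageTree:
    """Sample a :class:`LineageTree` from a simulated lineage on a time grid.

    Frames of a cell are the grid points in [birth, division); terminal
    cells (and stubs) persist to the simulation end. Volumes/surfaces are
    piecewise-constant at the cycle means. Positions are zero; spatial
    embedding belongs to the mechanics module.
    """
    finite = arrays.division[np.isfinite(arrays.division)]
    t_end = float(finite.max())
    if np.any(arrays.is_stub):
        t_end += stub_margin_steps * step
    width = max(4, len(str(len(arrays))))
    ids = [f"{cell_prefix}{i:0{width}d}" for i in range(len(arrays))]
    has_kids = np.zeros(len(arrays), dtype=bool)
    has_kids[arrays.mother[arrays.mother >= 0]] = True

    tracks = []
    for i in range(len(arrays)):
        b = arrays.birth[i]
        if has_kids[i]:
            end = arrays.division[i]
            t0 = np.ceil((b - 1e-9) / step) * step
            times = np.arange(t0, end - 1e-9, step)
        else:
            t0 = np.ceil((b - 1e-9) / step) * step
            times = np.arange(t0, t_end + step / 2, step)
        if len(times) == 0:
            raise ModelError(
                f"cell {ids[i]} has no frame at step {step}; use a finer step"
            )
        ncols = len(times)
        tracks.append(
            CellTrack(
                cell_id=ids[i],
                mother_id=ids[arrays.mother[i]] if arrays.mother[i] >= 0 else None,
                times=times,
                positions=np.zeros((ncols, 3)),
                volumes=np.full(ncols, arrays.vol[i]),
                surfaces=np.full(ncols, arrays.surf[i]),
                type_label=arrays.types[arrays.type_code[i]],
                generation=int(arrays.generation[i]),
            )
        )
    return LineageTree(
        tracks, step=step, window=(0.0, t_end), roots_born_at_start=True
    )


# -------------------------------------------------------------------- curves


def _step_cum(times: np.ndarray, weights: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Sum of weights with event time <= grid point (right-continuous step)."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    cw = np.concatenate([[0.0], np.cumsum(weights[order])])
    return cw[np.searchsorted(t, grid, side="right")]


def curves_from_arrays(arrays: LineageArrays, grid: np.ndarray) -> Dict[str, Dict[str, np.ndarray]]:
    """N/W/Z step curves on a grid, whole embryo and per type.

    A dividing cell is alive on [birth, division); terminal cells and stubs
    stay alive past their (unexecuted) division.
    """
    has_kids = np.zeros(len(arrays), dtype=bool)
    has_kids[arrays.mother[arrays.mother >= 0]] = True
    out: Dict[str, Dict[str, np.ndarray]] = {}

    def one(mask: np.ndarray) -> Dict[str, np.ndarray]:
        res = {}
        dmask = mask & has_kids
        for key, w in (("n", np.ones(len(arrays))), ("w", arrays.vol), ("z", arrays.surf)):
            res[key] = _step_cum(arrays.birth[mask], w[mask], grid) - _step_cum(
                arrays.division[dmask], w[dmask], grid
            )
        return res

    out["__all__"] = one(np.ones(len(arrays), dtype=bool))
    for ki, k in enumerate(arrays.types):
        mask = arrays.type_code == ki
        if mask.any():
            out[k] = one(mask)
    return out


def arrays_curves(arrays: LineageArrays, step: float = 2.0) -> EmbryoCurves:
    finite = arrays.division[np.isfinite(arrays.division)]
    grid = np.arange(0.0, float(finite.max()) + step / 2, step)
    cur = curves_from_arrays(arrays, grid)
    whole = cur.pop("__all__")
    return EmbryoCurves(
        times=grid, n=whole["n"], w=whole["w"], z=whole["z"], per_type=cur
    )


# ------------------------------------------------------------------ ensemble


@dataclass
class EnsembleSummary:
    """Mean and sd of N/W/Z over independent lineage realisations."""

    times: np.ndarray
    mean: Dict[str, Dict[str, np.ndarray]]  # label -> {n,w,z}
    sd: Dict[str, Dict[str, np.ndarray]]
    n_real: int
    base_seed: int
    seeds: List[int]
    division_stats: pd.DataFrame  # per (generation, type): pooled mean/var of m

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.times}
        for lab in self.mean:
            name = "" if lab == "__all__" else f"_{lab}"
            for key, col in (("n", "N"), ("w", "W"), ("z", "Z")):
                cols[f"{col}{name}_mean"] = self.mean[lab][key]
                cols[f"{col}{name}_sd"] = self.sd[lab][key]
        return pd.DataFrame(cols)


def _grid_bound(model: GroupModel) -> float:
    worst = 0.0
    for k in model.types:
        mu = model.init_m[k].mu
        var = model.init_m[k].variance
        for n in range(model.root_generation + 1, model.max_generation + 1):
            law = model.cycle.get((n, k))
            if law is not None:
                mu += law.mu
                var += law.variance
        worst = max(worst, mu + 6.0 * np.sqrt(var))
    return worst


def ensemble(
    model: GroupModel,
    n_real: int,
    base_seed: int,
    step: float = 2.0,
    generations: Optional[Tuple[int, int]] = None,
) -> EnsembleSummary:
    """Summarise ``n_real`` independent realisations (seeds = base_seed + i).

    Curves are accumulated streaming (mean/sd via sums and squared sums);
    division-time statistics are pooled per (generation, type) group over all
    cells and realisations.
    """
    if n_real < 2:
        raise ValueError("n_real must be >= 2")
    model.require_complete()
    grid = np.arange(0.0, _grid_bound(model) + step, step)
    seeds = [base_seed + i for i in range(n_real)]

    acc_sum: Dict[str, Dict[str, np.ndarray]] = {}
    acc_sq: Dict[str, Dict[str, np.ndarray]] = {}
    m_sum = m_sq = None
    layout = None
    for sd_i in seeds:
        arr = simulate(model, sd_i, generations=generations)
        cur = curves_from_arrays(arr, grid)
        for lab, d in cur.items():
            if lab not in acc_sum:
                acc_sum[lab] = {k: np.zeros_like(grid) for k in ("n", "w", "z")}
                acc_sq[lab] = {k: np.zeros_like(grid) for k in ("n", "w", "z")}
            for k in ("n", "w", "z"):
                acc_sum[lab][k] += d[k]
                acc_sq[lab][k] += d[k] ** 2
        if m_sum is None:
            m_sum = np.zeros(len(arr))
            m_sq = np.zeros(len(arr))
            layout = (arr.generation.copy(), arr.type_code.copy(), arr.types)
        m_sum += arr.division
        m_sq += arr.division**2

    mean = {}
    sd = {}
    for lab in acc_sum:
        mean[lab] = {k: acc_sum[lab][k] / n_real for k in ("n", "w", "z")}
        sd[lab] = {
            k: np.sqrt(np.maximum(acc_sq[lab][k] / n_real - mean[lab][k] ** 2, 0.0))
            for k in ("n", "w", "z")
        }

    gens, tcodes, labels = layout
    rows = []
    for n in np.unique(gens):
        for ki, k in enumerate(labels):
            mask = (gens == n) & (tcodes == ki)
            c = int(mask.sum())
            if c == 0:
                continue
            tot = c * n_real
            mu = float(m_sum[mask].sum() / tot)
            var = float(m_sq[mask].sum() / tot - mu**2)
            rows.append(
                dict(generation=int(n), type=k, n_cells=c, n_samples=tot, mean_m=mu, var_m=var)
            )
    return EnsembleSummary(
        times=grid,
        mean=mean,
        sd=sd,
        n_real=n_real,
        base_seed=base_seed,
        seeds=seeds,
        division_stats=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------- comparison


def _step_interp(xs: np.ndarray, ys: np.ndarray, t: np.ndarray) -> np.ndarray:
    idx = np.clip(np.searchsorted(xs, t, side="right") - 1, 0, len(xs) - 1)
    return ys[idx]


def compare_to_measured(
    summary: EnsembleSummary, measured: EmbryoCurves, z_limit: float = 2.0
) -> pd.DataFrame:
    """Coverage report of a measured embryo against the simulated ensemble.

    For each curve (N, W, Z; whole embryo and any shared type), the measured
    step curve is evaluated on the overlapping part of the ensemble grid and
    scored as z = (measured - mean) / sd. Returns coverage (fraction of
    points with |z| <= z_limit), the max |z| and the point count.
    """
    lo = max(summary.times[0], measured.times[0])
    hi = min(summary.times[-1], measured.times[-1])
    if hi <= lo:
        raise ValueError("disjoint time support between ensemble and measurement")
    sel = (summary.times >= lo) & (summary.times <= hi)
    grid = summary.times[sel]

    def score(lab: str, key: str, meas_y: np.ndarray) -> dict:
        mu = summary.mean[lab][key][sel]
        s = summary.sd[lab][key][sel]
        y = _step_interp(measured.times, meas_y, grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(s > 0, (y - mu) / s, np.where(np.abs(y - mu) < 1e-9, 0.0, np.inf))
        return dict(
            curve=key.upper(),
            label="embryo" if lab == "__all__" else lab,
            coverage=float(np.mean(np.abs(z) <= z_limit)),
            max_abs_z=float(np.max(np.abs(z))),
            n_points=len(grid),
        )

    rows = [
        score("__all__", key, y)
        for key, y in (("n", measured.n), ("w", measured.w), ("z", measured.z))
    ]
    for lab, cur in measured.per_type.items():
        if lab in summary.mean:
            for key in ("n", "w", "z"):
                rows.append(score(lab, key, cur[key]))
    return pd.DataFrame(rows)
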