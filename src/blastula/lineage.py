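"""Digital cell-lineage data model, file I/O, validation and feature extraction.

A lineage is stored as one row per (cell, time step) in a tab-separated table
with columns::

    cell_id  mother_id  t  x  y  z  type  volume  surface

``t`` is in minutes (an optional ``# time_unit: hpf`` directive line converts
hours-post-fertilisation on input). ``mother_id`` is empty for cells already
present at the first observed time step. A division is encoded implicitly by
two cells sharing the same ``mother_id``, starting strictly after the
mother's last time step. ``type``, ``volume`` and ``surface`` may be empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

CELL_TYPES = ("Mes", "Mac", "LMic", "SMic")

COLUMNS = ("cell_id", "mother_id", "t", "x", "y", "z", "type", "volume", "surface")

#: short feature codes used across the statistical modules
FEATURES = ("x", "m", "v", "s", "a", "b")


class LineageError(ValueError):
    """Structural or validation error in a lineage table."""


@dataclass
class CellTrack:
    """All per-time observations of one cell between its appearance and its end."""

    cell_id: str
    mother_id: Optional[str]
    times: np.ndarray
    positions: np.ndarray  # (n, 3)
    volumes: Optional[np.ndarray] = None
    surfaces: Optional[np.ndarray] = None
    type_label: Optional[str] = None
    generation: Optional[int] = None

    @property
    def t_first(self) -> float:
        return float(self.times[0])

    @property
    def t_last(self) -> float:
        return float(self.times[-1])


class LineageTree:
    """A validated forest of cell tracks linked by filiation.

    Parameters
    ----------
    tracks:
        The cell tracks, any order.
    step:
        Acquisition time step in minutes. Inferred from the data when omitted.
    window:
        Observation window ``(t_start, t_end)``. Defaults to the data extent.
    roots_born_at_start:
        If True, cells present at the first time step are known to be born
        exactly there (true for synthetic trees generated from birth), so
        their cycles count as fully observed. Real recordings cut into
        ongoing cycles, hence the default False.
    """

    def __init__(
        self,
        tracks: Iterable[CellTrack],
        step: Optional[float] = None,
        window: Optional[Tuple[float, float]] = None,
        roots_born_at_start: bool = False,
        validate: bool = True,
    ):
        self.tracks: Dict[str, CellTrack] = {}
        for tr in tracks:
            if tr.cell_id in self.tracks:
                raise LineageError(f"duplicate cell id {tr.cell_id!r}")
            self.tracks[tr.cell_id] = tr
        if not self.tracks:
            raise LineageError("empty lineage")
        self.children: Dict[str, List[str]] = {cid: [] for cid in self.tracks}
        for tr in self.tracks.values():
            if tr.mother_id is not None:
                if tr.mother_id not in self.tracks:
                    raise LineageError(
                        f"cell {tr.cell_id!r} references missing mother {tr.mother_id!r}"
                    )
                self.children[tr.mother_id].append(tr.cell_id)
        for kids in self.children.values():
            kids.sort()
        self.step = float(step) if step is not None else self._infer_step()
        if window is None:
            window = (
                min(tr.t_first for tr in self.tracks.values()),
                max(tr.t_last for tr in self.tracks.values()),
            )
        self.window: Tuple[float, float] = (float(window[0]), float(window[1]))
        self.roots_born_at_start = bool(roots_born_at_start)
        if validate:
            self.validate()

    # ------------------------------------------------------------------ basic
    def _infer_step(self) -> float:
        diffs: List[float] = []
        for tr in self.tracks.values():
            if len(tr.times) > 1:
                diffs.extend(np.diff(tr.times).tolist())
        if not diffs:
            return 1.0
        return float(min(diffs))

    @property
    def roots(self) -> List[str]:
        return sorted(
            cid for cid, tr in self.tracks.items() if tr.mother_id is None
        )

    @property
    def divisions(self) -> Dict[str, Tuple[str, str]]:
        return {
            cid: (kids[0], kids[1])
            for cid, kids in self.children.items()
            if len(kids) == 2
        }

    def __len__(self) -> int:
        return len(self.tracks)

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`LineageError` on failure."""
        tol = 1e-6 * max(self.step, 1.0)
        t_start = self.window[0]
        for cid, tr in self.tracks.items():
            if tr.times[0] < -tol:
                raise LineageError(f"cell {cid!r} has negative time")
            if np.any(np.diff(tr.times) <= 0):
                raise LineageError(f"cell {cid!r} has non-increasing times")
            if len(tr.times) > 1:
                d = np.diff(tr.times)
                if np.any(np.abs(d - self.step) > tol):
                    raise LineageError(
                        f"cell {cid!r} track is not contiguous on step {self.step}"
                    )
            for name, arr in (("volume", tr.volumes), ("surface", tr.surfaces)):
                if arr is not None:
                    finite = arr[np.isfinite(arr)]
                    if np.any(finite <= 0):
                        raise LineageError(f"cell {cid!r} has non-positive {name}")
            if tr.mother_id is None:
                if tr.times[0] > t_start + tol:
                    raise LineageError(
                        f"cell {cid!r} has no mother but appears at t={tr.times[0]}, "
                        f"after the first observed time step {t_start}"
                    )
        for cid, kids in self.children.items():
            if len(kids) not in (0, 2):
                raise LineageError(
                    f"cell {cid!r} has {len(kids)} daughters (expected 0 or 2)"
                )
            if len(kids) == 2:
                mother_last = self.tracks[cid].t_last
                starts = [self.tracks[k].t_first for k in kids]
                for k, s in zip(kids, starts):
                    if s <= mother_last + tol / 2:
                        raise LineageError(
                            f"daughter {k!r} starts at t={s}, not strictly after "
                            f"mother {cid!r} last time {mother_last}"
                        )
                if abs(starts[0] - starts[1]) > tol:
                    raise LineageError(
                        f"daughters of {cid!r} appear at different times {starts}"
                    )

    # ------------------------------------------------------------------- copy
    def copy(self) -> "LineageTree":
        tracks = [
            CellTrack(
                tr.cell_id,
                tr.mother_id,
                tr.times.copy(),
                tr.positions.copy(),
                None if tr.volumes is None else tr.volumes.copy(),
                None if tr.surfaces is None else tr.surfaces.copy(),
                tr.type_label,
                tr.generation,
            )
            for tr in self.tracks.values()
        ]
        return LineageTree(
            tracks,
            step=self.step,
            window=self.window,
            roots_born_at_start=self.roots_born_at_start,
            validate=False,
        )


# ---------------------------------------------------------------------- I/O


def _fmt(v: float) -> str:
    return f"{v:.10g}"


def read_lineage(path) -> LineageTree:
    """Read a tab-separated lineage table and return a validated tree."""
    time_unit = "min"
    roots_born_at_start = False
    rows: List[List[str]] = []
    header: Optional[List[str]] = None
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                directive = line[1:].strip()
                if directive.lower().startswith("time_unit"):
                    time_unit = directive.split(":", 1)[1].strip().lower()
                elif directive.lower().startswith("roots_born_at_start"):
                    roots_born_at_start = (
                        directive.split(":", 1)[1].strip().lower() == "true"
                    )
                continue
            if header is None:
                header = line.split("\t")
                if tuple(header) != COLUMNS:
                    raise LineageError(
                        f"unexpected header {header}; expected {list(COLUMNS)}"
                    )
                continue
            rows.append(line.split("\t"))
    if header is None or not rows:
        raise LineageError(f"no data rows in {path}")
    scale = 60.0 if time_unit == "hpf" else 1.0

    by_cell: Dict[str, List[List[str]]] = {}
    order: List[str] = []
    for r in rows:
        if len(r) != len(COLUMNS):
            raise LineageError(f"row with {len(r)} fields (expected {len(COLUMNS)})")
        cid = r[0]
        if cid not in by_cell:
            by_cell[cid] = []
            order.append(cid)
        by_cell[cid].append(r)

    tracks = []
    for cid in order:
        rs = by_cell[cid]
        mothers = {r[1] for r in rs}
        if len(mothers) != 1:
            raise LineageError(f"cell {cid!r} has inconsistent mother_id values")
        mother = rs[0][1] or None
        types = {r[6] for r in rs if r[6]}
        if len(types) > 1:
            raise LineageError(f"cell {cid!r} has inconsistent type labels {types}")
        times = np.array([float(r[2]) for r in rs]) * scale
        pos = np.array([[float(r[3]), float(r[4]), float(r[5])] for r in rs])
        vols = [float(r[7]) if r[7] else np.nan for r in rs]
        surfs = [float(r[8]) if r[8] else np.nan for r in rs]
        volumes = np.array(vols) if not all(np.isnan(vols)) else None
        surfaces = np.array(surfs) if not all(np.isnan(surfs)) else None
        tracks.append(
            CellTrack(
                cell_id=cid,
                mother_id=mother,
                times=times,
                positions=pos,
                volumes=volumes,
                surfaces=surfaces,
                type_label=next(iter(types)) if types else None,
            )
        )
    return LineageTree(tracks, roots_born_at_start=roots_born_at_start)


def write_lineage(tree: LineageTree, path) -> None:
    """Write a lineage tree in the canonical tab-separated dialect.

    Tracks are ordered by (first time, cell id) and rows by time, so
    ``write(read(f))`` is byte-identical for files in canonical order.
    """
    tracks = sorted(tree.tracks.values(), key=lambda tr: (tr.t_first, tr.cell_id))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# time_unit: min\n")
        if tree.roots_born_at_start:
            fh.write("# roots_born_at_start: true\n")
        fh.write("\t".join(COLUMNS) + "\n")
        for tr in tracks:
            for i, t in enumerate(tr.times):
                vol = (
                    _fmt(tr.volumes[i])
                    if tr.volumes is not None and np.isfinite(tr.volumes[i])
                    else ""
                )
                surf = (
                    _fmt(tr.surfaces[i])
                    if tr.surfaces is not None and np.isfinite(tr.surfaces[i])
                    else ""
                )
                fh.write(
                    "\t".join(
                        [
                            tr.cell_id,
                            tr.mother_id or "",
                            _fmt(t),
                            _fmt(tr.positions[i, 0]),
                            _fmt(tr.positions[i, 1]),
                            _fmt(tr.positions[i, 2]),
                            tr.type_label or "",
                            vol,
                            surf,
                        ]
                    )
                    + "\n"
                )


# ----------------------------------------------------- generations and types


def assign_generations_and_types(
    tree: LineageTree,
    root_generation: int = 6,
    root_labels: Optional[Mapping[str, str]] = None,
) -> LineageTree:
    """Assign generation indices and propagate type labels from the roots.

    Generation of a root is ``root_generation`` (32-cell stage = 6); each
    division increments the daughter generation by one. Types are inherited
    unchanged along descent. Modifies the tree in place and returns it.
    """
    roots = tree.roots
    if root_labels is not None:
        for cid, lab in root_labels.items():
            if cid not in tree.tracks:
                raise LineageError(f"root label for unknown cell {cid!r}")
            tree.tracks[cid].type_label = lab
    unlabelled = [cid for cid in roots if tree.tracks[cid].type_label is None]
    if unlabelled:
        raise LineageError(f"unlabelled root cells: {unlabelled}")
    stack = [(cid, root_generation, tree.tracks[cid].type_label) for cid in roots]
    while stack:
        cid, gen, lab = stack.pop()
        tr = tree.tracks[cid]
        tr.generation = gen
        tr.type_label = lab
        for kid in tree.children[cid]:
            stack.append((kid, gen + 1, lab))
    return tree


# ------------------------------------------------------------------ features


def extract_features(tree: LineageTree) -> pd.DataFrame:
    """Per-cell features: cycle length, division time, mean volume/surface, ratios.

    Returns a DataFrame indexed by cell id with columns ``mother_id, type,
    generation, birth, m, x, v, s, a, b, complete``. A cycle is *complete*
    when both its start (mother's division observed, or a root of a tree
    flagged ``roots_born_at_start``) and its end (own division observed) lie
    inside the observation window; only complete cycles carry ``x``, ``m``,
    ``v``, ``s`` values, and ratios ``a``, ``b`` additionally require a
    complete mother cycle. Incomplete cycles are excluded from every
    distribution downstream.
    """
    recs = {}
    for cid, tr in tree.tracks.items():
        kids = tree.children[cid]
        birth_observed = tr.mother_id is not None or tree.roots_born_at_start
        division_observed = len(kids) == 2
        complete = birth_observed and division_observed
        birth = tr.t_first
        m = np.nan
        x = np.nan
        v = np.nan
        s = np.nan
        if complete:
            m = tree.tracks[kids[0]].t_first
            x = m - birth
            if tr.volumes is not None:
                vv = tr.volumes[np.isfinite(tr.volumes)]
                if len(vv):
                    v = float(np.mean(vv))
            if tr.surfaces is not None:
                ss = tr.surfaces[np.isfinite(tr.surfaces)]
                if len(ss):
                    s = float(np.mean(ss))
        recs[cid] = dict(
            mother_id=tr.mother_id,
            type=tr.type_label,
            generation=tr.generation,
            birth=birth,
            m=m,
            x=x,
            v=v,
            s=s,
            a=np.nan,
            b=np.nan,
            complete=complete,
        )
    for cid, r in recs.items():
        mid = r["mother_id"]
        if mid is not None and mid in recs:
            mr = recs[mid]
            if np.isfinite(r["v"]) and np.isfinite(mr["v"]) and mr["v"] > 0:
                r["a"] = r["v"] / mr["v"]
            if np.isfinite(r["s"]) and np.isfinite(mr["s"]) and mr["s"] > 0:
                r["b"] = r["s"] / mr["s"]
    df = pd.DataFrame.from_dict(recs, orient="index")
    df.index.name = "cell_id"
    return df.sort_values(["birth"], kind="stable").sort_index(kind="stable")


# -------------------------------------------------------------------- curves


@dataclass
class EmbryoCurves:
    """Embryo-level step curves: cell count N, total volume W, total surface Z.

    ``per_type`` maps a type label to its ``(n, w, z)`` arrays on the same
    time grid; per-type curves sum to the whole-embryo curves.
    """

    times: np.ndarray
    n: np.ndarray
    w: np.ndarray
    z: np.ndarray
    per_type: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = {"t": self.times, "N": self.n, "W": self.w, "Z": self.z}
        for lab, cur in self.per_type.items():
            out[f"N_{lab}"] = cur["n"]
            out[f"W_{lab}"] = cur["w"]
            out[f"Z_{lab}"] = cur["z"]
        return pd.DataFrame(out)


def embryo_curves(tree: LineageTree) -> EmbryoCurves:
    """Compute N(t), W(t), Z(t) on the tree's native time grid, whole and per type."""
    times = np.unique(np.concatenate([tr.times for tr in tree.tracks.values()]))
    labels = sorted({tr.type_label for tr in tree.tracks.values() if tr.type_label})
    shape = len(times)
    total = {k: np.zeros(shape) for k in ("n", "w", "z")}
    per_type = {
        lab: {k: np.zeros(shape) for k in ("n", "w", "z")} for lab in labels
    }
    for tr in tree.tracks.values():
        i0 = np.searchsorted(times, tr.times[0] - 1e-9)
        idx = slice(i0, i0 + len(tr.times))
        buckets = [total] + ([per_type[tr.type_label]] if tr.type_label else [])
        vol = tr.volumes if tr.volumes is not None else np.zeros(len(tr.times))
        surf = tr.surfaces if tr.surfaces is not None else np.zeros(len(tr.times))
        vol = np.where(np.isfinite(vol), vol, 0.0)
        surf = np.where(np.isfinite(surf), surf, 0.0)
        for b in buckets:
            b["n"][idx] += 1
            b["w"][idx] += vol
            b["z"][idx] += surf
    return EmbryoCurves(
        times=times,
        n=total["n"],
        w=total["w"],
        z=total["z"],
        per_type={
            lab: {k: per_type[lab][k] for k in ("n", "w", "z")} for lab in labels
        },
    )


# ------------------------------------------------------------------- degrees


def contact_degrees(
    tree: LineageTree,
    contact_source: Mapping[float, Iterable[Tuple[str, str]]],
) -> pd.DataFrame:
    """Attach contact degrees d_i(t) from an external contact graph per time.

    ``contact_source`` maps a time to an iterable of undirected edges
    (pairs of cell ids). Returns a tidy DataFrame ``(cell_id, t, degree)``
    covering every cell alive at each listed time (degree 0 when isolated).
    """
    rows = []
    for t in sorted(contact_source):
        alive = {
            cid
            for cid, tr in tree.tracks.items()
            if tr.times[0] - 1e-9 <= t <= tr.times[-1] + 1e-9
        }
        deg = {cid: 0 for cid in alive}
        for i, j in contact_source[t]:
            for c in (i, j):
                if c not in tree.tracks:
                    raise LineageError(f"contact edge names unknown cell {c!r}")
            if i in deg:
                deg[i] += 1
            if j in deg:
                deg[j] += 1
        rows.extend({"cell_id": cid, "t": t, "degree": d} for cid, d in deg.items())
    return pd.DataFrame(rows, columns=["cell_id", "t", "degree"])
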