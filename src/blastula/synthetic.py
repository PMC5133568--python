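"""Synthetic digital-embryo cohorts with stored ground truth.

A cohort emulates a set of recorded specimens: every embryo is drawn from
the same set of group laws (a :class:`~blastula.model.GroupModel`), then
distorted by an embryo-specific affine time map (shift alpha, scale beta)
and spatial scale gamma, and finally clipped to an observation window. All
laws, distortion parameters and per-cell draws are kept as ground truth so
that recovery by the analysis modules can be tested.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from blastula.lineage import CellTrack, LineageTree, write_lineage
from blastula.model import GroupModel
from blastula.rescaling import RescaleParams, apply_rescale
from blastula.simulator import simulate, to_tree


class ConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``alphas``/``betas``/``gammas`` are per-embryo distortions applied to the
    common underlying dynamics; ``windows`` are observation windows in
    observed (distorted) time, ``None`` meaning the full recording.
    """

    model: GroupModel
    n_embryos: int = 5
    alphas: Sequence[float] = ()
    betas: Sequence[float] = ()
    gammas: Sequence[float] = ()
    windows: Sequence[Optional[Tuple[float, float]]] = ()
    step: float = 2.0
    seed: int = 0
    terminal_stubs: bool = True
    #: draw every embryo from the same underlying lineage (distortions still
    #: differ); isolates the rescaling transform from sampling noise
    shared_lineage: bool = False

    def __post_init__(self):
        if not self.alphas:
            self.alphas = [0.0] * self.n_embryos
        if not self.betas:
            self.betas = [1.0] * self.n_embryos
        if not self.gammas:
            self.gammas = [1.0] * self.n_embryos
        if not self.windows:
            self.windows = [None] * self.n_embryos
        for name, seq in (
            ("alphas", self.alphas),
            ("betas", self.betas),
            ("gammas", self.gammas),
            ("windows", self.windows),
        ):
            if len(seq) != self.n_embryos:
                raise ConfigError(f"{name} must list one value per embryo")
        if any(b <= 0 for b in self.betas) or any(g <= 0 for g in self.gammas):
            raise ConfigError("betas and gammas must be > 0")
        if any(a < 0 for a in self.alphas):
            raise ConfigError("alphas must be >= 0 (times are post-fertilisation)")
        if self.step <= 0:
            raise ConfigError("step must be > 0")

    @classmethod
    def default(cls, seed: int = 0, model: Optional[GroupModel] = None) -> "CohortConfig":
        """Five embryos with distinct time/space distortions, full windows."""
        return cls(
            model=model or GroupModel.default(),
            n_embryos=5,
            alphas=[0.0, 12.0, 25.0, 8.0, 18.0],
            betas=[1.0, 1.10, 0.92, 1.05, 0.96],
            gammas=[1.0, 1.07, 0.94, 1.03, 0.97],
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "n_embryos": self.n_embryos,
            "alphas": [float(a) for a in self.alphas],
            "betas": [float(b) for b in self.betas],
            "gammas": [float(g) for g in self.gammas],
            "windows": [list(map(float, w)) if w is not None else None for w in self.windows],
            "step": self.step,
            "seed": self.seed,
            "terminal_stubs": self.terminal_stubs,
            "shared_lineage": self.shared_lineage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(
            model=GroupModel.from_dict(d["model"]),
            n_embryos=int(d["n_embryos"]),
            alphas=d.get("alphas", ()),
            betas=d.get("betas", ()),
            gammas=d.get("gammas", ()),
            windows=[tuple(w) if w is not None else None for w in d.get("windows", ())],
            step=float(d.get("step", 2.0)),
            seed=int(d.get("seed", 0)),
            terminal_stubs=bool(d.get("terminal_stubs", True)),
            shared_lineage=bool(d.get("shared_lineage", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ----------------------------------------------------------------- truncation


def truncate_tree(tree: LineageTree, window: Tuple[float, float]) -> LineageTree:
    """Clip a tree to an observation window (observed time).

    Tracks are clipped frame-wise; cells left without any frame are dropped,
    and surviving cells whose mother was dropped become window roots.
    """
    w0, w1 = window
    kept = {}
    for cid, tr in tree.tracks.items():
        sel = (tr.times >= w0 - 1e-9) & (tr.times <= w1 + 1e-9)
        if not sel.any():
            continue
        kept[cid] = sel
    if not kept:
        raise ConfigError("observation window excludes the whole recording")
    tracks = []
    for cid, sel in kept.items():
        tr = tree.tracks[cid]
        mother = tr.mother_id if tr.mother_id in kept else None
        tracks.append(
            CellTrack(
                cell_id=cid,
                mother_id=mother,
                times=tr.times[sel],
                positions=tr.positions[sel],
                volumes=None if tr.volumes is None else tr.volumes[sel],
                surfaces=None if tr.surfaces is None else tr.surfaces[sel],
                type_label=tr.type_label,
                generation=tr.generation,
            )
        )
    # safety: a kept cell must keep 0 or 2 daughters (clipping is symmetric in
    # the daughters' shared start time, so this should never trigger)
    while True:
        kid_count: Dict[str, int] = {}
        for t in tracks:
            if t.mother_id is not None:
                kid_count[t.mother_id] = kid_count.get(t.mother_id, 0) + 1
        bad = {m for m, c in kid_count.items() if c == 1}
        if not bad:
            break
        tracks = [t for t in tracks if t.mother_id not in bad]
    clipped_start = tree.window[0] < w0 - 1e-9
    return LineageTree(
        tracks,
        step=tree.step,
        roots_born_at_start=tree.roots_born_at_start and not clipped_start,
    )


# ----------------------------------------------------------------- generation


def _embryo_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0])


def generate_embryo(
    config: CohortConfig, index: int
) -> Tuple[LineageTree, dict]:
    """Generate one synthetic embryo and its ground-truth record."""
    if not 0 <= index < config.n_embryos:
        raise ConfigError(f"embryo index {index} out of range")
    config.model.require_complete()
    seed = _embryo_seed(config.seed, 0 if config.shared_lineage else index)
    arrays = simulate(config.model, seed, terminal_stubs=config.terminal_stubs)
    tree = to_tree(arrays, step=config.step)
    distortion = RescaleParams(
        alpha=float(config.alphas[index]),
        beta=float(config.betas[index]),
        gamma=float(config.gammas[index]),
    )
    tree = apply_rescale(tree, distortion)
    window = config.windows[index]
    if window is not None:
        tree = truncate_tree(tree, window)
        gens = {tr.generation for tr in tree.tracks.values()}
        if config.model.root_generation not in gens:
            raise ConfigError(
                f"window {window} excludes generation {config.model.root_generation} entirely"
            )
    truth = {
        "index": index,
        "seed": seed,
        "alpha": distortion.alpha,
        "beta": distortion.beta,
        "gamma": distortion.gamma,
        "step": config.step,
        "window": list(window) if window is not None else None,
        "model": config.model.to_dict(),
        "cells": pd.DataFrame(
            {
                "cell": np.arange(len(arrays)),
                "mother": arrays.mother,
                "type": arrays.type_labels,
                "generation": arrays.generation,
                "birth": arrays.birth,
                "division": arrays.division,
                "x": arrays.x,
                "vol": arrays.vol,
                "surf": arrays.surf,
                "is_stub": arrays.is_stub,
            }
        ),
    }
    return tree, truth


def generate_cohort(config: CohortConfig) -> List[Tuple[LineageTree, dict]]:
    """Generate the full cohort (one call of :func:`generate_embryo` per index)."""
    return [generate_embryo(config, i) for i in range(config.n_embryos)]


def write_cohort(config: CohortConfig, outdir) -> List[str]:
    """Write trees and ground-truth sidecars to a directory; returns tree paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i, (tree, truth) in enumerate(generate_cohort(config)):
        path = os.path.join(outdir, f"embryo_{i}.tsv")
        write_lineage(tree, path)
        cells = truth.pop("cells")
        cells.to_csv(os.path.join(outdir, f"embryo_{i}.truth_cells.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, f"embryo_{i}.truth.yaml"), "wt", encoding="utf-8") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)
        paths.append(path)
    return paths
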