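"""Recursive multi-level probabilistic model of the cell lineage.

The model links per-(generation, type) group laws across generations:

* division times:  M_g = M_{g-1} + X_g  (normal; means and variances add)
* mean volumes:    V_g = V_{g-1} * A_g  (log-normal; log-parameters add)
* mean surfaces:   S_g = S_{g-1} * B_g  (log-normal; log-parameters add)

with X_g independent of M_{g-1} and the ratio laws independent of the
mother's volume/surface. Predicted final-group laws are compared with the
measured ones via the Kullback-Leibler divergence, symmetrised (Jeffreys)
and normalised by the mean pairwise divergence between the cohort members.
The cohort prototype is the per-(group, feature) centroid law minimising the
summed symmetrised KL divergence to the members.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize_scalar

from blastula.laws import LOGNORMAL, NORMAL, Law, convolve, kl_divergence, symmetrised_kl
from blastula.lineage import CELL_TYPES

GroupKey = Tuple[int, str]  # (generation, type label)

#: default cell counts of the 32-cell stage roots
ROOT_COUNTS = {"Mes": 16, "Mac": 8, "LMic": 4, "SMic": 4}

#: default category thresholds on the normalised divergence D-hat
CATEGORY_THRESHOLDS = {"close": 1.0, "good": 2.0}


class ModelError(ValueError):
    pass


@dataclass
class GroupModel:
    """Group laws of one embryo (or of the prototype).

    ``cycle[(n, k)]`` is the normal law of cell-cycle lengths of generation-n
    cells of type k (n from ``root_generation + 1`` to ``max_generation``);
    ``vol_ratio`` / ``surf_ratio`` are the log-normal daughter/mother ratio
    laws on the same keys; ``init_m`` / ``init_vol`` / ``init_surf`` are the
    laws of division time, mean volume and mean surface of the
    root-generation groups, per type.
    """

    root_generation: int = 6
    max_generation: int = 10
    types: Tuple[str, ...] = CELL_TYPES
    root_counts: Dict[str, int] = field(default_factory=lambda: dict(ROOT_COUNTS))
    cycle: Dict[GroupKey, Law] = field(default_factory=dict)
    vol_ratio: Dict[GroupKey, Law] = field(default_factory=dict)
    surf_ratio: Dict[GroupKey, Law] = field(default_factory=dict)
    init_m: Dict[str, Law] = field(default_factory=dict)
    init_vol: Dict[str, Law] = field(default_factory=dict)
    init_surf: Dict[str, Law] = field(default_factory=dict)

    # ----------------------------------------------------------------- checks
    def require_complete(self) -> None:
        for k in self.types:
            for d, name in (
                (self.init_m, "init_m"),
                (self.init_vol, "init_vol"),
                (self.init_surf, "init_surf"),
            ):
                if k not in d:
                    raise ModelError(f"missing {name} law for type {k}")
            for n in range(self.root_generation + 1, self.max_generation + 1):
                for d, name in (
                    (self.cycle, "cycle"),
                    (self.vol_ratio, "vol_ratio"),
                    (self.surf_ratio, "surf_ratio"),
                ):
                    if (n, k) not in d:
                        raise ModelError(f"missing {name} law for group ({n}, {k})")

    # ---------------------------------------------------------------- default
    @classmethod
    def default(
        cls, root_generation: int = 6, max_generation: int = 10
    ) -> "GroupModel":
        """A plausible placeholder parameter set (not fitted to any specimen).

        Cycle means lengthen and their spread widens with generation; volume
        ratios fluctuate around 0.5 and surface ratios around 0.5**(2/3).
        """
        mus = {7: 45.0, 8: 55.0, 9: 70.0, 10: 90.0}
        sigmas = {7: 4.0, 8: 5.0, 9: 6.5, 10: 8.5}
        type_shift = {"Mes": 0.0, "Mac": 4.0, "LMic": 8.0, "SMic": 14.0}
        init_vol_med = {"Mes": 3000.0, "Mac": 6000.0, "LMic": 2000.0, "SMic": 800.0}
        m = cls(root_generation=root_generation, max_generation=max_generation)
        gens = range(root_generation + 1, max_generation + 1)
        base = sorted(mus)
        for i, n in enumerate(gens):
            src = base[min(i, len(base) - 1)]
            for k in m.types:
                m.cycle[(n, k)] = Law(NORMAL, mus[src] + type_shift[k], sigmas[src])
                m.vol_ratio[(n, k)] = Law(LOGNORMAL, math.log(0.5), 0.12)
                m.surf_ratio[(n, k)] = Law(LOGNORMAL, (2 / 3) * math.log(0.5), 0.08)
        for k in m.types:
            m.init_m[k] = Law(NORMAL, 45.0 + type_shift[k], 5.0)
            mu_v = math.log(init_vol_med[k])
            m.init_vol[k] = Law(LOGNORMAL, mu_v, 0.15)
            # surface of a sphere of volume v: s = (36 pi)^(1/3) v^(2/3)
            m.init_surf[k] = Law(
                LOGNORMAL, math.log((36 * math.pi) ** (1 / 3)) + (2 / 3) * mu_v, 0.10
            )
        return m

    # ------------------------------------------------------------------- yaml
    def to_dict(self) -> dict:
        def law(l: Law) -> dict:
            return {"family": l.family, "mu": float(l.mu), "sigma": float(l.sigma)}

        return {
            "root_generation": self.root_generation,
            "max_generation": self.max_generation,
            "types": list(self.types),
            "root_counts": dict(self.root_counts),
            "cycle": {f"{n},{k}": law(v) for (n, k), v in sorted(self.cycle.items())},
            "vol_ratio": {
                f"{n},{k}": law(v) for (n, k), v in sorted(self.vol_ratio.items())
            },
            "surf_ratio": {
                f"{n},{k}": law(v) for (n, k), v in sorted(self.surf_ratio.items())
            },
            "init_m": {k: law(v) for k, v in sorted(self.init_m.items())},
            "init_vol": {k: law(v) for k, v in sorted(self.init_vol.items())},
            "init_surf": {k: law(v) for k, v in sorted(self.init_surf.items())},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroupModel":
        def law(spec) -> Law:
            return Law(spec["family"], float(spec["mu"]), float(spec["sigma"]))

        def gkey(s: str) -> GroupKey:
            n, k = s.split(",")
            return int(n), k

        return cls(
            root_generation=int(d["root_generation"]),
            max_generation=int(d["max_generation"]),
            types=tuple(d["types"]),
            root_counts={k: int(v) for k, v in d["root_counts"].items()},
            cycle={gkey(s): law(v) for s, v in d["cycle"].items()},
            vol_ratio={gkey(s): law(v) for s, v in d["vol_ratio"].items()},
            surf_ratio={gkey(s): law(v) for s, v in d["surf_ratio"].items()},
            init_m={k: law(v) for k, v in d["init_m"].items()},
            init_vol={k: law(v) for k, v in d["init_vol"].items()},
            init_surf={k: law(v) for k, v in d["init_surf"].items()},
        )

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroupModel":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # ------------------------------------------------------------- from stats
    @classmethod
    def from_stats(
        cls,
        stats: pd.DataFrame,
        root_generation: int = 6,
        max_generation: Optional[int] = None,
        eligible_only: bool = True,
    ) -> "GroupModel":
        """Build a model from a fitted group-statistics table.

        The table is the output of :func:`blastula.group_stats.fit_all`:
        one row per (generation, type, feature) with the fitted family and
        (mu, sigma). Cycle laws come from feature ``x``, ratio laws from
        ``a`` / ``b``, initial laws from the root-generation ``m``/``v``/``s``.
        """
        df = stats
        if eligible_only and "eligible" in df.columns:
            df = df[df["eligible"]]
        if max_generation is None:
            max_generation = int(df["generation"].max())
        m = cls(root_generation=root_generation, max_generation=max_generation)

        def law_of(row) -> Law:
            return Law(row["family"], float(row["mu"]), float(row["sigma"]))

        for _, row in df.iterrows():
            key = (int(row["generation"]), row["type"])
            feat = row["feature"]
            if feat == "x" and key[0] > root_generation:
                m.cycle[key] = law_of(row)
            elif feat == "a" and key[0] > root_generation:
                m.vol_ratio[key] = law_of(row)
            elif feat == "b" and key[0] > root_generation:
                m.surf_ratio[key] = law_of(row)
            elif key[0] == root_generation:
                if feat == "m":
                    m.init_m[key[1]] = law_of(row)
                elif feat == "v":
                    m.init_vol[key[1]] = law_of(row)
                elif feat == "s":
                    m.init_surf[key[1]] = law_of(row)
        return m


# ------------------------------------------------------------------ propagate


def propagate(
    model: GroupModel, from_gen: Optional[int] = None, to_gen: Optional[int] = None
) -> Dict[str, Dict[GroupKey, Law]]:
    """Propagate initial-group laws forward through the recursive relations.

    Returns derived laws ``{"m": ..., "v": ..., "s": ...}`` keyed by
    (generation, type) for every generation from ``from_gen`` (default: the
    model's root generation) to ``to_gen`` (default: max generation). The
    derived normal M_g has mu(M_g) = mu(M_{g-1}) + mu(X_g) and
    var(M_g) = var(M_{g-1}) + var(X_g); log-normal parameters add likewise
    in log-space.
    """
    if from_gen is None:
        from_gen = model.root_generation
    if to_gen is None:
        to_gen = model.max_generation
    if from_gen != model.root_generation:
        raise ModelError(
            f"propagation starts at the root generation {model.root_generation}"
        )
    out: Dict[str, Dict[GroupKey, Law]] = {"m": {}, "v": {}, "s": {}}
    for k in model.types:
        sub = propagate_type(model, k, to_gen=to_gen)
        for feat in out:
            out[feat].update(sub[feat])
    return out


def propagate_type(
    model: GroupModel, k: str, to_gen: Optional[int] = None
) -> Dict[str, Dict[GroupKey, Law]]:
    """Propagate one type's lineage; raises naming the first missing group."""
    if to_gen is None:
        to_gen = model.max_generation
    from_gen = model.root_generation
    out: Dict[str, Dict[GroupKey, Law]] = {"m": {}, "v": {}, "s": {}}
    for d, init, name in (
        (out["m"], model.init_m, "init_m"),
        (out["v"], model.init_vol, "init_vol"),
        (out["s"], model.init_surf, "init_surf"),
    ):
        if k not in init:
            raise ModelError(f"missing {name} law for type {k}")
        d[(from_gen, k)] = init[k]
    for n in range(from_gen + 1, to_gen + 1):
        for d, inc, name in (
            (out["m"], model.cycle, "cycle"),
            (out["v"], model.vol_ratio, "vol_ratio"),
            (out["s"], model.surf_ratio, "surf_ratio"),
        ):
            if (n, k) not in inc:
                raise ModelError(f"missing {name} law for group ({n}, {k})")
            d[(n, k)] = convolve(d[(n - 1, k)], inc[(n, k)])
    return out


# ------------------------------------------------------------------- evaluate


def _law_lookup(stats: pd.DataFrame, eligible_only: bool = True) -> Dict[Tuple[int, str, str], Law]:
    df = stats
    if eligible_only and "eligible" in df.columns:
        df = df[df["eligible"]]
    out = {}
    for _, row in df.iterrows():
        if row["sigma"] > 0:
            out[(int(row["generation"]), row["type"], row["feature"])] = Law(
                row["family"], float(row["mu"]), float(row["sigma"])
            )
    return out


def categorise(d_hat: float, thresholds: Mapping[str, float] = CATEGORY_THRESHOLDS) -> str:
    if not np.isfinite(d_hat):
        return "undefined"
    if d_hat <= thresholds["close"]:
        return "close"
    if d_hat <= thresholds["good"]:
        return "good"
    return "far"


def evaluate(
    model: GroupModel,
    measured: pd.DataFrame,
    cohort: Sequence[pd.DataFrame],
    thresholds: Mapping[str, float] = CATEGORY_THRESHOLDS,
) -> pd.DataFrame:
    """Compare model-predicted final-group laws with measured ones.

    For each type, the final group is the last generation with an eligible
    measured law of the feature (m: division times, v: mean volumes, s: mean
    surfaces). The symmetrised KL divergence between predicted and measured
    laws is normalised by the mean pairwise symmetrised divergence between
    the cohort members' measured laws for the same (group, feature); a zero
    normaliser (identical cohort) yields D-hat = NaN and category
    "undefined".
    """
    meas = _law_lookup(measured)
    cohort_laws = [_law_lookup(df) for df in cohort]
    derived: Dict[str, Dict[GroupKey, Law]] = {"m": {}, "v": {}, "s": {}}
    for k in model.types:
        # propagate each type independently: groups too small to fit leave
        # holes in the model and their types are simply not evaluated
        try:
            sub = propagate_type(model, k)
        except ModelError:
            continue
        for feat in derived:
            derived[feat].update(sub[feat])
    rows = []
    for feat in ("m", "v", "s"):
        for k in model.types:
            gens = [
                n
                for n in range(model.root_generation + 1, model.max_generation + 1)
                if (n, k, feat) in meas and (n, k) in derived[feat]
            ]
            if not gens:
                continue
            n = max(gens)
            pred = derived[feat][(n, k)]
            obs = meas[(n, k, feat)]
            d_sym = symmetrised_kl(pred, obs)
            members = [
                laws[(n, k, feat)] for laws in cohort_laws if (n, k, feat) in laws
            ]
            pair = [
                symmetrised_kl(p, q) for p, q in itertools.combinations(members, 2)
            ]
            norm = float(np.mean(pair)) if pair else np.nan
            d_hat = d_sym / norm if norm and norm > 0 else np.nan
            rows.append(
                dict(
                    generation=n,
                    type=k,
                    feature=feat,
                    d_kl=kl_divergence(pred, obs),
                    d_sym=d_sym,
                    normaliser=norm,
                    d_hat=d_hat,
                    category=categorise(d_hat, thresholds),
                )
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ prototype


def centroid_law(members: Sequence[Law]) -> Law:
    """Centroid law minimising the summed symmetrised KL to the members.

    For a family with parameters (mu, sigma) (log-space for log-normal) the
    optimal mu at fixed sigma is the precision-weighted mean
    ``sum(mu_e * (1/s_e^2 + 1/s^2)) / sum(1/s_e^2 + 1/s^2)``; sigma is found
    by bounded 1-D minimisation. The returned law never scores worse than
    any member on the objective.
    """
    if not members:
        raise ModelError("centroid of an empty member set")
    fam = members[0].family
    if any(m.family != fam for m in members):
        raise ModelError("centroid members must share a family")
    if all(m == members[0] for m in members):
        return members[0]
    mus = np.array([m.mu for m in members])
    sigs = np.array([m.sigma for m in members])
    if np.any(sigs <= 0):
        raise ModelError("centroid requires sigma > 0 members")

    def mu_star(sigma: float) -> float:
        w = 1.0 / sigs**2 + 1.0 / sigma**2
        return float(np.sum(w * mus) / np.sum(w))

    def objective_params(mu: float, sigma: float) -> float:
        cand = Law(fam, mu, sigma)
        return float(sum(symmetrised_kl(cand, m) for m in members))

    lo, hi = float(sigs.min()) / 10.0, float(sigs.max()) * 10.0
    res = minimize_scalar(
        lambda s: objective_params(mu_star(s), s),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best = Law(fam, mu_star(float(res.x)), float(res.x))
    best_val = objective_params(best.mu, best.sigma)
    for m in members:  # guarantee the centroid is at least as central as any member
        val = objective_params(m.mu, m.sigma)
        if val < best_val:
            best, best_val = m, val
    return best


def prototype_objective(candidate: Law, members: Sequence[Law]) -> float:
    return float(sum(symmetrised_kl(candidate, m) for m in members))


def build_prototype(cohort: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-embryo group statistics into the cohort prototype.

    Returns one row per (generation, type, feature) present in at least one
    embryo: the centroid (mu, sigma), the number of contributing members,
    a ``single_member`` flag for groups seen in only one embryo, and the
    cross-cohort dispersion of the member means.
    """
    cohort_laws = [_law_lookup(df) for df in cohort]
    keys = sorted({k for laws in cohort_laws for k in laws})
    rows = []
    for n, k, feat in keys:
        members = [laws[(n, k, feat)] for laws in cohort_laws if (n, k, feat) in laws]
        cen = centroid_law(members)
        rows.append(
            dict(
                generation=n,
                type=k,
                feature=feat,
                family=cen.family,
                mu=cen.mu,
                sigma=cen.sigma,
                n_members=len(members),
                single_member=len(members) == 1,
                mu_dispersion=float(np.std([m.mu for m in members], ddof=0)),
                objective=prototype_objective(cen, members),
            )
        )
    df = pd.DataFrame(rows)
    df["eligible"] = True
    return df


def prototype_model(prototype: pd.DataFrame, root_generation: int = 6) -> GroupModel:
    """Convert a prototype table back into a simulatable :class:`GroupModel`."""
    return GroupModel.from_stats(prototype, root_generation=root_generation)
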