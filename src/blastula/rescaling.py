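"""Temporal affine and spatial linear rescaling of embryos onto a cohort baseline.

Each embryo carries parameters (alpha, beta, gamma): applying them maps the
embryo onto the baseline via ``t -> beta * t + alpha``, positions ``* gamma``,
volumes ``* gamma**3`` and surfaces ``* gamma**2``. Temporal parameters are
fitted by minimising the L2 distance between the rescaled cell-number curve
and the cohort-average curve, alternating per-embryo fits with updates of
the average until a fixed point; the spatial factor is then fitted the same
way on the total-volume curves. The cohort average is identifiable only up
to a common affine map, so the first embryo is pinned to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from blastula.lineage import EmbryoCurves, LineageTree


class RescaleError(ValueError):
    pass


@dataclass(frozen=True)
class RescaleParams:
    """Per-embryo rescaling: time shift (min), time scale, spatial factor."""

    alpha: float = 0.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.beta <= 0 or self.gamma <= 0:
            raise RescaleError("beta and gamma must be > 0")

    def invert(self) -> "RescaleParams":
        return RescaleParams(
            alpha=-self.alpha / self.beta, beta=1.0 / self.beta, gamma=1.0 / self.gamma
        )


def apply_rescale(tree: LineageTree, params: RescaleParams) -> LineageTree:
    """Return a rescaled copy: t -> beta*t + alpha, x gamma, v gamma^3, s gamma^2."""
    out = tree.copy()
    for tr in out.tracks.values():
        tr.times = params.beta * tr.times + params.alpha
        tr.positions = tr.positions * params.gamma
        if tr.volumes is not None:
            tr.volumes = tr.volumes * params.gamma**3
        if tr.surfaces is not None:
            tr.surfaces = tr.surfaces * params.gamma**2
    out.step = tree.step * params.beta
    out.window = (
        params.beta * tree.window[0] + params.alpha,
        params.beta * tree.window[1] + params.alpha,
    )
    return out


def rescale_curves(curves: EmbryoCurves, params: RescaleParams) -> EmbryoCurves:
    g3, g2 = params.gamma**3, params.gamma**2
    return EmbryoCurves(
        times=params.beta * curves.times + params.alpha,
        n=curves.n.copy(),
        w=curves.w * g3,
        z=curves.z * g2,
        per_type={
            lab: {"n": c["n"].copy(), "w": c["w"] * g3, "z": c["z"] * g2}
            for lab, c in curves.per_type.items()
        },
    )


# ------------------------------------------------------------------- fitting


def _step_eval(xs: np.ndarray, ys: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Right-continuous step interpolation with end-hold."""
    idx = np.clip(np.searchsorted(xs, t, side="right") - 1, 0, len(xs) - 1)
    return ys[idx]


def _native_step(curves: EmbryoCurves) -> float:
    d = np.diff(curves.times)
    return float(d.min()) if len(d) else 1.0


def _eval_rescaled(
    curves: EmbryoCurves, values: np.ndarray, params: RescaleParams, grid: np.ndarray
) -> np.ndarray:
    # value of the rescaled curve at baseline time tau: curve((tau - alpha)/beta)
    return _step_eval(curves.times, values, (grid - params.alpha) / params.beta)


def fit_temporal(
    cohort: Sequence[EmbryoCurves],
    step: Optional[float] = None,
    max_iter: int = 50,
    tol: float = 1e-4,
    beta_range: Tuple[float, float] = (0.5, 2.0),
    alpha_halfspan: Optional[float] = None,
) -> List[RescaleParams]:
    """Fit per-embryo (alpha, beta) aligning cell-number curves to the cohort mean.

    Deterministic: a coarse grid search over (alpha, beta) seeds a
    derivative-free Nelder-Mead refinement (the objective is piecewise
    constant in alpha for step curves). The first embryo is pinned to the
    identity (gauge fixing); alternation stops when the largest parameter
    change drops below ``tol`` or after ``max_iter`` rounds.
    """
    if len(cohort) < 2:
        raise RescaleError("temporal fit needs at least two embryos")
    if step is None:
        step = min(_native_step(c) for c in cohort)
    spans = [c.times[-1] - c.times[0] for c in cohort]
    if alpha_halfspan is None:
        alpha_halfspan = 0.5 * max(spans)
    params = [RescaleParams() for _ in cohort]

    def grid_axis() -> np.ndarray:
        los = [p.beta * c.times[0] + p.alpha for p, c in zip(params, cohort)]
        his = [p.beta * c.times[-1] + p.alpha for p, c in zip(params, cohort)]
        if max(los) >= min(his):
            raise RescaleError("embryo windows do not overlap after rescaling")
        return np.arange(min(los), max(his) + step / 2, step)

    for _ in range(max_iter):
        grid = grid_axis()
        rescaled = np.array(
            [_eval_rescaled(c, c.n, p, grid) for p, c in zip(params, cohort)]
        )
        total = rescaled.sum(axis=0)

        def loss(e: int, alpha: float, beta: float) -> float:
            # leave-one-out cohort average: a self-inclusive target makes the
            # current position and the true alignment score identically
            avg = (total - rescaled[e]) / (len(cohort) - 1)
            y = _step_eval(cohort[e].times, cohort[e].n, (grid - alpha) / beta)
            return float(np.mean((y - avg) ** 2))

        new_params = [params[0]]
        for e in range(1, len(cohort)):
            t_anchor = 0.5 * (cohort[e].times[0] + cohort[e].times[-1])
            a, b = _refine(
                lambda aa, bb: loss(e, aa, bb),
                params[e].alpha,
                params[e].beta,
                alpha_halfspan,
                beta_range,
                floor_alpha=step / 10.0,
                t_anchor=t_anchor,
            )
            new_params.append(RescaleParams(alpha=a, beta=b, gamma=params[e].gamma))
        delta = max(
            max(abs(p.alpha - q.alpha) / max(step, 1.0), abs(p.beta - q.beta))
            for p, q in zip(new_params, params)
        )
        params = new_params
        if delta < tol:
            break
        alpha_halfspan = max(8 * step, alpha_halfspan / 4)  # shrink the coarse net
    grid_axis()  # final overlap check
    return params


def _refine(
    loss,
    a0: float,
    b0: float,
    alpha_span: float,
    beta_range: Tuple[float, float],
    floor_alpha: float,
    t_anchor: float,
    rounds: int = 7,
) -> Tuple[float, float]:
    """Deterministic nested grid search (the objective is piecewise constant,
    so derivative-free bracketing beats simplex methods).

    The search runs in (tau0, beta) with tau0 = alpha + beta * t_anchor and
    t_anchor at the embryo's mid-recording: the raw (alpha, beta) objective
    has a long diagonal valley (a shift can be traded against a stretch
    pivoting at the far end), which the anchored coordinates decouple.
    """
    best = (loss(a0, b0), a0 + b0 * t_anchor, b0)
    span = alpha_span
    log_hw = 0.5 * np.log(beta_range[1] / beta_range[0])
    for r in range(rounds):
        taus = best[1] + np.linspace(-span, span, 25)
        betas = best[2] * np.exp(np.linspace(-log_hw, log_hw, 17))
        betas = betas[(betas >= beta_range[0] / 2) & (betas <= beta_range[1] * 2)]
        for tau in taus:
            for b in betas:
                v = loss(tau - b * t_anchor, b)
                if v < best[0] - 1e-15:
                    best = (v, tau, b)
        span = max(span * 0.35, floor_alpha)
        log_hw *= 0.35
    return best[1] - best[2] * t_anchor, best[2]


def fit_spatial(
    cohort: Sequence[EmbryoCurves],
    temporal: Sequence[RescaleParams],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> List[RescaleParams]:
    """Fit per-embryo gamma aligning temporally rescaled volume curves.

    The scale on volumes is gamma^3; the first embryo is pinned to gamma=1.
    The per-embryo update is the closed-form least-squares scale against the
    running cohort average.
    """
    if len(cohort) != len(temporal):
        raise RescaleError("one temporal parameter set per embryo required")
    step = min(_native_step(c) for c in cohort)
    los = [p.beta * c.times[0] + p.alpha for p, c in zip(temporal, cohort)]
    his = [p.beta * c.times[-1] + p.alpha for p, c in zip(temporal, cohort)]
    if max(los) >= min(his):
        raise RescaleError("embryo windows do not overlap after temporal rescaling")
    grid = np.arange(max(los), min(his) + step / 2, step)
    w = np.array(
        [_eval_rescaled(c, c.w, p, grid) for c, p in zip(cohort, temporal)]
    )
    if np.any(np.all(w == 0, axis=1)):
        raise RescaleError("an embryo has an all-zero volume curve")
    s = np.ones(len(cohort))  # s_e = gamma_e^3
    for _ in range(max_iter):
        avg = np.mean(s[:, None] * w, axis=0)
        new_s = s.copy()
        for e in range(1, len(cohort)):
            new_s[e] = float(np.dot(avg, w[e]) / np.dot(w[e], w[e]))
        if np.max(np.abs(new_s - s)) < tol:
            s = new_s
            break
        s = new_s
    return [
        replace(p, gamma=float(np.cbrt(se))) for p, se in zip(temporal, s)
    ]


def fit_cohort(
    cohort: Sequence[EmbryoCurves], **temporal_kwargs
) -> List[RescaleParams]:
    """Temporal fit followed by spatial fit; returns full per-embryo params."""
    temporal = fit_temporal(cohort, **temporal_kwargs)
    return fit_spatial(cohort, temporal)
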