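"""Per-(generation, type) feature distributions: fits, goodness of fit, independence.

Cell features are binned into mesoscopic groups g = (generation n, type k).
Cycle lengths ``x`` and division times ``m`` are fitted as normal laws;
mean volumes ``v``, surfaces ``s`` and the daughter/mother ratios ``a``,
``b`` as log-normal laws (mean/sd of the log values). Groups need at least
``min_n`` complete-cycle values to be eligible. Goodness of fit uses a
chi-square test on equal-probability bins under the fitted law. Note that
``m`` is derived (m = root division + sum of ancestor cycle lengths), so its
fit is reported for inspection but never used for simulation.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from blastula.laws import LOGNORMAL, NORMAL, Law

#: parametric family per feature code
FEATURE_FAMILY = {
    "x": NORMAL,
    "m": NORMAL,
    "v": LOGNORMAL,
    "s": LOGNORMAL,
    "a": LOGNORMAL,
    "b": LOGNORMAL,
}

DEFAULT_MIN_N = 8


class StatsError(ValueError):
    pass


# ------------------------------------------------------------------- binning


def bin_by_group(features: pd.DataFrame) -> Dict[Tuple[int, str, str], np.ndarray]:
    """Map (generation, type, feature) to the array of complete-cycle values.

    Only finite values of complete cycles are included; empty groups are
    absent rather than zero-filled. ``features`` is the output of
    :func:`blastula.lineage.extract_features`.
    """
    df = features[features["complete"]]
    out: Dict[Tuple[int, str, str], np.ndarray] = {}
    for (n, k), sub in df.groupby(["generation", "type"], sort=True):
        for feat in FEATURE_FAMILY:
            vals = sub[feat].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals):
                out[(int(n), str(k), feat)] = vals
    return out


# --------------------------------------------------------------------- fits


def fit_group(sample: np.ndarray, family: str) -> Tuple[float, float]:
    """Fit (mu, sigma): sample mean / unbiased sd, in log-space for log-normal."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 2:
        raise StatsError("need at least 2 values to fit a law")
    if family == LOGNORMAL:
        if np.any(sample <= 0):
            raise StatsError("log-normal fit requires strictly positive values")
        sample = np.log(sample)
    elif family != NORMAL:
        raise StatsError(f"unknown family {family!r}")
    return float(np.mean(sample)), float(np.std(sample, ddof=1))


def gof_chisq(
    sample: np.ndarray, law: Law, n_bins: Optional[int] = None
) -> Tuple[float, float]:
    """Chi-square goodness of fit of a sample against a fitted law.

    Bins are equal-probability under the law (count = max(5, n // 8) unless
    given); the statistic has dof = bins - 1 - 2, the 2 accounting for the
    fitted (mu, sigma). Returns (statistic, p-value). Deterministic.
    """
    sample = np.asarray(sample, dtype=float)
    n = len(sample)
    if n < 2:
        raise StatsError("sample too small for a goodness-of-fit test")
    if np.std(sample) == 0:
        raise StatsError("degenerate (zero-variance) sample")
    if n_bins is None:
        n_bins = max(5, n // 8)
    edges = law.ppf(np.linspace(0.0, 1.0, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    obs, _ = np.histogram(sample, bins=edges)
    exp = n / n_bins
    stat = float(np.sum((obs - exp) ** 2) / exp)
    dof = n_bins - 1 - 2
    if dof < 1:
        raise StatsError("too few bins for a chi-square test")
    return stat, float(sps.chi2.sf(stat, dof))


def fit_all(
    features: pd.DataFrame, min_n: int = DEFAULT_MIN_N
) -> pd.DataFrame:
    """Fit every (generation, type, feature) group present in the features.

    Returns one row per group with the fitted family, (mu, sigma), sample
    size, an eligibility flag (n >= min_n) and the GOF p-value (NaN for
    ineligible or degenerate samples).
    """
    rows = []
    for (n, k, feat), vals in sorted(bin_by_group(features).items()):
        family = FEATURE_FAMILY[feat]
        if len(vals) < 2:
            continue
        mu, sigma = fit_group(vals, family)
        eligible = len(vals) >= min_n
        p = np.nan
        statistic = np.nan
        if eligible and sigma > 0:
            try:
                statistic, p = gof_chisq(vals, Law(family, mu, sigma))
            except StatsError:
                pass
        rows.append(
            dict(
                generation=n,
                type=k,
                feature=feat,
                family=family,
                mu=mu,
                sigma=sigma,
                n=len(vals),
                eligible=eligible,
                gof_stat=statistic,
                gof_p=p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "generation",
            "type",
            "feature",
            "family",
            "mu",
            "sigma",
            "n",
            "eligible",
            "gof_stat",
            "gof_p",
        ],
    )


# ------------------------------------------------------------- independence


def _r_squared(u: np.ndarray, v: np.ndarray) -> float:
    if len(u) < 3 or np.std(u) == 0 or np.std(v) == 0:
        return np.nan
    r = sps.pearsonr(u, v).statistic
    return float(r * r)


def independence_tests(
    features: pd.DataFrame,
    min_pairs: int = 3,
    r2_flag: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Mother-daughter and sister-sister R^2 per (group, feature).

    Pearson's R^2 is computed between paired values: (mother, daughter) for
    every complete pair, and (sister, sister) with the order within each
    pair randomised under a fixed seed (Pearson on unordered pairs is
    ill-defined). Groups are indexed by the daughters' (generation, type).
    Constant samples yield a missing R^2. Rows with R^2 above ``r2_flag``
    are flagged.
    """
    rng = np.random.default_rng(seed)
    df = features[features["complete"]]
    tested = ("x", "m", "v", "s")
    rows = []
    by_id = df
    mother_ok = df["mother_id"].isin(df.index)
    daughters = df[mother_ok]
    for (n, k), sub in daughters.groupby(["generation", "type"], sort=True):
        mothers = by_id.loc[sub["mother_id"]]
        for feat in tested:
            d_vals = sub[feat].to_numpy(dtype=float)
            m_vals = mothers[feat].to_numpy(dtype=float)
            ok = np.isfinite(d_vals) & np.isfinite(m_vals)
            if ok.sum() >= min_pairs:
                r2 = _r_squared(m_vals[ok], d_vals[ok])
                rows.append(
                    dict(
                        generation=int(n),
                        type=str(k),
                        feature=feat,
                        relation="mother-daughter",
                        r2=r2,
                        n_pairs=int(ok.sum()),
                        flagged=bool(np.isfinite(r2) and r2 > r2_flag),
                    )
                )
        # sisters: pair daughters sharing a mother
        sis = sub.groupby("mother_id").filter(lambda g: len(g) == 2)
        for feat in tested:
            left, right = [], []
            for _, pair in sis.groupby("mother_id"):
                vals = pair[feat].to_numpy(dtype=float)
                if not np.all(np.isfinite(vals)):
                    continue
                if rng.random() < 0.5:
                    vals = vals[::-1]
                left.append(vals[0])
                right.append(vals[1])
            if len(left) >= min_pairs:
                r2 = _r_squared(np.array(left), np.array(right))
                rows.append(
                    dict(
                        generation=int(n),
                        type=str(k),
                        feature=feat,
                        relation="sisters",
                        r2=r2,
                        n_pairs=len(left),
                        flagged=bool(np.isfinite(r2) and r2 > r2_flag),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["generation", "type", "feature", "relation", "r2", "n_pairs", "flagged"],
    )


def pool_features(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-embryo feature tables (cohort-level pooling)."""
    out = []
    for i, df in enumerate(frames):
        d = df.copy()
        d.index = [f"e{i}:{cid}" for cid in d.index]
        d["mother_id"] = [
            f"e{i}:{m}" if isinstance(m, str) else None for m in d["mother_id"]
        ]
        out.append(d)
    return pd.concat(out)
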