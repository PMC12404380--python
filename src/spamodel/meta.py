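"""Random-effects meta-analysis of Fisher-z transformed correlations/effects.

Per-study correlations and standardized regression effects are pooled on the
variance-stabilized Fisher-z scale with sampling variance 1/(n - 3) -- the
correlation convention, applied to the regression effects as well (the
standardized two-wave effects are themselves functions of correlations; see
the methods note for the caveat).  Between-study variance tau^2 is estimated
by REML (default) or DerSimonian-Laird; heterogeneity is summarized by
Cochran's Q (fixed-effect weights) and I^2 with a Q-profile confidence
interval.  Pooled values are back-transformed for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_effects import CORRELATION_FIELDS, CorrelationSet, EffectsBundle, effects_bundle
from .simulate import StudyRecord

__all__ = [
    "MetaResult",
    "fisher_z",
    "inv_fisher_z",
    "study_effects",
    "random_effects_pool",
    "meta_table",
    "META_TABLE_ROWS",
]

Method = Literal["reml", "dl"]


def fisher_z(r: float) -> float:
    """Variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    if not abs(r) < 1:
        raise ValueError(f"|r| = {abs(r)} >= 1 is outside the Fisher-z domain")
    return math.atanh(r)


def inv_fisher_z(z: float) -> float:
    """Back-transform tanh(z)."""
    return math.tanh(z)


def study_effects(rec: StudyRecord) -> EffectsBundle:
    """Per-study closed-form effects; missing inputs give missing effects."""
    return effects_bundle(rec.cs, strict=False)


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate and heterogeneity statistics for one association."""

    k: int
    n_total: int
    pooled: float           # back-transformed, in (-1, 1)
    ci_low: float
    ci_high: float
    pooled_z: float
    se_z: float
    tau2: float
    q: Optional[float]
    q_df: Optional[int]
    q_p: Optional[float]
    i2: Optional[float]          # percent
    i2_ci: Optional[tuple[float, float]]
    method: str
    z_values: tuple[float, ...]
    variances: tuple[float, ...]
    weights: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_total": self.n_total,
            "estimate": self.pooled,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "q": self.q,
            "q_df": self.q_df,
            "q_p": self.q_p,
            "i2": self.i2,
            "i2_ci_low": None if self.i2_ci is None else self.i2_ci[0],
            "i2_ci_high": None if self.i2_ci is None else self.i2_ci[1],
            "method": self.method,
        }


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max(0.0, (q - (len(y) - 1)) / c)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    def negative_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + np.log(np.sum(w))
            + np.sum(w * (y - mu) ** 2)
        )

    upper = max(10.0 * float(np.var(y)) + 1.0, 10.0 * float(np.max(v)))
    result = optimize.minimize_scalar(
        negative_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12},
    )
    return max(0.0, float(result.x))


def _q_profile_tau2_ci(
    y: np.ndarray, v: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Confidence bounds on tau^2 by inverting the generalized Q statistic."""
    k = len(y)

    def q_generalized(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        return float(np.sum(w * (y - mu) ** 2))

    alpha = 1.0 - level
    upper_q = stats.chi2.ppf(1 - alpha / 2, df=k - 1)
    lower_q = stats.chi2.ppf(alpha / 2, df=k - 1)

    def solve(target: float) -> float:
        # q_generalized is decreasing in tau2
        if q_generalized(0.0) <= target:
            return 0.0
        hi = 1.0
        while q_generalized(hi) > target and hi < 1e6:
            hi *= 10.0
        return float(optimize.brentq(lambda t: q_generalized(t) - target, 0.0, hi))

    return solve(upper_q), solve(lower_q)


def _typical_within_variance(v: np.ndarray) -> float:
    w = 1.0 / v
    k = len(v)
    return float((k - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2)))


def random_effects_pool(
    values: Sequence[float],
    variances: Sequence[float],
    method: Method = "reml",
) -> MetaResult:
    """Pool per-study Fisher-z estimates under the random-effects model.

    ``values`` are on the z scale with known sampling ``variances``.  For a
    single study the estimate passes through and heterogeneity statistics are
    flagged as undefined (None).
    """
    y = np.asarray(values, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size == 0:
        raise ValueError("no studies to pool")
    if y.shape != v.shape:
        raise ValueError("values and variances differ in length")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be strictly positive")
    k = int(y.size)

    if k == 1:
        z = float(y[0])
        se = float(np.sqrt(v[0]))
        return MetaResult(
            k=1, n_total=0, pooled=inv_fisher_z(z),
            ci_low=inv_fisher_z(z - 1.96 * se), ci_high=inv_fisher_z(z + 1.96 * se),
            pooled_z=z, se_z=se, tau2=0.0,
            q=None, q_df=None, q_p=None, i2=None, i2_ci=None,
            method=method, z_values=(z,), variances=(float(v[0]),), weights=(1.0,),
        )

    # Cochran's Q with fixed-effect weights
    w_fe = 1.0 / v
    mu_fe = float(np.sum(w_fe * y) / np.sum(w_fe))
    q = float(np.sum(w_fe * (y - mu_fe) ** 2))
    q_df = k - 1
    q_p = float(stats.chi2.sf(q, df=q_df))
    i2 = max(0.0, (q - q_df) / q) * 100.0 if q > 0 else 0.0

    tau2 = _dl_tau2(y, v) if method == "dl" else _reml_tau2(y, v)
    w = 1.0 / (v + tau2)
    pooled_z = float(np.sum(w * y) / np.sum(w))
    se_z = float(np.sqrt(1.0 / np.sum(w)))

    tau2_lo, tau2_hi = _q_profile_tau2_ci(y, v)
    s2 = _typical_within_variance(v)
    i2_ci = (
        100.0 * tau2_lo / (tau2_lo + s2),
        100.0 * tau2_hi / (tau2_hi + s2),
    )

    return MetaResult(
        k=k, n_total=0,
        pooled=inv_fisher_z(pooled_z),
        ci_low=inv_fisher_z(pooled_z - 1.96 * se_z),
        ci_high=inv_fisher_z(pooled_z + 1.96 * se_z),
        pooled_z=pooled_z, se_z=se_z, tau2=float(tau2),
        q=q, q_df=q_df, q_p=q_p, i2=float(i2), i2_ci=i2_ci,
        method=method,
        z_values=tuple(float(x) for x in y),
        variances=tuple(float(x) for x in v),
        weights=tuple(float(x) for x in w),
    )


#: the 14 pooled associations: six correlations, then four effects per direction
META_TABLE_ROWS = tuple(
    list(CORRELATION_FIELDS)
    + [f"{effect}_{direction}"
       for direction in ("xy", "yx")
       for effect in ("beta_lag_fwd", "beta_lag_rev", "beta_change",
                      "beta_change_on_change")]
)


def _study_value(rec: StudyRecord, row: str, bundle: EffectsBundle) -> Optional[float]:
    if row in CORRELATION_FIELDS:
        return getattr(rec.cs, row)
    effect, direction = row.rsplit("_", 1)
    return getattr(bundle.direction(direction), effect)


def meta_table(
    studies: Sequence[StudyRecord],
    method: Method = "reml",
) -> pd.DataFrame:
    """Pool the six correlations and eight effects across studies.

    Returns a 14-row frame; K and total N per row reflect which studies
    supply the inputs that row needs (studies lacking time-2 measures of Y
    drop out of every row involving Y2).  The change-on-change rows of the
    two directions are identical by construction.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    bundles = {rec.study: study_effects(rec) for rec in studies}
    rows = []
    results: dict[str, MetaResult] = {}
    for row in META_TABLE_ROWS:
        values, variances, n_values = [], [], []
        for rec in studies:
            value = _study_value(rec, row, bundles[rec.study])
            if value is None:
                continue
            values.append(fisher_z(value))
            variances.append(1.0 / (rec.n - 3))
            n_values.append(rec.n)
        if not values:
            raise ValueError(f"no study provides inputs for {row}")
        result = random_effects_pool(values, variances, method=method)
        result = MetaResult(**{**result.__dict__, "n_total": int(sum(n_values))})
        results[row] = result
        rows.append({"association": row, **result.to_dict()})
    frame = pd.DataFrame(rows).set_index("association")
    frame.attrs["results"] = results
    return frame
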