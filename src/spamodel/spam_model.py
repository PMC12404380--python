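"""The SPAM generative model: a trait-state account of two-wave panels.

The Spurious Prospective Associations Model (SPAM) generates the six
correlations among X1, X2, Y1, Y2 from four parameters and one sign:

* an overarching trait loads on the general level of each construct with
  magnitude ``a`` (same sign ``s=+1`` for positively associated construct
  pairs, opposite signs ``s=-1`` for negatively associated pairs),
* the general level of X loads ``b`` on both occasion measurements X1, X2,
  the general level of Y loads ``c`` on Y1, Y2,
* occasion-specific state factors add covariance ``d`` between X and Y
  measured at the same occasion.

All observed variances are fixed at 1, so the implied second moments are

    r(X1,X2) = b^2        r(Y1,Y2) = c^2
    cross-lagged  r(X1,Y2) = r(X2,Y1) = s a^2 b c
    concurrent    r(X1,Y1) = r(X2,Y2) = s a^2 b c + d

No path from X to Y (or back) exists, yet the implied structure produces
nonzero adjusted cross-lagged regression effects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_effects import CorrelationSet

__all__ = ["SpamParams", "InvalidParameterError", "implied_correlations",
           "moment_start_values", "simulate_from_model"]


class InvalidParameterError(ValueError):
    """SPAM parameters imply a non-positive-semidefinite structure."""


@dataclass(frozen=True)
class SpamParams:
    """SPAM parameters (a, s, b, c, d).

    ``a``, ``b``, ``c`` are standardized loadings in [0, 1); ``a`` may be 0
    only in testing paths.  ``d`` is the additive state covariance between
    the standardized measurements of the two constructs at the same occasion;
    it is bounded implicitly by positive semidefiniteness of the implied
    matrix.  ``s`` is +1 or -1.  The two trait loadings are a1 = a and
    a2 = s * a.
    """

    a: float
    s: int
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.s not in (+1, -1):
            raise ValueError(f"s must be +1 or -1, got {self.s}")
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} = {v} must lie in [0, 1)")
        if not np.isfinite(self.d):
            raise ValueError("d must be finite")

    @property
    def a1(self) -> float:
        return self.a

    @property
    def a2(self) -> float:
        return self.s * self.a

    def to_json(self) -> str:
        return json.dumps(
            {"a": self.a, "s": self.s, "b": self.b, "c": self.c, "d": self.d},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SpamParams":
        payload = json.loads(text)
        return cls(**payload)


def implied_correlations(params: SpamParams, check: bool = True) -> CorrelationSet:
    """Model-implied CorrelationSet for the given parameters.

    Raises :class:`InvalidParameterError` when the implied matrix is not
    positive semidefinite, reporting the feasible range of ``d``.
    """
    cross = params.s * params.a**2 * params.b * params.c
    concurrent = cross + params.d
    if not (-1.0 < concurrent < 1.0):
        raise InvalidParameterError(
            f"concurrent correlation {concurrent:.4f} leaves (-1, 1); "
            f"d = {params.d} is out of range"
        )
    cs = CorrelationSet(
        r_x1x2=params.b**2,
        r_x1y1=concurrent,
        r_x1y2=cross,
        r_x2y1=cross,
        r_x2y2=concurrent,
        r_y1y2=params.c**2,
    )
    if check and not cs.is_positive_semidefinite():
        low, high = _feasible_d(params)
        raise InvalidParameterError(
            f"implied matrix is not positive semidefinite; with a={params.a}, "
            f"b={params.b}, c={params.c}, s={params.s:+d} the state covariance "
            f"d must lie in [{low:.4f}, {high:.4f}], got {params.d}"
        )
    return cs


def _feasible_d(params: SpamParams, resolution: int = 2001) -> tuple[float, float]:
    """Bracket of d values keeping the implied matrix PSD (grid scan)."""
    grid = np.linspace(-1.0, 1.0, resolution)
    feasible = []
    for d in grid:
        candidate = SpamParams(params.a, params.s, params.b, params.c, float(d))
        try:
            implied_correlations(candidate, check=False).to_matrix()
        except (ValueError, InvalidParameterError):
            continue
        m = implied_correlations(candidate, check=False).to_matrix()
        if np.linalg.eigvalsh(m)[0] >= -1e-10:
            feasible.append(d)
    if not feasible:
        return (np.nan, np.nan)
    return (float(min(feasible)), float(max(feasible)))


def moment_start_values(cs: CorrelationSet, s: int = +1) -> SpamParams:
    """Closed-form method-of-moments parameters from a complete set.

    ``b`` and ``c`` are the square roots of the autocorrelations, ``a`` is
    recovered from the mean absolute cross-lagged correlation, and ``d`` is
    the mean concurrent minus the mean cross-lagged correlation.  When the
    two cross-lagged (and the two concurrent) correlations are equal, the
    model is just-identified in these moments and the recovery is exact.
    """
    cs.require("r_x1x2", "r_x1y1", "r_x1y2", "r_x2y1", "r_x2y2", "r_y1y2")
    if s not in (+1, -1):
        raise ValueError("s must be +1 or -1")
    if cs.r_x1x2 <= 0 or cs.r_y1y2 <= 0:
        raise InvalidParameterError(
            "non-positive autocorrelation; the trait-state decomposition "
            "requires r_x1x2 > 0 and r_y1y2 > 0"
        )
    b = float(np.sqrt(cs.r_x1x2))
    c = float(np.sqrt(cs.r_y1y2))
    mean_cross = (abs(cs.r_x1y2) + abs(cs.r_x2y1)) / 2.0
    mean_cross_signed = (cs.r_x1y2 + cs.r_x2y1) / 2.0
    if mean_cross_signed * s <= 0:
        message = (
            "mean cross-lagged correlation is zero"
            if mean_cross_signed == 0
            else "mean cross-lagged correlation has the opposite sign of s"
        )
        warnings.warn(message + "; a is clamped to the 0 boundary", stacklevel=2)
        a = 0.0
    else:
        ratio = mean_cross / (b * c)
        if ratio > 1.0:
            warnings.warn("trait loading clamped to the unit bound", stacklevel=2)
            ratio = 1.0
        a = float(np.sqrt(ratio))
    a = min(a, 1.0 - 1e-9)
    d = float((cs.r_x1y1 + cs.r_x2y2) / 2.0 - mean_cross_signed)
    return SpamParams(a=a, s=s, b=b, c=c, d=d)


def simulate_from_model(
    params: SpamParams,
    n: int,
    seed: Optional[int] = None,
    exact: bool = True,
):
    """Draw an ``n`` x 4 two-wave dataset from the SPAM.

    In exact mode the sample correlation matrix reproduces the implied one to
    machine precision (whiten-recolor construction); otherwise rows are iid
    multivariate normal draws.  Returns a :class:`spamodel.simulate.TwoWaveDataset`.
    """
    from .simulate import mvn_from_target  # deferred: simulate imports core only

    target = implied_correlations(params)
    return mvn_from_target(target, n=n, seed=seed, exact=exact)
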