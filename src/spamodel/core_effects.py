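"""Closed-form expected regression effects from two-wave correlation structures.

A two-construct, two-occasion panel (X1, X2, Y1, Y2) is summarized by six
Pearson correlations.  Because standardized least-squares coefficients are
functions of correlations alone, the four diagnostic regression effects --
the cross-lagged effect, its time-reversed twin, the effect of a baseline
score on a change score, and the change-on-change effect -- have closed
forms.  Their joint sign pattern separates a genuine prospective effect from
an artifact of shared trait variance and regression to the mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from io import StringIO
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationSet",
    "DirectionalEffects",
    "EffectsBundle",
    "SignPattern",
    "partial_beta",
    "lagged_effects",
    "change_effect",
    "change_on_change_effect",
    "effects_bundle",
    "classify_signs",
]

Direction = Literal["xy", "yx"]

#: order of variables in every assembled matrix
VARIABLES = ("X1", "X2", "Y1", "Y2")

#: correlation-field name for each upper-triangle cell of the 4x4 matrix
_FIELD_OF_CELL = {
    (0, 1): "r_x1x2",
    (0, 2): "r_x1y1",
    (0, 3): "r_x1y2",
    (1, 2): "r_x2y1",
    (1, 3): "r_x2y2",
    (2, 3): "r_y1y2",
}

CORRELATION_FIELDS = tuple(_FIELD_OF_CELL.values())


class MissingCorrelationError(ValueError):
    """A correlation required by the requested effect is absent."""


class DegenerateInputError(ValueError):
    """A perfect correlation makes the requested effect undefined."""


def _check_open_interval(name: str, value: float) -> None:
    if not (-1.0 < value < 1.0):
        raise ValueError(f"{name} = {value} must lie strictly within (-1, 1)")


@dataclass(frozen=True)
class CorrelationSet:
    """The six pairwise correlations among X1, X2, Y1, Y2.

    Entries may be ``None`` (missing), which happens in extracted per-study
    tables when a construct was not measured at the second occasion.  ``n``
    optionally records the sample size behind the correlations.
    """

    r_x1x2: Optional[float] = None
    r_x1y1: Optional[float] = None
    r_x1y2: Optional[float] = None
    r_x2y1: Optional[float] = None
    r_x2y2: Optional[float] = None
    r_y1y2: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        for name in CORRELATION_FIELDS:
            value = getattr(self, name)
            if value is not None:
                _check_open_interval(name, float(value))
        if self.n is not None and self.n < 1:
            raise ValueError(f"n = {self.n} must be a positive integer")

    # -- completeness ----------------------------------------------------

    def is_complete(self) -> bool:
        return all(getattr(self, name) is not None for name in CORRELATION_FIELDS)

    def require(self, *names: str) -> None:
        missing = [name for name in names if getattr(self, name) is None]
        if missing:
            raise MissingCorrelationError(
                "missing correlation(s): " + ", ".join(missing)
            )

    # -- matrix form ------------------------------------------------------

    def to_matrix(self) -> np.ndarray:
        """Assemble the symmetric 4x4 matrix (order X1, X2, Y1, Y2)."""
        self.require(*CORRELATION_FIELDS)
        m = np.eye(4)
        for (i, j), name in _FIELD_OF_CELL.items():
            m[i, j] = m[j, i] = getattr(self, name)
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray, n: Optional[int] = None) -> "CorrelationSet":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        values = {name: float(m[i, j]) for (i, j), name in _FIELD_OF_CELL.items()}
        return cls(n=n, **values)

    def is_positive_semidefinite(self, tol: float = 1e-10) -> bool:
        return bool(np.linalg.eigvalsh(self.to_matrix())[0] >= -tol)

    def is_positive_definite(self, tol: float = 1e-10) -> bool:
        return bool(np.linalg.eigvalsh(self.to_matrix())[0] > tol)

    # -- direction handling ----------------------------------------------

    def swapped(self) -> "CorrelationSet":
        """Exchange the X and Y roles (X1<->Y1, X2<->Y2)."""
        return CorrelationSet(
            r_x1x2=self.r_y1y2,
            r_x1y1=self.r_x1y1,
            r_x1y2=self.r_x2y1,
            r_x2y1=self.r_x1y2,
            r_x2y2=self.r_x2y2,
            r_y1y2=self.r_x1x2,
            n=self.n,
        )

    def oriented(self, direction: Direction) -> "CorrelationSet":
        if direction == "xy":
            return self
        if direction == "yx":
            return self.swapped()
        raise ValueError(f"direction must be 'xy' or 'yx', got {direction!r}")

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {name: getattr(self, name) for name in CORRELATION_FIELDS}
        if self.n is not None:
            payload["n"] = self.n
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CorrelationSet":
        payload = json.loads(text)
        unknown = set(payload) - set(CORRELATION_FIELDS) - {"n"}
        if unknown:
            raise ValueError(f"unknown field(s) in correlation JSON: {sorted(unknown)}")
        return cls(**payload)

    def to_csv(self) -> str:
        """Write the assembled matrix as a labeled 4x4 CSV."""
        frame = pd.DataFrame(self.to_matrix(), index=VARIABLES, columns=VARIABLES)
        return frame.to_csv()

    @classmethod
    def from_csv(cls, text: str, n: Optional[int] = None) -> "CorrelationSet":
        frame = pd.read_csv(StringIO(text), index_col=0)
        if list(frame.columns) != list(VARIABLES) or list(frame.index) != list(VARIABLES):
            raise ValueError(
                f"correlation CSV must be labeled {VARIABLES} on both axes"
            )
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("correlation CSV contains non-finite entries")
        return cls.from_matrix(values, n=n)


# ---------------------------------------------------------------------------
# closed-form effects
# ---------------------------------------------------------------------------


def partial_beta(r_xy: float, r_xz: float, r_yz: float) -> float:
    """Standardized coefficient of x predicting y while adjusting for z.

    ``r_xz`` is the correlation between the two predictors (x and z) and
    ``r_yz`` the correlation of the covariate with the outcome.  Solves the
    two-predictor normal equations in closed form:
    ``(r_xy - r_xz * r_yz) / (1 - r_xz**2)``.
    """
    for name, r in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not (-1.0 <= r <= 1.0):
            raise ValueError(f"{name} = {r} is not a correlation")
    if abs(r_xz) == 1.0:
        raise DegenerateInputError(
            "predictor and covariate are perfectly correlated; the adjusted "
            "coefficient is undefined"
        )
    return (r_xy - r_xz * r_yz) / (1.0 - r_xz**2)


def lagged_effects(cs: CorrelationSet, direction: Direction = "xy") -> tuple[float, float]:
    """Forward and time-reversed adjusted (cross-lagged) effects.

    Forward: X1 -> Y2 adjusting for Y1.  Reversed: X1 -> Y1 adjusting for Y2.
    Regression to the mean predicts the pair to share a sign when the
    association is spurious; a genuine prospective effect predicts opposite
    signs.
    """
    c = cs.oriented(direction)
    c.require("r_x1y2", "r_x1y1", "r_y1y2")
    beta_fwd = partial_beta(c.r_x1y2, c.r_x1y1, c.r_y1y2)
    beta_rev = partial_beta(c.r_x1y1, c.r_x1y2, c.r_y1y2)
    return beta_fwd, beta_rev


def change_effect(cs: CorrelationSet, direction: Direction = "xy") -> float:
    """Standardized unadjusted effect of X1 on the change score Y2 - Y1.

    Both variables are taken standardized, so the change-score standard
    deviation is ``sqrt(2 * (1 - r_y1y2))``.
    """
    c = cs.oriented(direction)
    c.require("r_x1y2", "r_x1y1", "r_y1y2")
    if c.r_y1y2 >= 1.0:
        raise DegenerateInputError("r_y1y2 = 1 gives a zero-variance change score")
    return (c.r_x1y2 - c.r_x1y1) / math.sqrt(2.0 * (1.0 - c.r_y1y2))


def change_on_change_effect(cs: CorrelationSet) -> float:
    """Standardized effect of the change X2 - X1 on the change Y2 - Y1.

    Symmetric under exchanging the X and Y roles, so it is direction-free.
    """
    cs.require(*CORRELATION_FIELDS)
    if cs.r_x1x2 >= 1.0 or cs.r_y1y2 >= 1.0:
        raise DegenerateInputError("a unit autocorrelation gives a zero-variance change score")
    numerator = cs.r_x1y1 + cs.r_x2y2 - cs.r_x1y2 - cs.r_x2y1
    return numerator / math.sqrt(4.0 * (1.0 - cs.r_x1x2) * (1.0 - cs.r_y1y2))


@dataclass(frozen=True)
class DirectionalEffects:
    """The four standardized effects for one direction of prediction."""

    beta_lag_fwd: Optional[float]
    beta_lag_rev: Optional[float]
    beta_change: Optional[float]
    beta_change_on_change: Optional[float]

    def as_tuple(self) -> tuple:
        return (
            self.beta_lag_fwd,
            self.beta_lag_rev,
            self.beta_change,
            self.beta_change_on_change,
        )


@dataclass(frozen=True)
class EffectsBundle:
    """Effects in both directions (X predicting Y, and Y predicting X)."""

    xy: DirectionalEffects
    yx: DirectionalEffects

    def direction(self, direction: Direction) -> DirectionalEffects:
        return self.xy if direction == "xy" else self.yx


def _maybe(fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except MissingCorrelationError:
        return None


def effects_bundle(cs: CorrelationSet, strict: bool = False) -> EffectsBundle:
    """Assemble all four effects in both directions.

    With ``strict=False`` (default) effects whose inputs are missing come back
    as ``None`` so that partially observed studies still contribute whatever
    they can; with ``strict=True`` a missing input raises.
    """
    directions = {}
    coc = change_on_change_effect(cs) if strict else _maybe(change_on_change_effect, cs)
    for direction in ("xy", "yx"):
        if strict:
            fwd, rev = lagged_effects(cs, direction)
            chg = change_effect(cs, direction)
        else:
            pair = _maybe(lagged_effects, cs, direction)
            fwd, rev = pair if pair is not None else (None, None)
            chg = _maybe(change_effect, cs, direction)
        directions[direction] = DirectionalEffects(fwd, rev, chg, coc)
    return EffectsBundle(xy=directions["xy"], yx=directions["yx"])


# ---------------------------------------------------------------------------
# sign-pattern diagnostic
# ---------------------------------------------------------------------------

Verdict = Literal[
    "true-increasing",
    "true-decreasing",
    "spurious-positive",
    "spurious-negative",
    "inconclusive",
]

# allowed epsilon-banded signs, per effect, for each verdict
_TEMPLATES: dict[str, tuple[frozenset, ...]] = {
    "true-increasing": (frozenset({+1}), frozenset({-1}), frozenset({+1}), frozenset({+1})),
    "true-decreasing": (frozenset({-1}), frozenset({+1}), frozenset({-1}), frozenset({-1})),
    "spurious-positive": (frozenset({+1}), frozenset({+1}), frozenset({0, -1}), frozenset({0, +1})),
    "spurious-negative": (frozenset({-1}), frozenset({-1}), frozenset({0, +1}), frozenset({0, -1})),
}


@dataclass(frozen=True)
class SignPattern:
    """Epsilon-banded signs of the four effects and the implied verdict."""

    direction: Direction
    signs: tuple[int, int, int, int]
    verdict: Verdict
    epsilon: float


def _banded_sign(value: float, epsilon: float) -> int:
    if abs(value) <= epsilon:
        return 0
    return 1 if value > 0 else -1


def classify_signs(
    bundle: EffectsBundle, epsilon: float = 0.02
) -> dict[Direction, SignPattern]:
    """Map each direction's effect signs to a verdict.

    A true prospective effect flips the sign of the time-reversed adjusted
    effect; a spurious association preserves it and pushes the change effect
    toward zero or the opposite sign.  Effects within ``epsilon`` of zero
    count as zero.  Any pattern matching no template is inconclusive (this
    includes bundles with missing effects).
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    out: dict[Direction, SignPattern] = {}
    for direction in ("xy", "yx"):
        effects = bundle.direction(direction).as_tuple()
        if any(e is None or not math.isfinite(e) for e in effects):
            out[direction] = SignPattern(direction, (0, 0, 0, 0), "inconclusive", epsilon)
            continue
        signs = tuple(_banded_sign(e, epsilon) for e in effects)
        verdict: Verdict = "inconclusive"
        for name, template in _TEMPLATES.items():
            if all(s in allowed for s, allowed in zip(signs, template)):
                verdict = name  # type: ignore[assignment]
                break
        out[direction] = SignPattern(direction, signs, verdict, epsilon)
    return out
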