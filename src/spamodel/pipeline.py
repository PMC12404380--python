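"""End-to-end evaluation procedures and file I/O.

``spam_evaluation`` runs the six-step simulation check on a pooled
correlation set: simulate a large dataset with exactly those correlations,
fit the SPAM, simulate again from the fitted model's predicted correlations,
re-estimate the four regression effects in both directions, and compare the
adjusted cross-lagged effects with the ones the input correlations imply.
If the model-predicted effects land where the observed ones are, the
observed prospective associations are compatible with a data-generating
mechanism containing no causal path between the constructs.

``analyze_two_wave`` applies the same logic directly to a raw two-wave
dataset, adding conventional least-squares confidence intervals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import __version__ as _version
from .core_effects import (
    CorrelationSet,
    DirectionalEffects,
    EffectsBundle,
    SignPattern,
    classify_signs,
    effects_bundle,
)
from .sem_fit import FitResult, fit_spam
from .simulate import (
    COLUMNS,
    TwoWaveDataset,
    empirical_effects,
    mvn_from_target,
    sample_correlations,
    studies_from_csv,
)

__all__ = [
    "EvaluationReport",
    "spam_evaluation",
    "analyze_two_wave",
    "io_read_correlations",
    "io_read_studies",
    "io_read_dataset",
    "io_write_report",
]

logger = logging.getLogger("spamodel")


def _bundle_to_dict(bundle: EffectsBundle) -> dict:
    return {
        direction: asdict(bundle.direction(direction))
        for direction in ("xy", "yx")
    }


def _signs_to_dict(signs: dict[str, SignPattern]) -> dict:
    return {
        direction: {
            "signs": list(pattern.signs),
            "verdict": pattern.verdict,
            "epsilon": pattern.epsilon,
        }
        for direction, pattern in signs.items()
    }


@dataclass(frozen=True)
class EvaluationReport:
    """Everything the six-step evaluation produces, with provenance."""

    input_correlations: CorrelationSet
    fit: FitResult
    predicted_correlations: CorrelationSet
    input_effects: EffectsBundle
    predicted_effects: EffectsBundle
    input_signs: dict[str, SignPattern]
    predicted_signs: dict[str, SignPattern]
    deltas: dict[str, dict[str, float]]
    seed: Optional[int]
    n: int
    exact: bool
    raw_effects_ci: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "software_version": _version,
            "options": {"seed": self.seed, "n": self.n, "exact": self.exact},
            "input_correlations": json.loads(self.input_correlations.to_json()),
            "fit": self.fit.to_dict(),
            "predicted_correlations": json.loads(
                self.predicted_correlations.to_json()
            ),
            "input_effects": _bundle_to_dict(self.input_effects),
            "predicted_effects": _bundle_to_dict(self.predicted_effects),
            "input_signs": _signs_to_dict(self.input_signs),
            "predicted_signs": _signs_to_dict(self.predicted_signs),
            "deltas": self.deltas,
            "raw_effects_ci": self.raw_effects_ci,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def summary(self) -> str:
        lines = [
            f"SPAM evaluation (n={self.n}, exact={self.exact}, seed={self.seed})",
            f"  fitted: {self.fit.table_row()}",
        ]
        for direction in ("xy", "yx"):
            observed = self.input_effects.direction(direction)
            predicted = self.predicted_effects.direction(direction)
            verdict = self.predicted_signs[direction].verdict
            lines.append(
                f"  {direction}: lagged fwd {observed.beta_lag_fwd:+.4f} -> "
                f"predicted {predicted.beta_lag_fwd:+.4f}; verdict {verdict}"
            )
        return "\n".join(lines)


def _effect_deltas(predicted: EffectsBundle, observed: EffectsBundle) -> dict:
    deltas: dict[str, dict[str, float]] = {}
    for direction in ("xy", "yx"):
        p = predicted.direction(direction)
        o = observed.direction(direction)
        deltas[direction] = {
            name: (None if pv is None or ov is None else float(pv - ov))
            for name, pv, ov in zip(
                ("beta_lag_fwd", "beta_lag_rev", "beta_change",
                 "beta_change_on_change"),
                p.as_tuple(), o.as_tuple(),
            )
        }
    return deltas


def _checksum(cs: CorrelationSet) -> str:
    return hashlib.sha256(cs.to_json().encode()).hexdigest()[:12]


def spam_evaluation(
    cs: CorrelationSet,
    n: int = 10_000,
    s: int = +1,
    seed: Optional[int] = None,
    exact: bool = True,
    epsilon: float = 0.02,
) -> EvaluationReport:
    """Run the six-step SPAM evaluation on a pooled correlation set.

    Steps: (1) take the input correlations; (2) simulate an n-row dataset
    with those correlations; (3) fit the SPAM to its sample correlations;
    (4) simulate a new dataset from the model-predicted correlations;
    (5) estimate the four standardized effects per direction in that dataset;
    (6) compare the adjusted lagged effects against the input-implied ones
    and classify the sign patterns.
    """
    if n < 100:
        raise ValueError("n must be at least 100 for a stable evaluation")
    if not cs.is_complete():
        raise ValueError("the evaluation needs all six correlations")
    logger.info("step 1: input correlations (checksum %s)", _checksum(cs))
    rng = np.random.default_rng(seed)

    logger.info("step 2: simulating n=%d (exact=%s)", n, exact)
    data_input = mvn_from_target(cs, n=n, seed=int(rng.integers(2**31)), exact=exact)
    observed_cs = sample_correlations(data_input)

    logger.info("step 3: fitting the SPAM (s=%+d)", s)
    fit = fit_spam(observed_cs, n_obs=n, s=s)
    if not fit.converged:
        raise RuntimeError("SPAM fit did not converge")
    predicted_cs = fit.predicted_correlations()
    logger.info("step 3: %s", fit.table_row())

    logger.info("step 4: simulating from predicted correlations")
    data_predicted = mvn_from_target(
        predicted_cs, n=n, seed=int(rng.integers(2**31)), exact=exact
    )

    logger.info("step 5: estimating regression effects")
    predicted_effects = empirical_effects(data_predicted)
    input_effects = effects_bundle(cs)

    logger.info("step 6: comparing lagged effects and classifying signs")
    deltas = _effect_deltas(predicted_effects, input_effects)
    return EvaluationReport(
        input_correlations=cs,
        fit=fit,
        predicted_correlations=predicted_cs,
        input_effects=input_effects,
        predicted_effects=predicted_effects,
        input_signs=classify_signs(input_effects, epsilon=epsilon),
        predicted_signs=classify_signs(predicted_effects, epsilon=epsilon),
        deltas=deltas,
        seed=seed,
        n=n,
        exact=exact,
    )


def _ols_ci(outcome: np.ndarray, predictors: list[np.ndarray]) -> tuple[float, float, float]:
    """Standardized coefficient of the first predictor with its 95% CI.

    All variables (including change scores built from z-scored components)
    are re-standardized before the fit, so the point estimate matches
    :func:`spamodel.simulate.empirical_effects` exactly.
    """
    design = sm.add_constant(
        np.column_stack([(p - p.mean()) / p.std() for p in predictors])
    )
    z_outcome = (outcome - outcome.mean()) / outcome.std()
    model = sm.OLS(z_outcome, design).fit()
    ci = model.conf_int(alpha=0.05)
    return float(model.params[1]), float(ci[1][0]), float(ci[1][1])


def analyze_two_wave(
    data: TwoWaveDataset,
    s: int = +1,
    epsilon: float = 0.02,
) -> EvaluationReport:
    """Full analysis of a raw two-wave dataset.

    Computes sample correlations, the four standardized effects per direction
    with conventional least-squares 95% confidence intervals, fits the SPAM
    directly to the sample matrix, and classifies the sign patterns.  Row
    order of the input is irrelevant.
    """
    if data.n < 30:
        raise ValueError("need at least 30 rows")
    cs = sample_correlations(data)
    observed_effects = empirical_effects(data)
    fit = fit_spam(cs, n_obs=data.n, s=s)
    if not fit.converged:
        logger.warning("SPAM fit flagged as non-converged")
    predicted_cs = fit.predicted_correlations()
    predicted_effects = effects_bundle(predicted_cs)

    values = data.values()
    z = (values - values.mean(axis=0)) / values.std(axis=0)
    x1, x2, y1, y2 = z.T
    ci_table: dict[str, dict[str, tuple[float, float, float]]] = {}
    for direction, (p1, p2, o1, o2) in {
        "xy": (x1, x2, y1, y2),
        "yx": (y1, y2, x1, x2),
    }.items():
        ci_table[direction] = {
            "beta_lag_fwd": _ols_ci(o2, [p1, o1]),
            "beta_lag_rev": _ols_ci(o1, [p1, o2]),
            "beta_change": _ols_ci(o2 - o1, [p1]),
            "beta_change_on_change": _ols_ci(o2 - o1, [p2 - p1]),
        }

    return EvaluationReport(
        input_correlations=cs,
        fit=fit,
        predicted_correlations=predicted_cs,
        input_effects=observed_effects,
        predicted_effects=predicted_effects,
        input_signs=classify_signs(observed_effects, epsilon=epsilon),
        predicted_signs=classify_signs(predicted_effects, epsilon=epsilon),
        deltas=_effect_deltas(predicted_effects, observed_effects),
        seed=None,
        n=data.n,
        exact=True,
        raw_effects_ci=ci_table,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def io_read_correlations(path: str | Path) -> CorrelationSet:
    """Read a CorrelationSet from a .json file or a labeled 4x4 .csv matrix."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            cs = CorrelationSet.from_json(text)
        else:
            cs = CorrelationSet.from_csv(text)
    except (ValueError, json.JSONDecodeError) as error:
        raise ValueError(f"{path}: {error}") from error
    return cs


def io_read_studies(path: str | Path):
    path = Path(path)
    try:
        return studies_from_csv(path.read_text())
    except ValueError as error:
        raise ValueError(f"{path}: {error}") from error


def io_read_dataset(path: str | Path) -> TwoWaveDataset:
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad = frame[list(COLUMNS)].isna() | ~np.isfinite(frame[list(COLUMNS)])
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax()) + 2  # 1-based + header line
        raise ValueError(f"{path}: non-finite value near line {row}")
    return TwoWaveDataset(frame)


def io_write_report(report: EvaluationReport, path: str | Path) -> None:
    """Write a report as JSON (.json) or human-readable text (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(report.to_json() + "\n")
    else:
        path.write_text(report.summary() + "\n")
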