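"""Multivariate-normal simulation and empirical effect estimation.

Two generation modes are provided.  Exact mode whitens an iid normal draw and
recolors it with the Cholesky factor of the target matrix, so the *sample*
correlations equal the target to machine precision -- the mode used to make
simulated evaluation pipelines deterministic.  Stochastic mode draws rows
independently, so sample correlations scatter around the target with the
usual O(1/sqrt(n)) error.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_effects import (
    CORRELATION_FIELDS,
    CorrelationSet,
    DirectionalEffects,
    EffectsBundle,
)
from .spam_model import SpamParams, implied_correlations

__all__ = [
    "TwoWaveDataset",
    "StudyRecord",
    "mvn_from_target",
    "sample_correlations",
    "empirical_effects",
    "make_study_fixtures",
    "studies_to_csv",
    "studies_from_csv",
]

COLUMNS = ("X1", "X2", "Y1", "Y2")


@dataclass(frozen=True)
class TwoWaveDataset:
    """n observations of two constructs at two occasions."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset lacks column(s) {missing}; expected {COLUMNS}")
        values = self.data[list(COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("dataset contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data[list(COLUMNS)].to_numpy(dtype=float)

    def to_csv(self) -> str:
        return self.data[list(COLUMNS)].to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str) -> "TwoWaveDataset":
        return cls(pd.read_csv(StringIO(text)))


@dataclass(frozen=True)
class StudyRecord:
    """One study's sample size and (possibly incomplete) correlation set."""

    study: str
    n: int
    cs: CorrelationSet

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError(
                f"study {self.study!r}: n = {self.n} < 4 makes the Fisher-z "
                "variance 1/(n-3) non-positive"
            )


def mvn_from_target(
    cs: CorrelationSet,
    n: int,
    seed: Optional[int] = None,
    exact: bool = True,
) -> TwoWaveDataset:
    """Simulate ``n`` rows of (X1, X2, Y1, Y2) with target correlations ``cs``.

    Exact mode requires ``n > 4`` (the centered draw must have full column
    rank) and a strictly positive-definite target; no smoothing is applied to
    deficient targets.
    """
    if n <= 4:
        raise ValueError(f"n = {n} too small; need n > 4")
    target = cs.to_matrix()
    eigenvalues = np.linalg.eigvalsh(target)
    if eigenvalues[0] <= 1e-10:
        raise ValueError(
            f"target correlation matrix is not positive definite "
            f"(smallest eigenvalue {eigenvalues[0]:.3e})"
        )
    rng = np.random.default_rng(seed)
    draw = rng.standard_normal((n, 4))
    chol_target = np.linalg.cholesky(target)
    if exact:
        draw -= draw.mean(axis=0)
        sample_cov = (draw.T @ draw) / n
        whitener = np.linalg.inv(np.linalg.cholesky(sample_cov))
        draw = draw @ whitener.T @ chol_target.T
    else:
        draw = draw @ chol_target.T
    return TwoWaveDataset(pd.DataFrame(draw, columns=list(COLUMNS)))


def sample_correlations(data: TwoWaveDataset) -> CorrelationSet:
    """The six pairwise Pearson correlations of a dataset, with n attached."""
    if data.n < 5:
        raise ValueError(f"n = {data.n} < 5; correlations would be unstable")
    values = data.values()
    sd = values.std(axis=0)
    degenerate = [COLUMNS[i] for i in range(4) if sd[i] == 0]
    if degenerate:
        raise ValueError(f"zero-variance column(s): {degenerate}")
    r = np.corrcoef(values.T)
    # duplicated columns give |r| = 1, outside CorrelationSet's open interval
    clipped = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    np.fill_diagonal(clipped, 1.0)
    return CorrelationSet.from_matrix(clipped, n=data.n)


def _standardized_beta(y: np.ndarray, predictors: Sequence[np.ndarray]) -> np.ndarray:
    design = np.column_stack([(p - p.mean()) / p.std() for p in predictors])
    outcome = (y - y.mean()) / y.std()
    rank = np.linalg.matrix_rank(design.T @ design / len(y))
    if rank < design.shape[1]:
        raise ValueError("collinear predictors; the design is degenerate")
    coef, *_ = np.linalg.lstsq(design, outcome, rcond=None)
    return coef


def empirical_effects(data: TwoWaveDataset) -> EffectsBundle:
    """The four effects per direction, by least squares on standardized data.

    Change scores are differences of z-scored columns, and each coefficient is
    re-standardized by the realized standard deviations, so on data with
    exactly the target correlations this path agrees with the closed forms to
    numerical precision.
    """
    if data.n < 10:
        raise ValueError(f"n = {data.n} < 10; too few rows for effect estimation")
    values = data.values()
    z = (values - values.mean(axis=0)) / values.std(axis=0)
    x1, x2, y1, y2 = z.T

    def one_direction(p1, p2, o1, o2) -> DirectionalEffects:
        fwd = _standardized_beta(o2, [p1, o1])[0]
        rev = _standardized_beta(o1, [p1, o2])[0]
        change = _standardized_beta(o2 - o1, [p1])[0]
        coc = _standardized_beta(o2 - o1, [p2 - p1])[0]
        return DirectionalEffects(float(fwd), float(rev), float(change), float(coc))

    return EffectsBundle(
        xy=one_direction(x1, x2, y1, y2),
        yx=one_direction(y1, y2, x1, x2),
    )


# ---------------------------------------------------------------------------
# synthetic multi-study fixtures
# ---------------------------------------------------------------------------

#: correlation entries unavailable when the Y construct lacks a time-2 measure
Y2_FIELDS = ("r_x1y2", "r_x2y2", "r_y1y2")


def _nearest_valid(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at 1e-8 followed by unit-diagonal renormalization."""
    w, v = np.linalg.eigh((matrix + matrix.T) / 2.0)
    repaired = (v * np.maximum(w, 1e-8)) @ v.T
    scale = np.sqrt(np.diag(repaired))
    return repaired / np.outer(scale, scale)


def make_study_fixtures(
    population: SpamParams,
    k: int,
    n_range: tuple[int, int] = (150, 800),
    tau_z: float = 0.1,
    seed: Optional[int] = None,
    missing_pattern: Optional[Iterable[int]] = None,
    max_retries: int = 20,
) -> list[StudyRecord]:
    """Generate ``k`` synthetic study records around a SPAM population.

    Each study's true correlations are the population implied correlations
    perturbed by Normal(0, ``tau_z``) on the Fisher-z scale (the conventional
    random-effects heterogeneity model), repaired to the nearest valid matrix
    if needed; the recorded values are sample correlations of a stochastic
    draw of size n ~ Uniform(n_range).  Studies whose index appears in
    ``missing_pattern`` have their Y2 entries blanked, emulating studies that
    did not measure the second construct at the second occasion.
    """
    if k < 2:
        raise ValueError("need at least two studies")
    if tau_z < 0:
        raise ValueError("tau_z must be non-negative")
    rng = np.random.default_rng(seed)
    population_matrix = implied_correlations(population).to_matrix()
    missing = set(missing_pattern or ())
    records: list[StudyRecord] = []
    for index in range(k):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        for _ in range(max_retries):
            z = np.arctanh(np.clip(population_matrix, -1 + 1e-12, 1 - 1e-12))
            off = ~np.eye(4, dtype=bool)
            noise = np.zeros((4, 4))
            upper = np.triu_indices(4, k=1)
            draws = rng.normal(0.0, tau_z, size=len(upper[0]))
            noise[upper] = draws
            noise += noise.T
            perturbed = np.tanh(np.where(off, z + noise, z))
            np.fill_diagonal(perturbed, 1.0)
            if np.linalg.eigvalsh(perturbed)[0] <= 1e-8:
                perturbed = _nearest_valid(perturbed)
            if np.linalg.eigvalsh(perturbed)[0] > 1e-10:
                break
        else:  # pragma: no cover - repair failed repeatedly
            raise RuntimeError("could not construct a valid study matrix")
        study_target = CorrelationSet.from_matrix(perturbed)
        data = mvn_from_target(study_target, n=n, seed=int(rng.integers(2**31)), exact=False)
        cs = sample_correlations(data)
        if index in missing:
            blanked = {f: getattr(cs, f) for f in CORRELATION_FIELDS}
            for f in Y2_FIELDS:
                blanked[f] = None
            cs = CorrelationSet(n=cs.n, **blanked)
        records.append(StudyRecord(study=f"study_{index + 1:02d}", n=n, cs=cs))
    return records


def studies_to_csv(records: Sequence[StudyRecord]) -> str:
    """Serialize study records to the per-study CSV table (blank = missing)."""
    rows = []
    for rec in records:
        row = {"study": rec.study, "n": rec.n}
        row.update({f: getattr(rec.cs, f) for f in CORRELATION_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows).to_csv(index=False)


def studies_from_csv(text: str) -> list[StudyRecord]:
    """Read a per-study CSV table (e.g. a transcribed published table)."""
    frame = pd.read_csv(StringIO(text))
    required = {"study", "n"}
    if not required.issubset(frame.columns):
        raise ValueError(f"study CSV must have columns {sorted(required)}")
    records = []
    for _, row in frame.iterrows():
        values = {}
        for f in CORRELATION_FIELDS:
            v = row.get(f)
            values[f] = None if pd.isna(v) else float(v)
        n = int(row["n"])
        records.append(
            StudyRecord(study=str(row["study"]), n=n, cs=CorrelationSet(n=n, **values))
        )
    return records
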