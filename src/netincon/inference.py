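"""GLS fitting of consistency/inconsistency models and the global Wald test.

Estimation is weighted least squares on study contrasts with a block-diagonal
total covariance: the declared within-study covariance plus a common
heterogeneity variance tau2 on every contrast with tau2/2 within-study
off-diagonals (exchangeable-arms structure).  The global inconsistency test is
a Wald chi-square on the identifiable inconsistency offsets of the
design-by-treatment interaction fit; it simultaneously tests every loop
inconsistency model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy import stats

from .errors import (
    IncompatibleLayoutError,
    RankDeficiencyError,
    SaturatedModelError,
    StructuralError,
)
from .model_build import DesignMatrix, ModelSpec, StudyLayout, build_matrix
from .partitions import Design, DesignSet, discrete_partition

__all__ = [
    "StudyRecord",
    "ContrastDataset",
    "FitResult",
    "InconsistencyTest",
    "fit_gls",
    "wald_inconsistency_test",
    "estimate_tau2",
]


@dataclass(frozen=True)
class StudyRecord:
    """One study's observed contrasts versus its baseline treatment.

    A study of k arms contributes k-1 contrasts; ``covariance`` is their
    within-study sampling covariance (symmetric positive definite).
    """

    study: str
    design: Design
    baseline: str
    treatments: tuple[str, ...]
    estimates: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        k = len(self.treatments)
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "covariance", cov)
        if self.baseline not in self.design:
            raise StructuralError(
                f"study {self.study}: baseline {self.baseline} not in design"
            )
        if {self.baseline, *self.treatments} != self.design.members:
            raise StructuralError(
                f"study {self.study}: arms do not match design "
                f"{self.design.label}"
            )
        if est.shape != (k,) or cov.shape != (k, k):
            raise StructuralError(
                f"study {self.study}: estimates/covariance shape mismatch"
            )
        if not np.allclose(cov, cov.T):
            raise StructuralError(f"study {self.study}: covariance not symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise StructuralError(
                f"study {self.study}: covariance not positive definite"
            ) from None

    @property
    def n_contrasts(self) -> int:
        return len(self.treatments)

    def layout(self) -> StudyLayout:
        return StudyLayout(
            study=self.study,
            design=self.design,
            baseline=self.baseline,
            contrasts=self.treatments,
        )


@dataclass(frozen=True)
class ContrastDataset:
    """Contrast-level network meta-analysis data."""

    records: tuple[StudyRecord, ...]

    def __init__(self, records: Sequence[StudyRecord]) -> None:
        if not records:
            raise StructuralError("dataset has no studies")
        names = [r.study for r in records]
        if len(set(names)) != len(names):
            raise StructuralError("duplicate study identifiers")
        object.__setattr__(self, "records", tuple(records))

    @property
    def treatments(self) -> frozenset[str]:
        return frozenset().union(*(r.design.members for r in self.records))

    def design_set(self) -> DesignSet:
        return DesignSet({r.design for r in self.records})

    def layout(self) -> list[StudyLayout]:
        return [r.layout() for r in self.records]

    @property
    def n_contrasts(self) -> int:
        return sum(r.n_contrasts for r in self.records)

    def stacked_estimates(self) -> np.ndarray:
        return np.concatenate([r.estimates for r in self.records])

    def within_covariance(self) -> np.ndarray:
        return scipy.linalg.block_diag(*(r.covariance for r in self.records))

    def heterogeneity_structure(self) -> np.ndarray:
        """Per-contrast heterogeneity pattern: 1 diagonal, 1/2 within study."""
        blocks = []
        for r in self.records:
            k = r.n_contrasts
            blocks.append(0.5 * (np.eye(k) + np.ones((k, k))))
        return scipy.linalg.block_diag(*blocks)


@dataclass(frozen=True)
class FitResult:
    """GLS parameter estimates, their covariance, and fit bookkeeping."""

    spec: ModelSpec
    names: tuple[str, ...]
    estimates: np.ndarray
    covariance: np.ndarray
    residual_df: int
    tau2: float
    fitted: np.ndarray
    residuals: np.ndarray

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def omega_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n.startswith("w_")]

    def to_dict(self) -> dict:
        return {
            "parameters": {
                n: {
                    "estimate": float(e),
                    "se": float(math.sqrt(max(v, 0.0))),
                }
                for n, e, v in zip(
                    self.names, self.estimates, np.diag(self.covariance)
                )
            },
            "residual_df": self.residual_df,
            "tau2": self.tau2,
        }


@dataclass(frozen=True)
class InconsistencyTest:
    """Global Wald test of the null of no inconsistency."""

    statistic: float
    df: int
    p_value: float
    tau2: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "Q": self.statistic,
            "df": self.df,
            "p_value": self.p_value if not self.degenerate else None,
            "tau2": self.tau2,
            "degenerate": self.degenerate,
        }


def _check_alignment(data: ContrastDataset, matrix: DesignMatrix) -> None:
    expected = tuple(
        (r.study, r.baseline, t) for r in data.records for t in r.treatments
    )
    if matrix.rows != expected:
        raise IncompatibleLayoutError(
            "design matrix rows do not align with the dataset's contrasts"
        )


def _total_covariance(data: ContrastDataset, tau2: float) -> np.ndarray:
    if tau2 < 0:
        raise StructuralError("tau2 must be nonnegative")
    V = data.within_covariance()
    if tau2 > 0:
        V = V + tau2 * data.heterogeneity_structure()
    return V


def _name_deficient_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    kept: list[int] = []
    rank = 0
    for k in range(X.shape[1]):
        r = int(np.linalg.matrix_rank(X[:, kept + [k]]))
        if r > rank:
            kept.append(k)
            rank = r
    return [names[k] for k in range(X.shape[1]) if k not in kept]


def fit_gls(
    data: ContrastDataset,
    spec: ModelSpec,
    matrix: DesignMatrix,
    tau2: float = 0.0,
) -> FitResult:
    """Weighted least-squares fit with covariance (X' V^-1 X)^-1.

    ``tau2`` is added to the within-study covariance with the exchangeable
    structure before weighting.  When the model saturates the data, the fit
    reproduces the observations exactly.
    """
    _check_alignment(data, matrix)
    X = matrix.values
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _name_deficient_columns(X, matrix.columns)
        raise RankDeficiencyError(
            f"design matrix is rank deficient; dependent columns: {bad}"
        )
    y = data.stacked_estimates()
    V = _total_covariance(data, tau2)
    Vc = scipy.linalg.cho_factor(V)
    Vinv_X = scipy.linalg.cho_solve(Vc, X)
    Vinv_y = scipy.linalg.cho_solve(Vc, y)
    A = X.T @ Vinv_X
    b = X.T @ Vinv_y
    try:
        Ac = scipy.linalg.cho_factor(A)
    except np.linalg.LinAlgError:
        bad = _name_deficient_columns(X, matrix.columns)
        raise RankDeficiencyError(
            f"singular normal equations; dependent columns: {bad}"
        ) from None
    beta = scipy.linalg.cho_solve(Ac, b)
    cov = scipy.linalg.cho_solve(Ac, np.eye(A.shape[0]))
    cov = 0.5 * (cov + cov.T)
    fitted = X @ beta
    return FitResult(
        spec=spec,
        names=matrix.columns,
        estimates=beta,
        covariance=cov,
        residual_df=int(X.shape[0] - X.shape[1]),
        tau2=float(tau2),
        fitted=fitted,
        residuals=y - fitted,
    )


def estimate_tau2(
    data: ContrastDataset, spec: ModelSpec, matrix: DesignMatrix
) -> float:
    """Method-of-moments heterogeneity estimate, truncated at zero.

    Matrix generalization of the DerSimonian-Laird estimator: with P the
    projection residual operator under within-study weighting, solves
    E[y'Py] = residual_df + tau2 * tr(P R) for tau2, where R is the
    exchangeable heterogeneity structure.
    """
    _check_alignment(data, matrix)
    X = matrix.values
    n, p = X.shape
    if n - p < 1:
        raise SaturatedModelError(
            "zero residual degrees of freedom: supply tau2 explicitly"
        )
    y = data.stacked_estimates()
    V0 = data.within_covariance()
    Vc = scipy.linalg.cho_factor(V0)
    Vinv = scipy.linalg.cho_solve(Vc, np.eye(n))
    Vinv_X = Vinv @ X
    A = X.T @ Vinv_X
    P = Vinv - Vinv_X @ scipy.linalg.solve(A, Vinv_X.T, assume_a="pos")
    q = float(y @ P @ y)
    R = data.heterogeneity_structure()
    denom = float(np.trace(P @ R))
    return max(0.0, (q - (n - p)) / denom)


def wald_inconsistency_test(
    data: ContrastDataset, tau2: float | None = None
) -> InconsistencyTest:
    """Global Wald test on the design-by-treatment interaction fit.

    Q = w' cov(w)^-1 w over the identifiable inconsistency estimates, with a
    chi-square reference on the model's inconsistency degrees of freedom.
    Networks with no closable inconsistency (e.g. a single design) yield a
    degenerate result with df = 0.  With ``tau2=None`` the heterogeneity is
    estimated under the full model; a saturated model then raises and an
    explicit tau2 must be given.
    """
    designs = data.design_set()
    layout = data.layout()
    spec, matrix = build_matrix(layout, discrete_partition(designs))
    df = len(spec.inconsistency_params)
    if df == 0:
        return InconsistencyTest(
            statistic=0.0,
            df=0,
            p_value=float("nan"),
            tau2=float(tau2 or 0.0),
            degenerate=True,
        )
    if tau2 is None:
        tau2 = estimate_tau2(data, spec, matrix)
    fit = fit_gls(data, spec, matrix, tau2=tau2)
    idx = fit.omega_indices()
    w = fit.estimates[idx]
    Cw = fit.covariance[np.ix_(idx, idx)]
    q = float(w @ scipy.linalg.solve(Cw, w, assume_a="pos"))
    q = max(q, 0.0)
    return InconsistencyTest(
        statistic=q,
        df=df,
        p_value=float(stats.chi2.sf(q, df)),
        tau2=float(tau2),
    )
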