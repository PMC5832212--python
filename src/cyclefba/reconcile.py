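"""Elemental-balance reconciliation of measured conversion rates.

Measured conversions (substrate, O2, CO2, NH4+, biomass, storage
polymers, ...) must satisfy conservation of the chosen elements or
element combinations (C, H, O, N, charge, COD/degree of reduction):
``E @ x = 0`` where ``E`` holds the amount of each conserved quantity
per unit of conversion.  When more conversions are measured than needed
to close the balances, the redundancy permits (1) a weighted
least-squares adjustment of the measurements onto the balance manifold
and (2) a chi-square test on the balance residuals that flags gross
measurement errors.  Unmeasured conversions that are *calculable*
(uniquely determined by the balances) are solved from the reconciled
values with first-order error propagation.

With measured values ``y`` (SE-covariance ``Sigma``, diagonal) and the
reduced balance matrix ``R`` obtained by projecting out the unmeasured
block, the classical gross-error statistic is

    h = eps' (R Sigma R')^{-1} eps,      eps = R y,

chi-square distributed with df = rank(R) under balanced truth; the test
compares h with the critical value at confidence 1 - alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ElementalMatrix",
    "MeasurementSet",
    "ReconciliationResult",
    "classify_conversions",
    "reconcile",
    "ReconciliationError",
    "element_matrix_from_frame",
]

_RANK_TOL = 1e-10


class ReconciliationError(ValueError):
    pass


@dataclass
class ElementalMatrix:
    """Conserved quantities (rows) x conversions (columns)."""

    elements: list[str]
    conversions: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.elements), len(self.conversions)):
            raise ReconciliationError(
                f"elemental matrix shape {self.matrix.shape} does not match "
                f"{len(self.elements)} elements x {len(self.conversions)} conversions"
            )
        zero_rows = [
            self.elements[i]
            for i in range(self.matrix.shape[0])
            if np.all(self.matrix[i] == 0)
        ]
        if zero_rows:
            raise ReconciliationError(
                f"all-zero balance rows (degenerate): {zero_rows}"
            )

    def columns(self, ids: list[str]) -> np.ndarray:
        idx = [self.conversions.index(i) for i in ids]
        return self.matrix[:, idx]


def element_matrix_from_frame(frame: pd.DataFrame) -> ElementalMatrix:
    """Build from a DataFrame with elements as index, conversions as columns."""
    return ElementalMatrix(
        elements=[str(i) for i in frame.index],
        conversions=[str(c) for c in frame.columns],
        matrix=frame.to_numpy(dtype=float),
    )


@dataclass
class MeasurementSet:
    ids: list[str]
    values: dict[str, float]
    standard_errors: dict[str, float]
    measured: dict[str, bool]

    def __post_init__(self) -> None:
        for cid in self.ids:
            if self.measured.get(cid, False):
                se = self.standard_errors.get(cid, 0.0)
                if not se > 0:
                    raise ReconciliationError(
                        f"measured conversion {cid!r} needs a positive SE, got {se}"
                    )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MeasurementSet":
        """Columns: id, value, se, measured (bool/0-1)."""
        ids = [str(i) for i in frame["id"]]
        return cls(
            ids=ids,
            values={str(r["id"]): float(r.get("value", np.nan))
                    for _, r in frame.iterrows()},
            standard_errors={str(r["id"]): float(r.get("se", 0.0))
                             for _, r in frame.iterrows()},
            measured={str(r["id"]): bool(r["measured"])
                      for _, r in frame.iterrows()},
        )

    @property
    def measured_ids(self) -> list[str]:
        return [i for i in self.ids if self.measured[i]]

    @property
    def unmeasured_ids(self) -> list[str]:
        return [i for i in self.ids if not self.measured[i]]


@dataclass
class Classification:
    calculable: list[str]
    non_calculable: list[str]
    redundancy_df: int
    reduced_matrix: np.ndarray  # R over measured conversions
    measured_ids: list[str]


def _left_null_space(A: np.ndarray) -> np.ndarray:
    """Rows spanning {p : p A = 0}."""
    if A.size == 0 or A.shape[1] == 0:
        return np.eye(A.shape[0])
    u, s, _ = np.linalg.svd(A)
    rank = int(np.sum(s > _RANK_TOL * max(A.shape) * (s[0] if s.size else 1.0)))
    return u[:, rank:].T


def _row_space(A: np.ndarray) -> np.ndarray:
    """Independent rows spanning the row space of A."""
    if A.size == 0:
        return A.reshape(0, A.shape[1] if A.ndim == 2 else 0)
    _, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > _RANK_TOL * max(A.shape) * (s[0] if s.size else 1.0)))
    return vt[:rank] * s[:rank, None]


def classify_conversions(
    E: ElementalMatrix, measured_flags: dict[str, bool]
) -> Classification:
    """Partition conversions and compute the redundancy of the system.

    An unmeasured conversion is calculable iff its value is pinned down by
    the balances once the measured ones are known, i.e. its coordinate is
    orthogonal to the null space of the unmeasured column block.  The
    redundancy degrees of freedom equal the rank of the reduced balance
    system acting on measured conversions alone.
    """
    measured_ids = [c for c in E.conversions if measured_flags.get(c, False)]
    unmeasured_ids = [c for c in E.conversions if not measured_flags.get(c, False)]
    E_m = E.columns(measured_ids)
    E_u = E.columns(unmeasured_ids)

    if unmeasured_ids:
        if E_u.size:
            _, s, vt = np.linalg.svd(E_u)
            rank = int(np.sum(s > _RANK_TOL * max(E_u.shape) * (s[0] if s.size else 1.0)))
            null_basis = vt[rank:]  # rows span null(E_u)
        else:
            null_basis = np.eye(len(unmeasured_ids))
        free = np.any(np.abs(null_basis) > 1e-8, axis=0)
        calculable = [c for c, f in zip(unmeasured_ids, free) if not f]
        non_calculable = [c for c, f in zip(unmeasured_ids, free) if f]
    else:
        calculable, non_calculable = [], []

    P = _left_null_space(E_u) if unmeasured_ids else np.eye(E.matrix.shape[0])
    R = _row_space(P @ E_m) if measured_ids else np.zeros((0, 0))
    return Classification(
        calculable=calculable,
        non_calculable=non_calculable,
        redundancy_df=R.shape[0],
        reduced_matrix=R,
        measured_ids=measured_ids,
    )


@dataclass
class ReconciliationResult:
    reconciled: dict[str, float]
    solved_unmeasured: dict[str, float]
    solved_unmeasured_se: dict[str, float]
    adjustments: dict[str, float]
    residual: np.ndarray
    h_statistic: float
    degrees_of_freedom: int
    chi2_critical: float
    alpha: float
    passed: bool
    classification: Classification = field(repr=False, default=None)

    def report(self) -> str:
        lines = [
            "conversion\treconciled\tadjustment",
        ]
        for cid, val in self.reconciled.items():
            lines.append(f"{cid}\t{val:.6g}\t{self.adjustments[cid]:+.6g}")
        for cid, val in self.solved_unmeasured.items():
            se = self.solved_unmeasured_se[cid]
            lines.append(f"{cid}\t{val:.6g}\t(solved, SE {se:.3g})")
        lines.append(
            f"# h = {self.h_statistic:.4g}, df = {self.degrees_of_freedom}, "
            f"chi2 critical ({1 - self.alpha:.0%}) = {self.chi2_critical:.4g}, "
            f"{'PASS' if self.passed else 'GROSS ERROR SUSPECTED'}"
        )
        return "\n".join(lines) + "\n"


def reconcile(
    E: ElementalMatrix,
    measurements: MeasurementSet,
    alpha: float = 0.01,
) -> ReconciliationResult:
    """Weighted least-squares reconciliation with a gross-error chi-square test.

    Minimises the SE-weighted squared adjustments of the measured
    conversions subject to the reduced balances, tests the residual
    statistic ``h`` against the chi-square critical value at significance
    ``alpha``, and solves calculable unmeasured conversions with
    first-order SE propagation.  With zero redundancy the measurements are
    returned unadjusted and the test is skipped (h = 0, df = 0).
    """
    cls = classify_conversions(E, measurements.measured)
    if cls.non_calculable:
        raise ReconciliationError(
            "unmeasured conversions not calculable from the balances: "
            f"{cls.non_calculable}"
        )
    measured_ids = cls.measured_ids
    y = np.array([measurements.values[c] for c in measured_ids])
    sig = np.array([measurements.standard_errors[c] for c in measured_ids])
    Sigma = np.diag(sig ** 2)
    R = cls.reduced_matrix
    df = cls.redundancy_df

    if df > 0:
        eps = R @ y
        W = R @ Sigma @ R.T
        try:
            W_inv_eps = np.linalg.solve(W, eps)
        except np.linalg.LinAlgError as exc:
            raise ReconciliationError(
                "singular weighted system; check SEs and balance rows"
            ) from exc
        h = float(eps @ W_inv_eps)
        adjustment = Sigma @ R.T @ W_inv_eps
        x = y - adjustment
        chi2_crit = float(stats.chi2.ppf(1 - alpha, df))
        passed = h <= chi2_crit
        residual = eps
        # covariance of the reconciled vector (for propagation to unmeasured)
        K = Sigma @ R.T @ np.linalg.solve(W, R @ Sigma)
        Sigma_x = Sigma - K
    else:
        x = y.copy()
        adjustment = np.zeros_like(y)
        h, chi2_crit, passed = 0.0, float("nan"), True
        residual = np.zeros(0)
        Sigma_x = Sigma

    solved: dict[str, float] = {}
    solved_se: dict[str, float] = {}
    unmeasured_ids = [c for c in E.conversions if not measurements.measured.get(c, False)]
    if unmeasured_ids:
        E_u = E.columns(unmeasured_ids)
        E_m = E.columns(measured_ids)
        G = -np.linalg.pinv(E_u) @ E_m
        xu = G @ x
        cov_u = G @ Sigma_x @ G.T
        for k, cid in enumerate(unmeasured_ids):
            solved[cid] = float(xu[k])
            solved_se[cid] = float(np.sqrt(max(cov_u[k, k], 0.0)))

    return ReconciliationResult(
        reconciled=dict(zip(measured_ids, map(float, x))),
        solved_unmeasured=solved,
        solved_unmeasured_se=solved_se,
        adjustments=dict(zip(measured_ids, map(float, adjustment))),
        residual=residual,
        h_statistic=h,
        degrees_of_freedom=df,
        chi2_critical=chi2_crit,
        alpha=alpha,
        passed=passed,
        classification=cls,
    )
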