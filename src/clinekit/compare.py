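"""Cross-locus cline-shape comparison by constrained likelihood-ratio tests.

For an ordered marker pair (i, j), the data at marker i are re-scored with
the six *shape* parameters (c, w, theta_L, theta_R, z_L, z_R) pinned to the
ML estimates from marker j, while keeping marker i's own asymptotic
frequencies (p_L, p_R).  The deviance D = 2 (lnL_free - lnL_constrained) is
referred to a chi-square distribution with 6 degrees of freedom.  Family-wise
error over all m (m - 1) ordered pairs is controlled by Bonferroni
correction; for ten markers this gives a per-test alpha of 0.05 / 90
~= 0.00056 and a critical deviance of 23.85.

D is deliberately asymmetric: D(i, j) scores marker i's data under marker
j's shape, and vice versa.  The constrained model is evaluated, not
re-optimized (all eight parameters pinned); re-optimization of the nuisance
frequencies is available behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import ValidationError
from .fitting import ClineDataset, ClineFitResult, ModelSpec, log_likelihood
from .model import SHAPE_PARAMS, ClineParams

__all__ = [
    "ComparisonResult",
    "constrained_loglik",
    "compare_pair",
    "compare_all",
    "bonferroni_critical_D",
    "SHAPE_DF",
]

#: Degrees of freedom of the shape test: the six shape parameters.
SHAPE_DF = 6


def bonferroni_critical_D(m: int, alpha_family: float = 0.05, *, divisor: int = None):
    """Per-test alpha and critical deviance for m markers' ordered-pair LRTs.

    The divisor defaults to the m (m - 1) ordered pairs; for ten markers
    this is 90 tests, alpha_per_test = 0.05 / 90 ~= 0.00056, and the
    chi-square(6) critical deviance 23.85.

    Returns (alpha_per_test, critical_D).
    """
    if m < 2:
        raise ValidationError("at least two markers are required")
    div = divisor if divisor is not None else m * (m - 1)
    alpha_per_test = alpha_family / div
    return alpha_per_test, float(chi2.isf(alpha_per_test, SHAPE_DF))


def _require_eight_parameter(fit: ClineFitResult, label: str = "fit") -> None:
    if set(fit.spec.free) != set(("c", "w", "theta_L", "theta_R", "z_L", "z_R", "p_L", "p_R")):
        raise ValidationError(f"{label} must be an eight-parameter fit (all parameters free)")


def constrained_loglik(
    data_i: ClineDataset,
    fit_i: ClineFitResult,
    shape_j: ClineParams,
    *,
    reoptimize_p: bool = False,
) -> float:
    """Log-likelihood of marker i's data under marker j's cline shape.

    The six shape parameters come from ``shape_j``; the asymptotic
    frequencies p_L, p_R stay at marker i's own ML estimates, so only the
    shape differs between the free and constrained models.  With
    ``reoptimize_p`` the two frequencies are re-fit under the foreign shape
    instead of pinned (sensitivity analysis only).
    """
    _require_eight_parameter(fit_i, "fit_i")
    composite = ClineParams(
        **shape_j.shape_dict(),
        p_L=fit_i.params_hat.p_L,
        p_R=fit_i.params_hat.p_R,
    )
    if not reoptimize_p:
        return log_likelihood(data_i, composite, tails=fit_i.spec.tails)

    def neg(pv):
        params = composite.replace(p_L=float(np.clip(pv[0], 0, 1)), p_R=float(np.clip(pv[1], 0, 1)))
        return -log_likelihood(data_i, params, tails=fit_i.spec.tails)

    res = minimize(
        neg,
        [composite.p_L, composite.p_R],
        method="L-BFGS-B",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
    )
    return -float(res.fun)


def compare_pair(
    data_i: ClineDataset,
    fit_i: ClineFitResult,
    fit_j: ClineFitResult,
    *,
    reoptimize_p: bool = False,
) -> float:
    """Deviance D for the ordered pair (i, j): marker i's data, marker j's shape."""
    _require_eight_parameter(fit_i, "fit_i")
    _require_eight_parameter(fit_j, "fit_j")
    lnl_constrained = constrained_loglik(data_i, fit_i, fit_j.params_hat, reoptimize_p=reoptimize_p)
    return max(0.0, 2.0 * (fit_i.lnL - lnl_constrained))


@dataclass
class ComparisonResult:
    """Ordered-pair deviance matrix with Bonferroni-corrected calls.

    ``D[i, j]`` scores marker i's data under marker j's shape (row = data
    source, column = shape source).  ``significant[i, j]`` is True when
    D >= critical_D; the diagonal is identically zero and never flagged.
    """

    markers: tuple
    D: np.ndarray
    df: int
    alpha_family: float
    alpha_per_test: float
    critical_D: float
    significant: np.ndarray = field(default=None)

    def __post_init__(self):
        self.markers = tuple(self.markers)
        self.D = np.asarray(self.D, dtype=float)
        m = len(self.markers)
        if self.D.shape != (m, m):
            raise ValidationError("D matrix shape must match the number of markers")
        if np.any(self.D < 0):
            raise ValidationError("all deviances must be non-negative")
        if np.any(np.abs(np.diag(self.D)) > 1e-4):
            raise ValidationError("diagonal deviances must be zero")
        if self.significant is None:
            self.significant = (self.D >= self.critical_D) & ~np.eye(m, dtype=bool)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=list(self.markers), columns=list(self.markers))

    def to_tsv(self, path) -> None:
        self.to_dataframe().rename_axis("data\\shape").to_csv(path, sep="\t", float_format="%.6f")

    def summary(self) -> dict:
        m = len(self.markers)
        return {
            "markers": list(self.markers),
            "df": self.df,
            "n_tests": m * (m - 1),
            "alpha_family": self.alpha_family,
            "alpha_per_test": self.alpha_per_test,
            "critical_D": self.critical_D,
            "n_significant": int(self.significant.sum()),
            "significant_pairs": [
                [self.markers[i], self.markers[j], float(self.D[i, j])]
                for i in range(m)
                for j in range(m)
                if self.significant[i, j]
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def compare_all(
    datasets: Mapping[str, ClineDataset],
    fits: Mapping[str, ClineFitResult],
    alpha_family: float = 0.05,
    *,
    bonferroni_divisor: int = None,
    reoptimize_p: bool = False,
) -> ComparisonResult:
    """All ordered pairwise shape comparisons among the given markers.

    The Bonferroni divisor defaults to the number of ordered pairs
    m (m - 1) — for ten markers, 90 tests and alpha_per_test ~= 0.00056 —
    and can be overridden (e.g. 45 unordered pairs).
    """
    markers = tuple(datasets.keys())
    if len(markers) < 2:
        raise ValidationError("at least two markers are required for comparison")
    if set(fits.keys()) != set(markers):
        raise ValidationError("datasets and fits must cover the same markers")
    for label in markers:
        _require_eight_parameter(fits[label], f"fit for {label!r}")

    m = len(markers)
    alpha_per_test, critical_D = bonferroni_critical_D(
        m, alpha_family, divisor=bonferroni_divisor
    )

    D = np.zeros((m, m))
    for i, mi in enumerate(markers):
        for j, mj in enumerate(markers):
            if i == j:
                continue
            D[i, j] = compare_pair(datasets[mi], fits[mi], fits[mj], reoptimize_p=reoptimize_p)
    return ComparisonResult(
        markers=markers,
        D=D,
        df=SHAPE_DF,
        alpha_family=alpha_family,
        alpha_per_test=alpha_per_test,
        critical_D=critical_D,
    )
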