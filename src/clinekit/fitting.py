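"""Binomial likelihood of cline data, ML fitting, support limits, nested LRT.

Each population contributes an independent binomial observation: k copies of
the focal (R) allele out of n sampled copies, with success probability given
by the cline curve at the population's transect position.  Model frequencies
are clamped to [eps, 1 - eps] (eps = 1e-9) so the log-likelihood stays finite
when asymptotic frequencies sit on the boundary.

The Metropolis sampler of the original ClineFit program is replaced here by
deterministic multi-start bounded optimization (Latin-hypercube starts +
L-BFGS-B) and profile-likelihood support limits (the 2-log-likelihood drop
convention, analogous to a 95% confidence interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import gammaln
from scipy.stats import chi2, qmc

from .errors import FitError, ValidationError
from .model import PARAM_NAMES, ClineParams, cline_frequency

__all__ = [
    "PopulationSample",
    "ClineDataset",
    "ModelSpec",
    "SupportInterval",
    "ClineFitResult",
    "log_likelihood",
    "fit_cline",
    "support_limits",
    "lrt_nested",
    "FREQ_EPS",
]

#: Clamp applied to model frequencies inside the likelihood.
FREQ_EPS = 1e-9


@dataclass(frozen=True)
class PopulationSample:
    """One population's sample at one locus: n allele copies, k of them R."""

    population_id: str
    x: float
    n: int
    k: int

    def __post_init__(self):
        if not np.isfinite(self.x):
            raise ValidationError(f"population {self.population_id!r}: x must be finite")
        if self.n < 0 or int(self.n) != self.n:
            raise ValidationError(f"population {self.population_id!r}: n must be a non-negative integer")
        if not (0 <= self.k <= self.n) or int(self.k) != self.k:
            raise ValidationError(f"population {self.population_id!r}: k must satisfy 0 <= k <= n")


@dataclass
class ClineDataset:
    """Per-population allele counts for one locus along the transect."""

    locus: str
    samples: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = tuple(self.samples)
        for s in self.samples:
            if not isinstance(s, PopulationSample):
                raise ValidationError("samples must be PopulationSample instances")

    @property
    def xs(self) -> np.ndarray:
        return np.array([s.x for s in self.samples], dtype=float)

    @property
    def ns(self) -> np.ndarray:
        return np.array([s.n for s in self.samples], dtype=float)

    @property
    def ks(self) -> np.ndarray:
        return np.array([s.k for s in self.samples], dtype=float)

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other):
        return (
            isinstance(other, ClineDataset)
            and self.locus == other.locus
            and self.samples == other.samples
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which cline parameters are free vs fixed, and which tails are enabled.

    ``free`` is an ordered subset of :data:`~clinekit.model.PARAM_NAMES`;
    every other parameter must appear in ``fixed`` with its pinned value.
    """

    free: tuple
    fixed: Mapping[str, float]
    tails_left: bool = True
    tails_right: bool = True

    def __post_init__(self):
        free = tuple(self.free)
        object.__setattr__(self, "free", free)
        object.__setattr__(self, "fixed", dict(self.fixed))
        names = set(free) | set(self.fixed)
        if names != set(PARAM_NAMES):
            missing = set(PARAM_NAMES) - names
            extra = names - set(PARAM_NAMES)
            raise ValidationError(f"free+fixed must cover all parameters (missing={sorted(missing)}, unknown={sorted(extra)})")
        if set(free) & set(self.fixed):
            raise ValidationError("a parameter cannot be both free and fixed")

    @property
    def tails(self):
        return (self.tails_left, self.tails_right)

    @property
    def n_free(self) -> int:
        return len(self.free)

    def build_params(self, free_values: Sequence[float]) -> ClineParams:
        d = dict(self.fixed)
        d.update(zip(self.free, free_values))
        return ClineParams(**d)

    def is_nested_in(self, full: "ModelSpec") -> bool:
        """True if every configuration of this spec is reachable under ``full``."""
        if not set(self.free) <= set(full.free):
            return False
        for name, value in self.fixed.items():
            if name in full.fixed and full.fixed[name] != value:
                return False
        return True

    # -- common model specifications -------------------------------------

    @classmethod
    def eight_parameter(cls) -> "ModelSpec":
        """All eight parameters free, exponential tails on both sides."""
        return cls(free=PARAM_NAMES, fixed={}, tails_left=True, tails_right=True)

    @classmethod
    def two_parameter(cls, p_L: float = 0.0, p_R: float = 1.0) -> "ModelSpec":
        """Pure sigmoid estimating only c and w; tails off, frequencies pinned."""
        return cls(
            free=("c", "w"),
            fixed={"theta_L": 1.0, "theta_R": 1.0, "z_L": 0.0, "z_R": 0.0, "p_L": p_L, "p_R": p_R},
            tails_left=False,
            tails_right=False,
        )

    @classmethod
    def sigmoid(cls) -> "ModelSpec":
        """Sigmoid with free asymptotic frequencies (c, w, p_L, p_R); no tails."""
        return cls(
            free=("c", "w", "p_L", "p_R"),
            fixed={"theta_L": 1.0, "theta_R": 1.0, "z_L": 0.0, "z_R": 0.0},
            tails_left=False,
            tails_right=False,
        )

    def to_dict(self) -> dict:
        return {
            "free": list(self.free),
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "tails_left": self.tails_left,
            "tails_right": self.tails_right,
        }

    @classmethod
    def from_dict(cls, d) -> "ModelSpec":
        return cls(
            free=tuple(d["free"]),
            fixed=d["fixed"],
            tails_left=bool(d["tails_left"]),
            tails_right=bool(d["tails_right"]),
        )


@dataclass(frozen=True)
class SupportInterval:
    """2-log-likelihood support limits around an ML estimate.

    ``low_bounded`` / ``high_bounded`` are False when the profile never
    dropped by the required amount before hitting the search bound; the
    bound itself is then reported.
    """

    low: float
    high: float
    low_bounded: bool = True
    high_bounded: bool = True


@dataclass
class ClineFitResult:
    """Outcome of a maximum-likelihood cline fit."""

    params_hat: ClineParams
    lnL: float
    spec: ModelSpec
    support: dict = field(default_factory=dict)
    n_starts: int = 0
    converged: bool = False
    seed: Optional[int] = None
    warnings: tuple = ()
    diagnostics: dict = field(default_factory=dict)


def _validate_for_likelihood(data: ClineDataset) -> None:
    if len(data) == 0:
        raise ValidationError("dataset is empty")


def log_likelihood(data: ClineDataset, params: ClineParams, *, tails=(True, True)) -> float:
    """Binomial log-likelihood (nats) of the dataset under a cline.

    Includes the log binomial coefficients, so the value is a true
    log-probability; invariant under permutation of populations, and
    populations with n = 0 contribute exactly 0.
    """
    _validate_for_likelihood(data)
    x, n, k = data.xs, data.ns, data.ks
    p = np.clip(cline_frequency(x, params, tails=tails), FREQ_EPS, 1.0 - FREQ_EPS)
    ln_coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p) + ln_coef))


def _bounds_for(data: ClineDataset, spec: ModelSpec) -> dict:
    """Optimization box per parameter, from the span of populations with n > 0."""
    x = data.xs[data.ns > 0]
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo
    if span <= 0:
        span = 1.0
    return {
        "c": (lo - span, hi + span),
        "w": (0.01, 10.0 * span),
        "theta_L": (1e-3, 1.0),
        "theta_R": (1e-3, 1.0),
        "z_L": (0.0, span),
        "z_R": (0.0, span),
        "p_L": (0.0, 1.0),
        "p_R": (0.0, 1.0),
    }


def _heuristic_start(data: ClineDataset, spec: ModelSpec, bounds: dict) -> np.ndarray:
    """Data-driven start: c at the midpoint-frequency crossing, w = span/4."""
    mask = data.ns > 0
    x, n, k = data.xs[mask], data.ns[mask], data.ks[mask]
    order = np.argsort(x)
    x, freq = x[order], (k / n)[order]
    span = max(x[-1] - x[0], 1.0)
    mid = 0.5 * (freq[0] + freq[-1])
    cross = np.nonzero(np.diff(np.sign(freq - mid)) != 0)[0]
    c0 = float(x[cross[0]]) if cross.size else float(np.median(x))
    defaults = {
        "c": c0,
        "w": span / 4.0,
        "theta_L": 1.0,
        "theta_R": 1.0,
        "z_L": 0.0,
        "z_R": 0.0,
        "p_L": float(freq[0]),
        "p_R": float(freq[-1]),
    }
    start = np.array([defaults[name] for name in spec.free])
    lo = np.array([bounds[name][0] for name in spec.free])
    hi = np.array([bounds[name][1] for name in spec.free])
    return np.clip(start, lo, hi)


def _neg_loglik(data: ClineDataset, spec: ModelSpec):
    tails = spec.tails

    def fun(values: np.ndarray) -> float:
        try:
            params = spec.build_params(values)
        except ValidationError:
            return 1e12
        return -log_likelihood(data, params, tails=tails)

    return fun


def fit_cline(
    data: ClineDataset,
    spec: ModelSpec,
    n_starts: int = 20,
    seed: int = 0,
) -> ClineFitResult:
    """Maximum-likelihood cline fit by multi-start bounded optimization.

    ``n_starts`` local L-BFGS-B searches are launched: one from a
    data-driven heuristic and the rest from a seeded Latin-hypercube sample
    of the parameter box.  The best converged optimum is returned; the
    result is a pure function of (data, spec, n_starts, seed).

    Raises
    ------
    FitError
        If every start fails to converge (diagnostics attached).
    """
    _validate_for_likelihood(data)
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    if int(np.sum(data.ns > 0)) < 3:
        raise ValidationError("at least 3 populations with n > 0 are required for a fit")

    bounds = _bounds_for(data, spec)
    box = [bounds[name] for name in spec.free]
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    fun = _neg_loglik(data, spec)

    starts = [_heuristic_start(data, spec, bounds)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(box), seed=seed)
        unit = sampler.random(n=n_starts - 1)
        starts.extend(lo + unit * (hi - lo))

    best = None
    diagnostics = []
    any_converged = False
    for x0 in starts:
        res = minimize(fun, x0, method="L-BFGS-B", bounds=box)
        diagnostics.append(
            {"x0": [float(v) for v in x0], "fun": float(res.fun), "success": bool(res.success), "message": str(res.message)}
        )
        any_converged = any_converged or bool(res.success)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not any_converged:
        raise FitError("no optimization start converged", diagnostics=diagnostics)

    params_hat = spec.build_params(np.clip(best.x, lo, hi))
    warnings = []
    k, n = data.ks, data.ns
    if np.all(k[n > 0] == 0) or np.all(k[n > 0] == n[n > 0]):
        warnings.append("degenerate_data_boundary_frequencies")
    return ClineFitResult(
        params_hat=params_hat,
        lnL=-float(best.fun),
        spec=spec,
        support={},
        n_starts=n_starts,
        converged=any_converged,
        seed=seed,
        warnings=tuple(warnings),
        diagnostics={"n_starts_converged": sum(d["success"] for d in diagnostics)},
    )


def _profile(data, spec, name, psi, warm_values, box_wo, free_wo):
    """Profile lnL at ``name`` = psi, re-optimizing the remaining free params."""
    reduced = ModelSpec(
        free=free_wo,
        fixed={**spec.fixed, name: psi},
        tails_left=spec.tails_left,
        tails_right=spec.tails_right,
    )
    if not free_wo:
        return log_likelihood(data, reduced.build_params(()), tails=spec.tails), np.array([])
    fun = _neg_loglik(data, reduced)
    res = minimize(fun, warm_values, method="L-BFGS-B", bounds=box_wo)
    return -float(res.fun), res.x


def support_limits(
    data: ClineDataset,
    fit: ClineFitResult,
    param_name: str,
    *,
    drop: float = 2.0,
    tol: float = 1e-3,
) -> SupportInterval:
    """Profile-likelihood support limits: the nearest points on each side of
    the ML estimate where the profile log-likelihood has fallen ``drop``
    (default 2.0) units below the maximum.

    If the profile never drops by ``drop`` before the optimization bound is
    reached, the bound is returned with the corresponding ``*_bounded``
    flag set False (never an error).
    """
    if param_name not in fit.spec.free:
        raise ValidationError(f"parameter {param_name!r} is not free in this fit")
    spec = fit.spec
    bounds = _bounds_for(data, spec)
    free_wo = tuple(n for n in spec.free if n != param_name)
    box_wo = [bounds[n] for n in free_wo]
    mle = float(getattr(fit.params_hat, param_name))
    warm0 = np.array([getattr(fit.params_hat, n) for n in free_wo])
    lnl_max = fit.lnL

    def deficit(psi, warm):
        lnl, xopt = _profile(data, spec, param_name, psi, warm, box_wo, free_wo)
        return lnl_max - lnl - drop, xopt

    results = {}
    for side, bound in (("low", bounds[param_name][0]), ("high", bounds[param_name][1])):
        warm = warm0.copy()
        prev_psi, prev_def = mle, -drop
        hit = None
        # geometric march from the MLE toward the bound
        for frac in (0.02, 0.05, 0.1, 0.2, 0.35, 0.5, 0.7, 0.85, 1.0):
            psi = mle + frac * (bound - mle)
            d, xopt = deficit(psi, warm)
            if len(xopt):
                warm = xopt
            if d > 0:
                hit = (prev_psi, psi)
                break
            prev_psi, prev_def = psi, d
        if hit is None:
            results[side] = (bound, False)
            continue
        a, b = hit

        def g(psi):
            d, _ = deficit(psi, warm)
            return d

        try:
            limit = brentq(g, a, b, xtol=max(tol * abs(b - a), 1e-9), rtol=1e-10)
        except ValueError:  # numerical non-bracketing at the march endpoints
            limit = b
        results[side] = (float(limit), True)

    low, low_b = results["low"]
    high, high_b = results["high"]
    if low > high:
        low, high = high, low
        low_b, high_b = high_b, low_b
    interval = SupportInterval(low=low, high=high, low_bounded=low_b, high_bounded=high_b)
    fit.support[param_name] = interval
    return interval


def lrt_nested(fit_full: ClineFitResult, fit_reduced: ClineFitResult):
    """Likelihood-ratio test of nested cline models.

    Returns (D, df, p) with D = max(0, 2 (lnL_full - lnL_reduced)),
    df = the number of extra free parameters, and p the upper-tail
    chi-square probability.  D is clipped at zero because optimizer noise
    can leave the constrained fit marginally above the free one.
    """
    if not fit_reduced.spec.is_nested_in(fit_full.spec):
        raise ValidationError("reduced model is not nested in the full model")
    df = fit_full.spec.n_free - fit_reduced.spec.n_free
    if df <= 0:
        raise ValidationError("full model must have more free parameters than the reduced model")
    D = max(0.0, 2.0 * (fit_full.lnL - fit_reduced.lnL))
    p = float(chi2.sf(D, df))
    return D, df, p
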