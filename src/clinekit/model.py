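"""Geographic allele-frequency cline curves.

The cline is the classic hybrid-zone model of Szymura & Barton as extended
by Porter: a central sigmoid whose maximum slope is 1/w at the center c,
flanked on either side by exponential tails that take over at junction
points a distance z_L (left) and z_R (right) from the center.  The tail on
each side decays at a rate theta_side times the sigmoid's log-slope at the
junction, so the curve is continuous everywhere and continuously
differentiable exactly when theta_side = 1.  The scaled curve runs from 0
to 1; the observable allele frequency is an affine rescaling between the
asymptotic frequencies p_L and p_R (which may be in either order, giving
ascending or descending clines).

All evaluation functions are vectorized over the transect coordinate ``x``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ValidationError

__all__ = ["ClineParams", "scaled_cline", "cline_frequency", "PARAM_NAMES", "SHAPE_PARAMS"]

#: Canonical parameter order used throughout fitting and serialization.
PARAM_NAMES = ("c", "w", "theta_L", "theta_R", "z_L", "z_R", "p_L", "p_R")

#: The six parameters that define cline *shape* (everything except the
#: asymptotic frequencies).
SHAPE_PARAMS = PARAM_NAMES[:6]


@dataclass(frozen=True)
class ClineParams:
    """The eight parameters of a single locus's spatial cline.

    Parameters
    ----------
    c : float
        Transect position of the maximum allele-frequency gradient
        (cline center), in km.
    w : float
        Cline width in km, defined as 1 / (slope of the scaled curve at c);
        must be > 0.
    theta_L, theta_R : float
        Tail decay-rate ratios in (0, 1]; at 1 the tail blends smoothly
        (C1) into the central sigmoid.
    z_L, z_R : float
        Distances (km, >= 0) from c to the left/right tail junctions.
    p_L, p_R : float
        Asymptotic allele frequencies at the far left / far right of the
        transect, each in [0, 1].  p_L > p_R gives a descending cline;
        p_L == p_R a flat one.
    """

    c: float
    w: float
    theta_L: float = 1.0
    theta_R: float = 1.0
    z_L: float = 0.0
    z_R: float = 0.0
    p_L: float = 0.0
    p_R: float = 1.0

    def __post_init__(self) -> None:
        checks = [
            (np.isfinite(self.c), "c must be finite"),
            (self.w > 0 and np.isfinite(self.w), "w must satisfy w > 0"),
            (0 < self.theta_L <= 1, "theta_L must satisfy 0 < theta_L <= 1"),
            (0 < self.theta_R <= 1, "theta_R must satisfy 0 < theta_R <= 1"),
            (self.z_L >= 0 and np.isfinite(self.z_L), "z_L must satisfy z_L >= 0"),
            (self.z_R >= 0 and np.isfinite(self.z_R), "z_R must satisfy z_R >= 0"),
            (0 <= self.p_L <= 1, "p_L must lie in [0, 1]"),
            (0 <= self.p_R <= 1, "p_R must lie in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)

    def replace(self, **changes) -> "ClineParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def shape_dict(self) -> dict:
        """The six shape parameters only (no asymptotic frequencies)."""
        return {name: float(getattr(self, name)) for name in SHAPE_PARAMS}

    @classmethod
    def from_dict(cls, d) -> "ClineParams":
        return cls(**{k: float(v) for k, v in d.items() if k in PARAM_NAMES})


def _check_x(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("x must be finite")
    return arr


def scaled_cline(x, params: ClineParams, *, tails=(True, True)):
    """Evaluate the scaled (0..1) cline curve at transect position(s) ``x``.

    The central region uses the sigmoid s0(x) = 1 / (1 + exp(-4 (x - c) / w)),
    whose slope at c is exactly 1/w.  Outside the junctions
    x_L = c - z_L and x_R = c + z_R (when the corresponding side's tail is
    enabled), the curve follows an exponential with rate
    theta_side * lambda_side, where lambda_side = (4/w) / (1 + exp(-4 z/w))
    is the sigmoid's log-slope at the junction.  This makes the curve
    continuous for all valid parameters and C1 at a junction iff
    theta_side = 1.

    A side with theta_side = 1 *and* z_side = 0 modifies the sigmoid not at
    all: the exponential there has exactly the sigmoid's value and slope at
    the (central) junction, and the curve is taken to be the pure sigmoid
    on that side, so the two-parameter model is nested in the full model at
    (theta, z) = (1, 0).

    Parameters
    ----------
    x : float or array-like
        Transect position(s) in km; must be finite.
    params : ClineParams
    tails : (bool, bool)
        Enable the left / right exponential tail.  With a side disabled the
        pure sigmoid extends over that side (the two-parameter model of the
        cline-fitting module disables both).

    Returns
    -------
    float or ndarray in (0, 1), matching the shape of ``x``.
    """
    arr = np.atleast_1d(_check_x(x))
    c, w = params.c, params.w
    s = expit(4.0 * (arr - c) / w)

    tail_left, tail_right = tails
    if tail_left and not (params.theta_L == 1.0 and params.z_L == 0.0):
        x_l = c - params.z_L
        left = arr < x_l
        if np.any(left):
            lam_l = (4.0 / w) * expit(4.0 * params.z_L / w)
            s_l = expit(-4.0 * params.z_L / w)
            s[left] = s_l * np.exp(params.theta_L * lam_l * (arr[left] - x_l))
    if tail_right and not (params.theta_R == 1.0 and params.z_R == 0.0):
        x_r = c + params.z_R
        right = arr > x_r
        if np.any(right):
            lam_r = (4.0 / w) * expit(4.0 * params.z_R / w)
            s_r = expit(4.0 * params.z_R / w)
            s[right] = 1.0 - (1.0 - s_r) * np.exp(-params.theta_R * lam_r * (arr[right] - x_r))
    if np.ndim(x) == 0:
        return float(s[0])
    return s.reshape(np.shape(x))


def cline_frequency(x, params: ClineParams, *, tails=(True, True)):
    """Allele frequency at ``x``: p_L + (p_R - p_L) * scaled_cline(x).

    Lies between min(p_L, p_R) and max(p_L, p_R); descending clines are
    simply p_L > p_R acting on the ascending scaled curve.
    """
    s = scaled_cline(x, params, tails=tails)
    return params.p_L + (params.p_R - params.p_L) * s
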