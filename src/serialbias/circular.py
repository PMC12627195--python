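"""Circular angle arithmetic and the derivative-of-Gaussian (DoG) bias curve.

Angles live on a 360-degree color wheel. Signed offsets (relative colors,
response errors) live in the half-open interval (-180, +180], with the
exactly-opposite color mapped to +180 by convention. All angles and bias
amplitudes are expressed in degrees; the DoG width parameter ``w`` has
units of 1/degrees.

The serial-bias curve is the first derivative of a Gaussian,

    y(x) = alpha * w * x * c * exp(-(w*x)**2) + beta,

where ``x`` is the previous trial's color relative to the current target,
``alpha`` is the signed peak amplitude (positive = attraction toward the
previous color, negative = repulsion), ``beta`` is a condition-independent
intercept, and ``c = sqrt(2)/exp(-0.5)`` normalizes the curve so that its
extremum over x equals ``alpha`` exactly (attained at x = 1/(w*sqrt(2))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DOG_NORM",
    "DoGParams",
    "wrap_angle",
    "wrap_signed",
    "signed_difference",
    "circular_mean",
    "dog",
    "dog_eval",
    "dog_peak_location",
]

#: DoG normalization constant, sqrt(2)/exp(-0.5); fixes max_x |y - beta| = |alpha|.
DOG_NORM: float = float(np.sqrt(2.0) / np.exp(-0.5))


def _check_finite(value, name: str):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return arr


def wrap_angle(raw):
    """Wrap any real angle(s) onto the color wheel, i.e. into [0, 360)."""
    arr = _check_finite(raw, "angle")
    out = np.mod(arr, 360.0)
    # np.mod can return 360.0 for tiny negative inputs due to rounding
    out = np.where(out >= 360.0, out - 360.0, out)
    return out if out.ndim else float(out)


def wrap_signed(raw):
    """Wrap any real angular value(s) into the signed interval (-180, +180].

    The boundary maps to +180: wrap_signed(-180) == wrap_signed(180) == 180.
    """
    arr = _check_finite(raw, "offset")
    m = np.mod(arr, 360.0)
    out = np.where(m > 180.0, m - 360.0, m)
    return out if out.ndim else float(out)


def signed_difference(a, b):
    """Signed angular distance ``a - b`` wrapped into (-180, +180].

    Positive values mean ``a`` is clockwise of ``b`` on the wheel.
    """
    a = _check_finite(a, "a")
    b = _check_finite(b, "b")
    return wrap_signed(a - b)


def circular_mean(offsets, *, resultant_tol: float = 1e-9):
    """Angle of the mean resultant vector of signed offsets, in (-180, +180].

    Equals the arithmetic mean whenever all offsets lie within an open
    half-circle around their mean. Raises if the mean resultant length is
    (numerically) zero — e.g. ``[0, 180]`` — because the mean direction is
    then undefined and silently returning an arbitrary angle would corrupt
    condition summaries.
    """
    arr = _check_finite(offsets, "offsets")
    arr = np.atleast_1d(arr).astype(float)
    if arr.size == 0:
        raise ValueError("circular_mean of an empty collection is undefined")
    rad = np.deg2rad(arr)
    z = np.mean(np.exp(1j * rad))
    if np.abs(z) < resultant_tol:
        raise ValueError(
            "circular mean undefined: mean resultant length is zero "
            f"(|R| = {np.abs(z):.3g})"
        )
    return wrap_signed(np.rad2deg(np.angle(z)))


@dataclass(frozen=True)
class DoGParams:
    """Parameters of the DoG bias curve.

    alpha : signed peak amplitude, degrees
    w     : width scale, 1/degrees, strictly positive
    beta  : intercept (overall bias), degrees
    """

    alpha: float
    w: float
    beta: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.alpha) or not np.isfinite(self.w) or not np.isfinite(self.beta):
            raise ValueError("DoG parameters must be finite")
        if self.w <= 0:
            raise ValueError(f"w must be > 0, got {self.w}")

    @property
    def c(self) -> float:
        return DOG_NORM


def dog(x, alpha: float, w: float, beta: float = 0.0):
    """Evaluate the DoG bias curve at relative color(s) ``x`` (degrees)."""
    x = np.asarray(x, dtype=float)
    wx = w * x
    out = alpha * wx * DOG_NORM * np.exp(-(wx**2)) + beta
    return out if out.ndim else float(out)


def dog_eval(x, params: DoGParams):
    """Evaluate the DoG curve for a :class:`DoGParams` bundle."""
    return dog(x, params.alpha, params.w, params.beta)


def dog_peak_location(params_or_w) -> float:
    """Positive x at which |dog(x) - beta| is maximal: 1/(w*sqrt(2)).

    Accepts a :class:`DoGParams` or a bare width. At the returned x,
    ``dog`` equals ``beta + alpha``.
    """
    w = params_or_w.w if isinstance(params_or_w, DoGParams) else float(params_or_w)
    if not np.isfinite(w) or w <= 0:
        raise ValueError(f"w must be finite and > 0, got {w}")
    return 1.0 / (w * np.sqrt(2.0))
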