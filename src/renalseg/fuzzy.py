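"""Fuzzy-set gray-level enhancement.

The enhancement maps a normalized gray level ``m`` in [0, 1] to an output
gray in [0, 255] following three rules:

* R1: a dark pixel is made darker,
* R2: a gray pixel stays gray,
* R3: a bright pixel is made brighter.

"Dark", "gray" and "bright" are fuzzy sets over the normalized gray axis,
parameterized by three breakpoints ``b1 < b2 < b3`` (defaults 0.15, 0.43,
0.71).  A pixel is fuzzified into the three membership degrees, then
defuzzified by the center-of-gravity rule with output singletons
``v_dark``, ``v_gray``, ``v_bright`` (defaults 0, 127, 255).

:func:`enhance_pixel` implements the published piecewise closed form of this
transform *literally*, including its third-branch offset of 0.45 which makes
the map discontinuous at m = 0.43 and m = 0.71.  The discontinuity is a
property of the printed formula and is deliberately preserved; pass
``continuous=True`` for the repaired variant (offset 0.43), which coincides
with the center-of-gravity route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, DomainError

__all__ = [
    "MembershipParams",
    "FuzzyMembership",
    "membership",
    "defuzzify_cog",
    "enhance_pixel",
    "enhance_image",
]


@dataclass(frozen=True)
class MembershipParams:
    """Breakpoints of the dark/gray/bright fuzzy sets and output singletons.

    ``b1``/``b2``/``b3`` are normalized gray levels: below ``b1`` a pixel is
    fully dark, at ``b2`` fully gray, from ``b3`` on fully bright.  The
    interpolation bounds of rule R1 are ``z1 = b1`` and ``z2 = b2``.
    """

    b1: float = 0.15
    b2: float = 0.43
    b3: float = 0.71
    v_dark: float = 0.0
    v_gray: float = 127.0
    v_bright: float = 255.0

    def __post_init__(self):
        if not (0.0 < self.b1 < self.b2 < self.b3 <= 1.0):
            raise ConfigurationError(
                f"breakpoints must satisfy 0 < b1 < b2 < b3 <= 1, "
                f"got {self.b1}, {self.b2}, {self.b3}"
            )
        if not (0.0 <= self.v_dark <= self.v_gray <= self.v_bright <= 255.0):
            raise ConfigurationError(
                "singletons must satisfy 0 <= v_dark <= v_gray <= v_bright <= 255"
            )

    @property
    def z1(self) -> float:
        """Lower interpolation bound of the dark rule."""
        return self.b1

    @property
    def z2(self) -> float:
        """Upper interpolation bound of the dark rule."""
        return self.b2


DEFAULT_PARAMS = MembershipParams()


@dataclass(frozen=True)
class FuzzyMembership:
    """Membership degrees of one pixel in the dark/gray/bright sets."""

    mu_dark: float
    mu_gray: float
    mu_bright: float

    def __post_init__(self):
        for name in ("mu_dark", "mu_gray", "mu_bright"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DomainError(f"{name}={v} outside [0, 1]")


def membership(m: float, params: MembershipParams = DEFAULT_PARAMS) -> FuzzyMembership:
    """Fuzzify a normalized gray level into dark/gray/bright degrees.

    dark is 1 below ``b1`` and falls linearly to 0 at ``b2``; bright is 0
    below ``b2`` and rises linearly to 1 at ``b3`` (staying 1 above); gray is
    the triangle peaking at ``b2`` over [b1, b3].
    """
    m = float(m)
    if not (0.0 <= m <= 1.0):
        raise DomainError(f"normalized gray level m={m} outside [0, 1]")
    b1, b2, b3 = params.b1, params.b2, params.b3

    if m < b1:
        dark = 1.0
    elif m < b2:
        dark = (b2 - m) / (b2 - b1)
    else:
        dark = 0.0

    if m < b2:
        bright = 0.0
    elif m < b3:
        bright = (m - b2) / (b3 - b2)
    else:
        bright = 1.0

    if m < b1 or m >= b3:
        gray = 0.0
    elif m < b2:
        gray = (m - b1) / (b2 - b1)
    else:
        gray = (b3 - m) / (b3 - b2)

    return FuzzyMembership(dark, gray, bright)


def defuzzify_cog(
    mu: FuzzyMembership, params: MembershipParams = DEFAULT_PARAMS
) -> float:
    """Center-of-gravity defuzzification.

    Returns ``(mu_d*v_d + mu_g*v_g + mu_b*v_b) / (mu_d + mu_g + mu_b)``,
    which always lies in ``[v_dark, v_bright]``.
    """
    total = mu.mu_dark + mu.mu_gray + mu.mu_bright
    if total <= 0.0:
        raise DegenerateInputError("all membership degrees are zero")
    return (
        mu.mu_dark * params.v_dark
        + mu.mu_gray * params.v_gray
        + mu.mu_bright * params.v_bright
    ) / total


def enhance_pixel(m, continuous: bool = False):
    """Piecewise gray-level transform of a normalized value in [0, 1].

    The four printed branches are::

        0                                              0    <= m < 0.15
        (m - 0.15)/0.28 * 127                          0.15 <= m < 0.43
        (m - 0.45)/0.28 * 255 + (0.71 - m)/0.28 * 127  0.43 <= m < 0.71
        255                                            otherwise

    The third branch's 0.45 offset (rather than 0.43) makes the transform
    jump at 0.43 (127 -> ~108.8) and at 0.71 (~236.8 -> 255).  With
    ``continuous=True`` the offset is 0.43 and the map is continuous.
    Accepts scalars or arrays; the result is clamped to [0, 255].
    """
    a = np.asarray(m, dtype=np.float64)
    if np.any(a < 0.0) or np.any(a > 1.0) or not np.all(np.isfinite(a)):
        raise DomainError("normalized gray levels must lie in [0, 1]")
    offset = 0.43 if continuous else 0.45
    out = np.select(
        [a < 0.15, a < 0.43, a < 0.71],
        [
            np.zeros_like(a),
            (a - 0.15) / 0.28 * 127.0,
            (a - offset) / 0.28 * 255.0 + (0.71 - a) / 0.28 * 127.0,
        ],
        default=255.0,
    )
    out = np.clip(out, 0.0, 255.0)
    return float(out) if np.isscalar(m) or a.ndim == 0 else out


def _infer_bit_depth(image: np.ndarray) -> int:
    hi = int(image.max())
    lo = int(image.min())
    return 8 if 0 <= lo and hi < 256 else 16


def enhance_image(
    image: np.ndarray,
    bit_depth: int | None = None,
    continuous: bool = False,
    out_dtype=None,
) -> np.ndarray:
    """Apply the fuzzy transform to every pixel of a gray image.

    Pixels are first min-max normalized to [0, 1] per image.  For integer
    images the transform is evaluated once per gray level into a lookup
    table indexed by raw value (``bit_depth`` 8 or 16 caps the table size);
    float images are evaluated directly.  A constant image has no defined
    normalization and is returned unchanged with a warning.

    Output values lie in [0, 255] (float64 unless ``out_dtype`` is an
    integer type, in which case values are rounded half-to-even and clamped).
    """
    a = np.asarray(image)
    if not np.all(np.isfinite(a)):
        raise DomainError("image contains non-finite values")
    lo, hi = a.min(), a.max()
    if lo == hi:
        warnings.warn(
            "constant image: min-max normalization undefined, passing through",
            RuntimeWarning,
            stacklevel=2,
        )
        return a.copy()

    if np.issubdtype(a.dtype, np.integer):
        if bit_depth is None:
            bit_depth = _infer_bit_depth(a)
        if bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        n_levels = int(hi) - int(lo) + 1
        if n_levels > 2**bit_depth:
            raise ConfigurationError(
                f"intensity range {n_levels} exceeds {bit_depth}-bit table"
            )
        levels = np.arange(int(lo), int(hi) + 1, dtype=np.float64)
        lut = enhance_pixel((levels - lo) / (hi - lo), continuous=continuous)
        out = lut[(a - lo).astype(np.int64)]
    else:
        m = (a.astype(np.float64) - lo) / (hi - lo)
        out = enhance_pixel(m, continuous=continuous)

    if out_dtype is not None and np.issubdtype(np.dtype(out_dtype), np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(out_dtype)
    return out
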