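"""First-degree fractional-polynomial (FP1) transformations.

An FP1 transform maps a positive-valued predictor ``x`` to ``((x + a)/s)**p - c``,
with the convention that power ``p = 0`` means the natural logarithm. The shift
``a`` and scale ``s`` are chosen so that ``(x + a)/s`` is strictly positive and of
order of magnitude one (e.g. ``(baseline + 1)/10`` for a 0-10 pain score); the
centering constant ``c`` is typically the development-sample mean of the
transformed values, so that the model intercept refers to an "average" patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The canonical FP1 power set. 0 denotes the natural log.
FP1_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPTransform:
    """A frozen first-degree fractional-polynomial transformation.

    Parameters
    ----------
    shift :
        Constant ``a`` added to ``x`` before scaling (e.g. +1 for scores that
        can be zero).
    scale :
        Positive divisor ``s`` applied after shifting (e.g. 10 for a 0-10
        score), bringing the argument to order of magnitude one.
    power :
        Exponent ``p`` from the canonical FP1 set; ``p = 0`` means ``log``.
    center :
        Constant ``c`` subtracted after the power transform.
    """

    shift: float = 0.0
    scale: float = 1.0
    power: float = 1.0
    center: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def is_linear(self) -> bool:
        return self.power == 1.0

    def __call__(self, x):
        return apply_fp(x, self)

    def describe(self, name: str) -> str:
        """Human-readable algebra, e.g. ``((Baseline+1)/10)^-1 - 1.10``."""
        arg = name
        if self.shift:
            arg = f"({arg}{self.shift:+g})"
        if self.scale != 1.0:
            arg = f"{arg}/{self.scale:g}"
        if self.shift or self.scale != 1.0:
            arg = f"({arg})"
        if self.power == 0.0:
            body = f"ln{arg}" if arg.startswith("(") else f"ln({arg})"
        elif self.power == 1.0:
            body = arg
        else:
            body = f"{arg}^{self.power:g}"
        if self.center:
            return f"{body} - {self.center:g}" if self.center > 0 else f"{body} + {-self.center:g}"
        return body


LINEAR = FPTransform()


def apply_fp(x, t: FPTransform):
    """Apply an FP1 transform: ``((x + a)/s)**p - c``, with log when ``p = 0``.

    Raises
    ------
    ValueError
        If any shifted/scaled value is non-positive (the power/log transform
        would be undefined); the offending value is identified.
    """
    arr = np.asarray(x, dtype=float)
    z = (arr + t.shift) / t.scale
    bad = z <= 0
    if np.any(bad):
        offending = arr[bad].flat[0] if arr.ndim else float(arr)
        raise ValueError(
            f"FP transform argument must be positive: x={offending!r} gives "
            f"(x{t.shift:+g})/{t.scale:g} <= 0"
        )
    out = np.log(z) if t.power == 0.0 else z ** t.power
    out = out - t.center
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def positivity_shift_scale(x: np.ndarray) -> tuple[float, float]:
    """Choose the FP shift/scale convention for observed values ``x``.

    The shift is the smallest round amount making all values strictly
    positive (0 when the minimum is already > 0, +1 for scores that include
    zero, otherwise the next integer above ``-min``); the scale is the power
    of 10 that brings the shifted values to order of magnitude one.
    """
    x = np.asarray(x, dtype=float)
    lo = float(np.min(x))
    if lo > 0:
        shift = 0.0
    else:
        shift = float(np.ceil(-lo))
        if lo + shift <= 0:
            shift += 1.0
    hi = float(np.max(x)) + shift
    scale = 10.0 ** np.floor(np.log10(hi)) if hi > 0 else 1.0
    return shift, float(scale)
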