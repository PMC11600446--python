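"""Four-parameter saturating (logistic) relationships.

Every regulated quantity in the model (hormone release, vascular tone,
tubular reabsorption, hypertrophy targets) is expressed through the same
four-parameter curve: amplitude ``A``, baseline offset ``b``, midpoint
``m`` and slope scale ``s``.  An *increasing* curve runs from ``b`` (at
-inf) to ``b + A`` (at +inf); a *decreasing* curve runs the opposite way
but is bounded by the same pair of values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["SigmoidFunction", "eval_sigmoid"]

_DIRECTIONS = ("increasing", "decreasing")


@dataclass(frozen=True)
class SigmoidFunction:
    """Saturating logistic relationship ``y = b + A * expit(+/-(x - m)/s)``.

    Parameters
    ----------
    A : float
        Amplitude (output units); output range is ``[b, b + A]``.
    b : float
        Baseline offset (output units).
    m : float
        Midpoint (input units); ``f(m) == b + A/2``.
    s : float
        Slope scale (input units); must be strictly positive.
    direction : {"increasing", "decreasing"}
        Orientation of the curve.
    """

    A: float
    b: float
    m: float
    s: float
    direction: str = "increasing"

    def __post_init__(self) -> None:
        if not (self.s > 0):
            raise ValueError(f"sigmoid slope scale must be > 0, got {self.s!r}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )

    @property
    def sign(self) -> float:
        return 1.0 if self.direction == "increasing" else -1.0

    def __call__(self, x):
        z = self.sign * (np.asarray(x, dtype=float) - self.m) / self.s
        return self.b + self.A * expit(z)


def eval_sigmoid(f: SigmoidFunction, x):
    """Evaluate ``f`` at ``x`` (scalar or array).

    Raises
    ------
    ValueError
        If ``f`` carries a non-positive slope scale (guarded again here so
        dict-built instances cannot bypass the dataclass check).
    """
    if not (f.s > 0):
        raise ValueError("sigmoid slope scale must be > 0")
    return f(x)
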