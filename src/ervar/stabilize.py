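"""Variance-stabilizing transforms.

All downstream estimators assume the trial-to-trial variance is the same for
every stimulus.  For count data whose variance grows with the mean this is
achieved by transforming the raw responses first.  If the mean-variance
relation is ``Var = a * mean^b`` (with ``b < 2``), the transform

    f(x) = x^(1 - b/2) / (a * (1 - b/2))

makes the variance approximately constant at 1.  Poisson counts (``a=1, b=1``)
are the common case: a plain square root stabilizes their variance at about
1/4.  Users must supply ``a`` and ``b``; fitting the mean-variance relation
(e.g. by Box-Cox search) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ResponseMatrix

__all__ = ["StabilizerSpec", "apply_stabilizer"]

_KINDS = ("sqrt", "power", "identity")


@dataclass(frozen=True)
class StabilizerSpec:
    """Which transform to apply.

    ``kind='sqrt'`` is the plain square root (the ``a=1, b=1`` power transform
    up to a constant factor of 2); ``kind='power'`` uses the general
    mean-variance exponent; ``kind='identity'`` passes data through untouched.
    """

    kind: str = "sqrt"
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "power":
            if self.a <= 0:
                raise ValueError(f"mean-variance slope a must be > 0, got {self.a}")
            if not self.b < 2:
                raise ValueError(
                    f"mean-variance exponent b must be < 2 so that the transform "
                    f"exponent 1 - b/2 is positive, got b={self.b}"
                )


def apply_stabilizer(raw_responses, spec: StabilizerSpec) -> ResponseMatrix:
    """Apply the transform element-wise to an m x n matrix of raw responses.

    Raw responses must be nonnegative for the sqrt and power kinds (zero is
    allowed: count data legitimately contains zeros).  Negative inputs are
    rejected with the offending cell named.
    """
    arr = np.asarray(raw_responses, dtype=float)
    if spec.kind != "identity" and np.any(arr < 0):
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{spec.kind} stabilizer requires nonnegative responses; "
            f"found {arr[i, j]} at stimulus {i}, repeat {j}"
        )
    if spec.kind == "identity":
        out = arr
    elif spec.kind == "sqrt":
        out = np.sqrt(arr)
    else:
        exponent = 1.0 - spec.b / 2.0
        out = arr**exponent / (spec.a * exponent)
    return ResponseMatrix(out)
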