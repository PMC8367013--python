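"""SNR as a recording-quality metric: noncentral-F power of the tuning test.

Whether a neuron is usefully tuned at all can be decided by the one-way
ANOVA F-test of stimulus modulation: the F statistic comparing
between-stimulus to within-stimulus variance follows, under the generative
assumptions, a noncentral F with (m-1, m(n-1)) degrees of freedom and
noncentrality ``m n SNR``.  Inverting its power function gives the minimal
SNR at which tuning is reliably detectable for a given experiment size —
a concrete, comparable quality bar for recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PowerSpec",
    "f_test_power",
    "min_snr_for_power",
    "snr_threshold_map",
    "snr_time_normalize",
]


@dataclass(frozen=True)
class PowerSpec:
    """F-test design: m stimuli, n repeats, test level alpha, target power beta."""

    m: int
    n: int
    alpha: float = 0.01
    beta: float = 0.99

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2:
            raise ValueError(f"need m >= 2 and n >= 2, got m={self.m}, n={self.n}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")

    @property
    def df1(self) -> int:
        return self.m - 1

    @property
    def df2(self) -> int:
        return self.m * (self.n - 1)

    @property
    def critical_value(self) -> float:
        return float(stats.f.isf(self.alpha, self.df1, self.df2))


def f_test_power(spec: PowerSpec, snr: float) -> float:
    """Probability of detecting tuning at the given SNR.

    Upper-tail probability of the noncentral F (noncentrality m*n*snr) beyond
    the central-F critical value.  At snr=0 this equals alpha exactly.
    """
    if snr < 0:
        raise ValueError("snr must be >= 0")
    if snr == 0:
        return spec.alpha
    nc = spec.m * spec.n * snr
    return float(stats.ncf.sf(spec.critical_value, spec.df1, spec.df2, nc))


def min_snr_for_power(spec: PowerSpec) -> float:
    """Minimal SNR at which the tuning test reaches power beta.

    Power is strictly increasing in SNR and spans (alpha, 1), so the root is
    unique; found by bracketed root-finding (bracket expanded if needed,
    tolerance 1e-8 on the power scale translated to the SNR axis).
    """
    lo, hi = 1e-6, 1e3
    while f_test_power(spec, hi) < spec.beta:
        hi *= 10.0
        if hi > 1e9:
            raise RuntimeError("power never reaches beta; degenerate spec")
    return float(
        optimize.brentq(lambda s: f_test_power(spec, s) - spec.beta, lo, hi, xtol=1e-10)
    )


def snr_threshold_map(m_grid, n_grid, alpha: float = 0.01, beta: float = 0.99) -> pd.DataFrame:
    """Minimal detectable SNR over a grid of experiment sizes.

    Rows are stimulus counts m, columns repeat counts n; suitable for direct
    CSV export with grid headers.
    """
    m_grid = [int(m) for m in np.atleast_1d(m_grid)]
    n_grid = [int(n) for n in np.atleast_1d(n_grid)]
    out = np.empty((len(m_grid), len(n_grid)))
    for i, m in enumerate(m_grid):
        for j, n in enumerate(n_grid):
            out[i, j] = min_snr_for_power(PowerSpec(m=m, n=n, alpha=alpha, beta=beta))
    return pd.DataFrame(out, index=pd.Index(m_grid, name="m"), columns=pd.Index(n_grid, name="n"))


def snr_time_normalize(snr: float, window_s: float, target_s: float = 1.0) -> float:
    """Rescale an SNR to a different spike-counting window length.

    Assumes a constant firing rate within the window (an optimistic
    assumption, stated plainly): for square-root-stabilized Poisson counts
    the signal variance grows linearly with duration while the stabilized
    noise variance stays fixed, so SNR scales as target / window.
    """
    if window_s <= 0 or target_s <= 0:
        raise ValueError("window durations must be positive")
    return snr * (target_s / window_s)
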