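"""Unbiased estimation of the fraction of tuning-curve variance a model explains.

A neuron's responses to ``m`` stimuli repeated ``n`` times each are arranged in
an ``m x n`` matrix ``Y`` (variance-stabilized, so trial-to-trial variance
``sigma^2`` is the same for every stimulus).  The estimand is ``r^2_ER``, the
squared Pearson correlation between the model predictions ``nu_i`` and the
*expected* responses ``mu_i`` — i.e. the correlation the model would achieve
against a noise-free tuning curve.  The naive squared correlation between
``nu`` and the trial-averaged responses is biased toward smaller values by
sampling noise in the averages; both its numerator and denominator are scaled
noncentral chi-squared variables whose expectations exceed the noise-free
targets by terms proportional to ``sigma^2 / n``.  Subtracting unbiased
estimates of those terms yields the corrected estimator ``r2_er`` implemented
here, together with the companion quantities: the pooled trial-to-trial
variance ``s^2``, the noise-corrected dynamic range ``d^2_ER``, the SNR
estimate ``d^2_ER / s^2``, and the linear-model generalization that corrects
``1 - SS_res/SS_tot`` for a least-squares fit with ``d`` parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ResponseMatrix",
    "Predictions",
    "NoiseEstimate",
    "EstimateResult",
    "SnrEstimate",
    "pooled_sample_variance",
    "dynamic_range_hat",
    "snr_hat",
    "naive_r2",
    "r2_er",
    "r2_er_linear",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """Variance-stabilized responses to ``m`` stimuli across ``n`` repeats.

    ``values[i, j]`` is the response to stimulus ``i`` on repeat ``j``.  The
    matrix must be rectangular (equal repeats for every stimulus) and finite;
    ragged designs must be pre-subset by the caller.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(
                f"response matrix must be 2-D (stimuli x repeats), got ndim={arr.ndim}"
            )
        if arr.shape[0] < 2:
            raise ValueError(f"need at least 2 stimuli, got m={arr.shape[0]}")
        if arr.shape[1] < 1:
            raise ValueError("need at least 1 repeat")
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite response at stimulus {bad[0]}, repeat {bad[1]}"
            )
        object.__setattr__(self, "values", arr)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def stimulus_means(self) -> np.ndarray:
        """Trial-averaged response per stimulus, ``Ybar_i``."""
        return self.values.mean(axis=1)


@dataclass(frozen=True)
class Predictions:
    """Model predictions ``nu_i`` for the ``m`` stimuli.

    ``dof`` is the number of free parameters of the linear fit that produced
    the predictions (1 for a raw single-covariate prediction, 2 for an
    intercept-plus-slope fit, and so on).  It only matters for the
    linear-model estimator and for Upsilon.
    """

    nu: np.ndarray
    dof: int = 1

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu, dtype=float).ravel()
        if nu.size < 2:
            raise ValueError("predictions must have length >= 2")
        if not np.all(np.isfinite(nu)):
            raise ValueError("predictions contain non-finite values")
        if np.allclose(nu, nu[0]):
            raise ValueError(
                "predictions are constant: sum((nu - nu_bar)^2) must be > 0"
            )
        if self.dof < 1:
            raise ValueError(f"dof must be a positive integer, got {self.dof}")
        object.__setattr__(self, "nu", nu)

    @property
    def m(self) -> int:
        return self.nu.size


@dataclass(frozen=True)
class NoiseEstimate:
    """Trial-to-trial variance ``sigma^2``, measured or assumed.

    ``source='sample'`` marks the pooled within-stimulus sample variance;
    ``source='assumed'`` marks a user-supplied constant, e.g. 1/4 for
    square-root-transformed Poisson counts in single-repeat designs.
    """

    sigma2_hat: float
    source: str = "sample"

    def __post_init__(self) -> None:
        if self.sigma2_hat < 0:
            raise ValueError(f"sigma2_hat must be >= 0, got {self.sigma2_hat}")
        if self.source not in ("sample", "assumed"):
            raise ValueError(f"source must be 'sample' or 'assumed', got {self.source!r}")


#: Trial-to-trial variance of square-root-transformed Poisson counts.
SQRT_POISSON_SIGMA2 = 0.25


@dataclass(frozen=True)
class EstimateResult:
    """Corrected estimate with its ingredients.

    ``r2_er`` is deliberately *not* truncated to [0, 1]: truncation would
    reintroduce the bias the correction removes.  ``unstable`` is set when the
    corrected denominator is <= 0, which legitimately happens for weak tuning;
    the raw ratio is still reported so callers can see how wild it is.
    """

    r2_er: float
    r2_naive: float
    numerator: float
    denominator: float
    sigma2_used: float
    unstable: bool
    m: int = field(default=0)
    n: int = field(default=0)


@dataclass(frozen=True)
class SnrEstimate:
    """Noise-corrected signal-to-noise ratio of a tuning curve."""

    snr_hat: float
    d2_er_hat: float
    sigma2_hat: float


def _as_response(Y) -> ResponseMatrix:
    return Y if isinstance(Y, ResponseMatrix) else ResponseMatrix(np.asarray(Y))


def _as_predictions(preds, m: int) -> Predictions:
    p = preds if isinstance(preds, Predictions) else Predictions(np.asarray(preds))
    if p.m != m:
        raise ValueError(f"predictions have length {p.m} but responses have m={m}")
    return p


def pooled_sample_variance(Y) -> NoiseEstimate:
    """Pooled trial-to-trial variance: mean over stimuli of per-stimulus
    unbiased sample variances, ``s^2 = (1/m) sum_i s_i^2``.

    Requires at least two repeats; single-repeat designs must supply an
    assumed variance instead (e.g. ``NoiseEstimate(0.25, source='assumed')``
    for square-root-transformed Poisson counts).
    """
    Y = _as_response(Y)
    if Y.n < 2:
        raise ValueError(
            "cannot estimate sample variance with n=1 repeat; supply an assumed "
            "sigma^2 instead (1/4 for square-root-transformed Poisson counts)"
        )
    s2 = float(np.mean(np.var(Y.values, axis=1, ddof=1)))
    return NoiseEstimate(s2, source="sample")


def _resolve_noise(Y: ResponseMatrix, noise) -> NoiseEstimate:
    if noise is None:
        return pooled_sample_variance(Y)
    if isinstance(noise, NoiseEstimate):
        return noise
    return NoiseEstimate(float(noise), source="assumed")


def dynamic_range_hat(Y, noise=None) -> float:
    """Noise-corrected dynamic range of the tuning curve.

    ``d^2_ER = (1/m) [ sum_i (Ybar_i - Ybar)^2 - (m-1) sigma^2 / n ]`` — the
    between-stimulus variance of trial averages, with the inflation due to
    averaging noise subtracted.  May be negative for weakly tuned neurons.
    """
    Y = _as_response(Y)
    noise = _resolve_noise(Y, noise)
    ybar = Y.stimulus_means
    ss = float(np.sum((ybar - ybar.mean()) ** 2))
    return (ss - (Y.m - 1) * noise.sigma2_hat / Y.n) / Y.m


def snr_hat(Y, noise=None) -> SnrEstimate:
    """Corrected SNR estimate, ``d^2_ER / sigma^2``.

    SNR compares tuning-curve variance to trial-to-trial variance; it is not a
    function of m or n, so it can be compared across experiments.  Negative
    values are returned as-is (the correction can overshoot for untuned
    neurons).
    """
    Y = _as_response(Y)
    noise = _resolve_noise(Y, noise)
    if noise.sigma2_hat <= 0:
        raise ValueError("SNR undefined: sigma2_hat must be > 0")
    d2 = dynamic_range_hat(Y, noise)
    return SnrEstimate(d2 / noise.sigma2_hat, d2, noise.sigma2_hat)


def naive_r2(ybar, preds) -> float:
    """Squared Pearson correlation between trial-averaged responses and the
    model predictions.  Biased toward 0 by trial-to-trial noise."""
    ybar = np.asarray(ybar, dtype=float).ravel()
    preds = _as_predictions(preds, ybar.size)
    yc = ybar - ybar.mean()
    ss_y = float(np.sum(yc**2))
    if ss_y <= 0:
        raise ValueError("trial-averaged responses are constant: correlation undefined")
    nc = preds.nu - preds.nu.mean()
    cross = float(np.sum(nc * yc))
    return cross**2 / (float(np.sum(nc**2)) * ss_y)


def r2_er(Y, preds, noise=None) -> EstimateResult:
    """Corrected estimate of the model-to-expected-response squared correlation.

    Both numerator and denominator of the naive squared correlation are scaled
    noncentral chi-squared variables; subtracting unbiased estimates of their
    noise terms gives

        numerator   = cross^2          - (sigma^2/n) * S_nu
        denominator = S_nu * S_ybar    - (sigma^2/n) * S_nu * (m - 1)

    with ``cross = sum (nu-nu_bar)(Ybar-Ybar_bar)``, ``S_nu = sum (nu-nu_bar)^2``
    and ``S_ybar = sum (Ybar_i - Ybar)^2``.  Predictions are internally rescaled
    to ``S_nu = 1``; the ratio is invariant to this.  If ``noise`` is omitted
    the pooled sample variance is used (requires n >= 2).
    """
    Y = _as_response(Y)
    if Y.m < 3:
        raise ValueError(f"corrected estimator requires m >= 3 stimuli, got m={Y.m}")
    preds = _as_predictions(preds, Y.m)
    noise = _resolve_noise(Y, noise)

    ybar = Y.stimulus_means
    yc = ybar - ybar.mean()
    nc = preds.nu - preds.nu.mean()
    s_nu = float(np.sum(nc**2))
    nc = nc / np.sqrt(s_nu)  # scale so sum((nu - nu_bar)^2) = 1

    bias = noise.sigma2_hat / Y.n
    # computed at unit model scale; reported on the original scale (the ratio
    # is invariant, the components are not)
    num = (float(np.sum(nc * yc)) ** 2 - bias) * s_nu
    den = (float(np.sum(yc**2)) - (Y.m - 1) * bias) * s_nu

    unstable = den <= 0
    value = num / den if den != 0 else np.inf * np.sign(num) if num != 0 else np.nan
    return EstimateResult(
        r2_er=float(value),
        r2_naive=naive_r2(ybar, preds),
        numerator=num,
        denominator=den,
        sigma2_used=noise.sigma2_hat,
        unstable=bool(unstable),
        m=Y.m,
        n=Y.n,
    )


def r2_er_linear(ybar, fitted, noise, n: int) -> float:
    """Corrected fraction of variance explained by a fitted linear model.

    For least-squares fitted values ``nu_hat`` from a ``d``-parameter linear
    model, corrects ``1 - SS_res/SS_tot`` for noise in the trial averages:

        1 - [ SS_res - (m-d) sigma^2/n ] / [ SS_tot - (m-1) sigma^2/n ]

    With ``d=2`` (intercept + slope fit of the trial averages on a single
    covariate) this is algebraically identical to :func:`r2_er`.
    """
    ybar = np.asarray(ybar, dtype=float).ravel()
    m = ybar.size
    fitted = _as_predictions(fitted, m)
    if fitted.dof >= m:
        raise ValueError(
            f"no residual degrees of freedom: dof={fitted.dof} must be < m={m}"
        )
    if not isinstance(noise, NoiseEstimate):
        noise = NoiseEstimate(float(noise), source="assumed")
    bias = noise.sigma2_hat / n
    ss_res = float(np.sum((ybar - fitted.nu) ** 2))
    ss_tot = float(np.sum((ybar - ybar.mean()) ** 2))
    return 1.0 - (ss_res - (m - fitted.dof) * bias) / (ss_tot - (m - 1) * bias)


def ols_fit(ybar, nu) -> Predictions:
    """Least-squares intercept+slope fit of trial averages on a covariate.

    Returns the fitted values as :class:`Predictions` with ``dof=2`` — the
    form expected by the linear-model estimator and by the prior noise-ceiling
    estimators that require regression-calibrated predictions.
    """
    ybar = np.asarray(ybar, dtype=float).ravel()
    nu = np.asarray(nu, dtype=float).ravel()
    nc = nu - nu.mean()
    slope = float(np.sum(nc * (ybar - ybar.mean())) / np.sum(nc**2))
    intercept = float(ybar.mean() - slope * nu.mean())
    return Predictions(intercept + slope * nu, dof=2)
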