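"""Model/Results object layer over the estimators.

`ExpectedResponseR2` bundles a response matrix and model predictions the way
statsmodels bundles endog/exog; `fit()` returns a results object carrying the
corrected estimate, its naive counterpart, the SNR of the recording and
instability diagnostics, with `conf_int()` and a readable `summary()`.
"""

from __future__ import annotations

import numpy as np

from . import ci as _ci
from .core import (
    EstimateResult,
    NoiseEstimate,
    Predictions,
    ResponseMatrix,
    SnrEstimate,
    pooled_sample_variance,
    r2_er,
    snr_hat,
)
from .stabilize import StabilizerSpec, apply_stabilizer

__all__ = ["ExpectedResponseR2", "ExpectedResponseR2Results"]


class ExpectedResponseR2:
    """Noise-corrected explained variance of a tuning-curve model.

    Parameters
    ----------
    responses : array-like, shape (m, n)
        Trial-by-stimulus responses (m stimuli, n repeats), already
        variance-stabilized unless a ``stabilizer`` is given.
    predictions : array-like, shape (m,)
        Model predictions for the m stimuli.
    dof : int
        Degrees of freedom of the fit that produced the predictions
        (1 for a raw covariate).
    sigma2 : float, optional
        Assumed trial-to-trial variance.  Defaults to the pooled sample
        variance of the responses (requires n >= 2); pass 0.25 for
        square-root-transformed Poisson counts with single repeats.
    stabilizer : StabilizerSpec, optional
        Variance-stabilizing transform applied to the raw responses first.

    Examples
    --------
    >>> model = ExpectedResponseR2([[1, 3], [2, 4], [5, 7]], [0, 1, 2])
    >>> res = model.fit()
    >>> round(res.r2_er, 2), round(res.r2_naive, 4)
    (1.05, 0.9231)
    """

    def __init__(self, responses, predictions, dof: int = 1, sigma2: float | None = None,
                 stabilizer: StabilizerSpec | None = None):
        if stabilizer is not None:
            self.responses = apply_stabilizer(responses, stabilizer)
        else:
            self.responses = (
                responses if isinstance(responses, ResponseMatrix)
                else ResponseMatrix(np.asarray(responses))
            )
        self.predictions = (
            predictions if isinstance(predictions, Predictions)
            else Predictions(np.asarray(predictions), dof=dof)
        )
        if self.predictions.m != self.responses.m:
            raise ValueError(
                f"{self.predictions.m} predictions for {self.responses.m} stimuli"
            )
        if sigma2 is None:
            self.noise = pooled_sample_variance(self.responses)
        else:
            self.noise = NoiseEstimate(float(sigma2), source="assumed")

    @classmethod
    def from_dataframe(cls, responses_df, predictions, **kwargs) -> "ExpectedResponseR2":
        """Build from a stimuli-by-repeats DataFrame (index ignored)."""
        return cls(np.asarray(responses_df, dtype=float), predictions, **kwargs)

    def fit(self) -> "ExpectedResponseR2Results":
        estimate = r2_er(self.responses, self.predictions, self.noise)
        snr = (
            snr_hat(self.responses, self.noise)
            if self.noise.sigma2_hat > 0
            else SnrEstimate(np.inf, np.nan, 0.0)
        )
        return ExpectedResponseR2Results(self, estimate, snr)


class ExpectedResponseR2Results:
    """Point estimates, diagnostics and interval methods for one recording."""

    def __init__(self, model: ExpectedResponseR2, estimate: EstimateResult, snr: SnrEstimate):
        self.model = model
        self.estimate = estimate
        self.snr = snr

    @property
    def r2_er(self) -> float:
        return self.estimate.r2_er

    @property
    def r2_naive(self) -> float:
        return self.estimate.r2_naive

    @property
    def snr_hat(self) -> float:
        return self.snr.snr_hat

    @property
    def unstable(self) -> bool:
        return self.estimate.unstable

    def conf_int(self, alpha: float = 0.8, method: str = "ecci", seed: int = 0,
                 **kwargs) -> _ci.ConfidenceInterval:
        """Interval for r^2_ER at coverage level alpha.

        ``method`` is one of 'ecci' (default; posterior-based inversion of
        the estimator's sampling distribution), 'npboot', 'pboot' or 'bca'.
        Extra keyword arguments reach the underlying routine (e.g.
        ``n_samples``, ``chain_length`` for ecci; ``B`` for the bootstraps).
        """
        if method == "ecci":
            return _ci.ecci(self.r2_er, self.model.responses, alpha=alpha, seed=seed, **kwargs)
        return _ci.bootstrap_ci(
            self.model.responses, self.model.predictions, method=method,
            alpha=alpha, seed=seed, **kwargs,
        )

    def summary(self, conf_int: _ci.ConfidenceInterval | None = None) -> str:
        est = self.estimate
        lines = [
            "Expected-response explained variance",
            "=" * 52,
            f"{'stimuli (m)':<32}{est.m:>20d}",
            f"{'repeats (n)':<32}{est.n:>20d}",
            f"{'sigma^2 ({})'.format(self.model.noise.source):<32}{est.sigma2_used:>20.6g}",
            "-" * 52,
            f"{'r^2_ER (corrected)':<32}{est.r2_er:>20.4f}",
            f"{'r^2 (naive)':<32}{est.r2_naive:>20.4f}",
            f"{'SNR_hat':<32}{self.snr.snr_hat:>20.4f}",
            f"{'dynamic range d^2_ER':<32}{self.snr.d2_er_hat:>20.6g}",
            f"{'unstable denominator':<32}{str(est.unstable):>20}",
        ]
        if conf_int is not None:
            tag = "(empty)" if conf_int.empty else f"[{conf_int.low:.3f}, {conf_int.high:.3f}]"
            lines.append(
                f"{f'{conf_int.alpha:.0%} CI ({conf_int.method})':<32}{tag:>20}"
            )
        lines.append("=" * 52)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ExpectedResponseR2Results r2_er={self.r2_er:.4f} "
            f"r2_naive={self.r2_naive:.4f} snr={self.snr_hat:.3g}>"
        )
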