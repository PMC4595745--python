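"""ERCC spike-in calibration: detection sensitivity and absolute copies.

Two calibrations are fitted from the spike-in ladder:

* **Detection curve** — each spike in each sample is scored detected
  (count >= threshold) or not, outcomes are pooled, and a logistic model of
  detection probability against log10(copies x kb) is fitted by maximum
  likelihood.  The abundance at 50% detection, x50 = 10^(-intercept/slope),
  summarizes assay sensitivity; a profile-likelihood interval is reported,
  and perfectly separated data yield a censored bound instead of an error.

* **Copies per TPM** — per sample, ordinary least squares of log10(copies)
  on log10(TPM) over detected spikes converts the relative TPM scale to
  absolute molecule counts; dividing the copies at 1 TPM by the number of
  sorted cells in the tube gives copies per cell at 1 TPM, aggregated as
  mean +/- sd across samples.  Because spike TPM is computed over the full
  genes-plus-spikes denominator, the spike-to-endogenous read ratio is
  already encoded in the fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import CountMatrix, SampleDesign, SpikeInReference, ValidationError
from .quantify import ExpressionMatrix

__all__ = [
    "DetectionCurve",
    "CopiesPerTpm",
    "DetectionCurveModel",
    "CopiesPerTpmModel",
    "fit_detection_curve",
    "fit_copies_per_tpm",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectionCurve:
    """Logistic detection-vs-abundance fit on the log10(copies x kb) axis."""

    intercept: float
    slope: float
    x50: float  # copies x kb at 50% detection probability
    ci: tuple  # profile-likelihood interval for x50 (or censoring bounds)
    censored: bool
    n_levels: int
    n_observations: int

    def detection_probability(self, copies_kb: np.ndarray) -> np.ndarray:
        z = self.intercept + self.slope * np.log10(copies_kb)
        return 1.0 / (1.0 + np.exp(-z))

    def summary(self) -> str:
        status = "censored" if self.censored else "ML fit"
        return (
            f"Detection curve ({status}): x50 = {self.x50:.3g} copies x kb "
            f"[{self.ci[0]:.3g}, {self.ci[1]:.3g}], slope = {self.slope:.3g}, "
            f"{self.n_observations} spike observations on {self.n_levels} levels"
        )


@dataclass
class CopiesPerTpm:
    """Per-sample log-log regression of copies on TPM, aggregated."""

    per_sample: pd.DataFrame  # sample_id, intercept, slope, copies_per_cell_at_1tpm
    copies_per_cell_mean: float
    copies_per_cell_sd: float
    excluded_samples: list

    def summary(self) -> str:
        return (
            f"1 TPM corresponds to {self.copies_per_cell_mean:.2f} +/- "
            f"{self.copies_per_cell_sd:.2f} copies per cell "
            f"({len(self.per_sample)} samples, {len(self.excluded_samples)} excluded)"
        )


def _logistic_nll(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    z = params[0] + params[1] * x
    # log(1+e^z) stable
    return float(np.sum(np.logaddexp(0.0, z)) - np.sum(y * z))


class DetectionCurveModel:
    """Maximum-likelihood logistic detection model for a spike-in ladder."""

    def __init__(
        self,
        counts: CountMatrix,
        ref: SpikeInReference,
        detect_threshold: int = 1,
    ) -> None:
        spikes = counts.spikes_only() if (~counts.is_spike).any() else counts
        common = [s for s in ref.spike_ids if s in spikes.counts.index]
        if not common:
            raise ValidationError("no spike-in rows shared between counts and reference")
        self.counts = spikes.counts.loc[common]
        self.copies_kb = ref.copies_kb().loc[common]
        self.detect_threshold = int(detect_threshold)
        positive = self.copies_kb > 0
        self.counts = self.counts.loc[positive]
        self.copies_kb = self.copies_kb.loc[positive]
        if np.unique(np.round(np.log10(self.copies_kb), 9)).size < 6:
            raise ValidationError("need >= 6 distinct copies x kb levels")

    def fit(self, profile_ci: bool = True) -> DetectionCurve:
        detected = (self.counts.to_numpy() >= self.detect_threshold).astype(float)
        x = np.repeat(np.log10(self.copies_kb.to_numpy()), self.counts.shape[1])
        y = detected.ravel()
        n_levels = np.unique(np.round(x, 9)).size

        det_x = x[y == 1]
        und_x = x[y == 0]
        if det_x.size == 0 or und_x.size == 0 or det_x.min() > und_x.max():
            # perfect separation: x50 only bounded by the separating gap
            if det_x.size == 0:
                lo, hi = float(10 ** x.max()), float("inf")
            elif und_x.size == 0:
                lo, hi = 0.0, float(10 ** x.min())
            else:
                lo, hi = float(10 ** und_x.max()), float(10 ** det_x.min())
            x50 = float(np.sqrt(max(lo, np.finfo(float).tiny) * hi)) if np.isfinite(hi) else lo
            return DetectionCurve(
                intercept=float("nan"),
                slope=float("nan"),
                x50=x50,
                ci=(lo, hi),
                censored=True,
                n_levels=n_levels,
                n_observations=y.size,
            )

        res = optimize.minimize(
            _logistic_nll, x0=np.array([0.0, 1.0]), args=(x, y), method="BFGS"
        )
        b0, b1 = res.x
        if b1 <= 0:
            warnings.warn("non-positive detection slope; curve flagged censored")
            return DetectionCurve(b0, b1, float("nan"), (0.0, float("inf")), True, n_levels, y.size)
        x50 = float(10.0 ** (-b0 / b1))
        ci = self._profile_ci(x, y, res.fun, x50) if profile_ci else (float("nan"), float("nan"))
        return DetectionCurve(float(b0), float(b1), x50, ci, False, n_levels, y.size)

    @staticmethod
    def _profile_ci(x, y, nll_hat, x50_hat, level=0.95):
        """Profile likelihood interval for x50 = 10^(-b0/b1)."""
        crit = stats.chi2.ppf(level, df=1) / 2.0

        def profile_excess(theta: float) -> float:
            # logit p = b * (x - theta); maximize over slope b
            def nll_b(b):
                return _logistic_nll(np.array([-b * theta, b]), x, y)

            res = optimize.minimize_scalar(nll_b, bounds=(1e-8, 100.0), method="bounded")
            return res.fun - nll_hat - crit

        theta_hat = np.log10(x50_hat)
        span = max(x.max() - x.min(), 1.0)
        lo_bracket = theta_hat - span
        hi_bracket = theta_hat + span
        try:
            lo = optimize.brentq(profile_excess, lo_bracket, theta_hat) if profile_excess(lo_bracket) > 0 else lo_bracket
        except ValueError:
            lo = lo_bracket
        try:
            hi = optimize.brentq(profile_excess, theta_hat, hi_bracket) if profile_excess(hi_bracket) > 0 else hi_bracket
        except ValueError:
            hi = hi_bracket
        return (float(10.0 ** lo), float(10.0 ** hi))


def fit_detection_curve(
    counts: CountMatrix,
    ref: SpikeInReference,
    detect_threshold: int = 1,
) -> DetectionCurve:
    """Convenience wrapper: build and fit a :class:`DetectionCurveModel`."""
    return DetectionCurveModel(counts, ref, detect_threshold).fit()


class CopiesPerTpmModel:
    """Per-sample log-log calibration of absolute copies against TPM."""

    def __init__(
        self,
        tpm: ExpressionMatrix,
        ref: SpikeInReference,
        design: SampleDesign,
        min_spikes: int = 6,
        min_decades: float = 2.0,
    ) -> None:
        if tpm.unit != "TPM":
            raise ValidationError("CopiesPerTpmModel expects a TPM matrix")
        self.ref = ref
        common = [s for s in ref.spike_ids if s in tpm.values.index]
        if not common:
            raise ValidationError("no spike rows in the TPM matrix")
        self.tpm = tpm.values.loc[common]
        self.copies = pd.Series(
            ref.table.set_index("spike_id")["copies_per_tube"].loc[common]
        )
        self.design = design
        self.min_spikes = min_spikes
        self.min_decades = min_decades

    def fit(self) -> CopiesPerTpm:
        n_cells = self.design.table.set_index("sample_id")["n_cells"]
        rows = []
        excluded = []
        for sample in self.tpm.columns:
            t = self.tpm[sample]
            ok = (t > 0) & (self.copies > 0)
            t, c = t[ok], self.copies[ok]
            if len(t) < self.min_spikes:
                excluded.append(sample)
                logger.warning("sample %s: only %d detected spikes, excluded", sample, len(t))
                continue
            span = np.log10(c.max() / c.min())
            if span < self.min_decades:
                excluded.append(sample)
                logger.warning(
                    "sample %s: detected spikes span %.2f decades (< %g), excluded",
                    sample, span, self.min_decades,
                )
                continue
            slope, intercept = np.polyfit(np.log10(t), np.log10(c), 1)
            copies_at_1tpm = 10.0 ** intercept
            rows.append(
                {
                    "sample_id": sample,
                    "intercept": intercept,
                    "slope": slope,
                    "copies_at_1tpm": copies_at_1tpm,
                    "copies_per_cell_at_1tpm": copies_at_1tpm / n_cells[sample],
                }
            )
        if not rows:
            raise ValidationError("no sample had enough detected spikes for calibration")
        per_sample = pd.DataFrame(rows)
        vals = per_sample["copies_per_cell_at_1tpm"]
        return CopiesPerTpm(
            per_sample=per_sample,
            copies_per_cell_mean=float(vals.mean()),
            copies_per_cell_sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            excluded_samples=excluded,
        )


def fit_copies_per_tpm(
    tpm: ExpressionMatrix,
    ref: SpikeInReference,
    design: SampleDesign,
    min_spikes: int = 6,
    min_decades: float = 2.0,
) -> CopiesPerTpm:
    """Convenience wrapper: build and fit a :class:`CopiesPerTpmModel`."""
    return CopiesPerTpmModel(tpm, ref, design, min_spikes, min_decades).fit()
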