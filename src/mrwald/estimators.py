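"""Statistical core: Wald ratios, fixed-effects IVW pooling, heterogeneity,
SD rescaling, and odds-ratio conversion.

For an instrument j with exposure association ``beta_X`` (SE ``se_X``) and
outcome association ``beta_Y`` (SE ``se_Y``), the Wald ratio estimate of the
causal effect of the exposure on the outcome is

    theta_j = beta_Y / beta_X

with delta-method standard error, to first order ``se_Y / |beta_X|`` or to
second order ``sqrt(se_Y^2/beta_X^2 + beta_Y^2 se_X^2 / beta_X^4)``.

Per-variant ratios are pooled by fixed-effects inverse-variance weighting
(weights ``w_j = 1/se_j^2``); the pooled estimate is the weighted mean with
standard error ``1/sqrt(sum w_j)``, and heterogeneity is quantified by
Cochran's Q = ``sum w_j (theta_j - theta_hat)^2``, chi-square with J-1
degrees of freedom under homogeneity.

Confidence intervals use the 1.96 normal quantile and p-values are two-sided
from the standard normal, the summary-level MR convention.  Nothing in this
module rounds: presentation-layer rounding lives in :mod:`mrwald.pipeline`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import InputError, StateError, UndefinedRatioError
from .summary_stats import HarmonizedInstrument

#: Normal quantile for 95% confidence intervals (field convention, not t).
Z_95 = 1.96

Scale = Literal["linear", "log_odds"]
SEOrder = Literal["first", "second"]


def _normal_p(z: float) -> float:
    """Two-sided p-value from a standard-normal z statistic."""
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class WaldEstimate:
    """Per-variant causal ratio estimate with delta-method uncertainty."""

    rsid: str
    ratio: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    per_sd: bool = False
    sd_used: float | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise InputError(f"{self.rsid}: Wald se must be > 0")
        if not (self.ci_low < self.ratio < self.ci_high):
            raise InputError(f"{self.rsid}: CI must bracket the estimate")


@dataclass
class MRResult:
    """Pooled causal estimate with heterogeneity and scale metadata.

    ``scale`` records whether the estimate is on a linear (continuous
    outcome) or log-odds (binary outcome) scale; ``per_sd`` whether it has
    been rescaled to a one-SD increment of the exposure, with ``sd_used``
    the multiplier applied.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    q_stat: float
    q_df: int
    q_pvalue: float | None
    scale: Scale = "linear"
    per_sd: bool = False
    sd_used: float | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise InputError("pooled se must be > 0")
        if self.q_df != self.n_snps - 1:
            raise InputError("q_df must equal n_snps - 1")
        if self.q_stat < -1e-12:
            raise InputError("Cochran's Q cannot be negative")


@dataclass
class OddsRatioResult:
    """Exponentiated log-odds MR result."""

    oratio: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass
class ExposureScale:
    """Mean and SD of the exposure on its natural and log scales.

    For circulating α-tocopherol the reference values (from the ULSAM
    cohort) are mean 13.1, SD 3.5 mg/L on the natural scale and mean 2.5,
    SD 0.25 on the log scale; the log-scale SD is the multiplier that turns
    a per-log-unit estimate into a per-SD estimate.
    """

    sd_linear: float
    sd_log: float
    mean_linear: float
    mean_log: float

    def __post_init__(self) -> None:
        for name in ("sd_linear", "sd_log", "mean_linear", "mean_log"):
            if not (getattr(self, name) > 0):
                raise InputError(f"ExposureScale.{name} must be strictly positive")


#: Serum α-tocopherol scale from the ULSAM reference cohort (mg/L).
ALPHA_TOCOPHEROL_SCALE = ExposureScale(
    sd_linear=3.5, sd_log=0.25, mean_linear=13.1, mean_log=2.5
)


def wald_ratio(
    instrument: HarmonizedInstrument, se_order: SEOrder = "first"
) -> WaldEstimate:
    """Wald ratio estimate for one harmonized instrument.

    ``se_order="first"`` uses ``se_Y/|beta_X|`` (the convention under which
    IVW pooling equals weighted regression through the origin);
    ``"second"`` adds the exposure-side sampling noise term.
    """
    bx, by = instrument.beta_exposure, instrument.beta_outcome
    sx, sy = instrument.se_exposure, instrument.se_outcome
    if bx == 0:
        raise UndefinedRatioError(instrument.rsid)
    ratio = by / bx
    if se_order == "first":
        se = sy / abs(bx)
    elif se_order == "second":
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise InputError(f"unknown se_order {se_order!r}")
    return WaldEstimate(
        rsid=instrument.rsid,
        ratio=ratio,
        se=se,
        ci_low=ratio - Z_95 * se,
        ci_high=ratio + Z_95 * se,
        pvalue=_normal_p(ratio / se),
    )


def ivw_pool(
    estimates: Sequence[WaldEstimate],
    model: Literal["fixed", "multiplicative"] = "fixed",
    scale: Scale = "linear",
) -> MRResult:
    """Pool per-variant Wald ratios by inverse-variance weighting.

    ``model="fixed"`` is the standard fixed-effects pool.
    ``model="multiplicative"`` additionally inflates the pooled SE by
    ``sqrt(Q/df)`` when Q/df > 1 (a multiplicative random-effects
    sensitivity analysis; the point estimate is unchanged).

    With a single estimate the pooled result equals it exactly and the
    heterogeneity p-value is undefined (``None``).
    """
    if not estimates:
        raise InputError("cannot pool an empty list of estimates")
    if model not in ("fixed", "multiplicative"):
        raise InputError(f"unknown model {model!r}")

    ratios = np.array([e.ratio for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    if not np.all(ses > 0):
        raise InputError("all standard errors must be > 0")

    weights = 1.0 / ses**2
    estimate = float(np.sum(weights * ratios) / np.sum(weights))
    se = float(1.0 / math.sqrt(np.sum(weights)))
    q_stat = float(np.sum(weights * (ratios - estimate) ** 2))
    q_df = len(estimates) - 1
    q_pvalue = float(stats.chi2.sf(q_stat, q_df)) if q_df > 0 else None

    if model == "multiplicative" and q_df > 0 and q_stat / q_df > 1.0:
        se *= math.sqrt(q_stat / q_df)

    return MRResult(
        estimate=estimate,
        se=se,
        ci_low=estimate - Z_95 * se,
        ci_high=estimate + Z_95 * se,
        pvalue=_normal_p(estimate / se),
        n_snps=len(estimates),
        q_stat=q_stat,
        q_df=q_df,
        q_pvalue=q_pvalue,
        scale=scale,
    )


def rescale_per_sd(result, sd: float):
    """Rescale an estimate to a one-SD increment of the exposure.

    Multiplies the estimate, SE and CI bounds by ``sd``; the z-score, hence
    the p-value, is unchanged.  Accepts an :class:`MRResult` or a
    :class:`WaldEstimate` and returns a new object of the same type with
    ``per_sd`` set and ``sd_used`` recorded.  Applying the rescaling twice
    is a :class:`StateError`.
    """
    if not (sd > 0):
        raise InputError(f"sd must be strictly positive, got {sd}")
    if getattr(result, "per_sd", False):
        raise StateError("per-SD rescaling already applied")
    if isinstance(result, MRResult):
        return dataclasses.replace(
            result,
            estimate=result.estimate * sd,
            se=result.se * sd,
            ci_low=result.ci_low * sd,
            ci_high=result.ci_high * sd,
            per_sd=True,
            sd_used=sd,
        )
    if isinstance(result, WaldEstimate):
        return dataclasses.replace(
            result,
            ratio=result.ratio * sd,
            se=result.se * sd,
            ci_low=result.ci_low * sd,
            ci_high=result.ci_high * sd,
            per_sd=True,
            sd_used=sd,
        )
    raise InputError(f"cannot rescale object of type {type(result).__name__}")


def to_odds_ratio(result: MRResult) -> OddsRatioResult:
    """Exponentiate a log-odds MR result to an odds-ratio summary.

    Refuses a linear-scale estimate: exponentiating a continuous-outcome
    effect has no odds-ratio interpretation.
    """
    if result.scale != "log_odds":
        raise StateError(
            "to_odds_ratio requires a log-odds scale estimate, "
            f"got scale={result.scale!r}"
        )
    return OddsRatioResult(
        oratio=math.exp(result.estimate),
        ci_low=math.exp(result.ci_low),
        ci_high=math.exp(result.ci_high),
        pvalue=result.pvalue,
    )


def relative_effect(result: MRResult, reference_mean: float) -> float:
    """Estimate as a percentage of a reference mean of the outcome.

    E.g. a pooled estimate of 0.07 g/cm² against a population mean heel
    eBMD of 0.51 g/cm² is a 13.7% relative increase.
    """
    if result.scale != "linear":
        raise StateError("relative_effect requires a linear-scale estimate")
    if not (reference_mean > 0):
        raise InputError(f"reference mean must be > 0, got {reference_mean}")
    return 100.0 * result.estimate / reference_mean
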