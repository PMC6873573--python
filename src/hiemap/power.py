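"""Sample-size and power calculators for the study design.

Two analytic designs are covered, each with a Monte-Carlo verification
oracle:

* two-group comparison of mean Dice accuracy — normal approximation
  n = 2 (z_{1-a/2} + z_power)^2 sd^2 / (m1 - m0)^2 per group, rounded up;
* detection of a Pearson correlation — Fisher-z approximation
  n = ((z_{1-a/2} + z_power) / atanh(rho))^2 + 3, rounded to nearest.

The one-in-ten rule caps the number of predictive features at
floor(n/10) to limit overfitting in multivariate models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from hiemap.core_io import ValidationError

__all__ = [
    "TwoGroupMeanDesign",
    "CorrelationDesign",
    "n_per_group_two_means",
    "n_correlation",
    "max_features_one_in_ten",
    "empirical_power_check",
]


@dataclass(frozen=True)
class TwoGroupMeanDesign:
    mean1: float
    mean0: float
    sd: float
    alpha: float = 0.05
    power: float = 0.8
    sided: str = "two"

    def __post_init__(self) -> None:
        if self.mean1 == self.mean0:
            raise ValidationError("zero effect: mean1 must differ from mean0")
        if self.sd <= 0:
            raise ValidationError("sd must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValidationError("alpha and power must lie in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValidationError("sided must be 'one' or 'two'")


@dataclass(frozen=True)
class CorrelationDesign:
    rho: float
    alpha: float = 0.05
    power: float = 0.95

    def __post_init__(self) -> None:
        if not (0.01 <= self.rho < 1):
            raise ValidationError("rho must lie in [0.01, 1); smaller values need unbounded n")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValidationError("alpha and power must lie in (0, 1)")


def _z_alpha(alpha: float, sided: str) -> float:
    return stats.norm.ppf(1 - alpha / 2 if sided == "two" else 1 - alpha)


def n_per_group_two_means(design: TwoGroupMeanDesign,
                          return_unrounded: bool = False):
    """Per-group sample size for a two-sample comparison of means.

    Normal approximation, rounded up to the next whole patient; the
    unrounded value is available alongside.
    """
    za = _z_alpha(design.alpha, design.sided)
    zb = stats.norm.ppf(design.power)
    effect = design.mean1 - design.mean0
    n_raw = 2.0 * (za + zb) ** 2 * design.sd ** 2 / effect ** 2
    n = int(math.ceil(n_raw - 1e-12))
    return (n, n_raw) if return_unrounded else n


def n_correlation(design: CorrelationDesign, return_unrounded: bool = False):
    """Sample size to detect a Pearson correlation of magnitude rho.

    Fisher-z approximation, rounded to the nearest integer; the
    unrounded value is available alongside.
    """
    za = _z_alpha(design.alpha, "two")
    zb = stats.norm.ppf(design.power)
    n_raw = ((za + zb) / math.atanh(design.rho)) ** 2 + 3.0
    n = int(round(n_raw))
    return (n, n_raw) if return_unrounded else n


def max_features_one_in_ten(n_patients: int) -> int:
    """One-in-ten rule: at most floor(n/10) predictors; 0 below n=10."""
    if n_patients < 10:
        return 0
    return n_patients // 10


def empirical_power_check(design, n: int, n_sims: int = 10_000,
                          seed: int = 0, null: bool = False) -> float:
    """Monte-Carlo rejection rate of the design's test at sample size n.

    Two-group design: n per group, pooled two-sample t-test at the
    design's alpha/sidedness.  Correlation design: Pearson test on
    bivariate-normal samples.  With ``null=True`` the data are simulated
    with zero effect, so the rejection rate estimates the type-I error
    (it should match alpha).  Used to verify the analytic formulas.
    """
    if n < 3:
        raise ValidationError("need n >= 3")
    rng = np.random.default_rng(seed)
    if isinstance(design, TwoGroupMeanDesign):
        mean1 = design.mean0 if null else design.mean1
        a = rng.normal(mean1, design.sd, size=(n_sims, n))
        b = rng.normal(design.mean0, design.sd, size=(n_sims, n))
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        sp2 = (va + vb) / 2.0
        t = (ma - mb) / np.sqrt(sp2 * 2.0 / n)
        df = 2 * n - 2
        if design.sided == "two":
            reject = np.abs(t) > stats.t.ppf(1 - design.alpha / 2, df)
        else:
            reject = t > stats.t.ppf(1 - design.alpha, df)
        return float(reject.mean())
    if isinstance(design, CorrelationDesign):
        rho = 0.0 if null else design.rho
        x = rng.standard_normal(size=(n_sims, n))
        e = rng.standard_normal(size=(n_sims, n))
        ycorr = rho * x + math.sqrt(1 - rho ** 2) * e
        xm = x - x.mean(axis=1, keepdims=True)
        ym = ycorr - ycorr.mean(axis=1, keepdims=True)
        r = (xm * ym).sum(axis=1) / np.sqrt((xm ** 2).sum(axis=1) * (ym ** 2).sum(axis=1))
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        reject = np.abs(t) > stats.t.ppf(1 - design.alpha / 2, n - 2)
        return float(reject.mean())
    raise ValidationError(f"unknown design type {type(design).__name__}")
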