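"""Two-sample Mendelian randomization estimators and diagnostics.

Implements the Wald ratio for single-variant instruments, fixed-effects
inverse-variance-weighted (IVW) pooling for multi-variant instruments,
Cochran's Q heterogeneity test, the MR-Egger intercept test for directional
pleiotropy, Benjamini–Hochberg FDR adjustment against an arbitrary family
size, and the 2×2 odds-ratio utility used for polygenic-score decile
contrasts.

Effects for case-control outcomes are log-odds; odds ratios and their 95%
intervals (z = 1.96 exactly) are derived at reporting time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .instruments import InstrumentSet

Z95 = 1.96


@dataclass(frozen=True)
class MRResult:
    """Per-gene causal estimate with diagnostics.

    ``theta`` is the causal effect of a one-unit increase in the exposure on
    the outcome (log-odds scale for binary outcomes). Heterogeneity (Q) is
    reported for ≥2 instruments and the Egger intercept for ≥3; otherwise
    those fields are None, mirroring standard MR reporting.
    """

    gene: str
    n_snps: int
    method: str  # wald_ratio | ivw_fe
    theta: float
    se: float
    pvalue: float
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    egger_slope: float | None = None

    @property
    def or_point(self) -> float:
        return math.exp(self.theta)

    @property
    def or_low95(self) -> float:
        return math.exp(self.theta - Z95 * self.se)

    @property
    def or_high95(self) -> float:
        return math.exp(self.theta + Z95 * self.se)

    @property
    def egger_intercept_ci(self) -> tuple[float, float] | None:
        if self.egger_intercept is None:
            return None
        a, s = self.egger_intercept, self.egger_intercept_se
        return (a - Z95 * s, a + Z95 * s)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> tuple[float, float, float]:
    """Single-instrument causal estimate by/bx.

    The SE is the first-order delta approximation sy/|bx|, which ignores the
    exposure-side sampling error — the conventional two-sample MR choice for
    genome-wide-significant instruments (``sx`` is accepted for signature
    symmetry and a possible second-order correction, but unused by default).
    """
    if bx == 0:
        raise ValueError("Wald ratio undefined for bx = 0")
    theta = by / bx
    se = sy / abs(bx)
    p = 2.0 * stats.norm.sf(abs(theta / se))
    return theta, se, p


def wald_ratio_second_order(bx: float, sx: float, by: float, sy: float) -> tuple[float, float, float]:
    """Wald ratio with the second-order delta-method SE (adds the bx term)."""
    if bx == 0:
        raise ValueError("Wald ratio undefined for bx = 0")
    theta = by / bx
    se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    p = 2.0 * stats.norm.sf(abs(theta / se))
    return theta, se, p


def ivw_fe(inst: InstrumentSet) -> MRResult:
    """Fixed-effects IVW estimate for a paired instrument set.

    Equivalent to the weighted regression of outcome on exposure effects
    through the origin with weights 1/se_outcome². Single-variant sets route
    to :func:`wald_ratio`; diagnostics (Q, Egger) are attached where the
    instrument count allows.
    """
    if not inst.has_outcome:
        raise ValueError(f"{inst.gene}: instrument set has no outcome effects")
    t = inst.table
    bx = t["beta_exposure"].to_numpy(float)
    by = t["beta_outcome"].to_numpy(float)
    sy = t["se_outcome"].to_numpy(float)
    if inst.n_snps == 1:
        sx = float(t["se_exposure"].iloc[0])
        theta, se, p = wald_ratio(float(bx[0]), sx, float(by[0]), float(sy[0]))
        return MRResult(gene=inst.gene, n_snps=1, method="wald_ratio", theta=theta, se=se, pvalue=p)
    w = sy**-2
    denom = float(np.sum(bx**2 * w))
    theta = float(np.sum(bx * by * w)) / denom
    se = denom**-0.5
    p = 2.0 * stats.norm.sf(abs(theta / se))
    q_stat, q_df, q_p = cochran_q(inst, theta)
    res = MRResult(
        gene=inst.gene, n_snps=inst.n_snps, method="ivw_fe",
        theta=theta, se=se, pvalue=p, q_stat=q_stat, q_df=q_df, q_pvalue=q_p,
    )
    if inst.n_snps >= 3:
        slope, a, a_se, a_p = egger(inst)
        res = MRResult(
            **{**res.__dict__, "egger_intercept": a, "egger_intercept_se": a_se,
               "egger_intercept_p": a_p, "egger_slope": slope}
        )
    return res


def cochran_q(inst: InstrumentSet, theta_ivw: float) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity across per-variant Wald ratios.

    Q = Σ wᵢ(θᵢ − θ_IVW)² with θᵢ = byᵢ/bxᵢ and wᵢ = bxᵢ²/syᵢ², referred to a
    chi-square with n−1 degrees of freedom. Single-variant instruments are
    not testable and raise.
    """
    if inst.n_snps < 2:
        raise ValueError("heterogeneity requires at least two instruments")
    t = inst.table
    bx = t["beta_exposure"].to_numpy(float)
    by = t["beta_outcome"].to_numpy(float)
    sy = t["se_outcome"].to_numpy(float)
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - theta_ivw) ** 2))
    df = inst.n_snps - 1
    return q, df, float(stats.chi2.sf(q, df))


def egger(inst: InstrumentSet) -> tuple[float, float, float, float]:
    """MR-Egger regression; returns (slope, intercept, intercept_se, intercept_p).

    Outcome effects are regressed on exposure effects with a free intercept
    and weights 1/se_outcome², after orienting every instrument so its
    exposure effect is non-negative (flipping the signs of both effects where
    needed). A nonzero intercept estimates average directional pleiotropy.
    Requires ≥3 instruments.
    """
    if inst.n_snps < 3:
        raise ValueError("MR-Egger requires at least three instruments")
    t = inst.table
    bx = t["beta_exposure"].to_numpy(float).copy()
    by = t["beta_outcome"].to_numpy(float).copy()
    sy = t["se_outcome"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    a_se = float(fit.bse[0])
    a_p = 2.0 * stats.norm.sf(abs(intercept / a_se)) if a_se > 0 else float("nan")
    return slope, intercept, a_se, a_p


def bh_adjust(raw_p, m_total: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values against family size m.

    ``m_total`` may exceed ``len(raw_p)`` when only the smallest p-values of
    a larger test family are in hand (e.g. the significant rows of a
    proteome-wide screen): adjusted₍ᵢ₎ = min over j ≥ i of (m/j)·p₍ⱼ₎ over the
    ascending-sorted values, capped at 1 and returned in input order.
    """
    p = np.asarray(raw_p, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("raw p-values must lie in (0, 1]")
    k = p.size
    m = k if m_total is None else int(m_total)
    if m < k:
        raise ValueError(f"m_total ({m}) smaller than number of p-values ({k})")
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, k + 1)
    stepped = np.minimum.accumulate((m / ranks * p[order])[::-1])[::-1]
    adj = np.empty(k)
    adj[order] = np.minimum(stepped, 1.0)
    return adj


def or_2x2(
    cases_exposed: int,
    controls_exposed: int,
    cases_unexposed: int,
    controls_unexposed: int,
) -> tuple[float, float, float]:
    """Odds ratio with Woolf 95% CI from a 2×2 contingency table.

    OR = (a·d)/(b·c) with the log-scale SE √(1/a + 1/b + 1/c + 1/d). Zero
    cells raise; callers wanting a continuity correction add 0.5 explicitly.
    """
    a, b, c, d = cases_exposed, controls_exposed, cases_unexposed, controls_unexposed
    if min(a, b, c, d) <= 0:
        raise ValueError("all four cell counts must be positive")
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or), math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se)
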