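"""Bayesian colocalization of two association signals via approximate Bayes factors.

For each variant j and trait t, a Wakefield approximate Bayes factor compares
the single-causal-variant alternative (effect prior N(0, w)) with the null,
using only the estimated effect and its standard error. Assuming at most one
causal variant per trait in the region, summing ABFs over causal-variant
configurations gives posterior probabilities for five hypotheses:

* H0 — neither trait associated;
* H1 / H2 — only trait 1 / trait 2 associated;
* H3 — both associated through *distinct* causal variants (LD confounding);
* H4 — both associated through one *shared* causal variant.

All accumulation is in log space (log-sum-exp); the H3 weight is computed as
a log-difference with a non-negativity clamp, since S1·S2 − S12 can cancel to
a tiny negative number in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
#: conventional prior effect SDs: 0.2 for quantitative traits, 0.15 case-control
SD_QUANT = 0.2
SD_CC = 0.15

SUGGESTIVE_PP_H4 = 0.5
STRONG_PP_H4 = 0.8


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant causal priors and per-trait prior effect variances.

    ``p1``/``p2`` are prior probabilities that a given variant is causal for
    trait 1/2 only; ``p12`` that it is causal for both. ``w1``/``w2`` are the
    prior variances (squared SD) of the causal effect for each trait.
    """

    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12
    w1: float = SD_QUANT**2
    w2: float = SD_QUANT**2

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("priors must satisfy 0 < p12 <= min(p1, p2) < 1")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("prior effect variances must be positive")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities over the five colocalization hypotheses."""

    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_snps: int
    priors: ColocPriors

    def as_array(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])


def log_abf(beta, se, w: float):
    """Log Wakefield approximate Bayes factor (alternative vs null).

    With V = se², z = beta/se and shrinkage r = w/(V + w):
    log ABF = ½·[log(1 − r) + r·z²]. ``w = 0`` collapses the alternative
    onto the null (log ABF = 0). Vectorized over beta/se.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if w < 0:
        raise ValueError("prior variance w must be non-negative")
    v = se**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def _log_diff_exp(log_a: float, log_b: float) -> float:
    """log(exp(log_a) − exp(log_b)), clamped to −inf when the difference ≤ 0."""
    if log_b >= log_a:
        return -np.inf
    return log_a + np.log1p(-np.exp(log_b - log_a))


def coloc_abf(
    beta1, se1, beta2, se2,
    priors: ColocPriors = ColocPriors(),
) -> ColocResult:
    """Enumerate single-causal-variant configurations and normalize.

    ``beta1/se1`` and ``beta2/se2`` are aligned per-variant effects for the
    two traits over an identical, harmonized variant list. With per-variant
    log ABFs l1, l2 and log-space sums S1 = Σⱼ ABF1ⱼ, S2 = Σⱼ ABF2ⱼ,
    S12 = Σⱼ ABF1ⱼ·ABF2ⱼ, the unnormalized hypothesis weights are
    1, p1·S1, p2·S2, p1·p2·(S1·S2 − S12), p12·S12.
    """
    l1 = np.atleast_1d(log_abf(beta1, se1, priors.w1))
    l2 = np.atleast_1d(log_abf(beta2, se2, priors.w2))
    if l1.shape != l2.shape:
        raise ValueError("variant lists of the two traits differ in length")
    n = l1.size
    if n < 1:
        raise ValueError("colocalization needs at least one variant")
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    log_h = np.array(
        [
            0.0,
            np.log(priors.p1) + s1,
            np.log(priors.p2) + s2,
            np.log(priors.p1) + np.log(priors.p2) + _log_diff_exp(s1 + s2, s12),
            np.log(priors.p12) + s12,
        ]
    )
    pp = np.exp(log_h - logsumexp(log_h))
    pp /= pp.sum()
    return ColocResult(*(float(x) for x in pp), n_snps=n, priors=priors)


def coloc_from_tables(stats1, stats2, priors: ColocPriors = ColocPriors()) -> ColocResult:
    """Colocalize two aligned tables bearing ``beta``/``se`` columns."""
    v1 = list(stats1["variant_id"]) if "variant_id" in stats1 else None
    v2 = list(stats2["variant_id"]) if "variant_id" in stats2 else None
    if v1 is not None and v2 is not None and v1 != v2:
        raise ValueError("variant lists are not identical; harmonize first")
    return coloc_abf(stats1["beta"], stats1["se"], stats2["beta"], stats2["se"], priors)


def classify_coloc(
    res: ColocResult,
    suggestive: float = SUGGESTIVE_PP_H4,
    strong: float = STRONG_PP_H4,
) -> str:
    """Label a result ``strong`` / ``suggestive`` / ``none`` from PP.H4.

    Strict inequalities: PP.H4 exactly at a threshold does not pass it.
    """
    if res.pp_h4 > strong:
        return "strong"
    if res.pp_h4 > suggestive:
        return "suggestive"
    return "none"
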