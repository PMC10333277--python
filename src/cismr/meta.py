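"""Fixed-effects GWAS meta-analysis, significance calling, and lead clumping.

Two harmonized studies are pooled per variant with inverse-variance weights;
genome-wide significant variants are thinned to distinct leads by greedy,
p-ordered clumping (LD r² rule when a matrix is available, distance rule
otherwise) and flagged as novel when farther than a window from every
previously reported lead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix, StudySumstats, VariantAssoc

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_R2_MAX = 0.6
DEFAULT_NOVELTY_WINDOW = 500_000


def maf_filter(study: StudySumstats, min_maf: float = 0.005) -> StudySumstats:
    """Drop variants whose minor-allele frequency is strictly below ``min_maf``.

    Records without an allele frequency are retained (and counted in the log);
    the filter cannot be applied to them.
    """
    kept, removed, no_eaf = [], 0, 0
    for rec in study.records:
        if rec.eaf is None:
            no_eaf += 1
            kept.append(rec)
            continue
        if min(rec.eaf, 1.0 - rec.eaf) < min_maf:
            removed += 1
        else:
            kept.append(rec)
    if removed or no_eaf:
        logger.info(
            "maf_filter(%s): removed %d variants below MAF %g (%d retained without eaf)",
            study.trait_name, removed, min_maf, no_eaf,
        )
    return StudySumstats(
        trait_name=study.trait_name,
        records=kept,
        trait_type=study.trait_type,
        n_cases=study.n_cases,
        n_controls=study.n_controls,
    )


def ivw_pool(betas, ses) -> tuple[float, float, float]:
    """Pool K study estimates of one quantity with inverse-variance weights.

    Returns (pooled beta, pooled se, two-sided p). With a single study this
    degenerates to that study's estimate.
    """
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if betas.size == 0:
        raise ValueError("nothing to pool")
    if np.any(ses <= 0):
        raise ValueError("non-positive se")
    w = ses**-2
    beta = float(np.sum(betas * w) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def ivw_meta(beta_a, se_a, beta_b, se_b) -> pd.DataFrame:
    """Fixed-effects inverse-variance-weighted pooling of two studies.

    Accepts scalars or aligned arrays. Pooled beta is the precision-weighted
    mean, pooled SE the reciprocal root of the summed precisions, and the
    p-value the two-sided normal tail of z = beta/SE.
    """
    beta_a, se_a = np.atleast_1d(np.asarray(beta_a, float)), np.atleast_1d(np.asarray(se_a, float))
    beta_b, se_b = np.atleast_1d(np.asarray(beta_b, float)), np.atleast_1d(np.asarray(se_b, float))
    for name, se in (("a", se_a), ("b", se_b)):
        bad = np.flatnonzero(~(se > 0))
        if bad.size:
            raise ValueError(f"non-positive se in study {name} at index {bad[0]}")
    w_a, w_b = se_a ** -2, se_b ** -2
    beta = (beta_a * w_a + beta_b * w_b) / (w_a + w_b)
    se = (w_a + w_b) ** -0.5
    z = beta / se
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "pvalue": 2.0 * stats.norm.sf(np.abs(z)),
            "n_studies": 2,
        }
    )


def meta_analyze(harmonized: pd.DataFrame) -> pd.DataFrame:
    """IVW-pool a :func:`cismr.sumstats.harmonize_pair` table per variant."""
    pooled = ivw_meta(
        harmonized["beta_a"], harmonized["se_a"],
        harmonized["beta_b"], harmonized["se_b"],
    )
    out = harmonized[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    out = out.reset_index(drop=True).join(pooled)
    if "eaf_a" in harmonized:
        out["eaf"] = harmonized["eaf_a"].to_numpy()
    return out


@dataclass(frozen=True)
class LeadVariant:
    """A distinct genome-wide-significant association."""

    variant_id: str
    chrom: str
    pos: int
    beta: float
    se: float
    pvalue: float
    is_novel: bool
    nearest_known_distance: int | None  # None when no known lead on any chromosome


def call_leads(
    meta: pd.DataFrame,
    ld: LDMatrix | None = None,
    known_leads: list[tuple[str, int]] | None = None,
    p_threshold: float = GENOME_WIDE_P,
    r2_max: float = DEFAULT_R2_MAX,
    novelty_window: int = DEFAULT_NOVELTY_WINDOW,
) -> list[LeadVariant]:
    """Greedy p-ordered selection of distinct leads with novelty flags.

    Candidates below ``p_threshold`` are visited in ascending p (ties broken
    by ascending position); a candidate is absorbed into an already-selected
    lead when their LD r² ≥ ``r2_max`` (when ``ld`` covers both), or — as a
    distance approximation when no LD is available — when it lies within
    ``novelty_window`` of the lead on the same chromosome. A lead is novel
    iff every known lead on its chromosome is farther than ``novelty_window``.
    """
    known = known_leads or []
    sig = meta.loc[meta["pvalue"] < p_threshold].sort_values(
        ["pvalue", "pos"], kind="mergesort"
    )
    leads: list[LeadVariant] = []
    chosen: list[pd.Series] = []
    for _, row in sig.iterrows():
        absorbed = False
        for lead in chosen:
            if lead["chrom"] != row["chrom"]:
                continue
            if (
                ld is not None
                and row["variant_id"] in ld.variant_ids
                and lead["variant_id"] in ld.variant_ids
            ):
                if ld.r2(row["variant_id"], lead["variant_id"]) >= r2_max:
                    absorbed = True
                    break
            elif abs(int(row["pos"]) - int(lead["pos"])) <= novelty_window:
                absorbed = True
                break
        if absorbed:
            continue
        chosen.append(row)
        dists = [abs(int(row["pos"]) - kp) for kc, kp in known if kc == row["chrom"]]
        nearest = min(dists) if dists else None
        leads.append(
            LeadVariant(
                variant_id=row["variant_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                pvalue=float(row["pvalue"]),
                is_novel=(nearest is None) or (nearest > novelty_window),
                nearest_known_distance=nearest,
            )
        )
    return leads
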