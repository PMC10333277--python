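"""cis-pQTL instrument selection and exposure–outcome pairing.

Instruments for a protein are variants within a cis window of its encoding
gene that associate with plasma protein abundance below a significance
threshold, thinned to an approximately independent set by greedy LD clumping.
The selected exposure-side variants are then joined to harmonized outcome
effects to form the per-gene table two-sample MR consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import LDMatrix, StudySumstats, harmonize_pair

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_INSTRUMENT_P = 5e-8
DEFAULT_R2_INDEPENDENT = 0.1


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic footprint (1-based inclusive coordinates)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")

    def cis_contains(self, chrom: str, pos: int, window: int = DEFAULT_CIS_WINDOW) -> bool:
        return chrom == self.chrom and self.start - window <= pos <= self.end + window


@dataclass
class InstrumentSet:
    """Per-gene instrument table for two-sample MR.

    ``table`` rows carry ``variant_id, pos, beta_exposure, se_exposure,
    pvalue_exposure, eaf`` and — after :func:`attach_outcome` —
    ``beta_outcome, se_outcome``.
    """

    gene: str
    protein: str
    table: pd.DataFrame
    ld: LDMatrix | None = None

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def has_outcome(self) -> bool:
        return "beta_outcome" in self.table.columns and self.n_snps > 0

    def __len__(self) -> int:
        return self.n_snps


def _greedy_clump(
    cand: pd.DataFrame,
    ld: LDMatrix | None,
    r2_independent: float,
    distance_window: int,
) -> pd.DataFrame:
    """Thin p-sorted candidates to an approximately independent set."""
    kept_rows = []
    for _, row in cand.iterrows():
        dependent = False
        for kept in kept_rows:
            if (
                ld is not None
                and row["variant_id"] in ld.variant_ids
                and kept["variant_id"] in ld.variant_ids
            ):
                if ld.r2(row["variant_id"], kept["variant_id"]) >= r2_independent:
                    dependent = True
                    break
            elif abs(int(row["pos"]) - int(kept["pos"])) <= distance_window:
                dependent = True
                break
        if not dependent:
            kept_rows.append(row)
    return pd.DataFrame(kept_rows, columns=cand.columns).reset_index(drop=True)


def select_cis_instruments(
    pqtl: StudySumstats,
    region: GeneRegion,
    window: int = DEFAULT_CIS_WINDOW,
    p_max: float = DEFAULT_INSTRUMENT_P,
    ld: LDMatrix | None = None,
    r2_independent: float = DEFAULT_R2_INDEPENDENT,
    clump_distance: int = DEFAULT_CIS_WINDOW,
) -> InstrumentSet:
    """Select approximately independent cis instruments for one protein.

    Candidates are variants on the gene's chromosome within
    ``[start − window, end + window]`` with exposure p < ``p_max``, sorted by
    ascending p and greedily clumped: a candidate correlated at
    r² ≥ ``r2_independent`` with an already-kept instrument (or within
    ``clump_distance`` of one, when no LD matrix is supplied) is discarded.
    An empty set is returned — with a logged reason — when no candidate
    survives; the caller excludes the gene from MR.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = [
        {
            "variant_id": r.variant_id,
            "pos": r.pos,
            "beta_exposure": r.beta,
            "se_exposure": r.se,
            "pvalue_exposure": r.pvalue,
            "eaf": np.nan if r.eaf is None else r.eaf,
        }
        for r in pqtl.records
        if region.cis_contains(r.chrom, r.pos, window) and r.pvalue < p_max
    ]
    cand = pd.DataFrame(
        rows,
        columns=["variant_id", "pos", "beta_exposure", "se_exposure", "pvalue_exposure", "eaf"],
    ).sort_values(["pvalue_exposure", "pos"], kind="mergesort")
    if cand.empty:
        logger.info("select_cis_instruments(%s): no cis variant below p=%g", region.gene, p_max)
        return InstrumentSet(gene=region.gene, protein=pqtl.trait_name, table=cand.reset_index(drop=True))
    clumped = _greedy_clump(cand, ld, r2_independent, clump_distance)
    sub_ld = None
    if ld is not None:
        ids = [v for v in clumped["variant_id"] if v in ld.variant_ids]
        if len(ids) == len(clumped):
            sub_ld = ld.subset(list(clumped["variant_id"]))
    return InstrumentSet(gene=region.gene, protein=pqtl.trait_name, table=clumped, ld=sub_ld)


def attach_outcome(inst: InstrumentSet, pqtl: StudySumstats, outcome: StudySumstats) -> InstrumentSet:
    """Join harmonized outcome effects onto an exposure-side instrument set.

    Harmonization brings the outcome study to the exposure study's effect
    alleles (negating outcome betas across allele swaps). Instruments absent
    from the outcome — or dropped as ambiguous palindromes — are removed and
    logged; no proxy lookup is attempted. Returns a possibly empty set.
    """
    if inst.n_snps == 0:
        return inst
    pair = harmonize_pair(pqtl, outcome)
    pair = pair.set_index("variant_id")
    rows = []
    missing = 0
    for _, row in inst.table.iterrows():
        vid = row["variant_id"]
        if vid not in pair.index:
            missing += 1
            continue
        out = dict(row)
        out["beta_outcome"] = float(pair.loc[vid, "beta_b"])
        out["se_outcome"] = float(pair.loc[vid, "se_b"])
        out["pvalue_outcome"] = float(pair.loc[vid, "pvalue_b"])
        rows.append(out)
    if missing:
        logger.info("attach_outcome(%s): %d instruments missing from outcome", inst.gene, missing)
    cols = list(inst.table.columns) + ["beta_outcome", "se_outcome", "pvalue_outcome"]
    table = pd.DataFrame(rows, columns=cols).reset_index(drop=True)
    sub_ld = None
    if inst.ld is not None and len(table) and all(v in inst.ld.variant_ids for v in table["variant_id"]):
        sub_ld = inst.ld.subset(list(table["variant_id"]))
    return InstrumentSet(gene=inst.gene, protein=inst.protein, table=table, ld=sub_ld)
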