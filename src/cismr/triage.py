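"""Per-gene target triage: pleiotropy assessment, directionality, druggability.

A gene that passes the MR FDR threshold and colocalizes with the outcome is a
*candidate* target. Candidates are then screened by a four-step horizontal-
pleiotropy assessment:

1. find secondary proteins/transcripts the gene's instruments also associate
   with at genome-wide significance;
2. flag proximity of the gene to known outcome risk loci (possible LD with an
   established signal);
3. run MR of each secondary trait (with its own cis instrument) on the
   outcome under a Bonferroni threshold;
4. map significant secondary traits to pathways: a secondary trait sharing a
   pathway with the primary gene indicates vertical pleiotropy (harmless),
   one in a disjoint pathway indicates horizontal pleiotropy (invalidates the
   instrument), and one without annotation leaves the verdict unknown.

Reporting helpers infer the therapeutic modality from the odds ratio
(OR > 1 → the protein raises risk → inhibitor; OR < 1 → agonist), check
directionality concordance against declared-harmful risk factors, and regroup
tractability buckets 1–9 into four interpretable druggability groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .instruments import GeneRegion
from .mr import MRResult

logger = logging.getLogger(__name__)

SECONDARY_P = 5e-8
KNOWN_LOCUS_WINDOW = 1_000_000
RISK_FACTOR_P = 1e-4


@dataclass(frozen=True)
class SecondaryTrait:
    """A secondary protein/transcript associated with a primary instrument."""

    source_instrument: str
    trait: str
    kind: str  # protein | expression
    assoc_p: float
    has_own_cis_instrument: bool = False


@dataclass(frozen=True)
class PleiotropyVerdict:
    """Outcome of the pathway-concordance step for one primary gene.

    ``flag`` precedence is conservative: any horizontal evidence flags the
    gene horizontal; otherwise any unannotated significant secondary trait
    leaves it unknown; otherwise vertical; ``none`` when no significant
    secondary trait exists.
    """

    gene: str
    flag: str  # none | vertical | horizontal | unknown
    evidence: tuple = ()


@dataclass(frozen=True)
class TriageVerdict:
    """Composite per-gene decision row."""

    gene: str
    mr_fdr_pass: bool
    coloc_class: str
    near_known_hf_locus: bool | None = None
    pleiotropy_flag: str | None = None
    modality: str | None = None
    druggability_group: str | None = None

    @property
    def candidate(self) -> bool:
        return self.mr_fdr_pass and self.coloc_class in ("suggestive", "strong")


def step1_secondary_traits(
    instrument_ids: Iterable[str],
    primary_trait: str,
    protein_assoc: pd.DataFrame,
    expression_assoc: pd.DataFrame | None = None,
    p_max: float = SECONDARY_P,
) -> list[SecondaryTrait]:
    """Secondary proteins/transcripts the instruments associate with.

    Association tables carry ``variant_id, trait, pvalue`` (expression tables
    optionally). All (instrument, trait) pairs with p < ``p_max`` are
    returned, excluding the primary trait itself.
    """
    ids = set(instrument_ids)
    out: list[SecondaryTrait] = []
    for kind, table in (("protein", protein_assoc), ("expression", expression_assoc)):
        if table is None or table.empty:
            continue
        hits = table[
            table["variant_id"].isin(ids)
            & (table["pvalue"] < p_max)
            & (table["trait"] != primary_trait)
        ]
        for _, row in hits.iterrows():
            out.append(
                SecondaryTrait(
                    source_instrument=str(row["variant_id"]),
                    trait=str(row["trait"]),
                    kind=kind,
                    assoc_p=float(row["pvalue"]),
                )
            )
    return out


def step2_known_locus_proximity(
    genes: Mapping[str, GeneRegion] | Sequence[GeneRegion],
    known_loci: Sequence[tuple[str, int]],
    window: int = KNOWN_LOCUS_WINDOW,
) -> dict[str, bool]:
    """Per-gene flag: does any known risk lead fall within ``window`` of it?

    Distance is measured from the gene body (zero inside the gene).
    """
    regions = genes.values() if isinstance(genes, Mapping) else genes
    out = {}
    for region in regions:
        near = any(
            chrom == region.chrom
            and (region.start - window) <= pos <= (region.end + window)
            for chrom, pos in known_loci
        )
        out[region.gene] = near
    return out


def step3_secondary_mr(
    secondary: Sequence[SecondaryTrait],
    mr_results: Mapping[str, MRResult],
) -> tuple[dict[str, float], float, list[str]]:
    """Bonferroni-screen secondary traits' own MR on the outcome.

    ``mr_results`` maps each secondary trait (instrumented by its own lead
    cis-pQTL, or lead cis-eQTL when no pQTL exists) to its MR result; traits
    without an entry have no usable cis instrument and are excluded with a
    log line. Returns (per-trait MR p, Bonferroni threshold 0.05/n over the n
    unique instrumented traits, significant trait names).
    """
    traits = sorted({s.trait for s in secondary})
    tested = {t: mr_results[t].pvalue for t in traits if t in mr_results}
    skipped = [t for t in traits if t not in mr_results]
    for t in skipped:
        logger.info("step3_secondary_mr: no cis instrument for %s; excluded", t)
    n = len(tested)
    threshold = 0.05 / n if n else float("nan")
    significant = [t for t, p in tested.items() if p < threshold]
    return tested, threshold, significant


def step4_pathway_concordance(
    primary_gene: str,
    significant_secondary: Sequence[str],
    pathways: Mapping[str, set[str]] | pd.DataFrame,
) -> PleiotropyVerdict:
    """Compare primary and secondary genes' pathway membership.

    ``pathways`` maps gene → set of pathway ids (or a two-column
    ``gene, pathway_id`` table). A significant secondary gene sharing ≥1
    pathway with the primary gene contributes vertical evidence; both
    annotated but disjoint → horizontal; secondary unannotated → unknown.
    """
    if isinstance(pathways, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for _, row in pathways.iterrows():
            mapping.setdefault(str(row["gene"]), set()).add(str(row["pathway_id"]))
        pathways = mapping
    primary_pw = pathways.get(primary_gene, set())
    evidence = []
    for gene in sorted(set(significant_secondary)):
        sec_pw = pathways.get(gene, set())
        if not sec_pw:
            kind = "unknown"
            shared = None
        elif primary_pw & sec_pw:
            kind = "vertical"
            shared = True
        else:
            kind = "horizontal"
            shared = False
        evidence.append((gene, kind, shared))
    kinds = {k for _, k, _ in evidence}
    if "horizontal" in kinds:
        flag = "horizontal"
    elif "unknown" in kinds:
        flag = "unknown"
    elif "vertical" in kinds:
        flag = "vertical"
    else:
        flag = "none"
    return PleiotropyVerdict(gene=primary_gene, flag=flag, evidence=tuple(evidence))


def direction_concordance(hf_beta: float, rf_beta: float, rf_harmful: bool) -> str:
    """Concordance of an outcome effect with a risk-factor effect.

    A variant or gene raising outcome risk is expected to raise a harmful
    risk factor (or lower a protective one). Zero betas carry no direction
    and raise, so callers exclude them from the tally.
    """
    if hf_beta == 0 or rf_beta == 0:
        raise ValueError("zero beta has no direction; exclude from the tally")
    expected = (1 if rf_beta > 0 else -1) * (1 if rf_harmful else -1)
    return "concordant" if (1 if hf_beta > 0 else -1) == expected else "discordant"


def infer_modality(or_point: float) -> str:
    """Therapeutic action implied by the MR odds ratio.

    OR > 1: more protein, more risk — an inhibitor should prevent disease.
    OR < 1: more protein, less risk — an agonist should. OR exactly 1 is
    directionless.
    """
    if or_point <= 0:
        raise ValueError("odds ratio must be positive")
    if or_point > 1:
        return "inhibitor"
    if or_point < 1:
        return "agonist"
    return "none"


def regroup_buckets(bucket: int | None, modality_class: str = "small_molecule") -> str:
    """Collapse tractability buckets 1–9 into four druggability groups.

    bucket 1 → licensed (any modality); 2–3 → clinical; 4–5 → preclinical
    for small molecules but only predicted-druggable for antibodies; 6–8 →
    predicted for small molecules; 9 or no bucket → non-druggable.
    """
    if bucket is None:
        return "non_druggable"
    if not 1 <= bucket <= 9:
        raise ValueError(f"bucket must be 1-9 or None, got {bucket}")
    if bucket == 1:
        return "licensed"
    if bucket in (2, 3):
        return "clinical"
    if bucket in (4, 5):
        return "predicted" if modality_class == "antibody" else "preclinical"
    if bucket in (6, 7, 8):
        return "predicted" if modality_class == "small_molecule" else "non_druggable"
    return "non_druggable"


def assemble_verdict(
    gene: str,
    adjusted_p: float,
    coloc_class: str,
    fdr: float = 0.05,
    near_known_locus: bool | None = None,
    pleiotropy_flag: str | None = None,
    or_point: float | None = None,
    druggability_group: str | None = None,
) -> TriageVerdict:
    """Combine per-gene components into the final verdict row.

    Candidate status requires adjusted p < ``fdr`` *and* at least suggestive
    colocalization. Missing components are carried as None, never silently
    defaulted.
    """
    modality = infer_modality(or_point) if or_point is not None else None
    return TriageVerdict(
        gene=gene,
        mr_fdr_pass=bool(adjusted_p < fdr),
        coloc_class=coloc_class,
        near_known_hf_locus=near_known_locus,
        pleiotropy_flag=pleiotropy_flag,
        modality=modality,
        druggability_group=druggability_group,
    )
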