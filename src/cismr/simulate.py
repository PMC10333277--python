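"""Synthetic GWAS/pQTL summary statistics with known ground truth.

Regional association z-scores are drawn from the standard summary-statistic
model z | λ ~ N(Rλ, R), where R is the LD correlation matrix and λ carries
the non-centrality ``effect_z`` at the causal variant — the marginal z-score
of every variant is inflated through its LD with the causal one, exactly the
structure colocalization reasons about. Betas are reported as z/√n with
SE 1/√n (a unit-variance trait scale). Scenarios H0–H4 mirror the
colocalization hypotheses: no causal variant, one trait only, two distinct
causal variants, or one shared causal variant.

A separate generator produces independent-instrument MR datasets with a
known causal effect and optional directional pleiotropy.

Every generator takes an integer seed and uses one ``numpy.random.default_rng``
stream, so identical calls are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet
from .sumstats import LDMatrix, StudySumstats, VariantAssoc

SCENARIOS = ("H0", "H1", "H2", "H3", "H4")

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class SimTruth:
    """Ground truth attached to a simulated dataset."""

    scenario: str
    causal_trait1: int | None
    causal_trait2: int | None
    true_theta: float
    pleiotropy_alpha: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def make_ld(n_snps: int, rho: float) -> LDMatrix:
    """AR(1) LD: r between variants j and k is rho^|j−k| (symmetric PD)."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(n_snps)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    ids = tuple(f"rs{i + 1}" for i in range(n_snps))
    return LDMatrix(ids, r)


def _study_from_z(
    z: np.ndarray,
    n: int,
    eaf: np.ndarray,
    positions: np.ndarray,
    alleles: list[tuple[str, str]],
    trait_name: str,
    chrom: str,
) -> StudySumstats:
    beta = z / np.sqrt(n)
    se = np.full_like(beta, 1.0 / np.sqrt(n))
    p = 2.0 * stats.norm.sf(np.abs(z))
    records = [
        VariantAssoc(
            variant_id=f"rs{i + 1}",
            chrom=chrom,
            pos=int(positions[i]),
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            beta=float(beta[i]),
            se=float(se[i]),
            pvalue=float(max(p[i], np.nextafter(0, 1))),
            eaf=float(eaf[i]),
            n=n,
        )
        for i in range(z.size)
    ]
    return StudySumstats(trait_name=trait_name, records=records)


def simulate_region(
    n_snps: int,
    ld: LDMatrix,
    scenario: str,
    effect_z: float = 10.0,
    n1: int = 10_000,
    n2: int = 10_000,
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    pos_step: int = 5_000,
    min_h3_r: float | None = 0.2,
    palindromic_fraction: float = 0.0,
    causal1: int | None = None,
    causal2: int | None = None,
) -> tuple[StudySumstats, StudySumstats, SimTruth]:
    """Simulate one region's summary statistics for two traits.

    Causal variants per scenario: H0 none; H1/H2 one for trait 1/2 only;
    H3 two distinct variants (chosen with pairwise LD |r| below
    ``min_h3_r`` when possible); H4 one shared variant. Causal indices are
    drawn uniformly unless pinned via ``causal1``/``causal2``. ``palindromic_fraction`` of variants receive A/T or C/G
    alleles (flagged for harmonization edge-case testing via their alleles).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if effect_z < 0:
        raise ValueError("effect_z must be >= 0")
    if len(ld.variant_ids) != n_snps:
        raise ValueError("LD matrix does not match n_snps")
    r = ld.r
    try:
        chol = np.linalg.cholesky(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular LD matrix; add jitter to the diagonal") from exc

    rng = np.random.default_rng(seed)
    c1 = c2 = None
    if scenario in ("H1", "H4"):
        c1 = int(rng.integers(n_snps)) if causal1 is None else int(causal1)
    if scenario == "H2":
        c2 = int(rng.integers(n_snps)) if causal2 is None else int(causal2)
    if scenario == "H4":
        c2 = c1
    if scenario == "H3":
        c1 = int(rng.integers(n_snps)) if causal1 is None else int(causal1)
        if causal2 is not None:
            c2 = int(causal2)
        else:
            low_ld = [
                j for j in range(n_snps)
                if j != c1 and (min_h3_r is None or abs(r[c1, j]) < min_h3_r)
            ]
            pool = low_ld if low_ld else [j for j in range(n_snps) if j != c1]
            c2 = int(rng.choice(pool))
        if c1 == c2:
            raise ValueError("H3 requires distinct causal variants")

    def draw(causal, n):
        lam = np.zeros(n_snps)
        if causal is not None:
            lam[causal] = effect_z
        return r @ lam + chol @ rng.standard_normal(n_snps)

    z1 = draw(c1, n1)
    z2 = draw(c2, n2)
    eaf = rng.uniform(0.05, 0.95, size=n_snps)
    positions = start_pos + pos_step * np.arange(n_snps)
    alleles = []
    for _ in range(n_snps):
        if palindromic_fraction > 0 and rng.random() < palindromic_fraction:
            alleles.append(_PALINDROMIC_PAIRS[int(rng.integers(len(_PALINDROMIC_PAIRS)))])
        else:
            alleles.append(_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))])
    s1 = _study_from_z(z1, n1, eaf, positions, alleles, "trait1", chrom)
    s2 = _study_from_z(z2, n2, eaf, positions, alleles, "trait2", chrom)
    truth = SimTruth(
        scenario=scenario, causal_trait1=c1, causal_trait2=c2,
        true_theta=0.0, pleiotropy_alpha=0.0, seed=seed,
    )
    return s1, s2, truth


def simulate_mr(
    k_instruments: int,
    theta: float,
    pleiotropy_alpha: float = 0.0,
    bx_mean: float = 0.2,
    bx_sd: float = 0.05,
    n_exp: int = 100_000,
    n_out: int = 50_000,
    seed: int = 0,
    gene: str = "SIMGENE",
) -> tuple[InstrumentSet, SimTruth]:
    """Simulate an independent-instrument two-sample MR dataset.

    True exposure effects are N(bx_mean, bx_sd²); observed exposure effects
    add noise with SE 1/√n_exp, and observed outcome effects are
    θ·bx_true + α + noise with SE 1/√n_out. The defaults put the exposure
    side firmly in the strong-instrument regime (lead-variant z-scores of
    tens, as cis-pQTLs show), so both the IVW attenuation and the extra
    outcome-scale dispersion θ²·se_exposure² from exposure-side noise are
    negligible relative to the outcome SE.
    """
    if k_instruments < 1:
        raise ValueError("k_instruments must be >= 1")
    rng = np.random.default_rng(seed)
    bx_true = rng.normal(bx_mean, bx_sd, size=k_instruments)
    sx = 1.0 / np.sqrt(n_exp)
    sy = 1.0 / np.sqrt(n_out)
    bx_hat = bx_true + sx * rng.standard_normal(k_instruments)
    by_hat = theta * bx_true + pleiotropy_alpha + sy * rng.standard_normal(k_instruments)
    table = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(k_instruments)],
            "pos": 1_000_000 + 5_000 * np.arange(k_instruments),
            "beta_exposure": bx_hat,
            "se_exposure": sx,
            "pvalue_exposure": 2.0 * stats.norm.sf(np.abs(bx_hat / sx)),
            "eaf": rng.uniform(0.05, 0.95, size=k_instruments),
            "beta_outcome": by_hat,
            "se_outcome": sy,
            "pvalue_outcome": 2.0 * stats.norm.sf(np.abs(by_hat / sy)),
        }
    )
    truth = SimTruth(
        scenario="MR", causal_trait1=None, causal_trait2=None,
        true_theta=theta, pleiotropy_alpha=pleiotropy_alpha, seed=seed,
    )
    return InstrumentSet(gene=gene, protein=gene, table=table), truth
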