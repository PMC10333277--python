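"""GWAS/pQTL summary-statistics containers, I/O, and cross-study harmonization.

Summary statistics are the atoms of every downstream analysis: one
:class:`VariantAssoc` per variant per trait, grouped into a
:class:`StudySumstats`. Two studies are joined on variant id and brought to a
common effect-allele orientation by :func:`harmonize_pair`, which resolves
allele swaps and strand flips and drops strand-ambiguous palindromic variants
whose allele frequency is too close to 0.5 to orient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical column names used by the reader/writer.
CANONICAL_COLUMNS = ("SNP", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P", "N")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str | None:
    """Reverse-complement a simple allele; None for indels/ambiguity codes."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele))
    except KeyError:
        return None


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G variants, which cannot be strand-resolved."""
    return _complement(effect_allele) == other_allele


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` (log-odds
    for case-control traits); ``eaf`` is the effect-allele frequency.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not (self.se > 0):
            problems.append("se must be > 0")
        if self.pos < 1:
            problems.append("pos must be >= 1")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append("eaf outside [0, 1]")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if not (0.0 < self.pvalue <= 1.0):
            problems.append("pvalue outside (0, 1]")
        return problems

    def pvalue_consistent(self, sig_figs: int = 1) -> bool:
        """Check p against the two-sided normal tail of beta/se (warn-level)."""
        if self.se <= 0:
            return False
        expected = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        if expected == 0.0 or self.pvalue == 0.0:
            return True  # below float underflow; cannot compare
        # agreement to 1 significant figure on a log-friendly ratio
        return math.isclose(expected, self.pvalue, rel_tol=0.5 * 10 ** (1 - sig_figs))


@dataclass
class StudySumstats:
    """An ordered, variant-id-unique collection of associations for one trait."""

    trait_name: str
    records: list[VariantAssoc]
    trait_type: str = "quantitative"
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError(f"unknown trait_type: {self.trait_type!r}")
        if self.trait_type == "case_control":
            if not (self.n_cases and self.n_controls and self.n_cases > 0 and self.n_controls > 0):
                raise ValueError("case_control traits require n_cases and n_controls > 0")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate variant_id in {self.trait_name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, VariantAssoc]:
        return {r.variant_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with canonical column names."""
        return pd.DataFrame(
            {
                "SNP": [r.variant_id for r in self.records],
                "CHR": [r.chrom for r in self.records],
                "POS": [r.pos for r in self.records],
                "EA": [r.effect_allele for r in self.records],
                "NEA": [r.other_allele for r in self.records],
                "EAF": [np.nan if r.eaf is None else r.eaf for r in self.records],
                "BETA": [r.beta for r in self.records],
                "SE": [r.se for r in self.records],
                "P": [r.pvalue for r in self.records],
                "N": [np.nan if r.n is None else r.n for r in self.records],
            }
        )


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise correlation (r, not r²) over an ordered variant list."""

    variant_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "variant_ids", tuple(self.variant_ids))
        k = len(self.variant_ids)
        if r.shape != (k, k):
            raise ValueError(f"LD matrix shape {r.shape} does not match {k} variants")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(r) > 1.0 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")

    def index_of(self, variant_id: str) -> int:
        return self.variant_ids.index(variant_id)

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in variant_ids]
        return LDMatrix(tuple(variant_ids), self.r[np.ix_(idx, idx)])

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)] ** 2)


# ---------------------------------------------------------------------------
# Reading / writing


DEFAULT_DIALECT: Mapping[str, str] = {c: c for c in CANONICAL_COLUMNS}

_MANDATORY = ("SNP", "CHR", "POS", "EA", "NEA", "BETA", "SE", "P")


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "quantitative",
    n_cases: int | None = None,
    n_controls: int | None = None,
    sep: str | None = None,
) -> StudySumstats:
    """Read delimited summary statistics into a :class:`StudySumstats`.

    Parameters
    ----------
    dialect
        Mapping from canonical names (``SNP``, ``CHR``, ``POS``, ``EA``,
        ``NEA``, ``EAF``, ``BETA``, ``SE``, ``P``, ``N``) to the file's
        column names. Unmapped optional columns (EAF, N) are treated as
        missing. Gzip input is handled transparently.
    sep
        Field delimiter; default sniffs whitespace vs comma.

    Rows violating record invariants (non-positive SE, equal alleles, p
    outside (0,1], ...) are dropped with a logged count. Alleles are
    upper-cased.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)

    if sep is None:
        # peek at the header to choose a delimiter
        import gzip

        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty summary-statistics file: {path}")
        sep = "," if "," in header else r"\s+"

    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except ValueError:  # python engine (exact float()) rejects the option
        df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"empty summary-statistics file: {path}")

    for canon in _MANDATORY:
        col = mapping[canon]
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} (for {canon})")

    def _col(canon):
        col = mapping.get(canon)
        return df[col] if col in df.columns else None

    eaf_col, n_col = _col("EAF"), _col("N")
    records: list[VariantAssoc] = []
    dropped = 0
    for i in range(len(df)):
        try:
            eaf = None
            if eaf_col is not None and pd.notna(eaf_col.iloc[i]):
                eaf = float(eaf_col.iloc[i])
            n = None
            if n_col is not None and pd.notna(n_col.iloc[i]):
                n = int(n_col.iloc[i])
            rec = VariantAssoc(
                variant_id=str(df[mapping["SNP"]].iloc[i]),
                chrom=str(df[mapping["CHR"]].iloc[i]),
                pos=int(df[mapping["POS"]].iloc[i]),
                effect_allele=str(df[mapping["EA"]].iloc[i]).upper(),
                other_allele=str(df[mapping["NEA"]].iloc[i]).upper(),
                beta=float(df[mapping["BETA"]].iloc[i]),
                se=float(df[mapping["SE"]].iloc[i]),
                pvalue=float(df[mapping["P"]].iloc[i]),
                eaf=eaf,
                n=n,
            )
        except (ValueError, TypeError):
            dropped += 1
            continue
        problems = rec.validate()
        if problems:
            dropped += 1
            continue
        if not rec.pvalue_consistent():
            logger.warning("p-value of %s inconsistent with beta/se", rec.variant_id)
        records.append(rec)
    if dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows", path, dropped)
    return StudySumstats(
        trait_name=trait_name or str(path),
        records=records,
        trait_type=trait_type,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def write_sumstats(study: StudySumstats, path) -> None:
    """Write tab-delimited summary statistics with canonical headers."""
    df = study.to_frame()
    # shortest-repr floats keep read∘write bit-exact for finite doubles
    for col in ("EAF", "BETA", "SE", "P"):
        df[col] = df[col].map(lambda v: "NA" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Harmonization


def _classify_alleles(ea_a, oa_a, ea_b, oa_b):
    """Relate study-b alleles to study-a orientation.

    Returns one of ``same``, ``swap``, ``flip`` (strand complement),
    ``flip_swap``, or ``None`` (irreconcilable).
    """
    if (ea_b, oa_b) == (ea_a, oa_a):
        return "same"
    if (ea_b, oa_b) == (oa_a, ea_a):
        return "swap"
    cea, coa = _complement(ea_b), _complement(oa_b)
    if cea is None or coa is None:
        return None
    if (cea, coa) == (ea_a, oa_a):
        return "flip"
    if (cea, coa) == (oa_a, ea_a):
        return "flip_swap"
    return None


def harmonize_pair(
    a: StudySumstats,
    b: StudySumstats,
    drop_ambiguous_maf: float = 0.08,
) -> pd.DataFrame:
    """Align two studies to shared variants on study-a's effect allele.

    Returns a table with one row per shared, resolvable variant and columns
    ``variant_id, chrom, pos, effect_allele, other_allele`` plus
    ``{eaf,beta,se,pvalue,n}_a`` and ``_b``. When study b's alleles are
    swapped relative to a, b's beta is negated and its eaf replaced by
    1 − eaf; strand flips are resolved by complementing. Palindromic (A/T,
    C/G) variants are kept only when their allele frequency is informative:
    any palindromic variant with eaf within ``drop_ambiguous_maf`` of 0.5 in
    either study, or with missing eaf, is removed. Irreconcilable allele
    sets are dropped and logged.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both studies must be non-empty")
    b_idx = b.by_id()
    rows = []
    n_dropped_alleles = 0
    n_dropped_palindromic = 0
    for ra in a.records:
        rb = b_idx.get(ra.variant_id)
        if rb is None:
            continue
        if is_palindromic(ra.effect_allele, ra.other_allele):
            eafs = (ra.eaf, rb.eaf)
            if any(e is None for e in eafs) or any(
                abs(e - 0.5) < drop_ambiguous_maf for e in eafs
            ):
                n_dropped_palindromic += 1
                continue
            # palindromic but orientable: flip b when its minor allele
            # disagrees with a's
            same_side = (ra.eaf - 0.5) * (rb.eaf - 0.5) > 0
            rel = "same" if same_side else "swap"
        else:
            rel = _classify_alleles(
                ra.effect_allele, ra.other_allele, rb.effect_allele, rb.other_allele
            )
        if rel is None:
            n_dropped_alleles += 1
            continue
        beta_b, eaf_b = rb.beta, rb.eaf
        if rel in ("swap", "flip_swap"):
            beta_b = -beta_b
            eaf_b = None if eaf_b is None else 1.0 - eaf_b
        rows.append(
            {
                "variant_id": ra.variant_id,
                "chrom": ra.chrom,
                "pos": ra.pos,
                "effect_allele": ra.effect_allele,
                "other_allele": ra.other_allele,
                "eaf_a": np.nan if ra.eaf is None else ra.eaf,
                "beta_a": ra.beta,
                "se_a": ra.se,
                "pvalue_a": ra.pvalue,
                "n_a": np.nan if ra.n is None else ra.n,
                "eaf_b": np.nan if eaf_b is None else eaf_b,
                "beta_b": beta_b,
                "se_b": rb.se,
                "pvalue_b": rb.pvalue,
                "n_b": np.nan if rb.n is None else rb.n,
            }
        )
    if n_dropped_alleles:
        logger.info("harmonize_pair: %d variants with irreconcilable alleles dropped", n_dropped_alleles)
    if n_dropped_palindromic:
        logger.info("harmonize_pair: %d ambiguous palindromic variants dropped", n_dropped_palindromic)
    cols = [
        "variant_id", "chrom", "pos", "effect_allele", "other_allele",
        "eaf_a", "beta_a", "se_a", "pvalue_a", "n_a",
        "eaf_b", "beta_b", "se_b", "pvalue_b", "n_b",
    ]
    return pd.DataFrame(rows, columns=cols)
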