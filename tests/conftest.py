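import numpy as np
import pytest

from cismr.sumstats import StudySumstats, VariantAssoc


def make_record(vid="rs1", chrom="1", pos=100, ea="A", nea="G",
                beta=0.1, se=0.05, p=None, eaf=0.3, n=1000):
    from scipy import stats

    if p is None:
        p = 2 * stats.norm.sf(abs(beta / se))
    return VariantAssoc(
        variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea,
        other_allele=nea, beta=beta, se=se, pvalue=p, eaf=eaf, n=n,
    )


@pytest.fixture
def small_study():
    recs = [
        make_record("rs1", pos=100, beta=0.10, se=0.02, eaf=0.30),
        make_record("rs2", pos=200, ea="C", nea="T", beta=-0.05, se=0.02, eaf=0.60),
        make_record("rs3", pos=300, ea="G", nea="T", beta=0.20, se=0.03, eaf=0.10),
    ]
    return StudySumstats(trait_name="toy", records=recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
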