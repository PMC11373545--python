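import numpy as np
import pytest
from hypothesis import settings

from protmr.core_io import SummaryStats, VariantAssociation
from protmr.instruments import HarmonizedSet

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


def make_assoc(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=None,
    n=5000,
):
    """A valid VariantAssociation with a consistent p-value unless given."""
    from scipy import stats

    if pval is None:
        z = abs(beta / se) if se > 0 else 0.0
        pval = float(max(2 * stats.norm.sf(z), np.nextafter(0, 1)))
    return VariantAssociation(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def make_sumstats(betas, ses=None, name="trait", start_pos=1_000_000, chrom="1", **kw):
    ses = ses if ses is not None else [0.01] * len(betas)
    assocs = [
        make_assoc(
            variant_id=f"rs{i + 1}",
            chrom=chrom,
            pos=start_pos + i * 100_000,
            beta=b,
            se=s,
            **kw,
        )
        for i, (b, s) in enumerate(zip(betas, ses))
    ]
    return SummaryStats(trait_name=name, associations=assocs)


@pytest.fixture
def ratio_set():
    """Harmonized set whose Wald ratios are exactly 0.1, 0.2, 0.3, 0.4 with
    equal outcome SEs and unit exposure effects."""
    return HarmonizedSet.from_arrays(
        beta_exp=[1.0, 1.0, 1.0, 1.0],
        se_exp=[0.01] * 4,
        beta_out=[0.1, 0.2, 0.3, 0.4],
        se_out=[0.05] * 4,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
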