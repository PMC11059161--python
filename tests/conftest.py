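import numpy as np
import pytest

from pqtlmr.summary_io import AssocRecord, RegionStats, VariantKey


def make_variant(rsid="rs1", chrom="1", pos=100, ea="A", oa="G"):
    return VariantKey(chrom=chrom, pos=pos, rsid=rsid, effect_allele=ea, other_allele=oa)


def make_record(
    rsid="rs1",
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pvalue=1e-6,
    n=10_000,
    trait_id="protein",
    trait_type="quantitative",
    n_case=None,
    n_control=None,
    pos=100,
    chrom="1",
):
    return AssocRecord(
        variant=make_variant(rsid=rsid, chrom=chrom, pos=pos, ea=ea, oa=oa),
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        trait_id=trait_id,
        trait_type=trait_type,
        n_case=n_case,
        n_control=n_control,
    )


def region_from_z(z_values, trait_id="trait", se=0.02, eaf=0.3, prefix="rs"):
    """Region whose records have the given z-scores (beta = z*se)."""
    records = [
        make_record(
            rsid=f"{prefix}{i}",
            pos=1000 + i,
            beta=float(z) * se,
            se=se,
            eaf=eaf,
            pvalue=0.5,
            trait_id=trait_id,
        )
        for i, z in enumerate(np.asarray(z_values, dtype=float))
    ]
    return RegionStats(records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240429)
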