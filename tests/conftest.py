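import numpy as np
import pandas as pd
import pytest

from mr2s import HarmonizedInstrument, SummaryStatRecord


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pval=1e-20,
    n=100_000,
):
    return SummaryStatRecord(
        snp_id=snp_id,
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


def make_instrument(
    snp_id="rs1",
    beta_exp=0.1,
    se_exp=0.01,
    beta_out=0.02,
    se_out=0.005,
    ea="A",
    oa="G",
):
    return HarmonizedInstrument(
        snp_id=snp_id,
        effect_allele=ea,
        other_allele=oa,
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        eaf_exp=0.3,
        eaf_out=0.3,
        action="none",
        palindromic=False,
    )


def instruments_from_arrays(bx, by, sy, sx=None):
    sx = sx if sx is not None else np.full(len(bx), 0.01)
    return [
        make_instrument(f"rs{i}", float(bx[i]), float(sx[i]), float(by[i]), float(sy[i]))
        for i in range(len(bx))
    ]


@pytest.fixture
def identity_ld():
    def _build(records):
        ids = [r.snp_id for r in records]
        return pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)

    return _build
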