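import numpy as np
import pytest

from liabilitymr.harmonize import KEPT, HarmonizedPair, HarmonizedSet
from liabilitymr.summary_data import SummaryDataset, VariantAssociation


def make_pair(
    rsid="rs1",
    beta_exp=0.2,
    se_exp=0.02,
    beta_out=0.02,
    se_out=0.01,
    n_exp=50_000.0,
    n_out=100_000.0,
    chrom=None,
    pos=None,
    **kwargs,
):
    return HarmonizedPair(
        rsid=rsid,
        effect_allele="A",
        other_allele="G",
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        n_exp=n_exp,
        n_out=n_out,
        chrom=chrom,
        pos=pos,
        disposition=KEPT,
        **kwargs,
    )


def make_set(bx, by, sy, sx=None, condition="cond", outcome="out", chrom=None, pos=None,
             **set_kwargs):
    """Harmonized set from parallel effect/SE arrays."""
    sx = sx if sx is not None else [0.01] * len(bx)
    chroms = chrom if chrom is not None else [None] * len(bx)
    poss = pos if pos is not None else [None] * len(bx)
    pairs = [
        make_pair(
            rsid=f"rs{i + 1}",
            beta_exp=bx[i],
            se_exp=sx[i],
            beta_out=by[i],
            se_out=sy[i],
            chrom=chroms[i],
            pos=poss[i],
        )
        for i in range(len(bx))
    ]
    return HarmonizedSet(condition_id=condition, outcome_id=outcome, pairs=pairs,
                         **set_kwargs)


def make_variant(
    rsid="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-10,
    **kwargs,
):
    return VariantAssociation(
        rsid=rsid,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_set():
    return make_set(
        bx=[0.4, 0.5, 0.3, 0.25],
        by=[0.02, 0.04, 0.05, 0.01],
        sy=[0.01, 0.02, 0.015, 0.012],
        sx=[0.02, 0.03, 0.02, 0.018],
    )
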