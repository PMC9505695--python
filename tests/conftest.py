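import numpy as np
import pytest

from tsmr.summary_io import HarmonizedInstrumentSet, SummaryStatRecord


def make_record(variant_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                eaf=0.3, beta=0.05, se=0.01, pvalue=1e-9, n=100_000,
                n_cases=None, trait_id="trait"):
    rec = SummaryStatRecord(variant_id=variant_id, chrom=chrom, pos=pos,
                            effect_allele=ea, other_allele=oa, eaf=eaf,
                            beta=beta, se=se, pvalue=pvalue, n=n,
                            n_cases=n_cases, trait_id=trait_id)
    rec.validate()
    return rec


def make_hset(beta_exposure, beta_outcome, se_exposure=None, se_outcome=None,
              n_exposure=400_000, n_outcome=800_000):
    """Build a harmonized set directly from effect arrays."""
    bx = np.asarray(beta_exposure, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    J = bx.size
    sx = np.full(J, 0.002) if se_exposure is None else np.asarray(se_exposure, float)
    sy = np.full(J, 0.006) if se_outcome is None else np.asarray(se_outcome, float)
    return HarmonizedInstrumentSet(
        exposure_id="exposure", outcome_id="outcome",
        variant_ids=[f"rs{i}" for i in range(J)],
        beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy,
        eaf=np.full(J, 0.3), n_exposure=np.full(J, float(n_exposure)),
        n_outcome=np.full(J, float(n_outcome)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_hset(rng):
    """A moderately sized random instrument set with a true slope of 0.1."""
    J = 10
    bx = rng.uniform(0.02, 0.08, J)
    sy = rng.uniform(0.004, 0.01, J)
    by = 0.1 * bx + rng.normal(0, sy)
    return make_hset(bx, by, se_outcome=sy)
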