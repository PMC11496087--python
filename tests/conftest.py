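import numpy as np
import pytest

from mrmediate.gwas_io import StudySummary, SummaryStatRecord
from mrmediate.harmonize import HarmonizedInstrument
from mrmediate.synthetic import MediationScenario, simulate_mediation_scenario


def make_record(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=1e-9,
    n=10_000,
    **kwargs,
):
    return SummaryStatRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
        **kwargs,
    )


def make_study(records, trait_name="study", trait_type="quantitative"):
    study = StudySummary(trait_name, trait_type)
    for rec in records:
        study.add(rec)
    return study


def make_instruments(beta_exp, se_exp, beta_out, se_out):
    """Build harmonized instruments directly from effect arrays."""
    return [
        HarmonizedInstrument(f"v{j}", float(be), float(se), float(bo), float(so), "kept_as_is")
        for j, (be, se, bo, so) in enumerate(zip(beta_exp, se_exp, beta_out, se_out))
    ]


def random_instruments(rng, n, theta=0.2):
    """Instrument sets drawn under the IVW-true model for oracle comparisons."""
    be = rng.uniform(0.1, 0.5, n)
    se_e = rng.uniform(0.01, 0.05, n)
    se_o = rng.uniform(0.01, 0.05, n)
    bo = theta * be + se_o * rng.standard_normal(n)
    return make_instruments(be, se_e, bo, se_o)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario simulated dataset, shared across tests."""
    return simulate_mediation_scenario(MediationScenario(seed=1234))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
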