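import warnings

import numpy as np
import pytest

from rsnpscan.genome import Genome
from rsnpscan.motifs import counts_to_pwm, trim_flanks
from rsnpscan.simulate import SyntheticScenario, build_study
from rsnpscan import diffbind as db
from rsnpscan.gwas import snps_from_frame


@pytest.fixture(scope="session")
def study():
    """Default synthetic study; shared across the suite (expensive)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_study(SyntheticScenario(seed=123))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for cheap structural tests."""
    sc = SyntheticScenario(seed=7, genome_length=30_000, n_motifs=2,
                           n_null_snps=300, n_gwas_null=60, n_proxies=20,
                           n_samples=30, n_coding_genes=60,
                           n_noncoding_genes=4, partners_per_module=5,
                           n_decoy_rems=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_study(sc)


@pytest.fixture(scope="session")
def genome(study):
    return Genome({study.scenario.chrom: study.genome})


@pytest.fixture(scope="session")
def pwms(study):
    return [trim_flanks(counts_to_pwm(m)) for m in study.motifs]


@pytest.fixture(scope="session")
def null_models(study, genome, pwms):
    panel = snps_from_frame(study.snps[study.snps.truth == "null"])
    return {p.id: db.estimate_scale(p, genome, panel) for p in pwms}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
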