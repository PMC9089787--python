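import numpy as np
import pytest

import eccircle as ec
from eccircle.calling import CallerConfig, call_eccdna, extract_junction_signals


@pytest.fixture(scope="session")
def toy_ref():
    """Small two-chromosome strain pair with elements and SNPs."""
    return ec.make_genome(seed=11, n_chroms=2, lengths=[300_000, 300_000], n_snps=1800)


@pytest.fixture(scope="session")
def wt_sample(toy_ref):
    """A simulated wild-type plasma sample (200 circles + background)."""
    cfg = ec.scenario_preset("wt", seed=11, n_circles=200)
    return ec.simulate_scenario(cfg, toy_ref)


@pytest.fixture(scope="session")
def wt_calls(toy_ref, wt_sample):
    """Called loci for the wild-type sample with default caller settings."""
    cfg = CallerConfig()
    extraction = extract_junction_signals(wt_sample.fragments, toy_ref.genome_a, cfg)
    return call_eccdna(extraction.signals, cfg, wt_sample.meta)
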