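import numpy as np
import pytest

from oncotrack import synthetic_data as synth


@pytest.fixture(scope="session")
def toy_model():
    return synth.make_toy_model(12, exons_per_gene=3, n_chroms=3, seed=42)


@pytest.fixture(scope="session")
def sim_sample(toy_model, tmp_path_factory):
    """One simulated SAM sample with known CNV structure and its truth table."""
    out = tmp_path_factory.mktemp("sam")
    loci = [g.locus_id for g in toy_model]
    cnv = synth.CnvSpec(multipliers={
        loci[0]: 0.0, loci[1]: 0.5, loci[2]: 1.5, loci[3]: 2.0,
    })
    cfg = synth.SimConfig(seed=7, n_genes=len(toy_model), base_coverage=80,
                          duplicate_fraction=0.15, low_quality_fraction=0.1)
    path = out / "tumour1.sam"
    truth = synth.simulate_reads(toy_model, cnv, cfg, "tumour1", path)
    return path, truth, cnv


@pytest.fixture
def rng():
    return np.random.default_rng(0)
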