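import pandas as pd
import pytest

import talclone as tc
from talclone import cases
from talclone.markers import Marker


@pytest.fixture
def zero_noise():
    return tc.NoiseConfig()


@pytest.fixture
def noisy():
    return tc.NoiseConfig(
        allelic_dropout_rate=0.1, assay_failure_rate=0.05, ct_sd=0.15
    )


@pytest.fixture
def small_markers():
    return [
        Marker("F", "STIL_TAL1", "fusion"),
        Marker("CDKN2A_del", "CDKN2A", "cn_loss"),
        Marker("snv1", "G1", "snv"),
        Marker("snv2", "G2", "snv"),
    ]


@pytest.fixture
def case6116_truth():
    return cases.case_6116()


@pytest.fixture
def case6030_truth():
    return cases.case_6030()


def simulate_called_matrix(truth, n_cells, noise, seed, wildtype_assays=False):
    """Simulate through the Ct layer and call genotypes back."""
    gm_true, labels = tc.sample_cells(truth, n_cells, seed=seed)
    panel = tc.AssayPanel.default_for(
        truth.markers, include_wildtype_assays=wildtype_assays
    )
    ct = tc.simulate_ct_readout(gm_true, panel, noise, seed=seed + 1)
    gm = tc.build_genotype_matrix(ct, panel)
    return gm_true, gm, panel
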