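import numpy as np
import pytest

from gba import coexnet, exprmat, synthio


@pytest.fixture(scope="session")
def default_dataset() -> synthio.SyntheticDataset:
    """The default synthetic study: 2000 genes, 5 modules x 50, fold 8,
    phi = 0.168531, 4 tissues x 2 replicates, seed 42."""
    return synthio.simulate_dataset(synthio.SimConfig())


@pytest.fixture(scope="session")
def default_network_inputs(default_dataset):
    """log2(TPM+1), PCC and HRR matrices of the default study, shared across
    the heavier network tests."""
    ds = default_dataset
    tpm = exprmat.compute_tpm(ds.counts)
    kept = exprmat.filter_low_expression(tpm, 5.0)
    log_expr = exprmat.log_transform(kept)
    corr = coexnet.pcc_matrix(log_expr)
    hrr = coexnet.hrr(coexnet.rank_neighbors(corr))
    return {"tpm": tpm, "log_expr": log_expr, "corr": corr, "hrr": hrr}


@pytest.fixture(scope="session")
def default_baits(default_dataset):
    """Three baits per planted module: the known pathway genes a study would
    anchor its guilt-by-association search on."""
    truth = default_dataset.truth
    baits = []
    per_module: dict[int, int] = {}
    for g in sorted(truth.module_of):
        m = truth.module_of[g]
        if m is not None and per_module.get(m, 0) < 3:
            baits.append(g)
            per_module[m] = per_module.get(m, 0) + 1
    return baits
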