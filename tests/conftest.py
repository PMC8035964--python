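import numpy as np
import pytest

import bacloc as bl


@pytest.fixture(scope="session")
def small_dataset():
    """A small but learnable synthetic gram-negative dataset."""
    cfg = bl.preset_config("gram_negative", n=150, seed=42)
    return bl.generate(cfg)


@pytest.fixture(scope="session")
def small_cv_result(small_dataset):
    """CV over the PSSM/GO views plus their consensus on the small dataset."""
    from bacloc.features import acc_matrix
    from bacloc.metrics import cv_run

    ds = small_dataset
    pssm = acc_matrix([ds.profiles[r.id] for r in ds.records])
    return cv_run(
        ds.labels,
        pssm=pssm,
        go_annotations=ds.annotations,
        variants=("pssm", "go_ppv", "consensus_pssm_go"),
        seed=42,
        n_estimators=100,
    )
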