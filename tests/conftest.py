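import numpy as np
import pytest

from prgscan import build_and_calibrate, make_reference_set
from prgscan.model import ProfileHMM


@pytest.fixture(scope="session")
def refset():
    """One synthetic reference set shared by the pipeline-level tests."""
    return make_reference_set(seed=3)


@pytest.fixture(scope="session")
def calibrated_models(refset):
    models, rejections = build_and_calibrate(refset.class_msas, refset.regions)
    assert not rejections
    return models


def degenerate_hmm(consensus: str, background=None) -> ProfileHMM:
    """All emission/transition mass on the consensus path (for oracle tests)."""
    M = len(consensus)
    from prgscan.seqio import AA_ALPHABET

    me = np.zeros((M, 20))
    for j, res in enumerate(consensus):
        me[j, AA_ALPHABET.index(res)] = 1.0
    bg = np.full(20, 1 / 20) if background is None else np.asarray(background)
    transitions = {
        "mm": np.ones(M), "mi": np.zeros(M), "md": np.zeros(M),
        "im": np.ones(M), "ii": np.zeros(M),
        "dm": np.ones(M), "dd": np.zeros(M),
    }
    return ProfileHMM(
        name=f"degenerate_{consensus}",
        class_of_origin="TNL",
        domain_label="NBS",
        match_emissions=me,
        insert_emissions=bg.copy(),
        transitions=transitions,
        background=bg,
    )
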