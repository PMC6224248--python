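import numpy as np
import pytest

from locoage import markov, simulate_cohort
from locoage.pipeline import _descriptor_frame


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (n=2000, 7-day tracks), shared across tests."""
    cohort, tracks = simulate_cohort(2000, seed=0)
    return cohort, tracks


@pytest.fixture(scope="session")
def default_descriptors(default_cohort):
    """Descriptor matrix and aligned metadata for the default cohort."""
    cohort, tracks = default_cohort
    scheme = markov.DiscretizationScheme()
    df = _descriptor_frame(tracks, scheme)
    meta = cohort.set_index("participant_id").loc[df["participant_id"]]
    return {
        "df": df,
        "X": df[markov.descriptor_names()].to_numpy(),
        "ages": meta["age"].to_numpy(),
        "genders": meta["gender"].to_numpy(),
        "meta": meta,
        "cohort": cohort,
    }


@pytest.fixture
def two_state_tm():
    """Hand-solvable two-state chain: pi = (2/3, 1/3), one relaxation rate 0.3."""
    from locoage import TransitionModel

    return TransitionModel.from_matrix(np.array([[0.9, 0.2], [0.1, 0.8]]))
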