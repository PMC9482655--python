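import warnings

import numpy as np
import pytest

from istfold.classify import classify
from istfold.sse import assign_sse
from istfold.synth import MimicSpec, make_ist_mimic, synthetic_spaca6

warnings.filterwarnings("ignore", message=".*missing backbone.*")


@pytest.fixture(scope="session")
def reference():
    """Synthetic SPACA6-architecture reference model with ground truth."""
    return synthetic_spaca6()


@pytest.fixture(scope="session")
def reference_annotation(reference):
    st, _ = reference
    return assign_sse(st, "A")


@pytest.fixture(scope="session")
def reference_report(reference):
    st, _ = reference
    return classify(st)


@pytest.fixture(scope="session")
def positive_mimic():
    return make_ist_mimic(MimicSpec())


def random_rigid_motion(seed: int):
    """Deterministic random rotation + translation."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=20.0, size=3)
    return Q, t
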