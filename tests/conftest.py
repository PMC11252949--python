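import numpy as np
import pytest

import lacdiff as ld


@pytest.fixture(scope="session")
def scheme():
    """The study acquisition: 10 b-values over 0.02-20 ms/um^2, t_d 53.2 ms."""
    return ld.default_scheme()


@pytest.fixture(scope="session")
def default_micro():
    return ld.MicrostructureParams(D_intra=0.40, r_soma=3.1, f_sphere=0.5)


@pytest.fixture()
def noiseless_pooled(scheme, default_micro):
    """Noiseless pooled intracellular curve at the reference parameters."""
    S = np.atleast_1d(ld.sticks_spheres_signal(
        scheme, scheme.b_values, default_micro.D_intra,
        default_micro.r_soma, default_micro.f_sphere))
    return ld.AttenuationCurve(
        metabolite="pooled", subject_id="ref", group="synthetic",
        b=scheme.b_values, S=S / S[0])
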