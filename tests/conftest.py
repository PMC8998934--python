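import numpy as np
import pytest

from t2flux import PhantomSpec, build_label_map, render_echo_stack

DEFAULT_TES = np.array([12.5, 29.2, 45.8, 62.5, 79.2, 95.8, 112.5, 129.2, 145.8, 162.5])


@pytest.fixture(scope="session")
def te_list() -> np.ndarray:
    return DEFAULT_TES.copy()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Down-scaled acquisition grid; geometry constants keep their defaults."""
    return PhantomSpec(matrix_size=(32, 32), n_slices=4)


@pytest.fixture(scope="session")
def noiseless_phantom(small_spec):
    """(label_map, stack) of a noiseless week-6 session on the small grid."""
    label_map = build_label_map(small_spec, session_week=6)
    stack = render_echo_stack(label_map, small_spec)
    return label_map, stack
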