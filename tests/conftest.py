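import numpy as np
import pytest

from bistablernn.cells import CellWeights, GRUWeights


def zero_cell(kind: str, input_dim: int, hidden: int) -> CellWeights:
    """All-zero BRC/nBRC weights: gates come out at a=1, c=0.5."""
    z = lambda *s: np.zeros(s)
    kw = dict(kind=kind, input_dim=input_dim, hidden=hidden,
              U=z(input_dim, hidden), U_a=z(input_dim, hidden),
              U_c=z(input_dim, hidden), b=z(hidden), b_a=z(hidden),
              b_c=z(hidden))
    if kind == "brc":
        kw.update(w_a=z(hidden), w_c=z(hidden))
    else:
        kw.update(W_a=z(hidden, hidden), W_c=z(hidden, hidden))
    return CellWeights(**kw)


def zero_gru(input_dim: int, hidden: int) -> GRUWeights:
    z = lambda *s: np.zeros(s)
    return GRUWeights(input_dim=input_dim, hidden=hidden,
                      U_z=z(input_dim, hidden), U_r=z(input_dim, hidden),
                      U_h=z(input_dim, hidden), W_z=z(hidden, hidden),
                      W_r=z(hidden, hidden), W_h=z(hidden, hidden),
                      b_z=z(hidden), b_r=z(hidden), b_h=z(hidden))


def scalar_brc(a_pre: float = 0.0, c_pre: float = 0.0) -> CellWeights:
    """1-neuron BRC whose gate pre-activations are pinned by biases, so the
    effective (a, c) are known in closed form (no input/recurrent gate
    drive)."""
    w = zero_cell("brc", 1, 1)
    w.b_a[:] = a_pre
    w.b_c[:] = c_pre
    return w


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
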