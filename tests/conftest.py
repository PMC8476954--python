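import numpy as np
import pandas as pd
import pytest

from sitmotif import synthetic_data as syn
from sitmotif import ticc
from sitmotif.cop_io import COPSeries


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_cop_series(x, y, present=None) -> COPSeries:
    x = np.asarray(x, dtype=float)
    present = np.ones(len(x), dtype=bool) if present is None else np.asarray(present)
    xs = np.where(present, x, np.nan)
    ys = np.where(present, np.asarray(y, dtype=float), np.nan)
    return COPSeries(samples=pd.DataFrame(
        {"t": np.arange(len(x), dtype=float), "x": xs, "y": ys, "present": present}))


@pytest.fixture(scope="session")
def two_state_fit():
    """A fitted 2-state segmentation with its ground truth (session-cached)."""
    specs = syn.demo_state_specs(2)
    seq, _ = syn.simulate_state_sequence(
        specs, 1500, dwell=60, seed=7, transitions=syn.uniform_transitions(2))
    cop = syn.emit_cop(seq, specs, seed=8)
    X, idx = ticc.stack_windows(cop, 5)
    model = ticc.fit_ticc(X, ticc.TICCConfig(K=2, seed=0))
    return {"specs": specs, "seq": seq, "windows": X, "idx": idx, "model": model}
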