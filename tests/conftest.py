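import numpy as np
import pandas as pd
import pytest

from humdea import FactorDef, FactorPanel, ModelSpec


def make_panel(X, Y, dmus=None, periods=("t1",), in_prefix="I", out_prefix="O"):
    """Single-period-per-block panel from (n, m) input and (n, r) output arrays.

    X, Y may be 2-D (one period) or dicts period -> array.
    """
    if not isinstance(X, dict):
        X = {periods[0]: X}
        Y = {periods[0]: Y}
    X = {t: np.asarray(v, dtype=float) for t, v in X.items()}
    Y = {t: np.asarray(v, dtype=float) for t, v in Y.items()}
    periods = list(X.keys())
    n = next(iter(X.values())).shape[0]
    m = next(iter(X.values())).shape[1]
    r = next(iter(Y.values())).shape[1]
    dmus = list(dmus) if dmus else [f"D{i+1}" for i in range(n)]
    in_ids = [f"{in_prefix}{k+1}" for k in range(m)]
    out_ids = [f"{out_prefix}{k+1}" for k in range(r)]
    rows = []
    for t in periods:
        for i in range(n):
            rows.append((dmus[i], t, *X[t][i], *Y[t][i]))
    frame = pd.DataFrame(rows, columns=["dmu", "period", *in_ids, *out_ids]).set_index(["dmu", "period"])
    factors = [FactorDef(f, "input") for f in in_ids] + [FactorDef(f, "output") for f in out_ids]
    return FactorPanel(dmus, periods, factors, frame)


@pytest.fixture
def abc_panel():
    """1 input / 1 output: A(2,2), B(4,8), C(8,8)."""
    return make_panel([[2], [4], [8]], [[2], [8], [8]], dmus=["A", "B", "C"])


@pytest.fixture
def crs_output():
    return ModelSpec("ccr", "output", "crs")


@pytest.fixture
def vrs_output():
    return ModelSpec("bcc", "output", "vrs")


def random_panel(seed, n=8, m=2, r=3, periods=1):
    rng = np.random.default_rng(seed)
    X = {f"t{t+1}": rng.uniform(1, 10, (n, m)) for t in range(periods)}
    Y = {f"t{t+1}": rng.uniform(1, 10, (n, r)) for t in range(periods)}
    return make_panel(X, Y)
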