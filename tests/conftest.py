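import numpy as np
import pytest
from hypothesis import settings

from eemlearn.eem_data import EEM, WavelengthGrid

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def small_grids():
    """A desk-scale grid pair: 12 emission x 10 excitation points, 10 nm step."""
    ex = WavelengthGrid(250.0, 340.0, 10.0)
    em = WavelengthGrid(260.0, 370.0, 10.0)
    return ex, em


@pytest.fixture
def small_eem(small_grids):
    ex, em = small_grids
    rng = np.random.default_rng(7)
    intensity = rng.uniform(1.0, 10.0, size=(len(em), len(ex)))
    return EEM(sample_id="s0", ex_grid=ex, em_grid=em, intensity=intensity)


def nipals_pls1(X, y, n_components):
    """Independent single-block PLS1 oracle (classic NIPALS with p-deflation).

    Returns (scores, fitted, predict_fn). Kept deliberately separate from the
    package's tri-linear implementation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xr = X - x_mean
    yr = y - y_mean
    W, P, C, T = [], [], [], []
    for _ in range(n_components):
        w = Xr.T @ yr
        w = w / np.linalg.norm(w)
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        c = yr @ t / (t @ t)
        Xr = Xr - np.outer(t, p)
        yr = yr - t * c
        W.append(w), P.append(p), C.append(c), T.append(t)
    T = np.column_stack(T)
    c_vec = np.array(C)
    fitted = y_mean + T @ c_vec

    def predict(Xnew):
        Xc = np.asarray(Xnew, float) - x_mean
        Tn = np.empty((Xc.shape[0], n_components))
        for f in range(n_components):
            t = Xc @ W[f]
            Tn[:, f] = t
            Xc = Xc - np.outer(t, P[f])
        return y_mean + Tn @ c_vec

    return T, fitted, predict
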