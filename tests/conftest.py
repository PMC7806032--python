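import numpy as np
import pytest

from perchsense.config import load_config
from perchsense.mechanics import run_trial


def smoke_config():
    """Scaled-down config for fast integration tests: short trials, few
    bootstrap iterations, windows that fit the shortened recordings."""
    cfg = load_config(fast=True)
    cfg["protocol"]["n_moves"] = 50  # 25 s recordings
    cfg["analysis"].update(n_iter=5, window_s=10.0, train_samples=4000)
    cfg["analysis"]["stiffness"].update(n_iter=10, segment_s=10.0)
    return cfg


@pytest.fixture(scope="session")
def cfg():
    return smoke_config()


@pytest.fixture(scope="session")
def recording(cfg):
    """One mid-size trial recording shared across estimator tests (60 s)."""
    return run_trial(radius_m=0.01, neck_preset="low", n_moves=120, seed=5, config=cfg)


@pytest.fixture(scope="session")
def noiseless_recording(recording):
    """The same trial without sensor noise (provenance copy)."""
    import dataclasses

    nl = recording.meta["noiseless"]
    return dataclasses.replace(
        recording, foot=nl["foot"], hip=nl["hip"], head=nl["head"], meta={"noise_sd": 0.0}
    )


def simulate_lti(A, B, C, D, u, x0=None):
    """Independent brute-force simulator used as an oracle in tests."""
    n = A.shape[0]
    x = np.zeros(n) if x0 is None else np.asarray(x0, float)
    y = np.empty((u.shape[0], C.shape[0]))
    for k in range(u.shape[0]):
        y[k] = C @ x + D @ u[k]
        x = A @ x + B @ u[k]
    return y


def random_stable_system(rng, n=3, m=3, p=3, rho=0.8):
    """Random stable discrete-time system with spectral radius ``rho``."""
    A = rng.standard_normal((n, n))
    A *= rho / np.max(np.abs(np.linalg.eigvals(A)))
    return A, rng.standard_normal((n, m)), rng.standard_normal((p, n)), rng.standard_normal((p, m))
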