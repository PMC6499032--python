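"""Shared fixtures: seeded SPD matrices and synthetic sessions.

Session-scoped fixtures cache the expensive pieces (model fits, processed
recordings) so that sensitivity, specificity and efficiency checks reuse
one computation.
"""

import numpy as np
import pytest

from rasr import ASRModel, SessionConfig, generate_session


def random_spd(rng, c, spread=1.0):
    """A well-conditioned random SPD matrix of dimension c."""
    A = rng.standard_normal((c, c))
    Q, _ = np.linalg.qr(A)
    lam = np.exp(spread * rng.standard_normal(c))
    return (Q * lam) @ Q.T


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def session():
    """Fixed-seed synthetic session (24 ch, 250 Hz, 240 s task)."""
    return generate_session(SessionConfig(), seed=1)


@pytest.fixture(scope="session")
def short_session():
    """Small session for fast functional tests (30 s task)."""
    return generate_session(SessionConfig(task_s=30.0), seed=7)


@pytest.fixture(scope="session")
def fitted(session):
    """Both models fitted on the session's calibration minute."""
    return {m: ASRModel(session.calibration, method=m).fit()
            for m in ("asr", "rasr")}


@pytest.fixture(scope="session")
def corrected(session, fitted):
    """Task recording corrected by both methods, with run states."""
    out = {}
    for m, res in fitted.items():
        cleaned = res.process(session.task)
        out[m] = (cleaned, res.last_state)
    return out
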