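"""Shared fixtures: synthetic sessions at desk-scale sampling rates."""

import numpy as np
import pytest

from adkit.synth import SynthConfig, generate_session

#: reduced sampling rates used throughout the suite to keep runtime small;
#: the generator defaults (1 kHz) are exercised in the detector tests
FAST_RATES = dict(eeg_rate=200.0, eye_rate=250.0)


@pytest.fixture(scope="session")
def coupled_session():
    """One full 2-h session with the default (arousal-consistent) couplings."""
    cfg = SynthConfig(session_duration=120.0, seed=7, **FAST_RATES)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_session():
    """A cheap 36-min session for I/O and plumbing tests."""
    cfg = SynthConfig(session_duration=36.0, latent_timescale_sd=10.0,
                      n_neurons=12, seed=5, **FAST_RATES)
    return generate_session(cfg)


def match_events(true_onsets, detected_onsets, tol_s=0.010):
    """Greedy one-to-one matching of event onsets within a tolerance.

    Returns the number of matches (used for recall/precision).
    """
    det = np.asarray(detected_onsets, float)
    used = np.zeros(det.size, bool)
    matched = 0
    for t in np.asarray(true_onsets, float):
        if det.size == 0:
            break
        d = np.abs(det - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            used[j] = True
            matched += 1
    return matched
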