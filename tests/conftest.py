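import numpy as np
import pytest

from motorseq import OperantSession, Phase


def make_session(presses=(), entries=(), licks=(), reinforcers=(), duration=None,
                 phase=Phase.FR8_SELFPACED, **kwargs):
    presses = np.asarray(presses, dtype=float)
    events = [a for a in (presses, entries, licks, reinforcers) if len(a)]
    if duration is None:
        duration = max((float(np.max(a)) for a in events), default=0.0) + 10.0
    return OperantSession(
        session_id=kwargs.pop("session_id", "t"),
        animal_id="a",
        genotype_label="ctrl",
        phase=phase,
        session_duration=duration,
        press_times=presses,
        entry_times=np.asarray(entries, dtype=float),
        lick_times=np.asarray(licks, dtype=float),
        reinforcer_times=np.asarray(reinforcers, dtype=float),
        **kwargs,
    )


@pytest.fixture
def session_factory():
    return make_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
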