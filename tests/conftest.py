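import numpy as np
import pytest

from choicehist import synthetic_data as synth


@pytest.fixture(scope="session")
def null_observer():
    """One 416-trial session from a bias-free observer (all history weights 0)."""
    design = synth.generate_design(seed=11)
    return synth.simulate_observer(design, synth.ObserverParams(), seed=12)


@pytest.fixture(scope="session")
def repeater_observer():
    """A long session from an observer with strong response-repetition bias."""
    design = synth.generate_design(n_reps=160, seed=21)
    params = synth.ObserverParams(hist_resp_weight=0.6)
    return synth.simulate_observer(design, params, seed=22)


@pytest.fixture(scope="session")
def conf_biased_observer():
    """A long session from an observer with strong confidence-history bias."""
    design = synth.generate_design(n_reps=160, seed=31)
    params = synth.ObserverParams(hist_conf_weight=0.5)
    return synth.simulate_observer(design, params, seed=32)
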