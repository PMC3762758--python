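import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hybridbci import erd as erd_mod
from hybridbci.signals import TrialSet, bandpass_window
from hybridbci.synth import SynthConfig, gen_erd_trials

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def erd_trainset():
    """20+20 synthetic motor-imagery trials, band-passed 8-30 Hz."""
    cfg = SynthConfig(seed=7, snr=1.0)
    ts = gen_erd_trials(cfg, 20, 20, attenuation=0.7)
    return TrialSet([bandpass_window(w, *erd_mod.ERD_BAND)
                     for w in ts.windows], "ERD")


@pytest.fixture(scope="session")
def erd_models(erd_trainset):
    """CSP model + linear SVM fitted on the session train set."""
    active = TrialSet([w for w in erd_trainset.windows
                       if w.label == "active"], "ERD")
    idle = TrialSet([w for w in erd_trainset.windows
                     if w.label == "idle"], "ERD")
    csp = erd_mod.fit_csp(active, idle)
    feats = np.stack([erd_mod.csp_features(csp, w)
                      for w in erd_trainset.windows])
    clf = erd_mod.train_erd(feats, erd_trainset.y)
    return csp, clf


@pytest.fixture(scope="session")
def trained_decoders():
    """Full decoder stack (CSP+SVM, selector) for arbitration tests."""
    from hybridbci.closedloop import train_decoders
    return train_decoders(seed=3)
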