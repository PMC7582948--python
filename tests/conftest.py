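import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import threatcode as tc
from threatcode.synthetic import fear_drive_levels

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def task_cfg():
    return tc.TaskConfig()


def make_session(specs, seed, behavior=None, cfg=None, group="con", rat="rat00"):
    """One synthetic session with the given unit specs; returns (bundle, s_true)."""
    cfg = cfg or tc.TaskConfig()
    behavior = behavior or tc.BehaviorParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    trials = tc.generate_trial_schedule(cfg, rng)
    pokes, s_true = tc.simulate_behavior(trials, behavior, cfg, rng)
    units = {}
    for ui, spec in enumerate(specs):
        levels = fear_drive_levels(trials, pokes, s_true, cfg, spec.fear_drive)
        urng = np.random.default_rng(np.random.SeedSequence([seed, 1, ui]))
        units[f"u{ui:02d}"] = tc.simulate_unit(trials, spec, levels, cfg, urng)
    meta = tc.SessionMeta(rat=rat, group=group, session="s00", seed=seed)
    bundle = tc.SessionBundle(trials=trials, pokes=pokes, units=units, meta=meta)
    return bundle, s_true


@pytest.fixture(scope="session")
def trained_bundle():
    """A session holding an excited, an inhibited and an unresponsive unit."""
    specs = [
        tc.UnitSpec(label="excited", baseline_rate=5.0, threat_gain=4.0),
        tc.UnitSpec(label="inhibited", baseline_rate=8.0, threat_gain=4.0),
        tc.UnitSpec(label="none", baseline_rate=5.0, threat_gain=0.0, fear_gain=0.0,
                    trial_noise_sd=0.0),
    ]
    bundle, s_true = make_session(specs, seed=2024)
    return bundle
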