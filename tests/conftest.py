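import numpy as np
import pytest
from hypothesis import settings

import microsem as m

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

SEED = 1


@pytest.fixture(scope="session")
def spec():
    """Reference two-group ground-truth specification."""
    return m.default_spec(seed=SEED)


@pytest.fixture(scope="session")
def gt_templates(spec):
    return spec.templates_by_group["HC"], spec.templates_by_group["SCZ"]


@pytest.fixture(scope="session")
def cohort(spec):
    """14+14 subjects, 120 s each, at reference noise (shared, heavy)."""
    return m.simulate_cohort(spec, subjects_per_group=14, duration_s=120.0,
                             seed=SEED)


@pytest.fixture(scope="session")
def fitted_templates(spec, cohort):
    """Group template sets recovered from the cohort by the full pipeline."""
    recs = [c.record for c in cohort]
    ref = spec.templates_by_group["HC"]
    hc = m.fit_group_templates([r for r in recs if r.group == "HC"], "HC",
                               seed=SEED, reference=ref)
    scz = m.fit_group_templates([r for r in recs if r.group == "SCZ"], "SCZ",
                                seed=SEED, reference=ref)
    return hc, scz


def make_segment(data, fs=250.0, group="unknown", subject_id="s0"):
    return m.EEGSegment(data=np.asarray(data, float), fs=fs,
                        channel_names=[f"ch{i}" for i in range(len(data))],
                        subject_id=subject_id, group=group)
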