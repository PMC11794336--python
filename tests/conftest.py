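import numpy as np
import pytest

from msrobust.data_model import standard_1010_montage
from msrobust.headmodel import HeadModel


@pytest.fixture(scope="session")
def montage19():
    return standard_1010_montage(19)


@pytest.fixture(scope="session")
def montage62():
    return standard_1010_montage(62)


@pytest.fixture(scope="session")
def montage12():
    return standard_1010_montage(12)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def default_session():
    """One full synthetic session at the default study conditions."""
    from msrobust.synthetic import SimulationConfig, make_session

    return make_session(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def conditioned_subject(default_session):
    """The default session after filtering, epoch screen, average reference,
    ICA and IC classification — shared by the cleaning-stage tests."""
    from msrobust import preprocess as pp
    from msrobust import ica_clean as ic

    rec, gt = default_session
    r = pp.apply_zero_phase_filter(rec, pp.HIGHPASS_1HZ)
    r = pp.apply_zero_phase_filter(r, pp.LOWPASS_45HZ)
    keep = pp.reject_extreme_epochs(r)
    r = pp.average_reference(r)
    dec = ic.fit_ica(r, seed=1, max_iter=200)
    table = ic.build_ic_table(dec, r.fs, r.montage)
    return {"rec": r, "keep": keep, "gt": gt, "dec": dec, "table": table}
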