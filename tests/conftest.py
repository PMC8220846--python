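import numpy as np
import pytest

from gaitpress import features as ft
from gaitpress import gait_synth as gs


@pytest.fixture(scope="session")
def two_subjects_per_class():
    """Small roster: two children per gait class, fixed anthropometrics."""
    subs = []
    for i, diag in enumerate(("normal", "toe_in", "toe_out", "flat")):
        fpa = {"normal": 10.0, "toe_in": -8.0, "toe_out": 25.0, "flat": 8.0}[diag]
        for j in range(2):
            subs.append(
                gs.SubjectParams(
                    subject_id=f"{diag}_{j}",
                    mass=22.0 + 4.0 * i + 3.0 * j,
                    cadence=2.0,
                    fpa=fpa,
                    diagnosis=diag,
                )
            )
    return subs


@pytest.fixture(scope="session")
def dynamic_features(two_subjects_per_class):
    """Feature table of a small balanced dynamic dataset (40/class)."""
    cfg = gs.SimConfig(section="dynamic", seed=11)
    recs, _ = gs.make_dataset(40, two_subjects_per_class, cfg, seed=11)
    df = ft.extract_features(recs)
    return ft.feature_matrix(df)


@pytest.fixture(scope="session")
def static_features(two_subjects_per_class):
    """Feature table of a small balanced static dataset (40/class)."""
    cfg = gs.SimConfig(section="static", seed=12)
    recs, _ = gs.make_dataset(40, two_subjects_per_class, cfg, seed=12)
    df = ft.extract_features(recs)
    return ft.feature_matrix(df)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
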