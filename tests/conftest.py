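import numpy as np
import pytest

from vkmet import chemometrics as chem
from vkmet import features, simdata


def control_model_subtable(table):
    """Restrict a four-group table to the control/model comparison."""
    mask = table.sample_mask("control") | table.sample_mask("model")
    return features.FeatureTable(
        table.feature_ids,
        table.mz,
        table.rt,
        table.intensities[:, mask],
        [s for s, m in zip(table.sample_ids, mask) if m],
        [g for g, m in zip(table.groups, mask) if m],
        table.is_qc[mask],
    )


def fit_study(study, seed=0):
    """Pareto-scale the control/model block and fit OPLS-DA."""
    sub = control_model_subtable(study.table)
    scaled = features.pareto_scale(sub)
    model = chem.fit_oplsda(scaled, sub.groups, seed=seed)
    return sub, scaled, model


@pytest.fixture(scope="session")
def study7():
    """Default synthetic four-group study at seed 7."""
    return simdata.generate_feature_study(simdata.SimParams(seed=7))


@pytest.fixture
def toy_table():
    """3-feature x 4-sample hand table (control/model, no QC)."""
    return features.FeatureTable(
        ["f1", "f2", "f3"],
        np.array([100.0, 200.0, 300.0]),
        np.array([1.0, 2.0, 3.0]),
        np.array([[10.0, 12.0, 20.0, 22.0],
                  [5.0, 5.0, 5.0, 5.0],
                  [8.0, 6.0, 2.0, 4.0]]),
        ["c1", "c2", "m1", "m2"],
        ["control", "control", "model", "model"],
        np.zeros(4, bool),
    )
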