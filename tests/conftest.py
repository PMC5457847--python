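import numpy as np
import pytest

import riskmir as rm


@pytest.fixture(scope="session")
def small_bundle() -> rm.SimulationBundle:
    """Scaled-down planted bundle for fast pipeline-level tests."""
    cfg = rm.SimulationConfig(
        n_genes=400,
        n_mirnas=40,
        n_pathways=8,
        pathway_size_range=(8, 12),
        target_density=8.0,
        n_rat_mirnas=40,
        seed=11,
    )
    return rm.simulate_bundle(cfg)


def make_study(case: np.ndarray, control: np.ndarray, feature_ids=None, platform="mRNA", study_id="t"):
    """Study from explicit per-group matrices (features x samples)."""
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n_feat = case.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i + 1}" for i in range(n_feat)]
    values = np.hstack([case, control])
    sample_ids = [f"c{i}" for i in range(case.shape[1])] + [f"n{i}" for i in range(control.shape[1])]
    labels = np.array(["case"] * case.shape[1] + ["control"] * control.shape[1], dtype=object)
    return rm.ExpressionStudy(study_id, platform, list(feature_ids), sample_ids, values, labels)


@pytest.fixture
def study_factory():
    return make_study
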