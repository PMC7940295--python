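import numpy as np
import pytest

from cystseg.core import StudyCase
from cystseg.ensemble import EnsembleModel, predict_case
from cystseg.network import NetworkConfig, build_network
from cystseg.phantom import PhantomSpec, generate_case, generate_cohort
from cystseg.preprocessing import normalize_intensity
from cystseg.training import TrainConfig, run_cross_validation, stratify_cases


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom_case():
    """A small, quick phantom with a moderate cyst load."""
    return generate_case(
        PhantomSpec(grid_shape=(48, 48, 12), target_cystic_index=0.3, seed=42)
    )


@pytest.fixture
def noiseless_case():
    return generate_case(
        PhantomSpec(grid_shape=(48, 48, 12), target_cystic_index=0.3, noise_sigma=0.0, seed=42)
    )


@pytest.fixture
def tiny_net_config():
    return NetworkConfig(kernel_schedule=[3, 3], base_filters=4, input_shape=(16, 16))


def _normalize_cohort(cases):
    return [
        StudyCase(normalize_intensity(c.image), c.kidney, dict(c.cyst_by_source))
        for c in cases
    ]


class TrainedPipeline:
    """Cross-validated ensemble trained on phantoms, shared across tests.

    20 training/validation phantoms and 6 hold-out phantoms at the 64x64
    test scale (base_filters 8, 15 epochs, 3 folds), with the ensemble's
    predictions attached to the hold-out cases under source ``auto``.
    """

    def __init__(self):
        cases = generate_cohort(26, seed=11)
        self.cases = _normalize_cohort(cases)
        self.plan = stratify_cases(self.cases, n_test=6, n_folds=3, seed=1)
        self.net_config = NetworkConfig(base_filters=8, input_shape=(64, 64))
        self.results = run_cross_validation(
            self.plan, self.cases, self.net_config, TrainConfig(epochs=15, seed=7)
        )
        members = []
        for state, _ in self.results:
            m = build_network(self.net_config, seed=0)
            m.load_state_dict(state)
            members.append(m)
        self.ensemble = EnsembleModel(members)
        by_id = {c.case_id: c for c in self.cases}
        self.test_cases = []
        for cid in self.plan.test_ids:
            c = by_id[cid]
            c.cyst_by_source["auto"] = predict_case(self.ensemble, c, normalized=True)
            self.test_cases.append(c)


@pytest.fixture(scope="session")
def trained_pipeline():
    return TrainedPipeline()
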