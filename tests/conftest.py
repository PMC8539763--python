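import pytest
from hypothesis import HealthCheck, settings

import endosyncom as es

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    return es.default_catalog()


@pytest.fixture(scope="session")
def truth(catalog):
    return es.reference_profile_truth(catalog, seed=7)


@pytest.fixture(scope="session")
def classification_from_truth(catalog, truth):
    """Classification frame built directly from the planted response classes."""
    frame = catalog.to_frame().rename(columns={"code": "strain"})
    frame["response"] = truth.response_class.loc[frame["strain"]].to_numpy()
    frame["label"] = [
        es.dose_response.CLASS_LABELS[(k, r)]
        for k, r in zip(frame["kingdom"], frame["response"])
    ]
    return frame
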