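import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset (seed 1) with the fitted pipeline,
    shared across tests that only read from it."""
    import rarebio as rb

    matrix, samples, events, truth = rb.generate(seed=1)
    norm = rb.normalize_matrix(matrix, samples)
    clf = rb.RarityClassifier().fit(norm)
    calls = clf.predict(norm)
    return {
        "matrix": norm,
        "samples": samples,
        "events": events,
        "truth": truth,
        "clf": clf,
        "calls": calls,
    }
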