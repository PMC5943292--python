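import pytest

from droptxtl import EnsembleSpec, generate_ensemble, reference_params


@pytest.fixture(scope="session")
def params():
    """Reference TXTL parameter set (crossover radius ≈ 17 μm)."""
    return reference_params()


@pytest.fixture(scope="session")
def noiseless_ensemble(params):
    """Deterministic droplet table straight off the endpoint curve."""
    spec = EnsembleSpec(n_droplets=120, params=params, noise_cv=0.0, seed=7)
    return generate_ensemble(spec)
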