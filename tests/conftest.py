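import pytest

from scfsol import fit_model, hcqs_dataset

#: standard fitting settings used across the suite
N_RESTARTS = 50
FIT_SEED = 1


class FitCache:
    """Lazily fit each model once per session with the standard settings."""

    def __init__(self, ds):
        self.ds = ds
        self._cache = {}

    def __getitem__(self, name):
        if name not in self._cache:
            self._cache[name] = fit_model(
                name, self.ds, n_restarts=N_RESTARTS, seed=FIT_SEED
            )
        return self._cache[name]


@pytest.fixture(scope="session")
def hcqs():
    ds = hcqs_dataset()
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def fits(hcqs):
    return FitCache(hcqs)
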