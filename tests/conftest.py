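import numpy as np
import pytest

import cbckit as ck


@pytest.fixture(scope="session")
def space():
    return ck.default_attributes()


@pytest.fixture(scope="session")
def prohibitions():
    return ck.default_prohibitions()


@pytest.fixture(scope="session")
def small_design(space, prohibitions):
    """A modest pooled design reused by estimation tests."""
    return ck.generate_design(
        space, prohibitions, n_versions=30, n_tasks=14, n_concepts=2, seed=101
    )


@pytest.fixture(scope="session")
def binary_space():
    """One binary attribute: the smallest nontrivial choice universe."""
    return ck.AttributeSpace((ck.Attribute("feature", ("on", "off")),))


@pytest.fixture(scope="session")
def make_manual_arrays():
    """Factory assembling a ChoiceArrays from raw matrices for oracle tests."""

    def _make(X, chosen, resp=None):
        X = np.asarray(X, dtype=float)
        chosen = np.asarray(chosen, dtype=int)
        if resp is None:
            resp = np.zeros(len(chosen), dtype=int)
        resp = np.asarray(resp, dtype=int)
        n_resp = int(resp.max()) + 1
        return ck.ChoiceArrays(
            X=X,
            chosen=chosen,
            resp=resp,
            respondent_ids=np.arange(n_resp),
            n_resp=n_resp,
        )

    return _make
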