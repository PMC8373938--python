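"""Shared fixtures: one toy bundle target and its derived inputs.

Everything is generated in-process from fixed seeds; the expensive
artefacts (mini library, threaded fragment library) are session-scoped.
"""

import numpy as np
import pytest

from cgfold import fragments, selection, synthetic


@pytest.fixture(scope="session")
def bundle_spec():
    return synthetic.three_helix_bundle()


@pytest.fixture(scope="session")
def bundle(bundle_spec):
    """(native structure, native contact map) of a 52-residue bundle."""
    return synthetic.make_toy_structure(bundle_spec, seed=11)


@pytest.fixture(scope="session")
def bundle_sse(bundle_spec):
    return synthetic.sse_prediction_from_plan(bundle_spec)


@pytest.fixture(scope="session")
def mini_library():
    return synthetic.make_mini_library(30, seed=77)


@pytest.fixture(scope="session")
def bundle_fragments(bundle, mini_library):
    native, _ = bundle
    filtered = fragments.homolog_filter(mini_library, native.sequence)
    return fragments.gapless_thread(native.sequence, native.ss, filtered)


@pytest.fixture(scope="session")
def bundle_ensemble(bundle):
    _, nmap = bundle
    return synthetic.make_predictor_ensemble(nmap, seed=5)


@pytest.fixture(scope="session")
def bundle_restraints(bundle_ensemble):
    return selection.select_restraints(bundle_ensemble, nf=20.0)
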