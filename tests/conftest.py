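"""Shared fixtures: the packaged training data and one fitted classifier.

The full fit (six matrices, LOO grid search, threshold calibration) takes
a couple of seconds, so it is session-scoped and shared by every test
that needs a realistic trained matrix set.
"""

from __future__ import annotations

import numpy as np
import pytest

from lc8motif import (
    MotifBindingClassifier,
    load_packaged_background,
    load_packaged_training,
)
from lc8motif.alphabet import AMINO_ACIDS, SCHEMES
from lc8motif.matrices import PSSM
from lc8motif.scoring import MatrixSet


@pytest.fixture(scope="session")
def training():
    return load_packaged_training()


@pytest.fixture(scope="session")
def background():
    return load_packaged_background()


@pytest.fixture(scope="session")
def fitted(training):
    X = training.binder_motifs + training.nonbinder_motifs
    y = ["binder"] * len(training.binder_motifs) + ["nonbinder"] * len(
        training.nonbinder_motifs
    )
    return MotifBindingClassifier().fit(X, y)


@pytest.fixture(scope="session")
def mset(fitted) -> MatrixSet:
    return fitted.matrix_set_


def random_pssm(rng: np.random.Generator, scheme_name: str = "identity",
                normalization: str = "background") -> PSSM:
    """A random matrix for oracle tests (anchor-masked iff nonbinder-normalized)."""
    scheme = SCHEMES[scheme_name]
    weights = rng.normal(size=(scheme.n_categories, 8))
    masked = normalization == "nonbinder"
    if masked:
        weights[:, 4:7] = 0.0
    return PSSM(scheme=scheme, normalization=normalization, weights=weights,
                anchor_masked=masked)


def random_matrix_set(rng: np.random.Generator, weights=None) -> MatrixSet:
    mats = {
        "identity_bg": random_pssm(rng, "identity", "background"),
        "identity_nb": random_pssm(rng, "identity", "nonbinder"),
        "polarity_bg": random_pssm(rng, "polarity", "background"),
        "polarity_nb": random_pssm(rng, "polarity", "nonbinder"),
        "volume_bg": random_pssm(rng, "volume", "background"),
        "volume_nb": random_pssm(rng, "volume", "nonbinder"),
    }
    if weights is None:
        weights = {
            "identity_bg": float(rng.uniform(0, 2)),
            "identity_nb": float(rng.uniform(0, 2)),
            "volume_bg": float(rng.uniform(0, 2)),
            "volume_nb": float(rng.uniform(0, 2)),
            "polarity_nb": float(rng.uniform(0, 2)),
        }
    return MatrixSet(matrices=mats, weights=weights)


def random_motif(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=8))
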