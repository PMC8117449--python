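"""Shared fixtures: acquisition tables, forward-simulated signals, and
physically valid random (D, W) tensor pairs."""

from __future__ import annotations

import numpy as np
import pytest

from fetdki import dki
from fetdki.phantom import default_acquisition


@pytest.fixture(scope="session")
def acquisition():
    """Two-shell (1000/2500 s/mm^2), 30-direction protocol with 2 b0."""
    bvals, bvecs = default_acquisition()
    return bvals, bvecs


@pytest.fixture(scope="session")
def design(acquisition):
    return dki.build_design_matrix(*acquisition)


def forward_signal(design, s0, D, w15):
    """Noise-free signal of the kurtosis model for one voxel."""
    md = float(np.trace(D) / 3.0)
    beta = np.concatenate([[np.log(s0)], dki.matrix_to_dt6(D), md**2 * np.asarray(w15)])
    return np.exp(design @ beta)


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))


def two_compartment_tensors(rng, lam_range=(0.3, 2.0)):
    """Random valid (D, w15): cumulant expansion of a 2-tensor mixture.

    A mixture of Gaussian compartments always yields a physically
    realizable diffusion/kurtosis pair with non-negative apparent kurtosis.
    """
    def rand_tensor():
        Q = random_rotation(rng)
        lam = rng.uniform(*lam_range, 3)
        return Q @ np.diag(lam) @ Q.T

    D1, D2 = rand_tensor(), rand_tensor()
    f = rng.uniform(0.3, 0.7)
    Dbar = f * D1 + (1 - f) * D2
    md = np.trace(Dbar) / 3.0

    def sym_dd(D):
        return (np.einsum("ij,kl->ijkl", D, D)
                + np.einsum("ik,jl->ijkl", D, D)
                + np.einsum("il,jk->ijkl", D, D)) / 3.0

    Wfull = 3.0 / md**2 * (f * sym_dd(D1) + (1 - f) * sym_dd(D2) - sym_dd(Dbar))
    return Dbar, dki.tensor_to_kt15(Wfull)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
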