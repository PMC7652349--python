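"""Shared fixtures: synthetic receptor families generated at session scope."""

import warnings

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from helixforge import (
    ReceptorEntry,
    evolve_family,
    make_ideal_bundle,
    mutation_rate_for_identity,
)

warnings.filterwarnings("ignore", message="All-NaN")


@pytest.fixture(scope="session")
def ancestor():
    return make_ideal_bundle(seed=1)


@pytest.fixture(scope="session")
def small_family(ancestor):
    """Six members, ~35% pairwise identity, loop indels, mild noise."""
    return evolve_family(
        ancestor, n_members=6, mutation_rate=0.4, indel_rate=0.3,
        noise_sigma=0.3, seed=5,
    )


@pytest.fixture(scope="session")
def family_with_target(ancestor):
    """Seven members; the last acts as a held-out modeling target."""
    fam = evolve_family(
        ancestor, n_members=7, mutation_rate=0.4, indel_rate=0.3,
        noise_sigma=0.3, seed=6,
    )
    member = fam.members[-1]
    target = ReceptorEntry(
        id=member.id, sequence=member.sequence,
        tm_segments=member.tm_segments, disulfides=member.disulfides,
    )
    return fam, target, fam.members[:-1]


@pytest.fixture(scope="session")
def recovery_family(ancestor):
    """Ten members at ~30% identity with loop indels (benchmark scale)."""
    return evolve_family(
        ancestor, n_members=10,
        mutation_rate=mutation_rate_for_identity(30.0),
        indel_rate=0.3, noise_sigma=0.3, seed=11,
    )


def quaternion_superpose_rmsd(P, Q):
    """Independent RMSD oracle: Horn's closed-form quaternion method.

    Builds the 4x4 key matrix from the cross-covariance of the centered
    point sets; the optimal rotation is the eigenvector of the largest
    eigenvalue. Shares no code with the SVD-based implementation.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    p = P - P.mean(axis=0)
    q = Q - Q.mean(axis=0)
    S = p.T @ q
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((p * p).sum() + (q * q).sum() - 2.0 * lam) / len(P)
    return float(np.sqrt(max(msd, 0.0)))


@pytest.fixture(scope="session")
def quaternion_rmsd():
    return quaternion_superpose_rmsd
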