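"""Shared fixtures: a small conjugate model and a mid-sized conformer pool.

The pool and its precomputed Debye curves are session-scoped because several
ensemble tests reuse them; everything is generated programmatically from
fixed seeds.
"""

import numpy as np
import pytest

import ubconj as u
from ubconj import synthetic as syn
from ubconj.pool import generate_pool


def make_conjugate_model(site: int | None = None):
    """A ubiquitin-sized and a GTPase-sized dummy body joined at a surface residue."""
    ub = syn.make_dummy_rigid_body(76, 11.8, seed=11,
                                   res_names=["ALA"] * 75 + ["GLY"])
    sub = syn.make_dummy_rigid_body(180, 16.5, seed=12, res_names=["LYS"] * 180)
    if site is None:
        # ubiquitination sites are surface-exposed: attach at the bead
        # farthest from the centroid
        d = np.linalg.norm(sub.coords - sub.coords.mean(axis=0), axis=1)
        site = int(np.argmax(d)) + 1
    return u.build_linearized_model(u.ConjugateSpec(sub, ub, site))


@pytest.fixture(scope="session")
def conjugate_model():
    return make_conjugate_model()


@pytest.fixture(scope="session")
def small_pool(conjugate_model):
    return generate_pool(conjugate_model, 60, seed=3)


@pytest.fixture(scope="session")
def big_pool(conjugate_model):
    return generate_pool(conjugate_model, 2000, seed=13)


@pytest.fixture(scope="session")
def ensemble_qgrid():
    return syn.default_qgrid(0.5, 120)


@pytest.fixture(scope="session")
def big_pool_curves(big_pool, ensemble_qgrid):
    return np.vstack([u.debye_curve(c, ensemble_qgrid).I for c in big_pool.conformers])
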