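"""Shared fixtures: small hand-built pedigrees and a simulated study."""

import numpy as np
import pytest

from pedscan import Pedigree, SimSpec, simulate_study


def ped_from(rows):
    """Build a Pedigree from (person, father, mother, sex, household) tuples,
    all in one pedigree 'P'."""
    return Pedigree.from_records(
        [
            {
                "pedigree_id": "P",
                "person_id": p,
                "father_id": f,
                "mother_id": m,
                "sex": s,
                "household_id": h,
            }
            for p, f, m, s, h in rows
        ]
    )


@pytest.fixture
def trio():
    return ped_from(
        [
            ("dad", None, None, "male", "h1"),
            ("mom", None, None, "female", "h1"),
            ("kid", "dad", "mom", "female", "h1"),
        ]
    )


@pytest.fixture
def full_sibs():
    return ped_from(
        [
            ("f", None, None, "male", "h1"),
            ("m", None, None, "female", "h1"),
            ("s1", "f", "m", "male", "h1"),
            ("s2", "f", "m", "female", "h1"),
        ]
    )


@pytest.fixture
def half_sibs():
    return ped_from(
        [
            ("f", None, None, "male", None),
            ("m1", None, None, "female", None),
            ("m2", None, None, "female", None),
            ("c1", "f", "m1", "male", None),
            ("c2", "f", "m2", "male", None),
        ]
    )


@pytest.fixture
def double_first_cousins():
    # two brothers married to two sisters; their children are double first cousins
    return ped_from(
        [
            ("gf1", None, None, "male", None),
            ("gm1", None, None, "female", None),
            ("gf2", None, None, "male", None),
            ("gm2", None, None, "female", None),
            ("b1", "gf1", "gm1", "male", None),
            ("b2", "gf1", "gm1", "male", None),
            ("s1", "gf2", "gm2", "female", None),
            ("s2", "gf2", "gm2", "female", None),
            ("c1", "b1", "s1", "male", None),
            ("c2", "b2", "s2", "female", None),
        ]
    )


@pytest.fixture
def inbred_ped():
    # child of full siblings: self-kinship (1 + 1/4) / 2 = 5/8
    return ped_from(
        [
            ("f", None, None, "male", None),
            ("m", None, None, "female", None),
            ("s1", "f", "m", "male", None),
            ("s2", "f", "m", "female", None),
            ("k", "s1", "s2", "male", None),
        ]
    )


@pytest.fixture(scope="session")
def small_study():
    """Deterministic 20-pedigree study reused across read/write tests."""
    spec = SimSpec(
        n_pedigrees=20,
        n_snps=30,
        seed=42,
        trait_missing=0.05,
        genotype_missing=0.02,
    )
    return simulate_study(spec)


def rng(seed=0):
    return np.random.default_rng(seed)
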