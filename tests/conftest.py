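"""Shared fixtures: reference model, planted loci and their projections.

Projections of full loci are the expensive step (banded global
alignment of ~10-kb sequences), so the canonical planted examples are
built once per session and shared across test modules.
"""

from __future__ import annotations

import pytest

from ervkit.align import project_locus
from ervkit.reference import build_mer11a, build_reference
from ervkit.simulate import make_locus, simulate_cohort

SMALL_COHORT_CONFIG = dict(
    n_human_shared=3, n_macaque_shared=4, n_species_specific=3,
    n_solo_ltr=1, seed=5)


@pytest.fixture(scope="session")
def model():
    return build_reference(1)


@pytest.fixture(scope="session")
def mer11a():
    return build_mer11a(1)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(dict(SMALL_COHORT_CONFIG))


@pytest.fixture(scope="session")
def planted(model, mer11a):
    """Canonical planted loci keyed by scenario name."""
    return {
        "macaque_v1": make_locus(model, profile="macaque", env_variant=1,
                                 T=10, seed=1, mer11a=mer11a),
        "macaque_v2": make_locus(model, profile="macaque", env_variant=2,
                                 T=10, seed=2, mer11a=mer11a),
        "macaque_v3": make_locus(model, profile="macaque", env_variant=3,
                                 T=10, seed=3, mer11a=mer11a),
        "human_type1": make_locus(model, profile="human", env_type="I",
                                  env_variant=0, T=5, seed=1,
                                  human_gag_ins=False),
        "disrupted": make_locus(model, profile="macaque", env_variant=1,
                                T=8, seed=11, mer11a=mer11a,
                                disrupt_gag=True, disrupt_pol=True,
                                disrupt_env=True),
    }


@pytest.fixture(scope="session")
def projections(planted, model):
    """Reference projections of the canonical planted loci."""
    ref = model.provirus_seq
    return {name: project_locus(pl.seq, ref, locus_id=name)
            for name, pl in planted.items()}
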