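from __future__ import annotations

import numpy as np
import pytest

from rdrpscout import profilehmm as phmm
from rdrpscout import synthetic as syn


@pytest.fixture(scope="session")
def small_family() -> syn.FamilySim:
    """A 10-member family with a 150-aa core, GDD motif, moderate divergence."""
    return syn.simulate_family(
        n_members=10, core_len_aa=150, divergence=0.3, triplet="GDD", seed=101, name="famA"
    )


@pytest.fixture(scope="session")
def small_profile(small_family) -> phmm.ProfileHMM:
    prof = phmm.build_profile(
        small_family.seed_alignment, motif_anchor_seed_col=small_family.anchor_col
    )
    return phmm.calibrate_profile(prof, n_decoys=2000, decoy_len=200, seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
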