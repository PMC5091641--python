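import numpy as np
import pytest

from clanseeker import ScoringParams, build_profile, msa_from_string

UNIFORM_BG = np.full(20, 0.05)


@pytest.fixture
def uniform_params() -> ScoringParams:
    return ScoringParams(background=UNIFORM_BG.copy())


def pure_profile(residues: str, ss=None, id: str = "p"):
    """Profile with one pure-frequency column per residue (alpha = 0)."""
    msa = msa_from_string(f">s\n{residues}\n", id=id)
    return build_profile(
        msa, ss=ss, pseudocount_alpha=0.0, background=UNIFORM_BG, id=id
    )


@pytest.fixture
def pure_profile_factory():
    return pure_profile
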