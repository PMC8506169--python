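import numpy as np
import pytest

from voxear import FractionationContext, load_tissue_library
from voxear.synthetic_plans import build_plan_set

SMALL_DIMS = (24, 24, 18)


@pytest.fixture(scope="session")
def library():
    return load_tissue_library()


@pytest.fixture(scope="session")
def ctx():
    return FractionationContext(n_fractions=15, rbe_factor=1.1)


@pytest.fixture(scope="session")
def unfractionated_ctx():
    """Single fraction, no RBE: alpha' == alpha, for closed-form checks."""
    return FractionationContext(n_fractions=1, rbe_factor=1.0)


@pytest.fixture(scope="session")
def small_plans(ctx):
    """Stage-1 plans for all four modality styles on a coarse shared phantom."""
    return build_plan_set(stage=1, ctx=ctx, dims=SMALL_DIMS, seed=7)
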