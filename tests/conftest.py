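import numpy as np
import pandas as pd
import pytest

from lnwire.glomeruli import GlomerulusMap
from lnwire.profiles import ProfileCollection


SMALL_NAMES = ("DA1", "VA1d", "VA1v", "DM5", "VL2a", "DL1", "D", "DM6")


@pytest.fixture
def small_map() -> GlomerulusMap:
    return GlomerulusMap(SMALL_NAMES)


def make_collection(matrix, map, brain_ids=None, hemispheres=None,
                    sex="female", mating_status="virgin"):
    """Build a collection from a binary matrix with minimal metadata."""
    matrix = np.asarray(matrix)
    n = matrix.shape[0]
    if brain_ids is None:
        brain_ids = [f"b{i}" for i in range(n)]
    if hemispheres is None:
        hemispheres = ["R"] * n
    sexes = [sex] * n if isinstance(sex, str) else list(sex)
    meta = pd.DataFrame({
        "brain_id": brain_ids, "hemisphere": hemispheres, "sex": sexes,
        "mating_status": [mating_status] * n, "genotype": ["syn"] * n,
        "condition": [""] * n})
    return ProfileCollection(map, meta, matrix)


@pytest.fixture
def make_coll(small_map):
    def _make(matrix, **kw):
        return make_collection(matrix, small_map, **kw)
    return _make
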