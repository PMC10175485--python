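import numpy as np
import pandas as pd
import pytest

import uvhotspot as uv
from uvhotspot.synthetic import DamageModelParams, default_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact default-parameter cohort shared across unit tests."""
    genome, regions, truth, params, cellular, naked = default_cohort(
        seed=11, n_sites=40)
    info, scaled = uv.scale_naked(cellular, naked, regions)
    return {
        "genome": genome, "regions": regions, "truth": truth,
        "params": params, "cellular": cellular, "naked": naked,
        "scaled": scaled, "info": info,
    }


def make_reads(rows):
    """BED6 DataFrame from (chrom, start, end, strand) tuples."""
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e, "name": ".", "score": 0,
          "strand": st} for c, s, e, st in rows])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
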