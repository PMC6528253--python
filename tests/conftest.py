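import numpy as np
import pytest

import platefit as pf


@pytest.fixture
def small_layout():
    """2x2 plate: test 0 in row A, test 10 in row B."""
    return pf.parse_layout([[0, 0], [10, 10]])


@pytest.fixture
def small_group(small_layout):
    return pf.bind_group(small_layout, "g", [[1, 3], [5, 7]])


@pytest.fixture
def dose_response_layout():
    """8 doses x 4 replicates, row-major on a 12-column plate, plus truth."""
    spec = pf.SimSpec(
        model=pf.FitModel.LOGISTIC4,
        truth=pf.Logistic4Params(bottom=0.0, top=100.0, ec50=1.0, hill=1.5),
        doses=(0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0),
        n_replicates=4,
        seed=11,
    )
    return pf.simulate_plate(spec) + (spec,)


def make_series(x, y, kind=pf.VariationKind.SD):
    """Build an AggregatedSeries directly from (x, y) arrays."""
    pts = tuple(
        pf.AggregatedPoint(x=float(xi), mean=float(yi), variation=None,
                           n_used=1, fully_masked=False)
        for xi, yi in sorted(zip(np.asarray(x, float), np.asarray(y, float)))
    )
    return pf.AggregatedSeries("series", pts, kind)
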