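import numpy as np
import pytest

from lactofit.dataio import LactationRecord
from lactofit.families import get_model

WOOD_PARAMS = (730.0, 0.26, 0.09)  # population-mean gamma curve

#: well-identified generating parameters per family (used for exact-recovery
#: tests; every curve is positive and finite on the fortnightly grid)
FAMILY_TRUE_PARAMS = {
    "wood": [730.0, 0.26, 0.09],
    "yadav": [600.0, -1500.0, -1.5],
    "dhanoa": [800.0, 0.012, 20.0, 0.08],
    "wilmink": [900.0, -600.0, -3.0, 0.08],
    "cappio_borlino": [500.0, 1.2, 0.02],
    "cobby_le_du": [800.0, 0.15, 0.008],
    "morant": [600.0, -0.8, -0.1, -2.0],
    "goodall": [730.0, 0.26, 0.09, 150.0],
    "grossman": [730.0, 0.26, 0.09, 0.05, -0.04],
}


@pytest.fixture
def fortnight_grid():
    """The fortnightly recording calendar out to DIM 140."""
    return np.arange(14.0, 141.0, 14.0)


@pytest.fixture
def noiseless_wood_lactation(fortnight_grid):
    """One lactation lying exactly on the population-mean Wood curve."""
    spec = get_model("wood")
    y = spec(WOOD_PARAMS, fortnight_grid)
    return LactationRecord(
        lactation_id="L1", goat_id="G1", herd=1, kidding_year=1998,
        kidding_month="Dec", litter_size="single", dam_age=3,
        dim=fortnight_grid, yield_g=np.atleast_1d(y),
    )


def make_lactation(dim, yield_g, lact_id="L1", **cov):
    defaults = dict(herd=1, kidding_year=1998, kidding_month="Dec",
                    litter_size="single", dam_age=3)
    defaults.update(cov)
    return LactationRecord(lactation_id=lact_id, goat_id="G" + lact_id[1:],
                           dim=np.asarray(dim, float),
                           yield_g=np.asarray(yield_g, float), **defaults)
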