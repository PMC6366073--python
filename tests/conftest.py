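import numpy as np
import pandas as pd
import pytest

from egmosaic import TaxonGroupMap


@pytest.fixture
def taxmap():
    return TaxonGroupMap(
        {
            "Kinetoplastida": {"KinA", "KinB", "KinC"},
            "Viridiplantae": {"PlantA", "PlantB", "PlantC"},
            "Metazoa": {"MetazoaA", "MetazoaB"},
        },
        focal_taxon="Eg",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def replicate_table():
    """Hand-written 3+3 replicate table covering the filter cases."""
    def row(det, vals):
        d = {f"det_light_{i+1}": bool(det[i]) for i in range(3)}
        d |= {f"det_dark_{i+1}": bool(det[3 + i]) for i in range(3)}
        d |= {f"val_light_{i+1}": vals[i] for i in range(3)}
        d |= {f"val_dark_{i+1}": vals[3 + i] for i in range(3)}
        return d

    nan = float("nan")
    data = {
        "full_both": row([1, 1, 1, 1, 1, 1], [100, 110, 90, 10, 9, 11]),
        "light_full_dark_zero": row([1, 1, 1, 0, 0, 0],
                                    [50, 55, 45, nan, nan, nan]),
        "dark_full_light_zero": row([0, 0, 0, 1, 1, 1],
                                    [nan, nan, nan, 20, 22, 18]),
        "light_full_dark_partial": row([1, 1, 1, 1, 0, 0],
                                       [80, 82, 78, 40, nan, nan]),
        "two_two": row([1, 1, 0, 1, 1, 0], [60, 62, nan, 30, 31, nan]),
        "equal_means": row([1, 1, 1, 1, 1, 1], [50, 50, 50, 50, 50, 50]),
    }
    return pd.DataFrame.from_dict(data, orient="index").rename_axis("id")
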