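import dendropy
import numpy as np
import pandas as pd
import pytest

from critdepth.soil_columns import STUDY_INCREMENTS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_increment_table(values_by_property, plots=("P1",), cls="dynamic"):
    """Long increment table over the six study increments.

    ``values_by_property``: property -> either a length-6 sequence (same for
    every plot) or a (n_plots, 6) array.
    """
    rows = []
    for prop, vals in values_by_property.items():
        vals = np.asarray(vals, dtype=float)
        if vals.ndim == 1:
            vals = np.tile(vals, (len(plots), 1))
        c = cls[prop] if isinstance(cls, dict) else cls
        for p, plot in enumerate(plots):
            for i, inc in enumerate(STUDY_INCREMENTS):
                rows.append((plot, prop, c, inc.top, inc.bottom, vals[p, i]))
    return pd.DataFrame(
        rows, columns=["plot_id", "property", "cls", "top_cm", "bottom_cm", "value"]
    )


@pytest.fixture
def simple_tree():
    """Cherry (A,B) plus outgroup C: A:1, B:2 on stem 3, C:4 from the root."""
    return dendropy.Tree.get(data="((A:1,B:2):3,C:4);", schema="newick")
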