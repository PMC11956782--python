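"""Shared fixtures.

``worked_example_*`` fixtures carry the published national worked example
(France, males aged 35-44, 2016): reported deaths for nine well-defined
cause groups plus the ill-defined category, and the OLS slopes estimated
across the 95 departments.  They let the rescaling/redistribution arithmetic
be checked against printed reference values without the (unavailable)
department-level source file.
"""

import numpy as np
import pandas as pd
import pytest

from ledermann import DeathsTable, SchemaConfig, StratumKey

CAUSES = [
    "infectious", "neoplasms", "circulatory", "respiratory", "digestive",
    "accidents", "suicides", "other_external", "other",
]

WORKED_DEATHS = pd.Series(
    [81, 1166, 685, 113, 396, 888, 956, 141, 618], index=CAUSES, dtype=float,
)
WORKED_DELTA = 927.0          # ill-defined deaths
WORKED_TOTAL = 5971.0         # all causes including ill-defined

# OLS slope column (negated regression slopes, already truncated at zero)
WORKED_SLOPES = pd.Series(
    [0.003, 0.0, 0.073, 0.007, 0.073, 0.218, 0.459, 0.0, 0.193],
    index=CAUSES, dtype=float,
)

# Printed reference columns for the same stratum.  The adjusted coefficients
# were rescaled from unrounded slopes before printing, so the tied printed
# slopes (0.073, 0.073) map to distinct printed coefficients (0.072, 0.071).
WORKED_LEDERMANN_COEFF = pd.Series(
    [0.003, 0.0, 0.072, 0.007, 0.071, 0.212, 0.447, 0.0, 0.188],
    index=CAUSES, dtype=float,
)
WORKED_LEDERMANN_DEATHS = pd.Series(
    [84, 1166, 752, 119, 462, 1085, 1370, 141, 792], index=CAUSES, dtype=float,
)
WORKED_PR_COEFF = pd.Series(
    [0.016, 0.231, 0.136, 0.022, 0.079, 0.176, 0.190, 0.028, 0.123],
    index=CAUSES, dtype=float,
)
WORKED_PR_DEATHS = pd.Series(
    [96, 1380, 811, 134, 469, 1051, 1132, 167, 731], index=CAUSES, dtype=float,
)


@pytest.fixture
def worked_example():
    return {
        "deaths": WORKED_DEATHS.copy(),
        "delta": WORKED_DELTA,
        "total": WORKED_TOTAL,
        "slopes": WORKED_SLOPES.copy(),
        "ledermann_coeff": WORKED_LEDERMANN_COEFF.copy(),
        "ledermann_deaths": WORKED_LEDERMANN_DEATHS.copy(),
        "pr_coeff": WORKED_PR_COEFF.copy(),
        "pr_deaths": WORKED_PR_DEATHS.copy(),
    }


@pytest.fixture
def toy_table():
    """Two areas, two well-defined causes plus ill-defined (hand arithmetic)."""
    counts = pd.DataFrame(
        {"c1": [8.0, 3.0], "c2": [2.0, 3.0], "illdef": [0.0, 4.0]},
        index=["A", "B"],
    )
    return DeathsTable(counts, "illdef", stratum=StratumKey(2016, "m", "35-44"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_deaths_table(rng, n_areas=6, n_causes=4, zero_area=False):
    """Random non-degenerate counts table used by property-style tests."""
    counts = rng.integers(0, 200, size=(n_areas, n_causes + 1)).astype(float)
    counts[:, 0] += 1.0  # keep at least one positive count per area
    if zero_area:
        counts[-1] = 0.0
    cols = [f"c{i}" for i in range(n_causes)] + ["illdef"]
    frame = pd.DataFrame(counts, columns=cols,
                         index=[f"a{i}" for i in range(n_areas)])
    return DeathsTable(frame, "illdef")


@pytest.fixture
def schema():
    return SchemaConfig(illdefined_label="illdef")
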