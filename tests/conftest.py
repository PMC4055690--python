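import numpy as np
import pandas as pd
import pytest

from ampdyn.io_formats import CommunityTable, TimeSeriesDesign, parse_newick
from ampdyn.synthetic import SyntheticParams, simulate_experiment

EXAMPLE_NEWICK = "((a:1,b:1):1,(c:1,d:1):1);"


@pytest.fixture
def example_tree():
    return parse_newick(EXAMPLE_NEWICK)


@pytest.fixture
def small_table():
    return CommunityTable(
        ["t1", "t2", "t3"],
        ["s1", "s2"],
        np.array([[3, 0], [2, 1], [5, 4]]),
    )


@pytest.fixture
def small_design():
    rows = []
    for region in ("V1V3", "V4"):
        for t in range(1, 5):
            for r in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{region}_t{t:02d}_r{r}",
                        "time_point": t,
                        "replicate": r,
                        "region": region,
                        "temperature": 20.0 + t,
                    }
                )
    return TimeSeriesDesign(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture(scope="session")
def default_experiment():
    """One simulated two-region experiment at the study defaults
    (12 months x 2 regions x 2 replicates, 2125 reads/sample)."""
    return simulate_experiment(SyntheticParams(seed=1))


@pytest.fixture(scope="session")
def small_experiment():
    """A cheaper simulation for pipeline plumbing tests."""
    return simulate_experiment(
        SyntheticParams(n_core=8, n_transient=12, T=6, depth=400, seed=3)
    )
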