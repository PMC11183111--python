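import numpy as np
import pandas as pd
import pytest

from orophylo import DatedTree, simulate_bm_trait, simulate_yule_tree


@pytest.fixture
def three_tip_tree() -> DatedTree:
    """The hand-checkable caterpillar ((A:1,B:1):1,C:2)."""
    return DatedTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def yule10() -> DatedTree:
    return simulate_yule_tree(10, 1.0, seed=42)


@pytest.fixture
def yule50() -> DatedTree:
    return simulate_yule_tree(50, 1.0, seed=7)


@pytest.fixture
def trait50(yule50) -> dict:
    return simulate_bm_trait(yule50, sigma2=1.0, seed=8)


@pytest.fixture
def landform_table() -> pd.DataFrame:
    """Predictor table with 5 landforms x 6 sites and numeric covariates."""
    rng = np.random.default_rng(11)
    landforms = np.repeat(
        ["karst", "karst-granitic", "granitic", "Danxia", "desert"], 6)
    n = len(landforms)
    return pd.DataFrame({
        "landform": landforms,
        "tectonic": rng.choice(["craton", "orogen"], n),
        "lon": rng.uniform(80, 130, n),
        "lat": rng.uniform(20, 50, n),
        "TCQ": rng.normal(size=n),
        "PREC": rng.normal(size=n),
    }, index=[f"s{i:02d}" for i in range(n)])
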