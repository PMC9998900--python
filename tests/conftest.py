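import numpy as np
import pandas as pd
import pytest

import multidiv as md

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:2):0.5);"


@pytest.fixture
def toy_tree() -> md.Phylogeny:
    return md.read_tree(TOY_NEWICK)


@pytest.fixture
def toy_traits() -> md.TraitTable:
    # five mixed-type traits over four species; pool height range 1.5 m
    df = pd.DataFrame(
        {
            "dispersal_type": ["wind", "animal", "wind", "water"],
            "growth_form": ["herb", "herb", "shrub", "herb"],
            "life_cycle": ["annual", "annual", "perennial", "annual"],
            "shoot_height": [0.5, 1.0, 2.0, 0.8],
            "flowering_phenology": [5, 5, 8, 6],
        },
        index=["A", "B", "C", "D"],
    )
    kinds = {
        "dispersal_type": "categorical",
        "growth_form": "categorical",
        "life_cycle": "categorical",
        "shoot_height": "continuous",
        "flowering_phenology": "ordinal",
    }
    return md.TraitTable(df, kinds, units={"shoot_height": "m"})


@pytest.fixture
def toy_community() -> md.CommunityMatrix:
    occ = np.array([[1, 1, 0, 0], [1, 1, 1, 0], [1, 0, 1, 1]], dtype=float)
    return md.CommunityMatrix(["s1", "s2", "s3"], ["A", "B", "C", "D"], occ)


@pytest.fixture
def toy_bundle(toy_community, toy_traits, toy_tree) -> md.DataBundle:
    return md.validate_bundle(toy_community, toy_traits, toy_tree)


@pytest.fixture
def random_distance():
    def make(n: int, seed: int = 0) -> md.DistanceMatrix:
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(seed)
        d = squareform(pdist(rng.normal(size=(n, 3))))
        return md.DistanceMatrix([f"s{i}" for i in range(n)], d)

    return make


@pytest.fixture(scope="session")
def neutral_bundle():
    bundle, _ = md.generate(md.scenario_presets()["neutral"], seed=3)
    return bundle
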