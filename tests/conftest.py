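import numpy as np
import pytest
from hypothesis import settings

from phylostand import parse_newick
from phylostand.community import PlotCommunity, TraitTable, TreeRecord
from phylostand.synthetic import SyntheticConfig, generate_study

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def simple_traits():
    return TraitTable(
        sla={"A": 4.0, "B": 8.0, "C": 12.0},
        mh={"A": 10.0, "B": 20.0, "C": 30.0},
        is_conifer={"A": True, "B": False, "C": False},
    )


def make_plot(stems, plot_id="p1", elevation=400.0, mat=10.0, map_mm=1300.0, age=45.0):
    return PlotCommunity(
        plot_id=plot_id,
        trees=[TreeRecord(species=s, dbh=d) for s, d in stems],
        elevation=elevation,
        mat=mat,
        map_mm=map_mm,
        stand_age=age,
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across tests (40 plots, 30 species)."""
    config = SyntheticConfig(
        n_pool=30, n_plots=40, richness_range=(3, 8), seed=7
    )
    return generate_study(config)
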