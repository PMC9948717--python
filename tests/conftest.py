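import dendropy
import numpy as np
import pandas as pd
import pytest

from betabef import CommunityTable, cophenetic_distances
from betabef.io import ENV_COLUMNS


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — all pairwise path lengths known by hand."""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_dist(three_tip_tree):
    return cophenetic_distances(three_tip_tree)


def make_table(cruise, counts, sites=None, taxa=None) -> CommunityTable:
    counts = np.asarray(counts)
    sites = sites or [f"s{i+1}" for i in range(counts.shape[0])]
    taxa = taxa or [f"t{j+1}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=sites, columns=taxa)
    return CommunityTable(cruise_id=cruise, counts=df).validate()


def make_metadata(tables, biomass=10.0) -> pd.DataFrame:
    rows = []
    for t in tables:
        for i, site in enumerate(t.site_ids):
            row = {"cruise": t.cruise_id, "site": site,
                   "bacterial_biomass": biomass + i, "hnf_biomass": 2.0}
            for k, col in enumerate(ENV_COLUMNS):
                row[col] = 10.0 + i + k
            rows.append(row)
    return pd.DataFrame(rows)
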