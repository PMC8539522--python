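"""Shared fixtures: toy tables, the bundled rule set and plate layout."""

import numpy as np
import pytest

from polarfunc.ecoplate import load_layout
from polarfunc.faprotax import load_regroup, load_rules
from polarfunc.zotu_io import ZotuTable, parse_taxonomy


@pytest.fixture(scope="session")
def mini_rules():
    return load_rules()


@pytest.fixture(scope="session")
def mini_regroup():
    spec, emap = load_regroup()
    return spec, emap


@pytest.fixture(scope="session")
def plate_layout():
    return load_layout()


@pytest.fixture
def toy_table():
    """3 ZOTUs x 2 samples with taxonomies hitting the bundled rules."""
    taxa = {
        "Zotu1": "Bacteria;Proteobacteria;Alpha;Sphingomonadales;Sphingomonadaceae;Sphingomonas",
        "Zotu2": "Bacteria;Proteobacteria;Delta;Desulfobacterales;Desulfobacteraceae;Desulfobacter",
        "Zotu3": "Bacteria;CandidateDivisionX",
    }
    return ZotuTable(
        zotu_ids=["Zotu1", "Zotu2", "Zotu3"],
        sample_ids=["L1", "L2"],
        counts=np.array([[120, 3], [5, 80], [10, 10]]),
        taxonomy={z: parse_taxonomy(t) for z, t in taxa.items()},
    )


@pytest.fixture
def toy_tsv(tmp_path, toy_table):
    from polarfunc.zotu_io import write_zotu_table

    path = tmp_path / "toy.tsv"
    write_zotu_table(toy_table, path)
    return path
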