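"""Shared fixtures: small hand-built tables, designs and gate files."""

import numpy as np
import pandas as pd
import pytest

from cytoboot import CellTable, GateDefinition, GateTree, StudyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_raw_table(rng):
    values = np.abs(rng.normal(3.0, 1.0, size=(50, 4)))
    meta = pd.DataFrame({"donor": ["d1"] * 25 + ["d2"] * 25, "group": "control"})
    return CellTable(values=values, channel_names=["CD38", "NKp46", "CD56", "CD16"], cell_meta=meta)


@pytest.fixture
def three_group_design():
    donors = pd.DataFrame(
        {
            "group": ["control", "control", "pregnant", "pregnant", "postpartum", "postpartum"],
            "cohort": "discovery",
        },
        index=pd.Index(["c1", "c2", "p1", "p2", "q1", "q2"], name="donor"),
    )
    return StudyDesign(donors=donors, pairing={"p1": "q1", "p2": "q2"})


@pytest.fixture
def nk_gate_tree():
    """Live lineage-negative NK conjunction: 5 threshold nodes."""
    return GateTree(
        gates=[
            GateDefinition("viability", 2.5, "below"),
            GateDefinition("CD3", 1.5, "below"),
            GateDefinition("CD19", 1.5, "below"),
            GateDefinition("CD14", 1.5, "below"),
            GateDefinition("CD56", 1.2, "above"),
        ],
        populations={},
        root_name="NK",
        scale="arcsinh",
    )
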