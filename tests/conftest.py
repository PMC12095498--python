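import numpy as np
import pandas as pd
import pytest

from palaeosed import PanelIndex, simulate_reference_panel
from palaeosed.reads import Fragment
from palaeosed.simulate import ReferencePanel


@pytest.fixture(scope="session")
def panel():
    """Standard 4-family synthetic panel (2 kb genomes, 5 diagnostics/group)."""
    return simulate_reference_panel(
        n_families=4, genome_length=2000, n_diag_per_group=5, seed=1)


@pytest.fixture(scope="session")
def index(panel):
    return PanelIndex(panel, k=16)


@pytest.fixture(scope="session")
def custom_group_panel():
    """Hand-built single-family panel with widely spaced diagnostic positions,
    for controlled group-call arithmetic."""
    rng = np.random.default_rng(42)
    genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    positions = [100, 400, 800, 1200, 1600]
    rows = []
    derived_map = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in positions:
        anc = genome[p - 1]
        rows.append({"group": "G1", "family": "TestFam", "genome": "TestFam_1",
                     "pos": p, "ancestral": anc, "derived": derived_map[anc],
                     "modern_specific": False, "damage_vulnerable": False})
    # a second group so "other-group" logic has something to look at
    for p in [250, 600, 1000]:
        anc = genome[p - 1]
        rows.append({"group": "G2", "family": "TestFam", "genome": "TestFam_1",
                     "pos": p, "ancestral": anc, "derived": derived_map[anc],
                     "modern_specific": False, "damage_vulnerable": False})
    table = pd.DataFrame(rows)
    return ReferencePanel(families=["TestFam"],
                          genomes={"TestFam": {"TestFam_1": genome}},
                          diagnostic_table=table)


def make_fragment(fid, seq, **kw):
    return Fragment(id=fid, sequence=seq, **kw)
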