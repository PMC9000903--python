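import numpy as np
import pandas as pd
import pytest

from faecalomics import SimulationConfig, make_reference_set


@pytest.fixture
def small_cfg():
    return SimulationConfig(
        seed=7,
        n_refs=20,
        n_reads_per_sample=300,
        multimap_family_sizes=(),
        per_base_error_rate=0.0,
    )


@pytest.fixture
def small_refs(small_cfg):
    return make_reference_set(small_cfg)


@pytest.fixture
def otu_fixture_3x2():
    """3 OTUs across 2 families, 2 samples, hand-checkable counts."""
    from faecalomics.containers import OtuTable, TAXONOMY_RANKS

    lineage = pd.DataFrame(
        [
            ["Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
             "Bacteroidaceae", "Bacteroides", "unassigned"],
            ["Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales",
             "Bacteroidaceae", "Bacteroides", "unassigned"],
            ["Bacteria", "Firmicutes", "Clostridia", "Oscillospirales",
             "Ruminococcaceae", "Faecalibacterium", "unassigned"],
        ],
        index=pd.Index(["OTU_1", "OTU_2", "OTU_3"], name="otu_id"),
        columns=list(TAXONOMY_RANKS),
    )
    counts = pd.DataFrame(
        {"S1": [10.0, 5.0, 85.0], "S2": [20.0, 20.0, 60.0]},
        index=lineage.index,
    )
    groups = pd.Series({"S1": "case", "S2": "control"})
    return OtuTable(counts, lineage, groups)
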