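import numpy as np
import pytest

from rtshift.io_formats import OtuTable, RepSeqSet, SampleMetadata, TaxonomyMap


@pytest.fixture
def toy_table() -> OtuTable:
    counts = np.array([[5, 0, 3], [1, 9, 2]])
    return OtuTable(["S1", "S2"], ["OTU1", "OTU2", "OTU3"], counts)


@pytest.fixture
def toy_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "OTU1": ("Bacteria", "Firmicutes", "Bacilli"),
            "OTU2": ("Bacteria", "Firmicutes", "Bacilli"),
            "OTU3": ("Bacteria", "Proteobacteria"),
        }
    )


@pytest.fixture
def toy_seqs() -> RepSeqSet:
    return RepSeqSet({"OTU1": "GCGC", "OTU2": "ATGC", "OTU3": "ATAT"})


def make_metadata(samples_per_condition: dict[tuple[str, float], list[str]]) -> SampleMetadata:
    enzyme, temp, repl = {}, {}, {}
    for (enz, t), samples in samples_per_condition.items():
        for i, s in enumerate(samples, start=1):
            enzyme[s] = enz
            temp[s] = float(t)
            repl[s] = f"R{i}"
    return SampleMetadata(enzyme, temp, repl)


@pytest.fixture
def four_condition_meta() -> SampleMetadata:
    return make_metadata(
        {
            ("ImProm-II", 42): [f"IP42_r{i}" for i in range(1, 5)],
            ("ImProm-II", 55): [f"IP55_r{i}" for i in range(1, 5)],
            ("SuperScript IV", 55): [f"SS55_r{i}" for i in range(1, 5)],
            ("TGIRT", 57): [f"TG57_r{i}" for i in range(1, 5)],
        }
    )
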