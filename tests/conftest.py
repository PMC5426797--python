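import pytest

from fernmir.identify import revcomp
from fernmir.io_formats import ReferenceMiRNA, load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


def star_of(mature: str) -> str:
    """Star strand with canonical 2-nt 3' overhang duplex geometry."""
    return revcomp(mature[:-2]) + "CC"


def make_reference(mirbase_id: str, sequence: str, high_confidence: bool = True) -> ReferenceMiRNA:
    return ReferenceMiRNA.from_id(mirbase_id, sequence, high_confidence)


@pytest.fixture(scope="session")
def reference_set():
    """Small mature-miRNA reference set (both arms) for identification tests."""
    families = {
        "166": "TCGGACCAGGCTTCATTCCCC",
        "390": "AAGCTCAGGAGGGATAGCGCC",
        "156": "TTGACAGAAGATAGAGAGCAC",
        "162": "GGAGGCAGCGGTTCATCGATC",
    }
    refs = []
    for num, mature in families.items():
        refs.append(make_reference(f"ath-miR{num}a-5p", mature))
        refs.append(make_reference(f"ath-miR{num}a-3p", star_of(mature)))
    return refs
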