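import pytest

from splicesat import GapSiteKey, SampleJunctions


def key(i: int, strand: str = "+") -> GapSiteKey:
    """Deterministic gap-site key for integer site id ``i``."""
    start = 100 * i + 21  # start > 20 so BED anchors stay on-sequence
    return GapSiteKey("chr1", start, start + 49, strand)


def batch(*site_id_sets) -> list[SampleJunctions]:
    """Build a batch of samples from sets of integer site ids."""
    return [
        SampleJunctions(f"s{idx + 1}", {key(i) for i in ids})
        for idx, ids in enumerate(site_id_sets)
    ]


@pytest.fixture
def abc_batch():
    """The worked three-sample batch: A={1,2}, B={2,3}, C={2}."""
    return batch({1, 2}, {2, 3}, {2})
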