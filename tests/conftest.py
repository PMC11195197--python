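import re

import pytest

from fbekit.motif import SYMBOL_SETS, ConsensusPattern, ElementMatch


@pytest.fixture
def gld1_rna():
    from fbekit.reference_data import GLD1_FBEA_FBEASTAR_RNA

    return GLD1_FBEA_FBEASTAR_RNA


def regex_scan(seq: str, pattern: ConsensusPattern, sequence_id: str = ""):
    """Independent matching oracle: degenerate consensus via a regex with
    character classes and an overlap-permitting lookahead."""
    classes = "".join(
        "[" + "".join(sorted(SYMBOL_SETS[s])) + "]" for s in pattern.symbols
    )
    rx = re.compile(f"(?=({classes}))")
    return [
        ElementMatch(sequence_id, pattern.name, m.start(), pattern.length, m.group(1))
        for m in rx.finditer(seq)
    ]
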