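import itertools
import re

import pytest
from hypothesis import HealthCheck, settings

from abascan import MotifPattern, load_motif_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def motif_set():
    return load_motif_set()


def oracle_spans(seq: str, pattern: MotifPattern) -> set[tuple[int, int]]:
    """Independent brute-force scanner: one fixed-width regular expression
    per gap-length vector, overlapping matches via a lookahead.  Returns
    the set of 1-based inclusive (start, end) spans."""
    spans: set[tuple[int, int]] = set()
    gap_ranges = [
        range(e.min_len, e.max_len + 1)
        for e in pattern.elements
        if e.kind == "gap"
    ]
    for vec in itertools.product(*gap_ranges):
        gaps = iter(vec)
        parts = []
        width = 0
        for el in pattern.elements:
            if el.kind == "anchor":
                parts.append("[" + "".join(sorted(el.allowed)) + "]")
                width += 1
            else:
                g = next(gaps)
                if g:
                    parts.append(f".{{{g}}}")
                width += g
        rx = re.compile("(?=(" + "".join(parts) + "))")
        for m in rx.finditer(seq):
            spans.add((m.start() + 1, m.start() + width))
    return spans
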