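"""Flexible-gap protein motif patterns and an exhaustive scanner.

The pattern grammar is the PROSITE-flavoured syntax used for candidate
abscisic-acid (ABA) binding sites and related signature motifs:

* a single canonical residue letter is an *anchor* (``D`` matches Asp only);
* a bracketed class ``[RSK]`` is an anchor matching any listed residue;
* ``.`` matches any single residue (a width-1 gap);
* ``.{m,n}`` is a flexible gap of between ``m`` and ``n`` residues.

No other regular-expression features are accepted; ``^ $ * + ?`` and friends
raise :class:`MotifSyntaxError` rather than being silently ignored.

Matching is boolean and exhaustive: :func:`scan_sequence` reports every
distinct ``(start, end)`` span for which *some* assignment of gap lengths
satisfies the pattern, including overlapping and nested spans.  Coordinates
are 1-based and inclusive at both ends throughout the package.
"""

from __future__ import annotations

import itertools
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .proteome_io import SequenceRecord

#: The twenty canonical amino-acid letters.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity / non-standard codes tolerated in sequences.  They never
#: satisfy an anchor class but do occupy gap positions.
AMBIGUOUS_AA = frozenset("BJOUXZ")
#: Full residue alphabet accepted in input sequences.
ACCEPTED_AA = CANONICAL_AA | AMBIGUOUS_AA


class MotifSyntaxError(ValueError):
    """Raised when a motif pattern string violates the grammar."""


@dataclass(frozen=True)
class MotifElement:
    """One element of a compiled pattern: an anchor class or a flexible gap.

    ``allowed`` is set for anchors only; ``min_len``/``max_len`` are the
    residue-count bounds of a gap (a bare ``.`` is a gap with both equal 1).
    """

    kind: str  # "anchor" or "gap"
    allowed: frozenset[str] | None = None
    min_len: int = 1
    max_len: int = 1

    def __post_init__(self) -> None:
        if self.kind == "anchor":
            if not self.allowed or not self.allowed <= CANONICAL_AA:
                raise MotifSyntaxError(
                    f"anchor class must be a nonempty subset of the canonical "
                    f"amino acids, got {self.allowed!r}"
                )
        elif self.kind == "gap":
            if not (0 <= self.min_len <= self.max_len):
                raise MotifSyntaxError(
                    f"gap bounds must satisfy 0 <= min <= max, "
                    f"got {{{self.min_len},{self.max_len}}}"
                )
        else:
            raise MotifSyntaxError(f"unknown element kind {self.kind!r}")

    @property
    def width_min(self) -> int:
        return 1 if self.kind == "anchor" else self.min_len

    @property
    def width_max(self) -> int:
        return 1 if self.kind == "anchor" else self.max_len


@dataclass(frozen=True)
class MotifPattern:
    """A compiled motif: ordered elements plus total span bounds."""

    name: str
    source_text: str
    elements: tuple[MotifElement, ...]
    span_min: int
    span_max: int

    @property
    def n_anchors(self) -> int:
        return sum(1 for e in self.elements if e.kind == "anchor")


@dataclass(frozen=True)
class MotifMatch:
    """One distinct (start, end) hit of a motif in a sequence (1-based,
    inclusive).  ``anchor_positions`` holds the position of each anchor
    element under the lexicographically smallest satisfying gap-length
    vector, which makes reported coordinates deterministic."""

    seq_id: str
    motif_name: str
    start: int
    end: int
    matched_text: str
    anchor_positions: tuple[int, ...]


@dataclass(frozen=True)
class MotifSite:
    """A maximal interval formed by transitively merging overlapping
    matches; the unit used when counting sites per protein (e.g. the two
    adenylate-cyclase catalytic centres of SOS2)."""

    seq_id: str
    motif_name: str
    start: int
    end: int
    n_matches: int


# ---------------------------------------------------------------------------
# Pattern parsing
# ---------------------------------------------------------------------------

def parse_motif(name: str, pattern_text: str) -> MotifPattern:
    """Compile ``pattern_text`` into a :class:`MotifPattern`.

    Raises :class:`MotifSyntaxError` on an empty pattern, characters outside
    the grammar, non-canonical letters in anchors, unterminated brackets or
    braces, and gaps with ``min > max``.
    """
    if not pattern_text:
        raise MotifSyntaxError("empty motif pattern")
    elements: list[MotifElement] = []
    i = 0
    text = pattern_text
    n = len(text)
    while i < n:
        c = text[i]
        if c == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise MotifSyntaxError(f"unterminated '[' at position {i} in {text!r}")
            letters = text[i + 1 : j]
            if not letters:
                raise MotifSyntaxError(f"empty residue class at position {i} in {text!r}")
            bad = set(letters) - CANONICAL_AA
            if bad:
                raise MotifSyntaxError(
                    f"non-canonical letter(s) {sorted(bad)} in class at position {i}"
                )
            elements.append(MotifElement("anchor", allowed=frozenset(letters)))
            i = j + 1
        elif c == ".":
            if i + 1 < n and text[i + 1] == "{":
                j = text.find("}", i + 2)
                if j < 0:
                    raise MotifSyntaxError(f"unterminated '{{' at position {i + 1} in {text!r}")
                body = text[i + 2 : j]
                parts = body.split(",")
                if len(parts) != 2:
                    raise MotifSyntaxError(
                        f"gap bounds must be '{{min,max}}', got '{{{body}}}'"
                    )
                try:
                    lo, hi = int(parts[0]), int(parts[1])
                except ValueError as exc:
                    raise MotifSyntaxError(f"non-integer gap bound in '{{{body}}}'") from exc
                if lo < 0 or lo > hi:
                    raise MotifSyntaxError(f"invalid gap bounds {{{lo},{hi}}} (need 0 <= min <= max)")
                elements.append(MotifElement("gap", min_len=lo, max_len=hi))
                i = j + 1
            else:
                elements.append(MotifElement("gap", min_len=1, max_len=1))
                i += 1
        elif c in CANONICAL_AA:
            elements.append(MotifElement("anchor", allowed=frozenset(c)))
            i += 1
        else:
            raise MotifSyntaxError(f"unexpected character {c!r} at position {i} in {text!r}")
    span_min = sum(e.width_min for e in elements)
    span_max = sum(e.width_max for e in elements)
    return MotifPattern(name, pattern_text, tuple(elements), span_min, span_max)


def load_motif_set(source: str | Path | None = None) -> dict[str, MotifPattern]:
    """Load a ``name = "pattern"`` TOML motif set.

    With no argument the packaged default set is loaded (the stringent and
    relaxed ABA-site motifs, the two adenylate-cyclase signature variants and
    the SH3 consensus).
    """
    if source is None:
        raw = resources.files("abascan.data").joinpath("motifs.toml").read_text()
        table = tomllib.loads(raw)
    else:
        with open(source, "rb") as fh:
            table = tomllib.load(fh)
    motifs: dict[str, MotifPattern] = {}
    for name, pattern in table.items():
        if not isinstance(pattern, str):
            raise MotifSyntaxError(f"motif {name!r}: pattern must be a string")
        motifs[name] = parse_motif(name, pattern)
    return motifs


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def gap_length_vectors(motif: MotifPattern) -> Iterator[tuple[int, ...]]:
    """All gap-length vectors of ``motif`` in lexicographic order."""
    ranges = [
        range(e.min_len, e.max_len + 1) for e in motif.elements if e.kind == "gap"
    ]
    return itertools.product(*ranges)


def scan_sequence(record: "SequenceRecord", motif: MotifPattern) -> list[MotifMatch]:
    """Find every distinct (start, end) span of ``motif`` in ``record``.

    Exhaustive backtracking over gap-length assignments; overlapping and
    nested spans are all reported.  Spans are deduplicated on (start, end)
    and the anchors of the lexicographically smallest gap vector are kept.
    The result is sorted by (start, end).
    """
    seq = record.residues
    n = len(seq)
    elements = motif.elements
    if n < motif.span_min:
        return []
    # Minimal residues still needed from element i onwards, for pruning.
    suffix_min = [0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        suffix_min[i] = suffix_min[i + 1] + elements[i].width_min

    found: dict[tuple[int, int], tuple[int, ...]] = {}
    anchors: list[int] = []

    def extend(idx: int, start: int, pos: int) -> None:
        if pos + suffix_min[idx] > n:
            return
        if idx == len(elements):
            key = (start, pos)
            if key not in found:
                found[key] = tuple(anchors)
            return
        el = elements[idx]
        if el.kind == "anchor":
            if seq[pos] in el.allowed:  # ambiguity codes are never in `allowed`
                anchors.append(pos)
                extend(idx + 1, start, pos + 1)
                anchors.pop()
        else:
            for g in range(el.min_len, el.max_len + 1):
                if pos + g + suffix_min[idx + 1] > n:
                    break
                extend(idx + 1, start, pos + g)

    first = elements[0]
    if first.kind == "anchor":
        starts: Iterable[int] = (i for i, c in enumerate(seq) if c in first.allowed)
    else:
        starts = range(n)
    for s in starts:
        extend(0, s, s)

    matches = []
    for (s0, e0) in sorted(found):
        matches.append(
            MotifMatch(
                seq_id=record.seq_id,
                motif_name=motif.name,
                start=s0 + 1,
                end=e0,  # e0 is exclusive 0-based == inclusive 1-based end
                matched_text=seq[s0:e0],
                anchor_positions=tuple(p + 1 for p in found[(s0, e0)]),
            )
        )
    return matches


def merge_matches(matches: list[MotifMatch]) -> list[MotifSite]:
    """Merge overlapping matches (transitive closure of >=1 shared position)
    into maximal :class:`MotifSite` intervals, sorted by start.

    All matches must share ``seq_id`` and ``motif_name``.
    """
    if not matches:
        return []
    keys = {(m.seq_id, m.motif_name) for m in matches}
    if len(keys) > 1:
        raise ValueError(f"merge_matches: mixed seq_id/motif_name: {sorted(keys)}")
    seq_id, motif_name = next(iter(keys))
    ordered = sorted(matches, key=lambda m: (m.start, m.end))
    sites: list[MotifSite] = []
    cur_start, cur_end, count = ordered[0].start, ordered[0].end, 1
    for m in ordered[1:]:
        if m.start <= cur_end:  # shares at least one position
            cur_end = max(cur_end, m.end)
            count += 1
        else:
            sites.append(MotifSite(seq_id, motif_name, cur_start, cur_end, count))
            cur_start, cur_end, count = m.start, m.end, 1
    sites.append(MotifSite(seq_id, motif_name, cur_start, cur_end, count))
    return sites


def expected_match_count(
    motif: MotifPattern,
    residue_freqs: Mapping[str, float],
    total_residues: int,
) -> float:
    """Expected number of distinct (start, end) hits of ``motif`` on an
    i.i.d. background sequence of ``total_residues`` residues.

    Computed as a union bound: the sum, over start positions and gap-length
    vectors, of the product of anchor-class probabilities.  Because two gap
    vectors can realise the same (start, end) span, this slightly
    *over*-counts distinct spans; it is documented and tested as an
    upper-bound approximation.
    """
    total = sum(residue_freqs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"residue frequencies sum to {total}, not 1")
    anchor_p = 1.0
    for el in motif.elements:
        if el.kind == "anchor":
            anchor_p *= sum(residue_freqs.get(a, 0.0) for a in el.allowed)
    n_anchors = motif.n_anchors
    expectation = 0.0
    for vec in gap_length_vectors(motif):
        span = n_anchors + sum(vec)
        n_starts = max(0, total_residues - span + 1)
        expectation += n_starts * anchor_p
    return expectation
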