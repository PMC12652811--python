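"""Proteome-wide scanning and the candidate table.

Runs a motif set over a proteome, collapses raw matches into merged sites,
and builds the candidate table: one row per protein that carries at least
one merged site of the *primary* motif (candidacy is presence-based, not
score-based), with per-motif site counts and presence flags for every motif
in the set — the analogue of listing candidate ABA-binding proteins with
their secondary-motif annotations.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .motifs import MotifMatch, MotifPattern, merge_matches, scan_sequence
from .proteome_io import SequenceRecord, TableError, _open_read, _open_write


@dataclass(frozen=True)
class CandidateRecord:
    """Per-protein motif content: merged-site counts and presence flags."""

    seq_id: str
    description: str
    site_counts: Mapping[str, int]
    flags: Mapping[str, bool]


@dataclass(frozen=True)
class CandidateSummary:
    """Counts over a candidate list: total candidates, candidates flagged
    per motif, candidates whose description contains each queried substring
    (case-insensitive), and the cross-tabulation of the two."""

    total: int
    motif_counts: Mapping[str, int]
    substring_counts: Mapping[str, int]
    substring_motif_counts: Mapping[tuple[str, str], int]


def scan_proteome(
    records: Sequence[SequenceRecord], motifs: Sequence[MotifPattern]
) -> list[MotifMatch]:
    """Scan every motif over every record; deterministic concatenation in
    (record, motif) input order."""
    if not motifs:
        raise ValueError("scan_proteome requires at least one motif")
    seen: set[str] = set()
    for rec in records:
        if rec.seq_id in seen:
            raise ValueError(f"duplicate sequence id {rec.seq_id!r}")
        seen.add(rec.seq_id)
    matches: list[MotifMatch] = []
    for rec in records:
        for motif in motifs:
            matches.extend(scan_sequence(rec, motif))
    return matches


def merged_sites_by_protein(
    matches: Iterable[MotifMatch],
) -> dict[tuple[str, str], list]:
    """Group matches by (seq_id, motif) and merge each group into sites."""
    grouped: dict[tuple[str, str], list[MotifMatch]] = defaultdict(list)
    for m in matches:
        grouped[(m.seq_id, m.motif_name)].append(m)
    return {key: merge_matches(ms) for key, ms in grouped.items()}


def build_candidates(
    matches: Iterable[MotifMatch],
    primary: str,
    motif_names: Sequence[str] | None = None,
    descriptions: Mapping[str, str] | None = None,
) -> list[CandidateRecord]:
    """Build the candidate table: proteins with >=1 merged site of the
    ``primary`` motif, with merged-site counts for every motif.

    ``motif_names`` fixes the motif universe (so motifs with zero hits still
    appear as count-0 columns); when omitted it is inferred from the matches.
    ``descriptions`` maps seq_id to the protein description shown in the
    table (defaults to empty).
    """
    matches = list(matches)
    names = list(motif_names) if motif_names is not None else sorted(
        {m.motif_name for m in matches}
    )
    if primary not in names:
        raise ValueError(f"primary motif {primary!r} not in motif set {names}")
    sites = merged_sites_by_protein(matches)
    counts: dict[str, dict[str, int]] = defaultdict(lambda: {n: 0 for n in names})
    for (seq_id, motif_name), site_list in sites.items():
        if motif_name in counts[seq_id]:
            counts[seq_id][motif_name] = len(site_list)
    descriptions = descriptions or {}
    candidates = []
    for seq_id in sorted(counts):
        site_counts = counts[seq_id]
        if site_counts[primary] < 1:
            continue
        candidates.append(
            CandidateRecord(
                seq_id=seq_id,
                description=descriptions.get(seq_id, ""),
                site_counts=dict(site_counts),
                flags={n: c >= 1 for n, c in site_counts.items()},
            )
        )
    return candidates


def summarize(
    candidates: Sequence[CandidateRecord],
    name_substrings: Sequence[str] = ("DNAJ",),
) -> CandidateSummary:
    """Summary counts over a candidate table.

    Substring matching on descriptions is case-insensitive; the
    cross-tabulation answers questions like "how many DNAJ candidates carry
    the SH3 consensus" (none, in the reported candidate set).
    """
    motif_names = sorted({n for c in candidates for n in c.flags})
    motif_counts = {
        n: sum(1 for c in candidates if c.flags.get(n, False)) for n in motif_names
    }
    substring_counts: dict[str, int] = {}
    cross: dict[tuple[str, str], int] = {}
    for sub in name_substrings:
        hits = [c for c in candidates if sub.lower() in c.description.lower()]
        substring_counts[sub] = len(hits)
        for n in motif_names:
            cross[(sub, n)] = sum(1 for c in hits if c.flags.get(n, False))
    return CandidateSummary(
        total=len(candidates),
        motif_counts=motif_counts,
        substring_counts=substring_counts,
        substring_motif_counts=cross,
    )


def write_candidate_table(
    candidates: Sequence[CandidateRecord],
    dest,
    motif_names: Sequence[str] | None = None,
) -> None:
    """Write candidates as TSV: ``seq_id description <motif>_sites...
    <motif>_flag...``, sorted by seq_id."""
    if motif_names is None:
        motif_names = sorted({n for c in candidates for n in c.site_counts})
    header = (
        ["seq_id", "description"]
        + [f"{n}_sites" for n in motif_names]
        + [f"{n}_flag" for n in motif_names]
    )
    with _open_write(dest) as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for c in sorted(candidates, key=lambda c: c.seq_id):
            writer.writerow(
                [c.seq_id, c.description]
                + [c.site_counts.get(n, 0) for n in motif_names]
                + [int(c.flags.get(n, False)) for n in motif_names]
            )


def read_candidate_table(source) -> list[CandidateRecord]:
    """Read a candidate TSV written by :func:`write_candidate_table`."""
    with _open_read(source) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableError("empty candidate table") from None
        if header[:2] != ["seq_id", "description"]:
            raise TableError(f"bad candidate-table header {header!r}")
        site_cols = [(i, h[: -len("_sites")]) for i, h in enumerate(header)
                     if h.endswith("_sites")]
        flag_cols = {h[: -len("_flag")]: i for i, h in enumerate(header)
                     if h.endswith("_flag")}
        out = []
        for row in reader:
            if not row:
                continue
            site_counts = {name: int(row[i]) for i, name in site_cols}
            flags = {name: bool(int(row[i])) for name, i in flag_cols.items()}
            out.append(CandidateRecord(row[0], row[1], site_counts, flags))
    return out
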